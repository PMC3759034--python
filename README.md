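# icarank

GLM and spatial-ICA analysis of motion-contaminated block-design task
fMRI, with feature-based automatic ranking of independent components.

## The problem

Clinical task fMRI at very high field (7 T) — presurgical motor mapping
in particular — suffers from head motion that is time-locked to the task
(chin and hand movement). Stimulus-correlated motion produces false
positives in the standard general linear model (GLM) analysis: edge
rims, ventricle outlines, fluctuating Nyquist ghosts and parallel-imaging
reconstruction errors all share the task's time course and survive
motion-parameter confound regression. Spatial independent component
analysis (ICA) separates these sources by their spatial independence
instead of their temporal similarity to the task, but produces hundreds
of variance-ordered components in which the activation typically sits
far down the list.

`icarank` implements both analysis paths and the piece that makes the
ICA path practical: automatic ranking of components by three simple
features, so the activation component is found at (or near) the top of a
sorted list instead of by visual inspection of every map:

* **glmcorr** — Pearson correlation between the unthresholded component
  map and the unthresholded GLM z-map over in-brain voxels;
* **templatecorr** — correlation between the component map and a binary
  anatomical template (e.g. a precentral-gyrus atlas mask) on the data
  grid;
* **speccorr** — correlation between the magnitude spectra of the
  component time course and of the predicted response
  (boxcar ⊛ double-gamma HRF). Magnitude spectra are invariant to
  response delay, so this feature tolerates atypical hemodynamics and
  late task performance while ignoring slow drift.

Rankings sort by |r| (component sign is arbitrary); ties break by
variance ordering.

Because no suitable public 7 T patient data exist, the package ships a
first-class synthetic-data module: ground-truthed 4D phantoms with the
standard block timing (four rest + three task phases of eight volumes,
TR 2.5 s, 56 volumes per run), focal activation, and every artifact
class above injected as a spatial-map × time-course source with
controllable task correlation. Every downstream stage is validated
against this ground truth.

## Worked example

```python
import icarank as ir

spec = ir.PhantomSpec(seed=42)        # 4 runs x 56 volumes, 32x32x16 grid,
res = ir.analyze_phantom(spec)        # 1.5% psc activation, artifacts at r=0.8
rep = res["report"]

print("model order:", res["model_order"])
print("truth-matched component:", rep["matched_component"],
      f"(spatial r = {rep['match_r']:.2f})")
print("rank by variance / glmcorr / templatecorr / speccorr:",
      rep["ranks"]["variance"], rep["ranks"]["glmcorr"],
      rep["ranks"]["templatecorr"], rep["ranks"]["speccorr"])
print(f"contamination: GLM {rep['glm_contamination']:.2f}, "
      f"ICA {rep['ica_contamination']:.2f}")
```

prints

```
model order: 108
truth-matched component: 3 (spatial r = 0.84)
rank by variance / glmcorr / templatecorr / speccorr: 4 1 1 1
contamination: GLM 0.96, ICA 0.34
```

Reading this: the Laplace-evidence model-order estimate decomposed the
patient into 108 components; the component whose map best matches the
true activation (spatial r = 0.84) is ranked **first** by all three
features but only fourth by variance — the situation the features exist
to fix. 96 % of the GLM's suprathreshold voxels fall in artifact
territory, against 34 % for the thresholded top-ranked component: the
GLM map is dominated by stimulus-correlated artifacts the ICA path
isolates into other components. The top of the ranking table
(`res["ranking"].to_frame()`):

```
 component  var_pct  glmcorr  templatecorr  speccorr
         3    1.226   -0.539        -0.838     0.909
         2    1.950    0.304         0.046     0.604
         0   17.581   -0.380         0.022     0.672
```

## Command line

Each stage is also a CLI command over NIfTI/TSV files:

```bash
icarank simulate --config spec.yaml --out patient/ --seed 7
icarank preprocess patient/data.nii patient/brain_mask.nii --out pre.nii \
        --highpass-sigma 20 --grand-mean 10000
icarank glm pre.nii patient/brain_mask.nii --motion patient/motion.tsv \
        --out glm/ --z-thresh 2.3 --cluster-p 0.05
icarank ica patient/data.nii patient/brain_mask.nii --out ica/ --seed 7
icarank rank --ica-dir ica/ --zmap glm/zstat.nii \
        --template patient/truth_motor_left.nii \
        --mask patient/brain_mask.nii --out rank/
```

`ica` writes a melodic-style layout (`melodic_IC.nii`, `melodic_mix.tsv`,
`melodic_FTmix.tsv`, `stats.json`) readable by third-party IC tools.

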