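# Methods

`icarank` implements a complete analysis chain for block-design motor fMRI
contaminated by stimulus-correlated motion, together with a ground-truthed
synthetic data generator that emulates the artifact phenomenology of
ultra-high-field (7 T) EPI. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Signal model of the synthetic phantom

A phantom run is 56 volumes at TR = 2.5 s on a 32 × 32 × 16 voxel grid:
four rest and three task phases of eight volumes each, rest first
(ABABABA). The grid is deliberately desk-scale — roughly a factor four
per axis below a 7 T acquisition matrix — so the full pipeline runs in
seconds; all temporal parameters are kept at their acquisition values.

The data are purely additive:

```
y(v, t) = B
        + Σ_r  1_r(v) · (psc_r/100 · B) · a_r · h_r(t)      activation
        + Σ_a  M_a(v) · A_a · c_a(t)                        artifacts
        + d(t) · 1_brain(v)                                  drift
        + ε(v, t),   ε ~ N(0, σ²)                            noise
```

* `B` — baseline, 1000 arbitrary units, which makes percent-signal-change
  arithmetic transparent (a 1.5 % psc is an amplitude of 15 units).
* `h_r(t)` — the boxcar convolved with the canonical double-gamma HRF,
  normalized to unit plateau, shifted by the region's response delay.
  With noise off, the configured psc is therefore exact at the response
  peak (tested to 1e-6).
* Activation geometry: two superior "motor" blobs (left/right, 1.5 % psc,
  ~55 voxels each) sharing one time course, and one central "subcortical"
  blob (0.75 % psc, response delayed 2.5 s) — the cortical/subcortical
  distinction the evaluation tables care about. Per-run amplitudes `a_r`
  allow runs to differ (e.g. activation confined to one run).
* Artifact footprints `M_a` are deterministic functions of the geometry:
  a one-voxel brain-edge shell weighted toward the anterior/posterior
  faces (in-plane motion at contrast boundaries), a one-voxel shell
  around the ventricles (through-plane / spin-history effects), the brain
  mask circularly shifted by half the field of view along the
  phase-encode axis (N/2 Nyquist ghost; the phase-encode axis is pinned
  to the second grid axis), and a broad patchy in-brain map built from a
  fixed-seed smoothed noise field (parallel-imaging reconstruction
  errors).
* Artifact time courses are unit-variance mixes of the task boxcar and
  orthogonalized noise, so the empirical task correlation equals the
  target exactly (default 0.8 for the edge/ventricle/ghost sources;
  the reconstruction-noise source is an integrated random walk).
* Drift is per-run linear plus half-cosine with random coefficients,
  amplitude 10 units: the decomposition is expected to isolate it, so
  some drift must exist to test that.
* Noise is i.i.d. Gaussian, σ = 5 (temporal SNR 200) — a high-field,
  large-voxel regime in which thermal noise is modest and artifacts, not
  noise, dominate the variance budget.

Artifacts are injected as spatial-map × time-course sources rather than
by resampling volumes through rigid-body transforms. This matches the
observed phenomenology of motion at very high field (edge rims, ghost
fluctuation, reconstruction errors — effects that are not voxel shifts)
and gives exact ground truth for every source; it does not emulate
interpolation artifacts of genuine re-registration, spin-history
history-dependence, or susceptibility distortion, so passing tests say
nothing about those mechanisms.

The simulated motion-parameter table concentrates the stimulus
correlation on the anterior-posterior translation (full target r) and
the through-plane translation (half), with the remaining axes as random
walks. Six independent equally-correlated columns would jointly span the
task direction almost perfectly and the confound regression would then
remove the stimulus-locked artifacts entirely — the opposite of what is
observed in practice, where motion parameters are an imperfect proxy of
artifact dynamics. Default magnitudes are 0.4 mm RMS translation and
0.008 rad summed rotation (the chin-task scale).

## Design objects

The boxcar regressor alternates rest-first; with exactly one more task
phase than rest phases the only alternating arrangement starts with
task, and larger imbalances are rejected. The canonical HRF is the
difference of two gamma densities (response delay 6 s, undershoot delay
16 s, unit dispersions, response:undershoot ratio 6, onset 0) sampled at
TR over a 32 s window and scaled to unit peak — the scale cancels in all
correlation-based quantities. The predicted response is the linear
(truncated, not circular) convolution of boxcar and HRF. Spectra are
magnitudes of the real FFT at non-negative frequencies; magnitude rather
than power is used throughout, and the DC bin, retained in the
container, is excluded from feature correlations.

## Preprocessing

Grand-mean scaling multiplies the whole 4D array by a single factor so
the in-mask grand mean reaches the target (default 10000). The high-pass
filter is Gaussian-weighted running-line fitting: at each time point a
straight line is fitted by weighted least squares with Gaussian weights
(σ = 20 s) centred there and its value subtracted; the series mean is
re-added afterwards so percent signal change stays interpretable. The
filter is implemented as a precomputed N × N linear operator applied to
all voxels at once, and is exactly linear up to that mean convention.
By default it is applied to the concatenated series; a per-run mode
exists. Motion summaries reduce the six columns to per-volume RMS
translation (square root of the mean of the three squared translations)
and the sum of the magnitudes of the three rotation angles.

Rigid-body motion correction and inter-run registration are not
performed here: the ICA path is designed to run without motion
correction, and registration of real acquisitions is delegated to
external tools.

## GLM

The design matrix holds the predicted response, optionally the six
motion parameters and their first differences (leading element zero),
and one intercept per run — temporal concatenation with per-run
intercepts is a fixed-effects analysis. Rank deficiency is rejected with
the offending columns named.

Serial correlation is handled by AR(1) prewhitening: an OLS pass
estimates the lag-1 residual autocorrelation per voxel; the coefficient
map is regularized by Gaussian smoothing within the mask (σ = 2 voxels),
quantized to 0.01-wide bins, and each bin's voxels are refitted with the
AR(1)-whitened design and data. The binning keeps the per-voxel
transform cost at a few hundred design factorizations instead of one per
voxel. Run boundaries are ignored by the whitening transform (one
transition sample per boundary); full FILM-style autocovariance
modelling is out of scope, and the calibration of the resulting z-values
is verified by simulation instead (white-noise z is standard normal to
KS ≈ 0.01 at 16k voxel fits; the prewhitening noise inflates the SD by
about 2 % at 56 volumes).

Smoothness is estimated from variance-normalized residuals: per axis,
FWHM = sqrt(4 ln 2 / var(Δe)) with Δe the spatial first differences, and
RESELs = in-mask voxels / Π FWHM. On unsmoothed lattice noise this gives
the theoretical sqrt(2 ln 2) ≈ 1.18 voxels; kernel-smoothed noise is
recovered with the intrinsic lattice smoothness adding in quadrature.

Cluster inference thresholds the z-map (default Z > 2.3) into
26-connected components (connectivity pinned in config) and assigns each
cluster a corrected p from the Gaussian-random-field Poisson-clumping
approximation: the expected cluster count is the 3D Euler-characteristic
density times the RESEL count, the expected cluster size comes from the
expected suprathreshold volume, and cluster size survives as
exp(−βk^(2/3)) with β matched to that mean. A minimum-extent filter and
a no-cluster-threshold mode (voxel threshold only) are available.

Monte-Carlo validation of this approximation showed the mean-matched
formula grows conservative as smoothness falls below ~2.5 voxels FWHM
(the empirical cluster-size tail decays 1.1–1.6× faster than the model,
converging to the model with increasing smoothness — the approximation
is asymptotic in threshold and smoothness). The calibration suite
therefore evaluates the family-wise error where GRF theory is considered
applicable, on 3-voxel-FWHM Gaussian null fields: measured FWE ≈ 0.02 at
nominal 0.05 over 500 simulations, i.e. valid and mildly conservative.
Null fields are scaled by the theoretical smoothed-noise SD; normalizing
each field by its empirical SD would condition away high-variance
realizations and bias the measured FWE toward zero.

## ICA

The decomposition follows the melodic convention: in-mask voxels are
samples, time points dimensions. Voxels are de-meaned and
variance-normalized over time, whitened by PCA to n dimensions, and
unmixed by symmetric fixed-point iteration with a logcosh contrast
(max 1000 iterations, tolerance 1e-6, seeded); non-convergence is
flagged and the final iterate returned. One practical consequence of the
voxelwise variance normalization: every voxel, however quiet, carries
unit variance into the decomposition, which bounds the achievable
spatial correlation between a component map and a small binary truth
mask (≈ 0.85 for ~2 % masks at these noise levels; exactly 1 only for
noise-free sources).

The model order is the argmax of the Laplace approximation to the
Bayesian evidence of a probabilistic-PCA model over the covariance
eigenspectrum. Numerically zero trailing eigenvalues (sample centering
removes one rank) are trimmed first; a zero tail makes the
saturated-rank evidence degenerate. The implementation agrees with an
independent reference implementation of the same criterion to machine
precision and recovers planted ranks exactly in tests. On default
phantoms the estimated order is large (≈ 100–120 of 224 time points),
echoing the very high model orders reported for artifact-rich high-field
data.

Maps are z-scored over in-mask voxels; mixing time courses and
per-component variance fractions come from the least-squares
back-projection of the normalized data onto the sources, with
var-explained as each rank-1 term's share of total variance (sums to
≤ 100 % because the sources are near-orthogonal in the whitened space).
Components are ordered by variance explained.

Thresholding of a component map fits 1-, 2- and 3-class Gaussian
mixtures by EM and selects by BIC; the heaviest-weight class is
background and voxels with non-background posterior above 0.5 are
retained. When the single-Gaussian null wins (or EM collapses), a z > 3
cutoff is used and flagged. Gaussian classes are used for all
components, a simplification relative to melodic's Gaussian+gamma
mixture.

## Ranking features

* `glmcorr` — Pearson correlation between the unthresholded component
  map and the unthresholded z-map over in-brain voxels.
* `templatecorr` — correlation between the component map and a binary
  template on the data grid. For real data the template is an atlas
  label mask (nearest-neighbour resampled; registration delegated); on
  phantoms the truth motor mask plays the template's role.
  Unthresholded maps are used, for consistency with `glmcorr`.
* `speccorr` — correlation of the magnitude spectra of the component
  time course and the predicted response over non-DC bins. The magnitude
  spectrum is exactly invariant to circular delay (tested to 1e-12),
  which is the feature's purpose: sensitivity to delayed or
  atypically-timed responses, insensitivity to slow drift.

Rankings sort by |r| descending: component sign is arbitrary, so signed
ranking would be seed-dependent. Ties break by the variance ordering.
Raw signed scores are reported alongside ranks.

## Evaluation

VOI time courses average a 9 × 9 × 9 cuboid (half-width 4, clipped at
grid boundaries) around a peak voxel, then average across runs
volume-by-volume. Detection statuses are explicit rule-based analogues
of an expert's yes / qualified-yes / no reading: `y` needs ≥ 5
suprathreshold voxels in the region and overall artifact contamination
≤ 0.3; any overlap with a failed condition gives `qualified_y`; no
overlap gives `n`. Both thresholds are configurable and reported with
the statuses. Contamination is the fraction of suprathreshold voxels
inside the union of artifact footprints, excluding true activation
regions from that union (the ghost and reconstruction footprints
legitimately overlap activation on this grid, and a correct detection
should not count as contamination). The method comparison scores the
GLM's significant-cluster map against the mixture-thresholded map of the
top template-ranked component, and reports the truth-matched component's
rank under all four orderings.

## Problem sizes and known limitations

The acceptance ensemble is ten phantoms of 4 runs × 56 volumes at
32 × 32 × 16 (about 25 s per patient end-to-end on one core); the FWE
calibration uses 500 null fields. These sizes were chosen so the whole
validation runs in minutes on a laptop while keeping every rate estimate
stable to a few percent.

What passing tests do not show: the generator has no anatomy, no
k-space/GRAPPA physics, no susceptibility distortion, and motion enters
as additive sources rather than rigid-body resampling, so conclusions
about real-data performance rest on the artifact phenomenology being
representative, not on the physics being simulated. Registration,
skull-stripping and bias correction are out of scope. The GRF cluster p
is mildly conservative at low smoothness (documented above). The
variance ordering of the activation component on phantoms (typically
position 4–7) is qualitatively, not quantitatively, comparable to real
high-field data, where activation ranks far lower among hundreds of
components.
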