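"""Ground-truthed 4D phantoms emulating 7 T block-design motor fMRI runs.

Each phantom run is 56 volumes at TR 2.5 s (four rest and three task
phases of eight volumes, ABABABA), containing focal activation plus the
artifact classes that head motion produces in high-field EPI:

* ``edge_rim`` — partial-volume signal change on the brain edge,
  weighted toward the anterior/posterior faces (in-plane motion);
* ``ventricle_outline`` — a one-voxel shell around the ventricles
  (through-plane motion / spin-history effects);
* ``nyquist_ghost`` — a copy of the brain displaced by half the field
  of view along the phase-encode axis (fluctuating N/2 ghost);
* ``recon_noise`` — a broad patchy in-brain map (parallel-imaging
  reconstruction errors).

Artifacts are injected as spatial-map x time-course sources with
controllable correlation to the task, which gives exact ground truth
for every source; true rigid-body resampling is deliberately not
simulated.  The grid is 32 x 32 x 16 voxels so the full analysis
pipeline runs in seconds while preserving all task timings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import build_block_regressor, canonical_hrf, predicted_response
from .preprocess import Volume4D, concatenate_runs

__all__ = [
    "ArtifactSpec",
    "ActivationSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom_geometry",
    "make_artifact_map",
    "simulate_motion_params",
    "simulate_run",
    "simulate_patient",
    "write_phantom",
]

ARTIFACT_KINDS = ("edge_rim", "ventricle_outline", "nyquist_ghost", "recon_noise")
TEMPORAL_PROFILES = (
    "stimulus_locked",
    "stimulus_locked_delayed",
    "random_walk",
    "single_run",
)
# phase-encode axis for ghost construction: second grid axis (anterior-posterior)
PHASE_ENCODE_AXIS = 1


@dataclass(frozen=True)
class ArtifactSpec:
    """One motion-artifact source: spatial footprint kind + temporal behaviour."""

    kind: str
    amplitude: float = 15.0
    temporal_profile: str = "stimulus_locked"
    correlation_with_task: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.temporal_profile not in TEMPORAL_PROFILES:
            raise ValueError(f"unknown temporal profile {self.temporal_profile!r}")
        if abs(self.correlation_with_task) > 1:
            raise ValueError("|correlation_with_task| must be <= 1")


@dataclass(frozen=True)
class ActivationSpec:
    """One activation region: geometry region name, effect size, timing."""

    region: str = "motor_left"
    percent_signal_change: float = 1.5
    response_delay_s: float = 0.0
    per_run_amplitudes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.percent_signal_change < 0:
            raise ValueError("percent_signal_change must be >= 0")


def _default_activation() -> list[ActivationSpec]:
    return [
        ActivationSpec("motor_left", 1.5),
        ActivationSpec("motor_right", 1.5),
        ActivationSpec("subcortical", 0.75, response_delay_s=2.5),
    ]


def _default_artifacts() -> list[ArtifactSpec]:
    return [
        ArtifactSpec("edge_rim", 15.0, "stimulus_locked", 0.8),
        ArtifactSpec("ventricle_outline", 15.0, "stimulus_locked_delayed", 0.8),
        ArtifactSpec("nyquist_ghost", 15.0, "stimulus_locked", 0.8),
        ArtifactSpec("recon_noise", 15.0, "random_walk", 0.0),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic patient acquisition."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    tr: float = 2.5
    n_runs: int = 4
    phase_len: int = 8
    n_rest_phases: int = 4
    n_task_phases: int = 3
    activation_regions: list[ActivationSpec] = field(
        default_factory=_default_activation
    )
    artifact_specs: list[ArtifactSpec] = field(default_factory=_default_artifacts)
    noise_sd: float = 5.0
    drift_amplitude: float = 10.0
    baseline: float = 1000.0
    motion_translation_mm: float = 0.4
    motion_rotation_rad: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 8 for g in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def run_length(self) -> int:
        return (self.n_rest_phases + self.n_task_phases) * self.phase_len


@dataclass
class GroundTruth:
    """Truth sidecar: every spatial source and its time course."""

    activation_masks: dict[str, np.ndarray]
    activation_timecourses: dict[str, np.ndarray]
    artifact_maps: dict[str, np.ndarray]
    artifact_timecourses: dict[str, np.ndarray]
    motion_params: np.ndarray

    @property
    def primary_activation_mask(self) -> np.ndarray:
        """Union of the cortical motor regions (the clinical target)."""
        masks = [
            m for name, m in self.activation_masks.items() if name.startswith("motor")
        ]
        if not masks:
            masks = list(self.activation_masks.values())
        out = np.zeros_like(masks[0], dtype=bool)
        for m in masks:
            out |= m.astype(bool)
        return out


# --------------------------------------------------------------------------
# geometry


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d <= 1.0


def make_phantom_geometry(
    spec: PhantomSpec, region_radius_frac: float = 0.16
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Build brain, ventricle, and activation-region masks for the grid.

    The brain is a filled ellipsoid; two small ventricle ellipsoids sit
    centrally inside it; the activation regions are two superior
    "motor" blobs (left/right) and one central "subcortical" blob,
    pairwise disjoint and disjoint from the ventricles.
    """
    shape = spec.grid_shape
    if region_radius_frac <= 0:
        raise ValueError("region radius must be positive")
    cx, cy, cz = [(s - 1) / 2 for s in shape]
    brain = _ellipsoid(shape, (cx, cy, cz), (0.42 * shape[0], 0.46 * shape[1], 0.44 * shape[2]))
    vent_l = _ellipsoid(
        shape, (cx - 0.09 * shape[0], cy, cz + 0.06 * shape[2]),
        (0.05 * shape[0], 0.12 * shape[1], 0.10 * shape[2]),
    )
    vent_r = _ellipsoid(
        shape, (cx + 0.09 * shape[0], cy, cz + 0.06 * shape[2]),
        (0.05 * shape[0], 0.12 * shape[1], 0.10 * shape[2]),
    )
    ventricles = (vent_l | vent_r) & brain
    r = region_radius_frac * min(shape)
    if r < 0.5:
        raise ValueError("region radius smaller than half a voxel: grid too small")
    rad = (r, r, max(0.75 * r, 1.0))
    regions = {
        "motor_left": _ellipsoid(
            shape, (cx - 0.18 * shape[0], cy - 0.10 * shape[1], cz + 0.20 * shape[2]), rad
        ),
        "motor_right": _ellipsoid(
            shape, (cx + 0.18 * shape[0], cy - 0.10 * shape[1], cz + 0.20 * shape[2]), rad
        ),
        "subcortical": _ellipsoid(
            shape, (cx, cy - 0.26 * shape[1], cz - 0.08 * shape[2]), rad
        ),
    }
    for name, m in regions.items():
        if not m.any():
            raise ValueError(f"region {name!r} is empty on this grid")
        if not (m <= brain).all():
            raise ValueError(f"region {name!r} extends outside the brain")
        if (m & ventricles).any():
            raise ValueError(f"region {name!r} overlaps the ventricles")
    names = list(regions)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (regions[a] & regions[b]).any():
                raise ValueError(f"regions {a!r} and {b!r} overlap")
    return brain, ventricles, regions


def make_artifact_map(
    kind: str,
    brain_mask: np.ndarray,
    ventricle_mask: np.ndarray,
    phase_axis: int = PHASE_ENCODE_AXIS,
) -> np.ndarray:
    """Deterministic spatial footprint (unit peak) for one artifact class."""
    brain = brain_mask.astype(bool)
    vent = ventricle_mask.astype(bool)
    if kind == "edge_rim":
        shell = brain & ~ndimage.binary_erosion(brain)
        coords = np.arange(brain.shape[phase_axis], dtype=float)
        c = (len(coords) - 1) / 2
        ap = np.abs(coords - c) / np.abs(coords - c).max()
        shape = [1, 1, 1]
        shape[phase_axis] = -1
        weight = 0.25 + 0.75 * ap.reshape(shape)
        out = shell * weight
    elif kind == "ventricle_outline":
        out = (ndimage.binary_dilation(vent) & ~vent).astype(float)
    elif kind == "nyquist_ghost":
        shift = brain.shape[phase_axis] // 2
        out = np.roll(brain, shift, axis=phase_axis).astype(float)
    elif kind == "recon_noise":
        rng = np.random.default_rng(987654321)  # fixed: footprint is deterministic
        f = ndimage.gaussian_filter(rng.standard_normal(brain.shape), sigma=2.5)
        f = np.abs(f) * brain
        out = np.where(f > np.percentile(f[brain], 60), f, 0.0)
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    peak = out.max()
    return out / peak if peak > 0 else out


# --------------------------------------------------------------------------
# time courses


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return x / sd


def _correlated_course(
    task: np.ndarray, target_r: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance series with empirical correlation exactly target_r to task."""
    t = _standardize(task)
    e = rng.standard_normal(len(task))
    e = e - t * (e @ t) / (t @ t)  # orthogonalize against task
    e = _standardize(e)
    return target_r * t + np.sqrt(1 - target_r**2) * e


def simulate_motion_params(
    n_volumes: int,
    profile: str,
    target_r_with_task: float = 0.0,
    seed: int = 0,
    task: np.ndarray | None = None,
    translation_mm: float = 0.4,
    rotation_rad: float = 0.008,
    run_length: int | None = None,
) -> np.ndarray:
    """Six-column motion table (x, y, z translations mm; 3 rotations rad).

    ``stimulus_locked`` profiles mix the task boxcar with orthogonalized
    noise so the empirical correlation equals the target exactly;
    ``random_walk`` is an integrated-noise drift; ``single_run``
    confines motion to the first run.  Amplitudes default to the
    chin-task scale (~0.4 mm RMS translation).
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if abs(target_r_with_task) > 1:
        raise ValueError("|target_r_with_task| must be <= 1")
    if profile not in TEMPORAL_PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    if task is None and profile.startswith("stimulus_locked"):
        raise ValueError("stimulus-locked profiles need the task boxcar")
    cols = []
    for _ in range(6):
        if profile == "stimulus_locked":
            course = _correlated_course(task, target_r_with_task, rng)
        elif profile == "stimulus_locked_delayed":
            delayed = np.roll(task, 1)
            course = _correlated_course(delayed, target_r_with_task, rng)
        elif profile == "random_walk":
            course = _standardize(np.cumsum(rng.standard_normal(n_volumes)))
        else:  # single_run
            rl = run_length or n_volumes
            course = np.zeros(n_volumes)
            course[:rl] = _standardize(np.cumsum(rng.standard_normal(rl)))
        cols.append(course)
    table = np.column_stack(cols)
    table[:, :3] *= translation_mm
    table[:, 3:] *= rotation_rad
    return table


def _artifact_course(
    spec: ArtifactSpec,
    task: np.ndarray,
    rng: np.random.Generator,
    run_length: int,
) -> np.ndarray:
    n = len(task)
    if spec.temporal_profile == "stimulus_locked":
        return _correlated_course(task, spec.correlation_with_task, rng)
    if spec.temporal_profile == "stimulus_locked_delayed":
        return _correlated_course(np.roll(task, 1), spec.correlation_with_task, rng)
    if spec.temporal_profile == "random_walk":
        return _standardize(np.cumsum(rng.standard_normal(n)))
    course = np.zeros(n)
    course[:run_length] = _standardize(np.cumsum(rng.standard_normal(run_length)))
    return course


def _activation_response(spec: PhantomSpec, region: ActivationSpec) -> np.ndarray:
    """HRF-convolved boxcar, delay applied, normalized to unit plateau."""
    boxcar = build_block_regressor(
        spec.n_rest_phases, spec.n_task_phases, spec.phase_len, spec.tr
    )
    hrf = canonical_hrf(spec.tr)
    resp = predicted_response(boxcar, hrf).values
    shift = int(round(region.response_delay_s / spec.tr))
    if shift > 0:
        resp = np.concatenate([np.zeros(shift), resp[:-shift]])
    peak = resp.max()
    return resp / peak if peak > 0 else resp


# --------------------------------------------------------------------------
# run / patient simulation


def simulate_run(
    spec: PhantomSpec,
    seed: int | None = None,
    run_index: int = 0,
) -> tuple[Volume4D, GroundTruth]:
    """Simulate one run: baseline + activation + artifacts + drift + noise.

    The signal model is purely additive:

        data = baseline
             + sum_r  mask_r * (psc_r/100 * baseline) * response_r(t) * amp_r
             + sum_a  map_a * amplitude_a * course_a(t)
             + drift(t)  (in-brain, linear + half-cosine)
             + N(0, noise_sd)

    where ``response_r`` is the HRF-convolved boxcar scaled to unit
    plateau, so the configured percent signal change is exact at the
    response peak in noise-free data.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    brain, ventricles, regions = make_phantom_geometry(spec)
    n = spec.run_length
    boxcar = build_block_regressor(
        spec.n_rest_phases, spec.n_task_phases, spec.phase_len, spec.tr
    ).values

    data = np.full(spec.grid_shape + (n,), float(spec.baseline))

    activation_masks: dict[str, np.ndarray] = {}
    activation_courses: dict[str, np.ndarray] = {}
    for act in spec.activation_regions:
        mask = regions[act.region]
        resp = _activation_response(spec, act)
        amp = 1.0
        if act.per_run_amplitudes is not None:
            amp = act.per_run_amplitudes[run_index % len(act.per_run_amplitudes)]
        course = resp * amp
        data[mask] += (act.percent_signal_change / 100.0 * spec.baseline) * course
        activation_masks[act.region] = mask
        activation_courses[act.region] = course

    artifact_maps: dict[str, np.ndarray] = {}
    artifact_courses: dict[str, np.ndarray] = {}
    for art in spec.artifact_specs:
        amap = make_artifact_map(art.kind, brain, ventricles)
        course = _artifact_course(art, boxcar, rng, n) * art.amplitude
        data += amap[..., None] * course[None, None, None, :]
        artifact_maps[art.kind] = amap
        artifact_courses[art.kind] = course

    if spec.drift_amplitude > 0:
        t = np.arange(n)
        lin = (t - t.mean()) / n
        halfcos = 0.5 * np.cos(np.pi * t / max(n - 1, 1))
        c1, c2 = rng.uniform(-1, 1, size=2)
        drift = spec.drift_amplitude * (c1 * lin + c2 * halfcos)
        data[brain] += drift

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    # Motion table: stimulus-correlated motion is concentrated in the
    # anterior-posterior translation (nodding/jaw axis) with a weaker
    # through-plane echo; the remaining axes drift as random walks.
    max_r = max(
        (abs(a.correlation_with_task) for a in spec.artifact_specs), default=0.0
    )
    cols = []
    for i in range(6):
        if i == 1 and max_r > 0:  # anterior-posterior translation
            cols.append(_correlated_course(boxcar, max_r, rng))
        elif i == 2 and max_r > 0:  # through-plane translation
            cols.append(_correlated_course(boxcar, max_r / 2, rng))
        else:
            cols.append(_standardize(np.cumsum(rng.standard_normal(n))))
    motion = np.column_stack(cols)
    motion[:, :3] *= spec.motion_translation_mm
    motion[:, 3:] *= spec.motion_rotation_rad

    vol = Volume4D(
        data=data,
        voxel_size=(1.8, 1.8, 3.3),
        tr=spec.tr,
        brain_mask=brain,
        run_boundaries=[0],
    )
    truth = GroundTruth(
        activation_masks=activation_masks,
        activation_timecourses=activation_courses,
        artifact_maps=artifact_maps,
        artifact_timecourses=artifact_courses,
        motion_params=motion,
    )
    return vol, truth


def simulate_patient(
    spec: PhantomSpec,
) -> tuple[Volume4D, GroundTruth, list[int]]:
    """Simulate ``n_runs`` runs and concatenate them along time.

    Per-run activation amplitudes (``ActivationSpec.per_run_amplitudes``)
    allow runs to differ, e.g. activation dominated by a single run.
    Run seeds are derived deterministically from ``spec.seed``.
    """
    vols, truths = [], []
    for i in range(spec.n_runs):
        run_seed = (spec.seed + i * 100003) % (2**31 - 1)
        v, t = simulate_run(spec, seed=run_seed, run_index=i)
        vols.append(v)
        truths.append(t)
    vol = concatenate_runs(vols)
    first = truths[0]
    truth = GroundTruth(
        activation_masks=first.activation_masks,
        activation_timecourses={
            k: np.concatenate([t.activation_timecourses[k] for t in truths])
            for k in first.activation_timecourses
        },
        artifact_maps=first.artifact_maps,
        artifact_timecourses={
            k: np.concatenate([t.artifact_timecourses[k] for t in truths])
            for k in first.artifact_timecourses
        },
        motion_params=np.vstack([t.motion_params for t in truths]),
    )
    return vol, truth, vol.run_boundaries


# --------------------------------------------------------------------------
# I/O


def write_phantom(
    out_dir: str | Path, vol: Volume4D, truth: GroundTruth, spec: PhantomSpec
) -> None:
    """Write NIfTI data + truth maps, TSV time courses/motion, JSON spec echo."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), out / "data.nii")
    nib.save(
        nib.Nifti1Image(vol.brain_mask.astype(np.uint8), affine),
        out / "brain_mask.nii",
    )
    for name, m in truth.activation_masks.items():
        nib.save(
            nib.Nifti1Image(m.astype(np.uint8), affine), out / f"truth_{name}.nii"
        )
    for name, m in truth.artifact_maps.items():
        nib.save(
            nib.Nifti1Image(m.astype(np.float32), affine),
            out / f"artifact_{name}.nii",
        )
    pd.DataFrame(truth.activation_timecourses).to_csv(
        out / "activation_timecourses.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth.artifact_timecourses).to_csv(
        out / "artifact_timecourses.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        truth.motion_params,
        columns=["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_rad", "rot_y_rad", "rot_z_rad"],
    ).to_csv(out / "motion.tsv", sep="\t", index=False)
    echo = asdict(spec)
    echo["grid_shape"] = list(spec.grid_shape)
    (out / "spec.json").write_text(json.dumps(echo, indent=2, default=list))
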