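"""In-pipeline preprocessing: concatenation, grand-mean scaling, high-pass
filtering, and motion-parameter summaries.

Rigid-body motion correction and inter-run registration are deliberately
not performed here; the ICA path is designed to run without motion
correction, and registration is delegated to external tools when real
acquisitions are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "Volume4D",
    "MotionSummary",
    "grand_mean_scale",
    "highpass_filter",
    "highpass_volume",
    "concatenate_runs",
    "summarize_motion",
]


@dataclass
class Volume4D:
    """A 4D fMRI dataset: (x, y, z, t) array plus grid metadata.

    ``run_boundaries`` holds the start index of each run in the
    concatenated time axis (``[0]`` for a single run).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    brain_mask: np.ndarray
    run_boundaries: list[int]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def run_slices(self) -> list[slice]:
        starts = list(self.run_boundaries) + [self.n_volumes]
        return [slice(a, b) for a, b in zip(starts[:-1], starts[1:])]


@dataclass(frozen=True)
class MotionSummary:
    """Per-volume and mean motion magnitude summaries.

    Translation is reduced to a per-volume RMS over the three axes
    (sqrt of the mean of the squared x, y, z displacements, mm);
    rotation to the sum of the magnitudes of the three angles (rad).
    """

    rms_translation_mm: np.ndarray
    summed_abs_rotation_rad: np.ndarray
    mean_rms_translation_mm: float
    mean_summed_abs_rotation_rad: float


def grand_mean_scale(vol: Volume4D, target: float = 10000.0) -> Volume4D:
    """Scale the whole 4D array by one factor so the in-mask grand mean hits target."""
    mask = vol.brain_mask.astype(bool)
    grand_mean = float(vol.data[mask].mean())
    if grand_mean <= 0:
        raise ValueError("in-mask grand mean must be positive")
    factor = target / grand_mean
    return replace(vol, data=vol.data * factor)


@lru_cache(maxsize=8)
def _running_line_smoother(n: int, sigma_vols: float) -> np.ndarray:
    """n x n matrix mapping a series to its Gaussian-weighted running-line fit.

    Row t0 is the local weighted-least-squares linear prediction at t0
    with Gaussian weights of SD ``sigma_vols`` centred there.
    """
    t = np.arange(n, dtype=float)
    s = np.empty((n, n))
    for i in range(n):
        w = np.exp(-0.5 * ((t - i) / sigma_vols) ** 2)
        sw = w.sum()
        tbar = (w * t).sum() / sw
        var = (w * (t - tbar) ** 2).sum()
        # prediction at t0 = weighted mean + slope * (t0 - tbar)
        s[i] = w / sw + (t[i] - tbar) * (w * (t - tbar)) / var
    return s


def highpass_filter(ts: np.ndarray, sigma_s: float, tr: float) -> np.ndarray:
    """Gaussian-weighted running-line high-pass filter.

    At each time point a straight line is fitted by weighted least
    squares with Gaussian weights (SD ``sigma_s`` seconds) centred
    there; the fitted value is subtracted and the series mean re-added,
    so the output keeps the original mean level.  Accepts a 1-D series
    or an (n_series, t) array filtered row-wise.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    x = ts[None, :] if one_d else ts
    n = x.shape[1]
    if n < 3:
        raise ValueError("series must have at least 3 volumes")
    smoother = _running_line_smoother(n, sigma_s / tr)
    out = x - x @ smoother.T + x.mean(axis=1, keepdims=True)
    return out[0] if one_d else out


def highpass_volume(
    vol: Volume4D, sigma_s: float, per_run: bool = False
) -> Volume4D:
    """Apply the high-pass filter voxelwise, over the concatenated series by
    default or run-by-run when ``per_run`` is set."""
    mask = vol.brain_mask.astype(bool)
    data = vol.data.copy()
    series = data[mask]  # (n_voxels, t)
    if per_run:
        for sl in vol.run_slices:
            series[:, sl] = highpass_filter(series[:, sl], sigma_s, vol.tr)
    else:
        series = highpass_filter(series, sigma_s, vol.tr)
    data[mask] = series
    return replace(vol, data=data)


def concatenate_runs(runs: list[Volume4D]) -> Volume4D:
    """Stack runs along the time axis, recording run boundaries."""
    if not runs:
        raise ValueError("need at least one run")
    first = runs[0]
    for r in runs[1:]:
        if r.data.shape[:3] != first.data.shape[:3]:
            raise ValueError("grid mismatch between runs")
        if abs(r.tr - first.tr) > 1e-9:
            raise ValueError("TR mismatch between runs")
    lengths = [r.n_volumes for r in runs]
    boundaries = list(np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int))
    return Volume4D(
        data=np.concatenate([r.data for r in runs], axis=3),
        voxel_size=first.voxel_size,
        tr=first.tr,
        brain_mask=first.brain_mask,
        run_boundaries=boundaries,
    )


def summarize_motion(motion_table: np.ndarray) -> MotionSummary:
    """Reduce a 6-column motion table to RMS translation and summed |rotation|.

    Columns are the three translations (mm) then the three rotations (rad).
    """
    motion = np.asarray(motion_table, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    rms = np.sqrt(np.mean(motion[:, :3] ** 2, axis=1))
    rot = np.sum(np.abs(motion[:, 3:]), axis=1)
    return MotionSummary(
        rms_translation_mm=rms,
        summed_abs_rotation_rad=rot,
        mean_rms_translation_mm=float(rms.mean()),
        mean_summed_abs_rotation_rad=float(rot.mean()),
    )
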