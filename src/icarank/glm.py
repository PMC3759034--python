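"""Voxelwise general linear model with motion confounds and Gaussian
random field cluster inference.

The task regressor (HRF-convolved boxcar) is fitted together with the
six rigid-body motion parameters (optionally their temporal
derivatives) and per-run intercepts; temporal concatenation of runs
makes this a fixed-effects analysis.  Serial correlation is handled by
AR(1) prewhitening with a spatially regularized autocorrelation
coefficient.  The z-map is thresholded (default Z > 2.3) into
26-connected clusters and each cluster receives a corrected p-value
from the Gaussian-random-field expected-cluster-count approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .preprocess import Volume4D

__all__ = [
    "DesignMatrix",
    "Cluster",
    "GlmResult",
    "build_design",
    "fit_glm",
    "estimate_smoothness",
    "cluster_threshold_grf",
]

Z_THRESH_DEFAULT = 2.3
CLUSTER_P_DEFAULT = 0.05
CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity, pinned
AR_RHO_SMOOTH_SIGMA = 2.0  # voxels; regularization of the AR(1) coefficient map


@dataclass(frozen=True)
class DesignMatrix:
    """Design matrix with labelled columns; the task column comes first."""

    matrix: np.ndarray
    labels: list[str]

    @property
    def task_index(self) -> int:
        return self.labels.index("task")

    @property
    def contrast(self) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        c[self.task_index] = 1.0
        return c


@dataclass(frozen=True)
class Cluster:
    voxels: np.ndarray  # (k, 3) integer coordinates
    size: int
    peak_z: float
    peak_coord: tuple[int, int, int]
    p_corrected: float
    significant: bool


@dataclass
class GlmResult:
    beta: np.ndarray  # task-contrast effect size map
    zmap: np.ndarray
    residuals: np.ndarray  # 4D
    dof: int
    fwhm_voxels: tuple[float, float, float]
    resels: float
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def significant_mask(self) -> np.ndarray:
        out = np.zeros(self.zmap.shape, dtype=bool)
        for c in self.clusters:
            if c.significant:
                out[tuple(c.voxels.T)] = True
        return out


def build_design(
    regressor: np.ndarray,
    motion: np.ndarray | None = None,
    run_boundaries: list[int] | None = None,
    motion_derivatives: bool = False,
) -> DesignMatrix:
    """Assemble task + motion confound + per-run intercept columns.

    Motion derivatives are first differences with a leading zero.
    Raises on rank deficiency, naming the offending columns.
    """
    regressor = np.asarray(regressor, dtype=float)
    n = len(regressor)
    cols = [regressor]
    labels = ["task"]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError("motion table must be (n_volumes, 6)")
        for i in range(6):
            cols.append(motion[:, i])
            labels.append(f"motion{i}")
        if motion_derivatives:
            for i in range(6):
                d = np.diff(motion[:, i], prepend=motion[0, i])
                d[0] = 0.0
                cols.append(d)
                labels.append(f"motion{i}_deriv")
    elif motion_derivatives:
        raise ValueError("motion derivatives requested without motion parameters")
    boundaries = run_boundaries or [0]
    starts = list(boundaries) + [n]
    for r, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
        ic = np.zeros(n)
        ic[a:b] = 1.0
        cols.append(ic)
        labels.append(f"intercept_run{r}")
    x = np.column_stack(cols)
    # rank check on demeaned non-intercept columns plus intercepts
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = []
        for j in range(x.shape[1]):
            rest = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(x):
                bad.append(labels[j])
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")
    return DesignMatrix(matrix=x, labels=labels)


def _ar1_coefficients(resid: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation per row of an (n_voxels, t) residual array."""
    r0 = resid - resid.mean(axis=1, keepdims=True)
    num = np.sum(r0[:, 1:] * r0[:, :-1], axis=1)
    den = np.sum(r0**2, axis=1)
    rho = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(rho, -0.95, 0.95)


def _smooth_in_mask(values: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    vol = np.zeros(mask.shape)
    vol[mask] = values
    num = ndimage.gaussian_filter(vol, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    return (num / np.maximum(den, 1e-12))[mask]


def _prewhiten(series: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) whitening transform along the last axis."""
    out = np.empty_like(series, dtype=float)
    out[..., 0] = series[..., 0] * np.sqrt(1 - rho**2)
    out[..., 1:] = series[..., 1:] - rho * series[..., :-1]
    return out


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    p = stats.t.sf(np.abs(t), dof)
    p = np.clip(p, 1e-300, 0.5)
    return np.sign(t) * stats.norm.isf(p)


def fit_glm(
    vol: Volume4D,
    design: DesignMatrix,
    prewhiten: bool = True,
    rho_bin_width: float = 0.01,
) -> GlmResult:
    """Fit the GLM voxelwise and return task beta and z maps.

    An OLS pass estimates voxelwise residual lag-1 autocorrelation; the
    coefficient map is regularized by Gaussian smoothing within the
    brain mask, quantized, and each quantile group refitted after AR(1)
    prewhitening of both data and design.  Residuals and smoothness are
    computed for the subsequent random-field cluster inference.
    """
    x = design.matrix
    n, p = x.shape
    if vol.n_volumes != n:
        raise ValueError("design rows must match number of volumes")
    dof = n - p
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    mask = vol.brain_mask.astype(bool)
    y = vol.data[mask]  # (v, t)
    c = design.contrast

    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T  # (v, p)
    resid = y - beta @ x.T

    if prewhiten:
        rho = _ar1_coefficients(resid)
        rho = _smooth_in_mask(rho, mask, AR_RHO_SMOOTH_SIGMA)
        bins = np.round(rho / rho_bin_width).astype(int)
        tval = np.empty(len(y))
        beta_c = np.empty(len(y))
        resid_w = np.empty_like(y)
        for b in np.unique(bins):
            idx = bins == b
            r = b * rho_bin_width
            xw = _prewhiten(x.T, r).T
            yw = _prewhiten(y[idx], r)
            pw = np.linalg.pinv(xw)
            bw = yw @ pw.T
            rw = yw - bw @ xw.T
            sigma2 = np.sum(rw**2, axis=1) / dof
            cvar = c @ np.linalg.inv(xw.T @ xw) @ c
            beta_c[idx] = bw @ c
            tval[idx] = beta_c[idx] / np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
            resid_w[idx] = rw
        resid = resid_w
    else:
        sigma2 = np.sum(resid**2, axis=1) / dof
        cvar = c @ np.linalg.inv(x.T @ x) @ c
        beta_c = beta @ c
        tval = beta_c / np.sqrt(np.maximum(sigma2 * cvar, 1e-300))

    zvals = _t_to_z(tval, dof)
    zmap = np.zeros(mask.shape)
    zmap[mask] = zvals
    beta_map = np.zeros(mask.shape)
    beta_map[mask] = beta_c
    resid4d = np.zeros(vol.data.shape)
    resid4d[mask] = resid

    fwhm, resels = estimate_smoothness(resid4d, mask)
    return GlmResult(
        beta=beta_map,
        zmap=zmap,
        residuals=resid4d,
        dof=dof,
        fwhm_voxels=fwhm,
        resels=resels,
    )


def estimate_smoothness(
    residuals: np.ndarray, mask: np.ndarray
) -> tuple[tuple[float, float, float], float]:
    """Estimate field smoothness (FWHM per axis, voxels) and RESEL count.

    Residual series are variance-normalized per voxel; the variance of
    spatial first differences of the normalized residuals gives, per
    axis, FWHM = sqrt(4 ln 2 / var).  RESELs = in-mask voxels / prod(FWHM).
    Accepts a 4D (x,y,z,t) or 3D (single field) array.
    """
    mask = mask.astype(bool)
    if residuals.ndim == 3:
        residuals = residuals[..., None]
    if residuals.shape[:3] != mask.shape:
        raise ValueError("residual grid must match mask")
    sd = residuals.std(axis=3, keepdims=True) if residuals.shape[3] > 1 else np.ones(1)
    if residuals.shape[3] > 1:
        flat = sd[..., 0] <= 0
        if (flat & mask).all():
            raise ValueError("flat residuals: smoothness undefined")
        norm = np.where(sd > 0, residuals / np.maximum(sd, 1e-300), 0.0)
    else:
        v = residuals[mask].std()
        if v <= 0:
            raise ValueError("flat residuals: smoothness undefined")
        norm = residuals / v
    fwhm = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        d = norm[tuple(sl_a) + (slice(None),)] - norm[tuple(sl_b) + (slice(None),)]
        lam = float(np.mean(d[pair] ** 2))
        lam = max(lam, 1e-12)
        fwhm.append(float(np.sqrt(4 * np.log(2) / lam)))
    resels = float(mask.sum() / np.prod(fwhm))
    return tuple(fwhm), resels


def _grf_cluster_p(k: int, z_thresh: float, resels: float, n_mask_voxels: int) -> float:
    """Corrected cluster p from the GRF Poisson-clumping approximation.

    Expected cluster count at the threshold comes from the 3D Euler
    characteristic density times the RESEL count; expected cluster size
    in voxels from the expected suprathreshold volume.  Cluster-size
    survival is modelled as exp(-beta k^(2/3)).
    """
    em = (
        resels
        * (4 * np.log(2)) ** 1.5
        * (z_thresh**2 - 1)
        * np.exp(-(z_thresh**2) / 2)
        / (2 * np.pi) ** 2
    )
    em = max(em, 1e-12)
    en = n_mask_voxels * stats.norm.sf(z_thresh)
    nbar = max(en / em, 1e-12)
    beta = (math.gamma(2.5) / nbar) ** (2.0 / 3.0)
    p_unc = np.exp(-beta * k ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_unc))


def cluster_threshold_grf(
    zmap: np.ndarray,
    mask: np.ndarray,
    z_thresh: float = Z_THRESH_DEFAULT,
    p_thresh: float = CLUSTER_P_DEFAULT,
    resels: float | None = None,
    min_extent: int = 0,
    no_cluster_threshold: bool = False,
) -> list[Cluster]:
    """Threshold a z-map into 26-connected clusters with corrected p-values.

    Clusters with corrected p below ``p_thresh`` (and at least
    ``min_extent`` voxels) are flagged significant; with
    ``no_cluster_threshold`` every suprathreshold cluster is flagged
    (voxel-threshold-only mode).
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    mask = mask.astype(bool)
    if not no_cluster_threshold and (resels is None or resels <= 0):
        raise ValueError("resels must be positive for corrected inference")
    supra = (zmap > z_thresh) & mask
    labelled, n_clusters = ndimage.label(supra, structure=CONNECTIVITY)
    clusters: list[Cluster] = []
    n_mask = int(mask.sum())
    for lab in range(1, n_clusters + 1):
        vox = np.argwhere(labelled == lab)
        k = len(vox)
        zvals = zmap[tuple(vox.T)]
        peak = int(np.argmax(zvals))
        if no_cluster_threshold:
            p_corr, sig = 1.0, True
        else:
            p_corr = _grf_cluster_p(k, z_thresh, resels, n_mask)
            sig = p_corr < p_thresh and k >= min_extent
        clusters.append(
            Cluster(
                voxels=vox,
                size=k,
                peak_z=float(zvals[peak]),
                peak_coord=tuple(int(v) for v in vox[peak]),
                p_corrected=p_corr,
                significant=sig,
            )
        )
    clusters.sort(key=lambda c: (-c.size, -c.peak_z))
    return clusters
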