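"""Probabilistic-PCA model-order selection, spatial ICA decomposition,
variance ordering, mixture-model thresholding, and component spectra.

The decomposition follows the melodic-style spatial-ICA convention:
in-mask voxels are samples and time points are dimensions, so each
independent component is a spatial map paired with a mixing time
course.  Components are ordered by the percentage of total variance
they explain — the ordering under which task activation tends to sit
low in the list when artifacts dominate, motivating feature ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .design import FrequencySpectrum, power_spectrum
from .preprocess import Volume4D

__all__ = [
    "ComponentSet",
    "MixtureThreshold",
    "estimate_model_order",
    "laplace_log_evidence",
    "decompose",
    "mixture_threshold",
    "component_spectra",
]

ICA_MAX_ITER = 1000
ICA_TOL = 1e-6


@dataclass
class ComponentSet:
    """Spatial ICA result: z-scored maps + mixing time courses."""

    maps: np.ndarray  # (n_components, n_mask_voxels), z-scored
    timecourses: np.ndarray  # (t, n_components)
    var_explained_pct: np.ndarray  # (n_components,)
    mask: np.ndarray  # 3D boolean
    tr: float
    model_order: int
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, i: int) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.maps[i]
        return vol

    @property
    def spectra(self) -> list[FrequencySpectrum]:
        return component_spectra(self)


@dataclass(frozen=True)
class MixtureThreshold:
    """Binary retention decision per voxel plus fit diagnostics."""

    retained: np.ndarray  # boolean, same length as input values
    n_classes: int
    fallback: bool  # True when the single-Gaussian z>3 fallback was used


def _voxelwise_normalize(y: np.ndarray) -> np.ndarray:
    """De-mean and variance-normalize each voxel's time series."""
    y = y - y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    return np.where(sd > 0, y / np.maximum(sd, 1e-300), 0.0)


def laplace_log_evidence(
    spectrum: np.ndarray, rank: int, n_samples: int
) -> float:
    """Laplace approximation to the log evidence of a PPCA model of given rank.

    ``spectrum`` holds the eigenvalues of the sample covariance over
    the time dimension (descending); ``n_samples`` is the number of
    in-mask voxels.  Follows Minka's Laplace-evidence expression for
    automatic dimensionality selection.
    """
    d = len(spectrum)
    if not 1 <= rank < d:
        return -np.inf
    eps = 1e-15
    if spectrum[rank - 1] < eps:
        return -np.inf
    i = np.arange(1, rank + 1)
    log_pu = -rank * np.log(2.0) + np.sum(
        gammaln((d - i + 1) / 2.0) - ((d - i + 1) / 2.0) * np.log(np.pi)
    )
    log_pl = -n_samples / 2.0 * np.sum(np.log(spectrum[:rank]))
    v = max(eps, float(np.sum(spectrum[rank:])) / (d - rank))
    log_pv = -np.log(v) * n_samples * (d - rank) / 2.0
    m = d * rank - rank * (rank + 1) / 2.0
    log_pp = np.log(2.0 * np.pi) * (m + rank) / 2.0
    filled = spectrum.copy()
    filled[rank:] = v
    log_az = 0.0
    for a in range(rank):
        log_az += float(
            np.sum(
                np.log(spectrum[a] - spectrum[a + 1 :])
                + np.log(1.0 / filled[a + 1 :] - 1.0 / filled[a])
                + np.log(n_samples)
            )
        )
    return float(
        log_pu + log_pl + log_pv + log_pp - log_az / 2.0
        - rank * np.log(n_samples) / 2.0
    )


def _covariance_spectrum(vol: Volume4D, mask: np.ndarray) -> tuple[np.ndarray, int]:
    y = _voxelwise_normalize(vol.data[mask.astype(bool)])
    n_samples = y.shape[0]
    yc = y - y.mean(axis=0, keepdims=True)
    s = np.linalg.svd(yc, compute_uv=False)
    spectrum = np.zeros(y.shape[1])
    spectrum[: len(s)] = s**2 / n_samples
    return spectrum, n_samples


def estimate_model_order(
    vol: Volume4D, mask: np.ndarray | None = None, max_order: int | None = None
) -> int:
    """Estimate the ICA model order by maximizing the Laplace evidence."""
    mask = vol.brain_mask if mask is None else mask
    if vol.n_volumes < 10:
        raise ValueError("need at least 10 time points")
    if int(mask.sum()) < vol.n_volumes:
        raise ValueError("need at least as many in-mask voxels as time points")
    spectrum, n_samples = _covariance_spectrum(vol, mask)
    if spectrum[0] <= 0:
        raise ValueError("degenerate (zero-variance) data")
    # drop numerically-zero eigenvalues (centering removes one rank);
    # a zero tail makes the evidence of the saturated model degenerate
    spectrum = spectrum[spectrum > 1e-10 * spectrum[0]]
    kmax = max_order or len(spectrum) - 1
    kmax = min(kmax, len(spectrum) - 1)
    evidence = [laplace_log_evidence(spectrum, k, n_samples) for k in range(1, kmax + 1)]
    return int(np.argmax(evidence)) + 1


def decompose(
    vol: Volume4D,
    mask: np.ndarray | None = None,
    n: int | None = None,
    seed: int = 0,
) -> ComponentSet:
    """Spatial ICA: voxelwise normalize, PCA-whiten to n dims, unmix.

    Unmixing uses the symmetric (parallel) fixed-point iteration with a
    logcosh contrast.  Maps are z-scored over in-mask voxels; mixing
    time courses and per-component variance fractions come from the
    least-squares back-projection of the normalized data onto the maps.
    Non-convergence is reported via the ``converged`` flag; the final
    iterate is still returned.
    """
    mask = (vol.brain_mask if mask is None else mask).astype(bool)
    y = _voxelwise_normalize(vol.data[mask])  # (v, t)
    if n is None:
        n = estimate_model_order(vol, mask)
    if n > min(y.shape):
        raise ValueError("model order exceeds data rank")
    pca = PCA(n_components=n, whiten=True, svd_solver="full", random_state=seed)
    white = pca.fit_transform(y)  # (v, n)
    ica = FastICA(
        whiten=False,
        fun="logcosh",
        max_iter=ICA_MAX_ITER,
        tol=ICA_TOL,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(white)  # (v, n)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    whiten=False,
                    fun="logcosh",
                    max_iter=ICA_MAX_ITER,
                    tol=ICA_TOL,
                    random_state=seed,
                )
                sources = ica.fit_transform(white)

    yc = y - y.mean(axis=0, keepdims=True)
    mixing = np.linalg.lstsq(sources, yc, rcond=None)[0]  # (n, t)
    total_var = float(np.sum(yc**2))
    var_pct = np.array(
        [
            100.0 * np.sum(sources[:, i] ** 2) * np.sum(mixing[i] ** 2) / total_var
            for i in range(n)
        ]
    )
    maps = sources.T  # (n, v)
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    order = np.argsort(-var_pct)
    return ComponentSet(
        maps=maps[order],
        timecourses=mixing[order].T,
        var_explained_pct=var_pct[order],
        mask=mask,
        tr=vol.tr,
        model_order=n,
        converged=converged,
    )


def mixture_threshold(
    map_values: np.ndarray,
    posterior: float = 0.5,
    seed: int = 0,
) -> MixtureThreshold:
    """Threshold a z-scored component map with a 1-D Gaussian mixture.

    Candidate mixtures with 1, 2, and 3 classes (background plus
    positive and/or negative tails) are fitted by EM and compared by
    BIC.  When a multi-class model wins, voxels whose posterior
    probability of belonging to a non-background class exceeds
    ``posterior`` are retained (background = the heaviest-weight
    class).  When the single-Gaussian null wins, or EM collapses, the
    fallback |z| cutoff of 3 on the positive side is used and flagged.
    """
    x = np.asarray(map_values, dtype=float).ravel()
    if x.std() == 0:
        raise ValueError("constant map: mixture model undefined")
    xr = x.reshape(-1, 1)
    fits = []
    for k in (1, 2, 3):
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                random_state=seed,
                n_init=1,
                reg_covar=1e-6,
            ).fit(xr)
            fits.append((gm.bic(xr), k, gm))
        except ValueError:
            continue
    if not fits:
        return MixtureThreshold(retained=x > 3.0, n_classes=1, fallback=True)
    fits.sort(key=lambda f: f[0])
    _, best_k, gm = fits[0]
    if best_k == 1:
        return MixtureThreshold(retained=x > 3.0, n_classes=1, fallback=True)
    background = int(np.argmax(gm.weights_))
    post = gm.predict_proba(xr)
    non_bg = np.delete(post, background, axis=1).sum(axis=1)
    return MixtureThreshold(retained=non_bg > posterior, n_classes=best_k, fallback=False)


def component_spectra(components: ComponentSet) -> list[FrequencySpectrum]:
    """Magnitude spectrum of each component's mixing time course."""
    return [
        power_spectrum(components.timecourses[:, i], components.tr)
        for i in range(components.n_components)
    ]
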