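"""Feature-based ranking of independent components.

Three intuitive features score every component against reference
objects from the task analysis, so that the activation component can
be found near the top of a sorted list rather than by inspecting
hundreds of variance-ordered maps:

* ``glmcorr`` — Pearson correlation between the unthresholded IC map
  and the unthresholded GLM z-map over in-brain voxels;
* ``templatecorr`` — correlation between the IC map and a binary
  anatomical template (e.g. a precentral-gyrus mask) on the same grid;
* ``speccorr`` — correlation between the magnitude spectrum of the IC
  time course and that of the predicted response, which is insensitive
  to response delay (the magnitude spectrum is shift invariant) and to
  slow drift.

Rankings sort by |r|: the sign of an ICA component is arbitrary, so
signed ranking would be seed-dependent.  Raw signed scores are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import FrequencySpectrum
from .ica import ComponentSet

__all__ = [
    "FeatureScores",
    "RankingTable",
    "glmcorr",
    "templatecorr",
    "atlas_to_mask",
    "speccorr",
    "rank_components",
    "score_components",
]

FEATURES = ("variance", "glmcorr", "templatecorr", "speccorr")


@dataclass(frozen=True)
class FeatureScores:
    component_id: int
    glmcorr: float
    templatecorr: float
    speccorr: float
    var_explained_pct: float


@dataclass
class RankingTable:
    """Per-feature rank permutations and per-component rank positions."""

    scores: list[FeatureScores]
    order: dict[str, np.ndarray]  # feature -> component ids, best first

    def rank_of(self, component_id: int, feature: str) -> int:
        """1-based rank position of a component under a feature."""
        return int(np.where(self.order[feature] == component_id)[0][0]) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scores:
            rows.append(
                {
                    "component": s.component_id,
                    "var_pct": s.var_explained_pct,
                    "glmcorr": s.glmcorr,
                    "templatecorr": s.templatecorr,
                    "speccorr": s.speccorr,
                    **{
                        f"rank_{f}": self.rank_of(s.component_id, f)
                        for f in FEATURES
                    },
                }
            )
        return pd.DataFrame(rows)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("length mismatch")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance input: correlation set to 0", stacklevel=3)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def glmcorr(ic_map: np.ndarray, zmap: np.ndarray, mask: np.ndarray) -> float:
    """Correlation of the unthresholded IC map with the unthresholded z-map."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    if ic_map.shape != zmap.shape or ic_map.shape != mask.shape:
        raise ValueError("grid mismatch")
    return _pearson(ic_map[mask], zmap[mask])


def templatecorr(
    ic_map: np.ndarray, template_mask: np.ndarray, mask: np.ndarray
) -> float:
    """Correlation of the IC map with a binary anatomical template."""
    mask = mask.astype(bool)
    template = template_mask.astype(float)
    if ic_map.shape != template.shape or ic_map.shape != mask.shape:
        raise ValueError("grid mismatch")
    if template[mask].sum() == 0:
        raise ValueError("template empty after masking")
    return _pearson(ic_map[mask], template[mask])


def atlas_to_mask(
    atlas_volume: np.ndarray,
    label: int,
    target_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Binary mask of an integer-labelled atlas region.

    When the atlas grid differs from ``target_shape``, the mask is
    resampled by nearest neighbour (registration proper is delegated
    to external tools).
    """
    atlas = np.asarray(atlas_volume)
    mask = atlas == label
    if not mask.any():
        raise ValueError(f"label {label} absent from atlas")
    if target_shape is not None and mask.shape != tuple(target_shape):
        zoom = [t / s for t, s in zip(target_shape, mask.shape)]
        mask = ndimage.zoom(mask.astype(np.uint8), zoom, order=0).astype(bool)
    return mask


def speccorr(
    ic_spectrum: FrequencySpectrum, model_spectrum: FrequencySpectrum
) -> float:
    """Correlation of magnitude spectra over non-DC bins.

    The DC bin carries no task information and would otherwise dominate
    the magnitudes, so it is excluded.
    """
    if len(ic_spectrum.magnitudes) != len(model_spectrum.magnitudes):
        raise ValueError("spectra have different bin counts")
    if abs(ic_spectrum.df - model_spectrum.df) > 1e-12:
        raise ValueError("spectra have different frequency resolution")
    return _pearson(ic_spectrum.magnitudes[1:], model_spectrum.magnitudes[1:])


def rank_components(scores: list[FeatureScores]) -> RankingTable:
    """Sort components by |r| (descending) under each feature.

    The variance ordering is kept as the default descending
    var-explained list; ties under any feature are broken by that
    variance ordering.
    """
    if not scores:
        raise ValueError("need at least one component")
    ids = np.array([s.component_id for s in scores])
    var = np.array([s.var_explained_pct for s in scores])
    var_order = ids[np.argsort(-var, kind="stable")]
    pos_in_var = {cid: i for i, cid in enumerate(var_order)}
    order: dict[str, np.ndarray] = {"variance": var_order}
    for feat in ("glmcorr", "templatecorr", "speccorr"):
        vals = np.array([abs(getattr(s, feat)) for s in scores])
        keys = sorted(
            range(len(scores)),
            key=lambda i: (-vals[i], pos_in_var[ids[i]]),
        )
        order[feat] = ids[np.array(keys)]
    return RankingTable(scores=list(scores), order=order)


def score_components(
    components: ComponentSet,
    zmap: np.ndarray,
    template_mask: np.ndarray,
    model_spectrum: FrequencySpectrum,
) -> RankingTable:
    """Score every component on all three features and rank."""
    spectra = components.spectra
    scores = [
        FeatureScores(
            component_id=i,
            glmcorr=glmcorr(components.map_volume(i), zmap, components.mask),
            templatecorr=templatecorr(
                components.map_volume(i), template_mask, components.mask
            ),
            speccorr=speccorr(spectra[i], model_spectrum),
            var_explained_pct=float(components.var_explained_pct[i]),
        )
        for i in range(components.n_components)
    ]
    return rank_components(scores)
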