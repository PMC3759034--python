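"""Comparison machinery: VOI time courses, region detection statuses,
and GLM-vs-ICA contamination metrics on ground-truthed phantoms.

Detection statuses are explicit rule-based analogues of an expert's
yes / qualified-yes / no judgement: a region counts as detected (``y``)
when enough suprathreshold voxels fall inside it and the overall
suprathreshold set is not dominated by artifact territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import GlmResult
from .ica import ComponentSet, mixture_threshold
from .preprocess import Volume4D
from .ranking import RankingTable, FEATURES
from .synthetic import GroundTruth

__all__ = [
    "VoiTimecourse",
    "DetectionStatus",
    "find_peak",
    "extract_voi_timecourse",
    "detection_status",
    "contamination_fraction",
    "match_truth_component",
    "compare_methods",
]

MIN_VOXELS_DEFAULT = 5
MAX_CONTAMINATION_DEFAULT = 0.3
VOI_HALF_WIDTH = 4  # gives the 9 x 9 x 9 voxel cuboid


@dataclass(frozen=True)
class VoiTimecourse:
    center: tuple[int, int, int]
    half_width: int
    mean_course: np.ndarray  # per concatenated volume
    run_average: np.ndarray  # per within-run volume, averaged across runs


@dataclass(frozen=True)
class DetectionStatus:
    region: str
    method: str  # "glm" | "ica"
    status: str  # "y" | "qualified_y" | "n"
    suprathreshold_count: int
    contamination_fraction: float


def find_peak(map_: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    """Argmax voxel of a map within a mask; ties go to the lowest coordinates."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.where(mask, map_, -np.inf)
    vals = np.where(np.isnan(vals), -np.inf, vals)
    if not np.isfinite(vals).any():
        raise ValueError("no finite in-mask values")
    # argmax on C-ordered flat array returns the lexicographically first tie
    flat = int(np.argmax(vals))
    return tuple(int(c) for c in np.unravel_index(flat, map_.shape))


def extract_voi_timecourse(
    vol: Volume4D,
    center: tuple[int, int, int],
    half_width: int = VOI_HALF_WIDTH,
    run_boundaries: list[int] | None = None,
) -> VoiTimecourse:
    """Mean time course over a (2h+1)^3 cuboid, then averaged across runs.

    The cuboid is clipped at grid boundaries.  Run averaging requires
    equal run lengths (as in the standard paradigm).
    """
    shape = vol.data.shape[:3]
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise ValueError("center outside grid")
    sl = tuple(
        slice(max(c - half_width, 0), min(c + half_width + 1, s))
        for c, s in zip(center, shape)
    )
    course = vol.data[sl].mean(axis=(0, 1, 2))
    boundaries = run_boundaries or vol.run_boundaries
    starts = list(boundaries) + [vol.n_volumes]
    lengths = {b - a for a, b in zip(starts[:-1], starts[1:])}
    if len(lengths) != 1:
        raise ValueError("run averaging requires equal run lengths")
    run_len = lengths.pop()
    run_avg = course.reshape(-1, run_len).mean(axis=0)
    return VoiTimecourse(
        center=tuple(center),
        half_width=half_width,
        mean_course=course,
        run_average=run_avg,
    )


def contamination_fraction(
    binary_map: np.ndarray, artifact_masks: list[np.ndarray]
) -> float:
    """Fraction of suprathreshold voxels lying inside any artifact footprint."""
    supra = binary_map.astype(bool)
    total = int(supra.sum())
    if total == 0:
        return 0.0
    art = np.zeros_like(supra)
    for m in artifact_masks:
        art |= np.asarray(m) > 0
    return float((supra & art).sum() / total)


def detection_status(
    binary_map: np.ndarray,
    region_mask: np.ndarray,
    artifact_masks: list[np.ndarray],
    min_voxels: int = MIN_VOXELS_DEFAULT,
    max_contamination: float = MAX_CONTAMINATION_DEFAULT,
    region: str = "",
    method: str = "",
) -> DetectionStatus:
    """y / qualified_y / n detection rule for one region.

    ``y``: at least ``min_voxels`` suprathreshold voxels inside the
    region and overall contamination no greater than
    ``max_contamination``; ``qualified_y``: some overlap but one
    condition fails; ``n``: no overlap at all.
    """
    region_mask = region_mask.astype(bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    supra = binary_map.astype(bool)
    overlap = int((supra & region_mask).sum())
    contam = contamination_fraction(supra, artifact_masks)
    if overlap >= min_voxels and contam <= max_contamination:
        status = "y"
    elif overlap >= 1:
        status = "qualified_y"
    else:
        status = "n"
    return DetectionStatus(
        region=region,
        method=method,
        status=status,
        suprathreshold_count=int(supra.sum()),
        contamination_fraction=contam,
    )


def match_truth_component(
    components: ComponentSet, truth_mask: np.ndarray
) -> tuple[int, float]:
    """Component whose map best matches a truth mask (max |spatial r|)."""
    t = truth_mask.astype(float)[components.mask]
    if t.std() == 0:
        raise ValueError("truth mask constant within brain mask")
    rs = []
    for i in range(components.n_components):
        m = components.maps[i]
        rs.append(abs(float(np.corrcoef(m, t)[0, 1])))
    best = int(np.argmax(rs))
    return best, rs[best]


def compare_methods(
    glm_result: GlmResult,
    components: ComponentSet,
    ranking: RankingTable,
    truth: GroundTruth,
    min_voxels: int = MIN_VOXELS_DEFAULT,
    max_contamination: float = MAX_CONTAMINATION_DEFAULT,
    seed: int = 0,
) -> dict:
    """Per-region detection + contamination report for GLM vs ICA.

    The GLM map is the union of significant clusters; the ICA map is
    the mixture-thresholded map of the component ranked first by the
    template feature.  Also reports the truth-matched component's rank
    position under all four orderings.
    """
    glm_map = glm_result.significant_mask
    top_ic = int(ranking.order["templatecorr"][0])
    mt = mixture_threshold(components.maps[top_ic], seed=seed)
    ica_map = np.zeros(components.mask.shape, dtype=bool)
    vals = components.maps[top_ic]
    # keep the positive side of the component (sign aligned to its mean retained value)
    retained = mt.retained
    if retained.any() and vals[retained].mean() < 0:
        vals = -vals
    ica_map[components.mask] = retained & (vals > 0)

    # artifact territory excludes true activation regions: a voxel inside
    # an activation region is a correct detection, not contamination
    act_union = np.zeros(components.mask.shape, dtype=bool)
    for m in truth.activation_masks.values():
        act_union |= m.astype(bool)
    artifact_masks = [
        (np.asarray(m) > 0) & ~act_union for m in truth.artifact_maps.values()
    ]
    statuses: list[DetectionStatus] = []
    for name, region in truth.activation_masks.items():
        for method, bmap in (("glm", glm_map), ("ica", ica_map)):
            statuses.append(
                detection_status(
                    bmap,
                    region,
                    artifact_masks,
                    min_voxels=min_voxels,
                    max_contamination=max_contamination,
                    region=name,
                    method=method,
                )
            )
    matched, match_r = match_truth_component(
        components, truth.primary_activation_mask
    )
    ranks = {f: ranking.rank_of(matched, f) for f in FEATURES}
    return {
        "statuses": statuses,
        "glm_contamination": contamination_fraction(glm_map, artifact_masks),
        "ica_contamination": contamination_fraction(ica_map, artifact_masks),
        "matched_component": matched,
        "match_r": match_r,
        "top_templatecorr_component": top_ic,
        "ranks": ranks,
        "ica_threshold_fallback": mt.fallback,
    }
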