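"""End-to-end analysis of one (synthetic) patient: GLM path, ICA path,
feature ranking, and the GLM-vs-ICA comparison report.

The GLM path grand-mean-scales and high-pass-filters the concatenated
series, fits the task + motion-confound model, and applies random-field
cluster inference.  The ICA path runs on the unfiltered series (the
decomposition is expected to isolate drifts in separate components),
estimates the model order by Laplace evidence, and decomposes.  The
ranking step scores each component against the z-map, a template mask,
and the predicted-response spectrum.
"""

from __future__ import annotations

import numpy as np

from .design import build_block_regressor, canonical_hrf, power_spectrum, predicted_response
from .evaluation import compare_methods
from .glm import build_design, cluster_threshold_grf, fit_glm
from .ica import decompose, estimate_model_order
from .preprocess import grand_mean_scale, highpass_volume
from .ranking import score_components
from .synthetic import PhantomSpec, simulate_patient

__all__ = ["analyze_phantom", "task_regressor_for"]

HIGHPASS_SIGMA_S = 20.0
GRAND_MEAN_TARGET = 10000.0


def task_regressor_for(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(boxcar, predicted response) tiled over the patient's runs."""
    boxcar = build_block_regressor(
        spec.n_rest_phases, spec.n_task_phases, spec.phase_len, spec.tr
    )
    hrf = canonical_hrf(spec.tr)
    resp = predicted_response(boxcar, hrf).values
    return np.tile(boxcar.values, spec.n_runs), np.tile(resp, spec.n_runs)


def analyze_phantom(
    spec: PhantomSpec,
    z_thresh: float = 2.3,
    cluster_p: float = 0.05,
    motion_derivatives: bool = False,
    max_model_order: int | None = None,
) -> dict:
    """Simulate a patient and run both analysis paths plus ranking.

    Returns a report dict with the GLM result, component set, ranking
    table, the comparison report, and the ground truth.
    """
    vol, truth, boundaries = simulate_patient(spec)
    _, response = task_regressor_for(spec)

    # GLM path: grand-mean scale, high-pass, fit, cluster inference
    vol_glm = highpass_volume(grand_mean_scale(vol, GRAND_MEAN_TARGET), HIGHPASS_SIGMA_S)
    design = build_design(
        response,
        motion=truth.motion_params,
        run_boundaries=boundaries,
        motion_derivatives=motion_derivatives,
    )
    glm_result = fit_glm(vol_glm, design)
    glm_result.clusters = cluster_threshold_grf(
        glm_result.zmap,
        vol.brain_mask,
        z_thresh=z_thresh,
        p_thresh=cluster_p,
        resels=glm_result.resels,
    )

    # ICA path: no temporal filtering
    order = estimate_model_order(vol, vol.brain_mask, max_order=max_model_order)
    components = decompose(vol, vol.brain_mask, n=order, seed=spec.seed)

    # ranking against z-map, template (truth primary region), model spectrum
    template = truth.primary_activation_mask
    model_spec = power_spectrum(response, spec.tr)
    ranking = score_components(components, glm_result.zmap, template, model_spec)

    report = compare_methods(
        glm_result, components, ranking, truth, seed=spec.seed
    )
    return {
        "volume": vol,
        "truth": truth,
        "glm": glm_result,
        "components": components,
        "ranking": ranking,
        "report": report,
        "model_order": order,
    }
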