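"""Task design objects: block regressor, canonical HRF, predicted response, spectra.

The block paradigm alternates rest (A) and task (B) phases, rest first
(ABABABA).  The predicted BOLD response is the boxcar convolved with a
canonical double-gamma hemodynamic response function; its magnitude
spectrum is the reference object for the spectral component feature,
chosen over the time course itself because the magnitude spectrum is
invariant to response delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BoxcarRegressor",
    "Hrf",
    "HrfParams",
    "PredictedResponse",
    "FrequencySpectrum",
    "build_block_regressor",
    "canonical_hrf",
    "predicted_response",
    "power_spectrum",
]


@dataclass(frozen=True)
class BoxcarRegressor:
    """0/1 task indicator per volume for a rest-first block design."""

    values: np.ndarray
    tr: float
    phase_len: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (conventional defaults, seconds)."""

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    onset: float = 0.0
    window: float = 32.0


@dataclass(frozen=True)
class Hrf:
    """Canonical HRF sampled at TR resolution, scaled to unit peak."""

    samples: np.ndarray
    tr: float
    params: HrfParams = field(default_factory=HrfParams)


@dataclass(frozen=True)
class PredictedResponse:
    """Boxcar convolved with the HRF, truncated to the regressor length."""

    values: np.ndarray
    tr: float

    @property
    def spectrum(self) -> "FrequencySpectrum":
        return power_spectrum(self.values, self.tr)


@dataclass(frozen=True)
class FrequencySpectrum:
    """Magnitude of the DFT at non-negative frequencies."""

    magnitudes: np.ndarray
    df: float

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(len(self.magnitudes)) * self.df


def build_block_regressor(
    n_rest: int, n_task: int, phase_len: int, tr: float
) -> BoxcarRegressor:
    """Build the alternating rest/task boxcar, one value per volume.

    Rest comes first whenever the phase counts permit; with exactly one
    more task phase than rest phases the only alternating arrangement
    starts with task.  More task phases than that cannot alternate and
    are rejected.
    """
    if n_rest < 0 or n_task < 0:
        raise ValueError("phase counts must be non-negative")
    if phase_len < 1:
        raise ValueError("phase_len must be >= 1")
    if n_task > n_rest + 1:
        raise ValueError(
            f"cannot alternate {n_task} task with {n_rest} rest phases"
        )
    phases: list[int] = []
    rest_first = n_task <= n_rest
    a, b = (0, 1) if rest_first else (1, 0)
    n_a, n_b = (n_rest, n_task) if rest_first else (n_task, n_rest)
    while n_a or n_b:
        if n_a:
            phases.append(a)
            n_a -= 1
        if n_b:
            phases.append(b)
            n_b -= 1
    values = np.repeat(np.asarray(phases, dtype=float), phase_len)
    return BoxcarRegressor(values=values, tr=float(tr), phase_len=phase_len)


def canonical_hrf(tr: float, params: HrfParams | None = None) -> Hrf:
    """Canonical double-gamma HRF sampled at TR over the response window.

    The impulse response is a gamma density for the positive response
    minus a later, broader gamma density for the undershoot scaled by
    1/ratio.  The curve is scaled to unit peak: the scale cancels in
    every correlation-based quantity downstream.
    """
    p = params or HrfParams()
    if tr <= 0:
        raise ValueError("tr must be positive")
    if p.response_dispersion <= 0 or p.undershoot_dispersion <= 0:
        raise ValueError("dispersions must be positive")
    t = np.arange(0.0, p.window + 1e-9, tr) - p.onset
    peak = stats.gamma.pdf(
        t, p.response_delay / p.response_dispersion, scale=p.response_dispersion
    )
    undershoot = stats.gamma.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = peak - undershoot / p.ratio
    h = h / np.max(np.abs(h))
    return Hrf(samples=h, tr=float(tr), params=p)


def predicted_response(boxcar: BoxcarRegressor, hrf: Hrf) -> PredictedResponse:
    """Linear discrete convolution of boxcar and HRF, truncated to the run length."""
    if len(boxcar.values) == 0 or len(hrf.samples) == 0:
        raise ValueError("empty inputs")
    if abs(boxcar.tr - hrf.tr) > 1e-9:
        raise ValueError("boxcar and HRF must share the same TR")
    full = np.convolve(boxcar.values, hrf.samples)
    return PredictedResponse(values=full[: len(boxcar.values)], tr=boxcar.tr)


def power_spectrum(values: np.ndarray, tr: float = 1.0) -> FrequencySpectrum:
    """Magnitude spectrum at non-negative frequencies (DC bin retained).

    The DC bin is kept in the container but excluded from feature
    correlations by the ranking module.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 4:
        raise ValueError("need a 1-D series of length >= 4")
    mags = np.abs(np.fft.rfft(values))
    df = 1.0 / (len(values) * tr)
    return FrequencySpectrum(magnitudes=mags, df=df)
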