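"""Two-point equivalent-noise decomposition.

An observer judging the mean orientation/direction of a field of noisy
elements has total uncertainty

    sigma_obs = sqrt((sigma_int^2 + sigma_ext^2) / eta)

where ``sigma_int`` is the internal noise on a single element, ``sigma_ext``
the external (stimulus) noise, and ``eta`` the sampling efficiency — the
effective number of elements pooled. Two measurements pin both parameters
down:

* zero external noise:  sigma_obs,0 = sigma_int / sqrt(eta)
* high external noise (sigma_ext >> sigma_int):
  sigma_obs,H ~ sigma_ext,H / sqrt(eta)

so that

    eta       = sigma_ext,H^2 / sigma_obs,H^2
    sigma_int = sigma_obs,0 * sqrt(eta)

with first-order uncertainty propagation

    delta_eta       = (2 sigma_ext,H / sigma_obs,H^2) * delta_sigma_ext,H
    delta_sigma_int = sqrt(eta * delta_sigma_obs,0^2
                           + sigma_obs,0^2 / (4 eta) * delta_eta^2)

In the high-noise condition the observed noise level sigma_obs,H is fixed by
design (default pi/4 rad, i.e. 45 deg): the tilt is held there and the
external noise is staircased to the 70.7%-correct point, so sigma_obs,H is
set rather than measured and carries no uncertainty.

Staircase thresholds are 70.7%-correct tilt levels, not standard deviations;
``threshold_to_sigma`` bridges the two with a calibration constant k. For a
Gaussian observer the 70.7% tilt threshold equals Phi^-1(0.7071) * sigma, so
the default k = Phi^-1(sqrt(1/2)) ~ 0.5449 recovers the generating sigma
exactly; k = 1 keeps thresholds as-is (the literal convention in which the
70.7% threshold is *called* sigma_obs). sigma_int estimates are invariant to
this choice; eta estimates scale with k^2.
"""
from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

from .staircase import StaircaseProtocol, StaircaseState, ThresholdEstimate

__all__ = [
    "K_GAUSSIAN",
    "SIGMA_OBS_HIGH_DEFAULT",
    "ENInputs",
    "ENEstimate",
    "predicted_sigma_obs",
    "estimate_en_parameters",
    "threshold_to_sigma",
    "EquivalentNoiseModel",
    "EquivalentNoiseResults",
    "en_inputs_from_estimates",
    "zero_noise_protocol",
    "high_noise_protocol",
]

#: Phi^-1(sqrt(1/2)): z-score of the 70.7%-correct point of a Gaussian
#: psychometric function (the 1-up/2-down convergence level).
K_GAUSSIAN: float = float(stats.norm.ppf(math.sqrt(0.5)))

#: High-noise design point: the fixed tilt, 45 deg from vertical.
SIGMA_OBS_HIGH_DEFAULT: float = math.pi / 4


@dataclass(frozen=True)
class ENInputs:
    """Two-point measurements, all in radians.

    sigma_obs0 / delta_sigma_obs0: zero-external-noise threshold and its SD
    (already converted through the calibration constant where one is used);
    sigma_extH / delta_sigma_extH: the staircased external-noise level at
    70.7% correct under high noise (a physical SD, never rescaled);
    sigma_obsH: the fixed observed-noise level of the high-noise condition.
    """

    sigma_obs0: float
    delta_sigma_obs0: float
    sigma_extH: float
    delta_sigma_extH: float
    sigma_obsH: float = SIGMA_OBS_HIGH_DEFAULT

    def __post_init__(self):
        for name in ("sigma_obs0", "delta_sigma_obs0", "sigma_extH", "delta_sigma_extH"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.sigma_obsH <= 0:
            raise ValueError(f"sigma_obsH must be > 0, got {self.sigma_obsH}")


@dataclass(frozen=True)
class ENEstimate:
    """Sampling efficiency and internal noise with propagated uncertainties.
    ``high_noise_regime_ok`` flags whether sigma_ext,H >> sigma_int actually
    held (criterion: sigma_ext,H >= 3 * estimated sigma_int)."""

    eta: float
    sigma_int: float
    delta_eta: float
    delta_sigma_int: float
    high_noise_regime_ok: bool


def predicted_sigma_obs(sigma_int: float, sigma_ext: float, eta: float) -> float:
    """Observed noise predicted by the equivalent-noise model,
    sqrt((sigma_int^2 + sigma_ext^2) / eta)."""
    if eta <= 0:
        raise ValueError(f"eta must be > 0, got {eta}")
    if sigma_int < 0 or sigma_ext < 0:
        raise ValueError("sigma_int and sigma_ext must be >= 0")
    return math.sqrt((sigma_int**2 + sigma_ext**2) / eta)


def estimate_en_parameters(inputs: ENInputs) -> ENEstimate:
    """Invert the two-point system for (eta, sigma_int) and propagate the
    measurement uncertainties to first order."""
    if inputs.sigma_extH <= 0:
        raise ValueError(f"sigma_extH must be > 0, got {inputs.sigma_extH}")
    eta = inputs.sigma_extH**2 / inputs.sigma_obsH**2
    sigma_int = inputs.sigma_obs0 * math.sqrt(eta)
    delta_eta = 2.0 * inputs.sigma_extH / inputs.sigma_obsH**2 * inputs.delta_sigma_extH
    delta_sigma_int = math.sqrt(
        eta * inputs.delta_sigma_obs0**2
        + inputs.sigma_obs0**2 / (4.0 * eta) * delta_eta**2
    )
    return ENEstimate(
        eta=eta,
        sigma_int=sigma_int,
        delta_eta=delta_eta,
        delta_sigma_int=delta_sigma_int,
        high_noise_regime_ok=bool(inputs.sigma_extH >= 3.0 * sigma_int),
    )


def threshold_to_sigma(
    threshold: float,
    delta: float = 0.0,
    calibration_k: float = K_GAUSSIAN,
    degrees: bool = False,
) -> tuple[float, float]:
    """Convert a 70.7%-correct tilt threshold (and its SD) to an equivalent
    noise SD: sigma = threshold / k. Pass ``degrees=True`` for inputs in
    degrees; all model math is in radians."""
    if calibration_k <= 0:
        raise ValueError(f"calibration_k must be > 0, got {calibration_k}")
    if threshold < 0 or delta < 0:
        raise ValueError("threshold and delta must be >= 0")
    scale = math.radians(1.0) if degrees else 1.0
    return threshold * scale / calibration_k, delta * scale / calibration_k


def en_inputs_from_estimates(
    zero_noise: ThresholdEstimate,
    high_noise: ThresholdEstimate,
    calibration_k: float = K_GAUSSIAN,
    tilt_high: float = SIGMA_OBS_HIGH_DEFAULT,
) -> ENInputs:
    """Assemble ENInputs from the two staircase threshold estimates.

    The zero-noise tilt threshold is converted through the calibration
    constant; the high-noise threshold is already an external-noise SD and is
    used raw; the fixed high-noise tilt is converted the same way as any tilt
    threshold, giving sigma_obsH = tilt_high / k (with k = 1 this is the
    literal sigma_obsH = pi/4 convention)."""
    sigma_obs0, delta_obs0 = threshold_to_sigma(
        zero_noise.threshold, zero_noise.spread, calibration_k
    )
    sigma_obsH, _ = threshold_to_sigma(tilt_high, 0.0, calibration_k)
    return ENInputs(
        sigma_obs0=sigma_obs0,
        delta_sigma_obs0=delta_obs0,
        sigma_extH=high_noise.threshold,
        delta_sigma_extH=high_noise.spread,
        sigma_obsH=sigma_obsH,
    )


class EquivalentNoiseModel:
    """Model wrapper around the two-point decomposition.

    Parameters
    ----------
    inputs : ENInputs
        The two-point measurements.

    Use :meth:`from_thresholds` to start from raw staircase estimates.
    """

    def __init__(self, inputs: ENInputs):
        self.inputs = inputs

    @classmethod
    def from_thresholds(
        cls,
        zero_noise: ThresholdEstimate,
        high_noise: ThresholdEstimate,
        calibration_k: float = K_GAUSSIAN,
        tilt_high: float = SIGMA_OBS_HIGH_DEFAULT,
    ) -> "EquivalentNoiseModel":
        return cls(en_inputs_from_estimates(zero_noise, high_noise, calibration_k, tilt_high))

    def fit(self) -> "EquivalentNoiseResults":
        return EquivalentNoiseResults(self, estimate_en_parameters(self.inputs))


class EquivalentNoiseResults:
    """Fitted (eta, sigma_int) with uncertainties and diagnostics."""

    def __init__(self, model: EquivalentNoiseModel, estimate: ENEstimate):
        self.model = model
        self._estimate = estimate

    @property
    def eta(self) -> float:
        return self._estimate.eta

    @property
    def sigma_int(self) -> float:
        return self._estimate.sigma_int

    @property
    def delta_eta(self) -> float:
        return self._estimate.delta_eta

    @property
    def delta_sigma_int(self) -> float:
        return self._estimate.delta_sigma_int

    @property
    def high_noise_regime_ok(self) -> bool:
        return self._estimate.high_noise_regime_ok

    @property
    def estimate(self) -> ENEstimate:
        return self._estimate

    def predict(self, sigma_ext) -> np.ndarray:
        """Predicted sigma_obs along an external-noise axis (the fitted EN
        curve)."""
        sigma_ext = np.asarray(sigma_ext, dtype=float)
        return np.sqrt((self.sigma_int**2 + sigma_ext**2) / self.eta)

    def to_series(self) -> pd.Series:
        i, e = self.model.inputs, self._estimate
        return pd.Series(
            {
                "sigma_obs0": i.sigma_obs0,
                "delta_sigma_obs0": i.delta_sigma_obs0,
                "sigma_extH": i.sigma_extH,
                "delta_sigma_extH": i.delta_sigma_extH,
                "sigma_obsH": i.sigma_obsH,
                "eta": e.eta,
                "delta_eta": e.delta_eta,
                "sigma_int": e.sigma_int,
                "delta_sigma_int": e.delta_sigma_int,
                "regime_ok": e.high_noise_regime_ok,
            }
        )

    def summary(self) -> str:
        e = self._estimate
        lines = [
            "Equivalent-noise decomposition (two-point)",
            "=" * 44,
            f"sampling efficiency  eta       = {e.eta:8.4f} +/- {e.delta_eta:.4f}",
            f"internal noise       sigma_int = {e.sigma_int:8.4f} +/- {e.delta_sigma_int:.4f} rad",
            f"high-noise regime (sigma_extH >= 3 sigma_int): "
            f"{'ok' if e.high_noise_regime_ok else 'VIOLATED'}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EquivalentNoiseResults eta={self.eta:.3f} sigma_int={self.sigma_int:.3f}>"
        )


# --- staircase protocols for the two EN measurements ------------------------

def zero_noise_protocol(max_trials: int = 150,
                        min_total_reversals: int | None = None) -> StaircaseProtocol:
    """Tilt staircase at zero external noise: level is the tilt magnitude in
    radians, smaller tilt is harder."""
    return StaircaseProtocol(
        initial_level=0.35,
        step_schedule=(0.12, 0.08, 0.05, 0.035, 0.025, 0.015, 0.01),
        level_bounds=(0.001, math.pi / 2),
        harder="decrease",
        max_trials=max_trials,
        min_total_reversals=min_total_reversals,
    )


def high_noise_protocol(max_trials: int = 150,
                        min_total_reversals: int | None = None) -> StaircaseProtocol:
    """External-noise staircase at the fixed high-noise tilt: level is
    sigma_ext in radians, more noise is harder.

    The noise task's psychometric function is shallow in sigma_ext, so the
    terminal steps stay coarse (0.15 rad) — finer steps freeze the track
    before it reaches its convergence level — and the upper bound (2 pi)
    sits well above the 70.7% noise level of efficient observers
    (~1.44 sqrt(eta) rad for a Gaussian observer) so clamping cannot
    truncate the track's stationary distribution."""
    return StaircaseProtocol(
        initial_level=0.1,
        step_schedule=(0.6, 0.5, 0.4, 0.3, 0.25, 0.2, 0.15),
        level_bounds=(0.0, 2 * math.pi),
        harder="increase",
        max_trials=max_trials,
        min_total_reversals=min_total_reversals,
    )
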