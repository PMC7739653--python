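"""Lactate-threshold estimation, V̇O₂peak extraction and submaximal stop rules.

Blood lactate is modelled as an exponential function of oxygen uptake,
``La = a·exp(b·V̇O₂)``, fitted by nonlinear least squares on the lactate
scale and initialised from the log-linear regression of ln(La) on V̇O₂.
The threshold oxygen uptake at a fixed lactate (conventionally 4 mmol·L⁻¹)
is the closed-form inversion ``V̇O₂ = ln(threshold/a)/b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .types import InputError, LactateModelFit, StageRecord, TerminationCriteria


def _exp_model(vo2: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(b * vo2)


def fit_lactate_model(
    vo2_mL_kg_min: Sequence[float],
    lactate_mmol: Sequence[float],
    *,
    exclude_first_point: bool = False,
) -> LactateModelFit:
    """Fit ``La = a·exp(b·V̇O₂)`` to stage data.

    V̇O₂ in mL·kg⁻¹·min⁻¹ so that the inverted threshold is on the scale the
    field reports. Points with non-positive lactate are dropped (they carry
    no information for the exponential model). ``exclude_first_point`` drops
    the lowest-intensity stage, whose near-baseline lactate sometimes sits
    off the exponential.
    """
    x = np.asarray(vo2_mL_kg_min, dtype=float)
    y = np.asarray(lactate_mmol, dtype=float)
    if x.shape != y.shape:
        raise InputError("vo2 and lactate vectors must have equal length")
    keep = y > 0
    x, y = x[keep], y[keep]
    if exclude_first_point and x.size > 0:
        i0 = int(np.argmin(x))
        mask = np.ones(x.size, dtype=bool)
        mask[i0] = False
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise InputError(f"need >= 3 stages with positive lactate, got {x.size}")
    if np.unique(x).size < 3:
        raise InputError("need >= 3 distinct V̇O₂ values")

    # log-linear initialiser: ln(La) = ln(a) + b·V̇O₂
    slope, intercept = np.polyfit(x, np.log(y), 1)
    if slope <= 0:
        raise InputError(
            "lactate does not increase with V̇O₂; exponential fit is degenerate"
        )
    p0 = (math.exp(intercept), slope)
    try:
        popt, _ = curve_fit(_exp_model, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise InputError(f"lactate model failed to converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    if a <= 0 or b <= 0:
        raise InputError(f"degenerate lactate fit: a={a}, b={b}")
    rss = float(np.sum((y - _exp_model(x, a, b)) ** 2))
    return LactateModelFit(a=a, b=b, rss=rss, n_points=int(x.size))


def fit_lactate_model_from_stages(
    stages: Sequence[StageRecord],
    body_mass_kg: float,
    **kwargs,
) -> LactateModelFit:
    """Convenience wrapper: fit from StageRecords holding absolute V̇O₂ (L·min⁻¹)."""
    vo2 = [s.vo2_L_min * 1000.0 / body_mass_kg for s in stages]
    la = [s.lactate_mmol for s in stages]
    return fit_lactate_model(vo2, la, **kwargs)


def vo2_at_lactate(fit: LactateModelFit, threshold_mmol: float = 4.0) -> float:
    """Oxygen uptake at a fixed blood-lactate concentration.

    Closed-form inversion of the exponential model; plugging the result back
    into the model returns the threshold exactly.
    """
    if threshold_mmol <= 0:
        raise InputError("threshold must be positive")
    if threshold_mmol <= fit.a:
        raise InputError(
            f"threshold {threshold_mmol} mmol/L is at or below the model "
            f"baseline a={fit.a:.3g}; inversion undefined"
        )
    return math.log(threshold_mmol / fit.a) / fit.b


def compute_vo2peak(vo2_series: Sequence[float], *, window: int = 3) -> float:
    """Peak oxygen uptake: highest mean of ``window`` consecutive 10-s samples."""
    v = np.asarray(vo2_series, dtype=float)
    if v.size < window:
        raise InputError(f"need at least {window} samples, got {v.size}")
    if np.any(~np.isfinite(v)):
        raise InputError("vo2_series contains non-finite samples")
    means = np.convolve(v, np.ones(window) / window, mode="valid")
    return float(means.max())


@dataclass(frozen=True)
class StopDecision:
    """Outcome of the submaximal termination check, with per-criterion flags."""

    stop: bool
    rer_met: bool
    ve_vo2_met: bool
    hr_met: bool
    rpe_met: bool


def submax_should_stop(
    stage: StageRecord,
    hr_max: float,
    criteria: TerminationCriteria = TerminationCriteria(),
) -> StopDecision:
    """Whether the incremental test should cease after this stage.

    All four criteria must hold: RER > 1.0, V̇E/V̇O₂ > 30, HR ≥ 90% of the
    athlete's known HR_max, and RPE ≥ 16 (Borg 6–20). Boundary behaviour
    follows the stated rules: RER and the ventilatory equivalent are strict
    inequalities, HR and RPE are inclusive.
    """
    if hr_max <= 0:
        raise InputError("hr_max must be positive")
    rer_met = stage.rer > criteria.rer_min
    ve_vo2 = stage.ve_L_min / stage.vo2_L_min
    ve_vo2_met = bool(ve_vo2 > criteria.ve_vo2_min)
    hr_met = bool(stage.hr >= criteria.hr_frac_min * hr_max)
    rpe_met = bool(stage.rpe >= criteria.rpe_min)
    return StopDecision(
        stop=rer_met and ve_vo2_met and hr_met and rpe_met,
        rer_met=rer_met,
        ve_vo2_met=ve_vo2_met,
        hr_met=hr_met,
        rpe_met=rpe_met,
    )
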