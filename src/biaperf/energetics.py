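"""Roller-skiing treadmill energetics.

Implements the external-power model for uphill treadmill roller skiing,
the oxygen-uptake-to-metabolic-rate conversion (a Weir-type caloric
equivalent restricted to RER ≤ 1.00), gross efficiency, and the
time-trial aerobic/anaerobic energy partition with its accumulated-O₂-deficit
(AOD) conversion.

Conventions
-----------
* Power against gravity and rolling resistance:
  ``PO = v · m_sys · g · (sin α + μR · cos α)`` with ``v`` in m·s⁻¹.
* Aerobic metabolic rate from oxygen uptake (L·min⁻¹) and RER:
  ``MR_ae = 4184 · V̇O₂ · (1.1·RER + 3.9) / 60`` watts. At RER = 1.00 this is
  20.92 kJ per litre of O₂, the carbohydrate caloric equivalent.
* Per-kg quantities are obtained by feeding per-kg inputs; the formulas are
  mass-linear so no separate per-kg code path exists.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import EnergeticsResult, InputError, StageRecord, TreadmillProtocol

#: mL of O₂ equivalent per joule of anaerobic energy, assuming 100%
#: carbohydrate utilisation during supramaximal work.
O2_EQUIVALENT_ML_PER_J = 0.047801

#: Default sampling period of the metabolic cart, seconds.
SAMPLE_PERIOD_S = 10.0

KMH_TO_MS = 1.0 / 3.6


def compute_power_output(
    speed_m_s: float, m_sys_kg: float, protocol: TreadmillProtocol
) -> float:
    """External power output in watts on an inclined treadmill.

    Parameters
    ----------
    speed_m_s:
        Belt speed, m·s⁻¹ (≥ 0).
    m_sys_kg:
        System mass (body + carried equipment), kg (> 0). Pass 1.0 to get
        power per kilogram.
    protocol:
        Supplies incline, rolling-resistance coefficient and g.
    """
    if speed_m_s < 0:
        raise InputError(f"speed must be non-negative, got {speed_m_s}")
    if m_sys_kg <= 0:
        raise InputError(f"system mass must be positive, got {m_sys_kg}")
    return speed_m_s * m_sys_kg * protocol.demand_factor


def compute_aerobic_metabolic_rate(
    vo2_L_min: float, rer: float, *, clamp_rer: bool = False
) -> float:
    """Aerobic metabolic rate in watts from oxygen uptake and RER.

    The caloric equivalent ``4184·(1.1·RER + 3.9)/60`` W·min·L⁻¹ is only
    valid for RER ≤ 1.00 (beyond that, excess CO₂ is non-metabolic).
    RER above 1.00 raises unless ``clamp_rer=True``, which clamps it to 1.00.
    """
    if vo2_L_min < 0:
        raise InputError(f"vo2_L_min must be non-negative, got {vo2_L_min}")
    if rer > 1.0:
        if not clamp_rer:
            raise InputError(
                f"RER {rer} > 1.00 invalidates the caloric equivalent; "
                "pass clamp_rer=True to clamp to 1.00"
            )
        rer = 1.0
    return 4184.0 * vo2_L_min * (1.1 * rer + 3.9) / 60.0


def compute_gross_efficiency(po_W: float, mr_ae_W: float) -> float:
    """Gross efficiency in percent: 100 · PO / MR_ae."""
    if mr_ae_W <= 0:
        raise InputError(f"mr_ae_W must be positive, got {mr_ae_W}")
    if po_W < 0:
        raise InputError(f"po_W must be non-negative, got {po_W}")
    return 100.0 * po_W / mr_ae_W


def select_reference_stage(stages: Sequence[StageRecord]) -> StageRecord:
    """Pick the submaximal stage whose RER is closest to 1.00 from below.

    Only stages with RER ≤ 1.00 qualify. Ties go to the latest (highest
    workload) stage, the one closest to race intensity.
    """
    eligible = [s for s in stages if s.rer <= 1.0]
    if not eligible:
        raise InputError("no valid reference stage: all stages have RER > 1.00")
    # max() keeps the last item among equals when the key ties, but be
    # explicit: sort by (distance from 1.00, -position) and take the best.
    best = None
    best_key = None
    for pos, s in enumerate(eligible):
        key = (1.0 - s.rer, -pos)
        if best_key is None or key < best_key:
            best_key = key
            best = s
    assert best is not None
    return best


def mean_tt_vo2(
    vo2_series: Sequence[float],
    tt_time_s: float,
    *,
    sample_period_s: float = SAMPLE_PERIOD_S,
    skip_onset_samples: int = 0,
) -> float:
    """Time-weighted mean of a sampled V̇O₂ series over a time trial.

    Each sample is the average over one sampling period; the final sample
    covers only the remainder ``tt_time_s - (n-1)·period`` and is weighted
    accordingly. ``skip_onset_samples`` drops leading samples (the onset
    transient) from the average, re-weighting the rest.
    """
    v = np.asarray(vo2_series, dtype=float)
    if v.size == 0:
        raise InputError("vo2_series must be non-empty")
    if tt_time_s <= 0:
        raise InputError("tt_time_s must be positive")
    n = v.size
    durations = np.full(n, sample_period_s)
    last = tt_time_s - sample_period_s * (n - 1)
    if not 0.0 < last <= sample_period_s + 1e-9:
        raise InputError(
            f"series length {n} inconsistent with tt_time_s={tt_time_s} "
            f"at {sample_period_s}-s sampling"
        )
    durations[-1] = last
    if skip_onset_samples:
        if skip_onset_samples >= n:
            raise InputError("cannot skip all samples")
        v = v[skip_onset_samples:]
        durations = durations[skip_onset_samples:]
    return float(np.sum(v * durations) / np.sum(durations))


def integrate_mr_ae_trapezoid(
    vo2_series: Sequence[float],
    tt_time_s: float,
    *,
    sample_period_s: float = SAMPLE_PERIOD_S,
) -> float:
    """Aerobic energy (J per unit of the V̇O₂ series' mass basis) by
    trapezoidal integration of the per-sample MR_ae trace at RER = 1.00.

    Samples are placed at the midpoints of their sampling intervals and the
    edge intervals are closed with rectangles. Serves as an independent
    cross-check of the mean-V̇O₂ shortcut used by :func:`compute_tt_energetics`.
    """
    v = np.asarray(vo2_series, dtype=float)
    if v.size == 0:
        raise InputError("vo2_series must be non-empty")
    mr = np.array([compute_aerobic_metabolic_rate(x / 1000.0, 1.0) for x in v])
    n = v.size
    starts = sample_period_s * np.arange(n)
    ends = np.minimum(starts + sample_period_s, tt_time_s)
    mids = 0.5 * (starts + ends)
    if n == 1:
        return float(mr[0] * tt_time_s)
    core = float(np.trapezoid(mr, mids))
    head = float(mr[0] * (mids[0] - 0.0))
    tail = float(mr[-1] * (tt_time_s - mids[-1]))
    return core + head + tail


def compute_aod(e_an_J_per_kg: float) -> float:
    """Accumulated O₂ deficit (mL·kg⁻¹) from anaerobic energy (J·kg⁻¹).

    Negative input (sub-maximal trial) yields a negative value; callers flag
    that upstream rather than erroring here.
    """
    if not math.isfinite(e_an_J_per_kg):
        raise InputError("e_an_J_per_kg must be finite")
    return O2_EQUIVALENT_ML_PER_J * e_an_J_per_kg


def compute_tt_energetics(
    tt_time_s: float,
    vo2_series_mL_kg_min: Sequence[float],
    ge_pct: float,
    po_tt_W_per_kg: float,
    *,
    sample_period_s: float = SAMPLE_PERIOD_S,
    skip_onset_samples: int = 0,
) -> EnergeticsResult:
    """Partition a time trial into aerobic and anaerobic energy, per kg.

    The required metabolic rate is ``MR_req = PO_tt / (GE/100)`` using the
    gross efficiency from the submaximal reference stage. The aerobic rate
    comes from the time-weighted mean V̇O₂ of the trial at RER fixed to 1.00
    (100% carbohydrate utilisation during supramaximal work). Energies are
    rates × trial time; the anaerobic energy is converted to an accumulated
    O₂ deficit with 0.047801 mL O₂ per joule.
    """
    if tt_time_s <= 0:
        raise InputError("tt_time_s must be positive")
    if ge_pct <= 0:
        raise InputError(f"ge_pct must be positive, got {ge_pct}")
    if po_tt_W_per_kg < 0:
        raise InputError("po_tt_W_per_kg must be non-negative")

    mean_vo2 = mean_tt_vo2(
        vo2_series_mL_kg_min,
        tt_time_s,
        sample_period_s=sample_period_s,
        skip_onset_samples=skip_onset_samples,
    )
    mr_req = po_tt_W_per_kg / (ge_pct / 100.0)
    mr_ae = compute_aerobic_metabolic_rate(mean_vo2 / 1000.0, 1.0)
    mr_an = mr_req - mr_ae

    e_req = mr_req * tt_time_s
    e_ae = mr_ae * tt_time_s
    e_an = e_req - e_ae
    e_ae_pct = 100.0 * e_ae / e_req if e_req > 0 else float("nan")
    e_an_pct = 100.0 - e_ae_pct

    return EnergeticsResult(
        po_tt_W_per_kg=po_tt_W_per_kg,
        mr_req_W_per_kg=mr_req,
        mr_ae_W_per_kg=mr_ae,
        mr_an_W_per_kg=mr_an,
        e_req_J_per_kg=e_req,
        e_ae_J_per_kg=e_ae,
        e_an_J_per_kg=e_an,
        e_ae_pct=e_ae_pct,
        e_an_pct=e_an_pct,
        aod_mL_per_kg=compute_aod(e_an),
        ge_pct=ge_pct,
        mean_tt_vo2_mL_kg_min=mean_vo2,
        tt_time_s=tt_time_s,
        anaerobic_negative=bool(mr_an < 0),
    )
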