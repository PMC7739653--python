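"""Domain types for treadmill roller-skiing energetics.

All quantities carry explicit units in their field names where ambiguity is
possible. Power and metabolic rates are expressed per kilogram of body mass
throughout the time-trial chain, matching how the physiological literature
reports them for weight-bearing locomotion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class InputError(ValueError):
    """Raised when an operation receives physically invalid input."""


@dataclass(frozen=True)
class TreadmillProtocol:
    """Treadmill test protocol constants for one sex group.

    Parameters
    ----------
    incline_deg:
        Treadmill inclination angle in degrees.
    mu_r:
        Dimensionless rolling-resistance coefficient of the roller skis.
    g:
        Gravitational acceleration, m·s⁻².
    distance_m:
        Time-trial distance in metres.
    start_speed_kmh:
        Initial belt speed for the self-paced time trial, km·h⁻¹.
    submax_start_speed_kmh:
        Belt speed of the first submaximal stage, km·h⁻¹.
    submax_increment_kmh:
        Speed increment between successive submaximal stages, km·h⁻¹.
    """

    incline_deg: float
    mu_r: float
    g: float = 9.81
    distance_m: float = 900.0
    start_speed_kmh: float = 13.0
    submax_start_speed_kmh: float = 7.0
    submax_increment_kmh: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.incline_deg <= 20.0:
            raise InputError(f"incline_deg must be in [0, 20], got {self.incline_deg}")
        if not 0.0 < self.mu_r < 0.1:
            raise InputError(f"mu_r must be in (0, 0.1), got {self.mu_r}")
        if self.g <= 0:
            raise InputError("g must be positive")
        if self.distance_m <= 0:
            raise InputError("distance_m must be positive")

    @property
    def incline_rad(self) -> float:
        return math.radians(self.incline_deg)

    @property
    def demand_factor(self) -> float:
        """g·(sin α + μR·cos α): power per unit mass per unit speed, W·s·m⁻¹·kg⁻¹."""
        a = self.incline_rad
        return self.g * (math.sin(a) + self.mu_r * math.cos(a))


@dataclass(frozen=True)
class AthleteProfile:
    """Anthropometrics and identity of one athlete."""

    athlete_id: str
    sex: str  # "female" | "male"
    body_mass_kg: float
    equipment_mass_kg: float = 0.0
    height_cm: float = float("nan")
    age_yr: float = float("nan")
    hr_max: float = float("nan")

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.body_mass_kg <= 0:
            raise InputError("body_mass_kg must be positive")
        if self.equipment_mass_kg < 0:
            raise InputError("equipment_mass_kg must be non-negative")

    @property
    def system_mass_kg(self) -> float:
        """Mass moved against gravity and rolling resistance."""
        return self.body_mass_kg + self.equipment_mass_kg


@dataclass(frozen=True)
class StageRecord:
    """One submaximal treadmill stage (values from the last 30 s of the stage)."""

    speed_kmh: float
    vo2_L_min: float
    rer: float
    lactate_mmol: float
    hr: float = float("nan")
    rpe: float = float("nan")
    ve_L_min: float = float("nan")
    stage_index: int = 0

    def __post_init__(self) -> None:
        if self.vo2_L_min <= 0:
            raise InputError("vo2_L_min must be positive")
        if not 0.6 <= self.rer <= 1.4:
            raise InputError(f"rer out of physiological range [0.6, 1.4]: {self.rer}")
        if self.lactate_mmol < 0:
            raise InputError("lactate_mmol must be non-negative")


@dataclass(frozen=True)
class EnergeticsResult:
    """Aerobic/anaerobic partition of a time trial, per kg body mass.

    Invariants: ``mr_req = mr_ae + mr_an`` and ``e_ae_pct + e_an_pct = 100``
    hold by construction; ``aod_mL_per_kg`` is non-negative whenever
    ``mr_an`` is.
    """

    po_tt_W_per_kg: float
    mr_req_W_per_kg: float
    mr_ae_W_per_kg: float
    mr_an_W_per_kg: float
    e_req_J_per_kg: float
    e_ae_J_per_kg: float
    e_an_J_per_kg: float
    e_ae_pct: float
    e_an_pct: float
    aod_mL_per_kg: float
    ge_pct: float
    mean_tt_vo2_mL_kg_min: float
    tt_time_s: float
    anaerobic_negative: bool = field(default=False)
    """True when MR_an came out negative (sub-maximal effort or noisy inputs)."""


@dataclass(frozen=True)
class LactateModelFit:
    """Two-parameter exponential blood-lactate model  La = a·exp(b·V̇O₂).

    ``a`` is in mmol·L⁻¹, ``b`` in (mL·kg⁻¹·min⁻¹)⁻¹ when fitted on
    body-mass-relative oxygen uptake.
    """

    a: float
    b: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise InputError(f"degenerate lactate fit: a={self.a}, b={self.b}")
        if self.n_points < 3:
            raise InputError("lactate fit needs at least 3 points")

    def predict(self, vo2: float) -> float:
        return self.a * math.exp(self.b * vo2)


@dataclass(frozen=True)
class TerminationCriteria:
    """Submaximal-test stop rules; the test ceases when ALL are met."""

    rer_min: float = 1.0
    ve_vo2_min: float = 30.0
    hr_frac_min: float = 0.90
    rpe_min: float = 16.0

    def __post_init__(self) -> None:
        for name in ("rer_min", "ve_vo2_min", "hr_frac_min", "rpe_min"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
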