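"""Synthetic biathlete cohort generator.

Draws per-sex cohorts whose physiological marginals (V̇O₂max, gross
efficiency, fractional utilisation at 4 mmol·L⁻¹ lactate, anaerobic
capacity, anthropometrics) match published elite-biathlete distributions,
and whose field-competition skiing speed is a latent linear combination of
those traits. The combination weights are population parameters chosen at
construction time so that the variance explained by each trait matches the
calibration targets — they are not tuned to any generated sample.

The generator then simulates the two laboratory tests:

* an incremental submaximal test (4-min stages, +2 km·h⁻¹ per stage) whose
  oxygen cost follows the athlete's gross efficiency and whose blood lactate
  follows an exponential lactate–V̇O₂ curve anchored at 4 mmol·L⁻¹ at the
  athlete's fractional utilisation;
* a self-paced treadmill time trial whose duration solves the energy
  balance: required energy (distance × demand / GE) = aerobic supply
  (mono-exponential V̇O₂ onset toward V̇O₂max) + anaerobic capacity.

With all noise terms at zero, every laboratory-derived quantity recovered
by the analysis pipeline equals its generating latent value (closure), so
parameter-recovery tests separate estimation error from biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .energetics import (
    KMH_TO_MS,
    O2_EQUIVALENT_ML_PER_J,
    SAMPLE_PERIOD_S,
    compute_power_output,
)
from .thresholds import submax_should_stop
from .types import (
    AthleteProfile,
    InputError,
    StageRecord,
    TerminationCriteria,
    TreadmillProtocol,
)

#: W per (mL·kg⁻¹·min⁻¹) of oxygen uptake at RER = 1.00 (carbohydrate).
W_PER_ML_KG_MIN = 4184.0 * 5.0 / 60.0 / 1000.0  # 0.348667


@dataclass(frozen=True)
class SexParams:
    """Per-sex trait distributions (mean, SD) and protocol constants."""

    vo2max: tuple[float, float]          # mL·kg⁻¹·min⁻¹
    ge_pct: tuple[float, float]          # %
    frac_util_pct: tuple[float, float]   # V̇O₂@4mmol as % of V̇O₂max
    aod: tuple[float, float]             # mL·kg⁻¹
    body_mass_kg: tuple[float, float]
    height_cm: tuple[float, float]
    age_yr: tuple[float, float]
    hr_max: tuple[float, float]
    bc_speed_m_s: tuple[float, float]    # field-competition skiing speed
    bc_course_m: float
    #: BC-speed loadings on the standardized latents
    #: (V̇O₂max, GE, AOD, fractional utilisation); each squared loading is
    #: that trait's share of BC-speed variance.
    bc_loadings: tuple[float, float, float, float]


@dataclass(frozen=True)
class NoiseParams:
    """Measurement / day-to-day noise magnitudes."""

    vo2_sigma_mL_kg_min: float = 1.5
    lactate_sigma_mmol: float = 0.2
    rer_sigma: float = 0.01
    aod_day_cv: float = 0.10  # day-to-day CV of anaerobic capacity

    def zeroed(self) -> "NoiseParams":
        return NoiseParams(0.0, 0.0, 0.0, 0.0)


# Calibration: female/male elite-biathlete cohorts. The first three BC
# loadings are the square roots of each trait's published share of BC-speed
# variance (females 31/35/1 %, males 21/31/0 % for V̇O₂max/GE/anaerobic
# capacity). The fourth (fractional utilisation) is solved so the threshold
# uptake V̇O₂@4mmol = frac_util·V̇O₂max carries its published share too
# (30% female, 35% male): with independent latents,
# corr(V̇O₂@4mmol, BC) = α_v·w_v + α_f·w_f where (α_v, α_f) are the
# linearised loadings of the threshold uptake on the two latents.
def solve_frac_loading(
    vo2max: tuple[float, float],
    frac_util_pct: tuple[float, float],
    w_v: float,
    threshold_share: float,
) -> float:
    """BC loading on fractional utilisation that gives the threshold uptake
    its target share of BC-speed variance.

    Linearising V̇O₂@4mmol = frac·V̇O₂max around the means, its standardized
    loadings on the two latents are proportional to (frac_mean·sd_vo2max,
    vo2max_mean·sd_frac); the implied correlation with BC speed is then
    α_v·w_v + α_f·w_f, set equal to sqrt(threshold_share).
    """
    sv = frac_util_pct[0] / 100.0 * vo2max[1]
    sf = vo2max[0] * frac_util_pct[1] / 100.0
    norm = math.hypot(sv, sf)
    alpha_v, alpha_f = sv / norm, sf / norm
    w_f = (math.sqrt(threshold_share) - alpha_v * w_v) / alpha_f
    if not 0.0 <= w_f <= 1.0:
        raise InputError(f"threshold share {threshold_share} not attainable")
    return w_f


FEMALE_PARAMS = SexParams(
    vo2max=(55.6, 4.1),
    ge_pct=(16.6, 0.8),
    frac_util_pct=(82.1, 3.6),
    aod=(49.2, 9.9),
    body_mass_kg=(62.8, 5.6),
    height_cm=(166.4, 6.3),
    age_yr=(22.9, 3.2),
    hr_max=(188.0, 6.0),
    bc_speed_m_s=(4.7, 0.3),
    bc_course_m=10000.0,
    bc_loadings=(
        math.sqrt(0.31),
        math.sqrt(0.35),
        math.sqrt(0.01),
        solve_frac_loading((55.6, 4.1), (82.1, 3.6), math.sqrt(0.31), 0.30),
    ),
)
MALE_PARAMS = SexParams(
    vo2max=(66.0, 3.2),
    ge_pct=(18.4, 1.1),
    frac_util_pct=(81.3, 3.9),
    aod=(57.7, 15.5),
    body_mass_kg=(74.8, 5.6),
    height_cm=(178.8, 6.2),
    age_yr=(24.0, 3.9),
    hr_max=(191.0, 7.0),
    bc_speed_m_s=(6.1, 0.2),
    bc_course_m=12500.0,
    bc_loadings=(
        math.sqrt(0.21),
        math.sqrt(0.31),
        0.0,
        solve_frac_loading((66.0, 3.2), (81.3, 3.9), math.sqrt(0.21), 0.35),
    ),
)

FEMALE_PROTOCOL = TreadmillProtocol(
    incline_deg=3.5, mu_r=0.0224, distance_m=900.0,
    start_speed_kmh=13.0, submax_start_speed_kmh=7.0,
)
MALE_PROTOCOL = TreadmillProtocol(
    incline_deg=4.5, mu_r=0.0216, distance_m=1000.0,
    start_speed_kmh=14.0, submax_start_speed_kmh=8.0,
)

#: V̇O₂ onset time constant during the time trial, seconds.
VO2_ONSET_TAU_S = 25.0
#: V̇O₂ at the start of the trial as a fraction of V̇O₂max (post re-warm-up).
VO2_BASELINE_FRAC = 0.40

# physiologic bounds for latent traits (clip rare extreme draws)
_BOUNDS = {
    "vo2max": (35.0, 90.0),
    "ge_pct": (12.0, 24.0),
    "frac_util": (0.65, 0.95),
    "aod": (15.0, 120.0),
}


@dataclass(frozen=True)
class CohortConfig:
    n_per_sex: int = 14
    seed: int = 0
    female: SexParams = field(default_factory=lambda: FEMALE_PARAMS)
    male: SexParams = field(default_factory=lambda: MALE_PARAMS)
    female_protocol: TreadmillProtocol = FEMALE_PROTOCOL
    male_protocol: TreadmillProtocol = MALE_PROTOCOL
    noise: NoiseParams = field(default_factory=NoiseParams)
    max_stages: int = 6

    def __post_init__(self) -> None:
        if self.n_per_sex < 2:
            raise InputError("n_per_sex must be >= 2")
        for sex in (self.female, self.male):
            ss = sum(w * w for w in sex.bc_loadings)
            if ss > 1.0 + 1e-12:
                raise InputError(
                    "BC loadings imply a non-positive-definite covariance: "
                    f"sum of squared loadings {ss:.3f} > 1"
                )

    def params_for(self, sex: str) -> SexParams:
        return self.female if sex == "female" else self.male

    def protocol_for(self, sex: str) -> TreadmillProtocol:
        return self.female_protocol if sex == "female" else self.male_protocol

    def noiseless(self) -> "CohortConfig":
        return replace(self, noise=self.noise.zeroed())


@dataclass(frozen=True)
class SyntheticAthlete:
    """An athlete plus the latent traits the generator drew for them."""

    profile: AthleteProfile
    true_vo2max: float       # mL·kg⁻¹·min⁻¹
    true_ge_pct: float       # %
    true_frac_util: float    # fraction of V̇O₂max at 4 mmol·L⁻¹
    true_aod: float          # mL·kg⁻¹
    bc_speed_m_s: float

    def __post_init__(self) -> None:
        lo, hi = _BOUNDS["vo2max"]
        if not lo <= self.true_vo2max <= hi:
            raise InputError(f"true_vo2max {self.true_vo2max} outside [{lo}, {hi}]")
        lo, hi = _BOUNDS["ge_pct"]
        if not lo <= self.true_ge_pct <= hi:
            raise InputError(f"true_ge_pct {self.true_ge_pct} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class CompetitionResult:
    athlete_id: str
    bc_speed_m_s: float
    total_ski_time_s: float


@dataclass(frozen=True)
class TimeTrialRecord:
    athlete_id: str
    distance_m: float
    time_s: float
    vo2_series_mL_kg_min: tuple[float, ...]  # consecutive 10-s samples


def _clip(name: str, x: np.ndarray) -> np.ndarray:
    lo, hi = _BOUNDS[name]
    return np.clip(x, lo, hi)


def generate_cohort(config: CohortConfig) -> list[SyntheticAthlete]:
    """Draw a two-sex cohort with calibrated marginals and BC-speed structure.

    The three performance latents (V̇O₂max, GE, anaerobic capacity) are
    independent standard normals scaled to their marginal (mean, SD); the
    standardized BC speed is their weighted sum plus independent residual,
    with weights from ``SexParams.bc_loadings``. Because the latents are
    mutually independent, each squared loading is exactly that trait's
    population share of BC-speed variance, and the population correlation of
    a trait with BC speed equals its loading.
    """
    rng = np.random.default_rng(config.seed)
    athletes: list[SyntheticAthlete] = []
    for sex in ("female", "male"):
        p = config.params_for(sex)
        n = config.n_per_sex
        z_v, z_g, z_a, z_f, z_e = rng.standard_normal((5, n))
        vo2max = _clip("vo2max", p.vo2max[0] + p.vo2max[1] * z_v)
        ge = _clip("ge_pct", p.ge_pct[0] + p.ge_pct[1] * z_g)
        aod = _clip("aod", p.aod[0] + p.aod[1] * z_a)
        frac = _clip(
            "frac_util",
            (p.frac_util_pct[0] + p.frac_util_pct[1] * z_f) / 100.0,
        )
        w_v, w_g, w_a, w_f = p.bc_loadings
        resid_sd = math.sqrt(max(0.0, 1.0 - (w_v**2 + w_g**2 + w_a**2 + w_f**2)))
        z_bc = w_v * z_v + w_g * z_g + w_a * z_a + w_f * z_f + resid_sd * z_e
        bc = p.bc_speed_m_s[0] + p.bc_speed_m_s[1] * z_bc

        # anthropometrics: mass and height share a build factor (r ≈ 0.5)
        z_build = rng.standard_normal(n)
        mass = p.body_mass_kg[0] + p.body_mass_kg[1] * (
            0.5 * z_build + math.sqrt(0.75) * rng.standard_normal(n)
        )
        height = p.height_cm[0] + p.height_cm[1] * (
            0.5 * z_build + math.sqrt(0.75) * rng.standard_normal(n)
        )
        age = p.age_yr[0] + p.age_yr[1] * rng.standard_normal(n)
        hr_max = p.hr_max[0] + p.hr_max[1] * rng.standard_normal(n)

        for i in range(n):
            prefix = "F" if sex == "female" else "M"
            athletes.append(
                SyntheticAthlete(
                    profile=AthleteProfile(
                        athlete_id=f"{prefix}{i + 1:02d}",
                        sex=sex,
                        body_mass_kg=float(max(mass[i], 40.0)),
                        height_cm=float(height[i]),
                        age_yr=float(max(age[i], 16.0)),
                        hr_max=float(hr_max[i]),
                    ),
                    true_vo2max=float(vo2max[i]),
                    true_ge_pct=float(ge[i]),
                    true_frac_util=float(frac[i]),
                    true_aod=float(aod[i]),
                    bc_speed_m_s=float(bc[i]),
                )
            )
    return athletes


def _lactate_params(athlete: SyntheticAthlete) -> tuple[float, float]:
    """Exponential lactate-curve parameters anchored so La = 4 mmol·L⁻¹ at
    the athlete's threshold uptake and La = 1 mmol·L⁻¹ at 55% V̇O₂max."""
    vo2_at_4 = athlete.true_frac_util * athlete.true_vo2max
    vo2_at_1 = 0.55 * athlete.true_vo2max
    b = math.log(4.0 / 1.0) / (vo2_at_4 - vo2_at_1)
    a = 4.0 * math.exp(-b * vo2_at_4)
    return a, b


def _rer_at_intensity(intensity: float) -> float:
    """RER rising linearly from 0.85 at 50% to 1.05 at 100% of V̇O₂max."""
    return float(np.clip(0.85 + 0.4 * (intensity - 0.5), 0.70, 1.15))


def _stage_steady_state(
    mr_W_per_kg: float, vo2max: float
) -> tuple[float, float]:
    """Solve the (V̇O₂, RER) fixed point for a stage of given metabolic rate.

    RER depends on relative intensity, which depends on V̇O₂, which depends
    on RER through the caloric equivalent; iterate to the joint solution.
    """
    rer = 0.95
    vo2 = mr_W_per_kg / W_PER_ML_KG_MIN
    for _ in range(60):
        vo2 = mr_W_per_kg * 60000.0 / (4184.0 * (1.1 * rer + 3.9))
        rer_new = _rer_at_intensity(vo2 / vo2max)
        if abs(rer_new - rer) < 1e-12:
            rer = rer_new
            break
        rer = rer_new
    return vo2, rer


def generate_submax_test(
    athlete: SyntheticAthlete,
    protocol: TreadmillProtocol,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[StageRecord]:
    """Simulate the incremental submaximal test for one athlete.

    Stages of increasing speed are generated until the four-criterion
    termination rule fires (evaluated on the noiseless physiology) or the
    stage would demand more than V̇O₂max. Measurement noise is then applied
    to the recorded V̇O₂, RER and lactate.
    """
    a_la, b_la = _lactate_params(athlete)
    noise = config.noise
    mass = athlete.profile.body_mass_kg
    criteria = TerminationCriteria()
    stages: list[StageRecord] = []
    for k in range(config.max_stages):
        speed_kmh = protocol.submax_start_speed_kmh + k * protocol.submax_increment_kmh
        po = compute_power_output(speed_kmh * KMH_TO_MS, 1.0, protocol)  # W·kg⁻¹
        mr = po / (athlete.true_ge_pct / 100.0)
        vo2, rer = _stage_steady_state(mr, athlete.true_vo2max)
        exhausted = vo2 > athlete.true_vo2max
        if exhausted:
            # stage demand exceeds V̇O₂max: the athlete rides the ceiling for
            # a final, non-steady-state stage (RER pushed above 1.00)
            rer = _rer_at_intensity(vo2 / athlete.true_vo2max)
            vo2 = athlete.true_vo2max
        intensity = vo2 / athlete.true_vo2max
        lactate = a_la * math.exp(b_la * vo2)
        hr = min(athlete.profile.hr_max, athlete.profile.hr_max * (0.45 + 0.60 * intensity))
        rpe = float(np.clip(round(6.0 + 14.0 * intensity), 6, 20))
        ve_ratio = 22.0 + 18.0 * max(0.0, intensity - 0.6) / 0.4
        vo2_meas = vo2 + noise.vo2_sigma_mL_kg_min * rng.standard_normal()
        rer_meas = float(np.clip(rer + noise.rer_sigma * rng.standard_normal(), 0.6, 1.4))
        la_meas = max(0.3, lactate + noise.lactate_sigma_mmol * rng.standard_normal())
        vo2_L_min = vo2_meas * mass / 1000.0
        record = StageRecord(
            speed_kmh=speed_kmh,
            vo2_L_min=vo2_L_min,
            rer=rer_meas,
            lactate_mmol=la_meas,
            hr=float(hr),
            rpe=rpe,
            ve_L_min=ve_ratio * vo2_L_min,
            stage_index=k + 1,
        )
        stages.append(record)
        # termination on the true (noiseless) physiology keeps stage counts
        # deterministic given the latent traits
        truth = StageRecord(
            speed_kmh=speed_kmh, vo2_L_min=vo2 * mass / 1000.0, rer=rer,
            lactate_mmol=lactate, hr=float(hr), rpe=rpe,
            ve_L_min=ve_ratio * vo2 * mass / 1000.0, stage_index=k + 1,
        )
        if exhausted or (
            len(stages) >= 3
            and submax_should_stop(truth, athlete.profile.hr_max, criteria).stop
        ):
            break
    if len(stages) < 3:
        raise InputError(
            f"athlete {athlete.profile.athlete_id}: fewer than 3 submaximal "
            "stages before termination; traits outside the protocol's range"
        )
    return stages


def _aerobic_energy(t: float, mr_max: float) -> float:
    """∫₀ᵗ MR_ae(s) ds for the mono-exponential onset model, J·kg⁻¹."""
    f0 = VO2_BASELINE_FRAC
    tau = VO2_ONSET_TAU_S
    return mr_max * (t - (1.0 - f0) * tau * (1.0 - math.exp(-t / tau)))


def generate_tt(
    athlete: SyntheticAthlete,
    protocol: TreadmillProtocol,
    config: CohortConfig,
    rng: np.random.Generator,
) -> TimeTrialRecord:
    """Simulate the self-paced time trial for one athlete.

    The finish time solves the energy balance
    ``distance · demand_factor / GE = E_ae(t) + AOD/0.047801`` where the
    aerobic side integrates a mono-exponential V̇O₂ rise from 40% to 100% of
    V̇O₂max (τ = 25 s). The recorded V̇O₂ series holds 10-s interval means of
    that trajectory plus measurement noise.
    """
    ge = athlete.true_ge_pct / 100.0
    e_req = protocol.demand_factor * protocol.distance_m / ge  # J·kg⁻¹
    aod_today = athlete.true_aod
    if config.noise.aod_day_cv > 0:
        aod_today = max(
            5.0, aod_today * (1.0 + config.noise.aod_day_cv * rng.standard_normal())
        )
    e_an = aod_today / O2_EQUIVALENT_ML_PER_J
    mr_max = W_PER_ML_KG_MIN * athlete.true_vo2max

    def balance(t: float) -> float:
        return _aerobic_energy(t, mr_max) + e_an - e_req

    t_hi = 3600.0
    if balance(t_hi) < 0:
        raise InputError(
            f"athlete {athlete.profile.athlete_id}: aerobic supply plus "
            "anaerobic capacity cannot cover the trial's energy demand"
        )
    if balance(1e-9) >= 0:
        raise InputError("anaerobic capacity alone exceeds demand; degenerate trial")
    t_fin = brentq(balance, 1e-9, t_hi, xtol=1e-10, rtol=1e-14)

    # 10-s interval means of vo2(t) = vo2max·(1 − (1−f0)·e^{−t/τ})
    f0, tau = VO2_BASELINE_FRAC, VO2_ONSET_TAU_S
    vmax = athlete.true_vo2max
    n = int(math.ceil(t_fin / SAMPLE_PERIOD_S))
    samples = []
    for i in range(n):
        t0 = i * SAMPLE_PERIOD_S
        t1 = min((i + 1) * SAMPLE_PERIOD_S, t_fin)
        integral = vmax * (
            (t1 - t0)
            - (1.0 - f0) * tau * (math.exp(-t0 / tau) - math.exp(-t1 / tau))
        )
        mean_v = integral / (t1 - t0)
        if config.noise.vo2_sigma_mL_kg_min > 0:
            mean_v += config.noise.vo2_sigma_mL_kg_min * rng.standard_normal()
        samples.append(float(mean_v))
    return TimeTrialRecord(
        athlete_id=athlete.profile.athlete_id,
        distance_m=protocol.distance_m,
        time_s=float(t_fin),
        vo2_series_mL_kg_min=tuple(samples),
    )


def generate_competition(
    cohort: Sequence[SyntheticAthlete], config: CohortConfig
) -> list[CompetitionResult]:
    """Field-competition results: the BC speed fixed at cohort generation,
    plus the implied total skiing time over the sex's course length."""
    out = []
    for ath in cohort:
        course = config.params_for(ath.profile.sex).bc_course_m
        out.append(
            CompetitionResult(
                athlete_id=ath.profile.athlete_id,
                bc_speed_m_s=ath.bc_speed_m_s,
                total_ski_time_s=course / ath.bc_speed_m_s,
            )
        )
    return out
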