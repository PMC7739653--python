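"""End-to-end analysis: laboratory energetics per athlete, then cohort
statistics per sex (comparisons, correlations, blockwise regressions).

``simulate`` writes the CSV fixture set from the synthetic-cohort generator;
``run_analysis`` consumes those files (or real data in the same layout) and
produces an :class:`AnalysisReport`. The analysis path contains no random
number generation: identical inputs give identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .cohort import (
    CohortConfig,
    generate_cohort,
    generate_competition,
    generate_submax_test,
    generate_tt,
)
from .energetics import (
    KMH_TO_MS,
    compute_aerobic_metabolic_rate,
    compute_gross_efficiency,
    compute_power_output,
    compute_tt_energetics,
    select_reference_stage,
)
from .stats import (
    GroupSummary,
    RegressionPartition,
    blockwise_regression,
    cohens_d,
    pearson_correlation,
    shapiro_wilk,
    students_t_test,
)
from .thresholds import compute_vo2peak, fit_lactate_model_from_stages, vo2_at_lactate
from .types import InputError, TreadmillProtocol

#: variables compared between sexes (same protocol-independent scale)
COMPARABLE_VARS = [
    "vo2_at_4mmol", "frac_util_pct", "vo2peak", "hr_max", "aod",
    "body_mass_kg", "height_cm", "age_yr",
]
#: variables summarised per sex but not compared (protocols differ)
PROTOCOL_BOUND_VARS = [
    "ge_pct", "po_tt_W_per_kg", "tt_time_s", "tt_speed_m_s",
    "mr_req", "mr_ae", "mr_an", "e_ae_pct", "e_an_pct",
]
#: laboratory variables correlated with field skiing speed
CORRELATION_VARS = [
    "vo2peak", "vo2_at_4mmol", "frac_util_pct", "ge_pct", "tt_speed_m_s",
    "mr_ae", "mr_an", "aod",
]
REGRESSION_MODELS = {
    "vo2peak_model": ["vo2peak", "e_an_pct", "ge_pct"],
    "vo2_at_4mmol_model": ["vo2_at_4mmol", "e_an_pct", "ge_pct"],
}


@dataclass(frozen=True)
class AnalysisReport:
    athletes: pd.DataFrame
    sex_comparison: pd.DataFrame
    correlations: pd.DataFrame
    regressions: dict[str, dict[str, RegressionPartition]]
    normality: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "athletes": self.athletes.to_dict(orient="records"),
            "sex_comparison": self.sex_comparison.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "regressions": {
                sex: {name: asdict(part) for name, part in models.items()}
                for sex, models in self.regressions.items()
            },
            "normality": self.normality.to_dict(orient="records"),
            "exclusions": self.exclusions,
        }
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def analyze_athlete(
    profile,
    stages,
    tt,
    protocol: TreadmillProtocol,
    *,
    lactate_threshold_mmol: float = 4.0,
) -> dict:
    """Full laboratory chain for one athlete.

    Reference stage → GE; exponential lactate fit → V̇O₂@4mmol; TT series →
    V̇O₂peak; TT power → aerobic/anaerobic partition → AOD. Raises
    :class:`InputError` with a reason suitable for the exclusion log.
    """
    ref = select_reference_stage(stages)
    po_ref = compute_power_output(
        ref.speed_kmh * KMH_TO_MS, profile.system_mass_kg, protocol
    )
    mr_ae_ref = compute_aerobic_metabolic_rate(ref.vo2_L_min, ref.rer)
    ge_pct = compute_gross_efficiency(po_ref, mr_ae_ref)

    fit = fit_lactate_model_from_stages(stages, profile.body_mass_kg)
    vo2_4 = vo2_at_lactate(fit, lactate_threshold_mmol)

    vo2peak = compute_vo2peak(tt.vo2_series_mL_kg_min)
    tt_speed = tt.distance_m / tt.time_s
    po_tt_per_kg = compute_power_output(
        tt_speed, profile.system_mass_kg, protocol
    ) / profile.body_mass_kg
    result = compute_tt_energetics(
        tt.time_s, tt.vo2_series_mL_kg_min, ge_pct, po_tt_per_kg
    )
    return {
        "athlete_id": profile.athlete_id,
        "sex": profile.sex,
        "body_mass_kg": profile.body_mass_kg,
        "height_cm": profile.height_cm,
        "age_yr": profile.age_yr,
        "hr_max": profile.hr_max,
        "ge_pct": ge_pct,
        "lactate_a": fit.a,
        "lactate_b": fit.b,
        "vo2_at_4mmol": vo2_4,
        "vo2peak": vo2peak,
        "frac_util_pct": 100.0 * vo2_4 / vo2peak,
        "tt_time_s": tt.time_s,
        "tt_speed_m_s": tt_speed,
        "po_tt_W_per_kg": result.po_tt_W_per_kg,
        "mr_req": result.mr_req_W_per_kg,
        "mr_ae": result.mr_ae_W_per_kg,
        "mr_an": result.mr_an_W_per_kg,
        "e_ae_pct": result.e_ae_pct,
        "e_an_pct": result.e_an_pct,
        "aod": result.aod_mL_per_kg,
        "mean_tt_vo2": result.mean_tt_vo2_mL_kg_min,
        "anaerobic_negative": result.anaerobic_negative,
    }


def run_analysis(
    stage_csv: str | Path,
    tt_csv: str | Path,
    athletes_csv: str | Path,
    protocol_yaml: str | Path,
) -> AnalysisReport:
    """Run the complete analysis over the three-file CSV layout."""
    stages_by_athlete = bio.read_stage_csv(stage_csv)
    tt_by_athlete = bio.read_tt_csv(tt_csv)
    roster = bio.read_athletes_csv(athletes_csv)
    protocols = bio.read_protocol_yaml(protocol_yaml)

    rows = []
    exclusions: list[tuple[str, str]] = []
    for _, r in roster.iterrows():
        aid = str(r["athlete_id"])
        profile = bio.athlete_profile_from_row(r)
        if aid not in stages_by_athlete:
            exclusions.append((aid, "missing submaximal stage data"))
            continue
        if aid not in tt_by_athlete:
            exclusions.append((aid, "missing time-trial data"))
            continue
        try:
            row = analyze_athlete(
                profile,
                stages_by_athlete[aid],
                tt_by_athlete[aid],
                protocols[profile.sex],
            )
        except InputError as exc:
            exclusions.append((aid, str(exc)))
            continue
        row["bc_speed_m_s"] = float(r["bc_speed_m_s"])
        rows.append(row)

    athletes = pd.DataFrame(rows)
    return AnalysisReport(
        athletes=athletes,
        sex_comparison=sex_comparison_table(athletes),
        correlations=correlation_table(athletes),
        regressions=regression_models(athletes),
        normality=normality_table(athletes),
        exclusions=exclusions,
    )


def sex_comparison_table(athletes: pd.DataFrame) -> pd.DataFrame:
    """Per-sex mean ± SD for every variable; t / p / ES only for variables
    measured on protocol-independent scales (the two sexes ski different
    inclines and distances, so GE, PO and TT metabolic rates are summarised
    but not compared)."""
    rows = []
    f = athletes[athletes["sex"] == "female"]
    m = athletes[athletes["sex"] == "male"]
    for var in COMPARABLE_VARS + PROTOCOL_BOUND_VARS:
        if var not in athletes.columns:
            continue
        fa, ma = f[var].to_numpy(float), m[var].to_numpy(float)
        row = {
            "variable": var,
            "female_n": len(fa), "female_mean": np.mean(fa), "female_sd": np.std(fa, ddof=1),
            "male_n": len(ma), "male_mean": np.mean(ma), "male_sd": np.std(ma, ddof=1),
            "t": np.nan, "p": np.nan, "es": np.nan, "magnitude": "",
        }
        if var in COMPARABLE_VARS and len(fa) >= 2 and len(ma) >= 2:
            t, _, p = students_t_test(fa, ma)
            es = cohens_d(GroupSummary.from_sample(fa), GroupSummary.from_sample(ma))
            row.update({"t": t, "p": p, "es": es.d, "magnitude": es.magnitude})
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(athletes: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and p) of each laboratory variable with field skiing speed,
    per sex."""
    rows = []
    for sex in ("female", "male"):
        sub = athletes[athletes["sex"] == sex]
        y = sub["bc_speed_m_s"].to_numpy(float)
        for var in CORRELATION_VARS:
            if var not in sub.columns or len(sub) < 3:
                continue
            x = sub[var].to_numpy(float)
            try:
                r, p = pearson_correlation(x, y)
            except InputError:
                r, p = np.nan, np.nan
            rows.append({"sex": sex, "variable": var, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def regression_models(
    athletes: pd.DataFrame,
) -> dict[str, dict[str, RegressionPartition]]:
    """Blockwise regressions of field skiing speed on laboratory variables,
    per sex, in fixed entry order: (V̇O₂peak | V̇O₂@4mmol), then relative
    anaerobic energy contribution, then GE."""
    out: dict[str, dict[str, RegressionPartition]] = {}
    for sex in ("female", "male"):
        sub = athletes[athletes["sex"] == sex]
        models = {}
        for name, predictors in REGRESSION_MODELS.items():
            if len(sub) <= len(predictors) + 1:
                continue
            X = sub[predictors].to_numpy(float)
            y = sub["bc_speed_m_s"].to_numpy(float)
            models[name] = blockwise_regression(y, X, predictors)
        out[sex] = models
    return out


def normality_table(athletes: pd.DataFrame) -> pd.DataFrame:
    """Shapiro–Wilk W and p per sex for the comparable variables (reported,
    never used to gate the analysis)."""
    rows = []
    for sex in ("female", "male"):
        sub = athletes[athletes["sex"] == sex]
        for var in COMPARABLE_VARS:
            if var not in sub.columns or len(sub) < 3:
                continue
            try:
                w, p = shapiro_wilk(sub[var].to_numpy(float))
            except InputError:
                w, p = np.nan, np.nan
            rows.append({"sex": sex, "variable": var, "W": w, "p": p})
    return pd.DataFrame(rows)


def simulate(config: CohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write the CSV fixture set ``run_analysis`` reads.

    Deterministic and idempotent under a fixed config. Returns the paths
    keyed by role: stages / tt / athletes / protocol.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    stages_by_athlete = {}
    incline_by_athlete = {}
    tts = []
    for ath in cohort:
        protocol = config.protocol_for(ath.profile.sex)
        stages_by_athlete[ath.profile.athlete_id] = generate_submax_test(
            ath, protocol, config, rng
        )
        incline_by_athlete[ath.profile.athlete_id] = protocol.incline_deg
        tts.append(generate_tt(ath, protocol, config, rng))
    competition = generate_competition(cohort, config)

    paths = {
        "stages": out / "stages.csv",
        "tt": out / "tt.csv",
        "athletes": out / "athletes.csv",
        "protocol": out / "protocol.yaml",
    }
    bio.write_stage_csv(paths["stages"], stages_by_athlete, incline_by_athlete)
    bio.write_tt_csv(paths["tt"], tts)
    bio.write_athletes_csv(paths["athletes"], cohort, competition)
    bio.write_protocol_yaml(
        paths["protocol"],
        {"female": config.female_protocol, "male": config.male_protocol},
    )
    return paths


def simulate_and_analyze(config: CohortConfig, work_dir: str | Path) -> AnalysisReport:
    """Convenience: write the fixture set then analyse it."""
    paths = simulate(config, work_dir)
    return run_analysis(
        paths["stages"], paths["tt"], paths["athletes"], paths["protocol"]
    )


def format_report_tables(report: AnalysisReport) -> str:
    """Human-readable report with the field's customary precision:
    one decimal for physiological means, two for r and ES, three for p."""
    lines = []
    lines.append("Per-sex summaries and comparisons")
    for _, r in report.sex_comparison.iterrows():
        base = (
            f"  {r['variable']:<16} F {r['female_mean']:6.1f} ± {r['female_sd']:4.1f}"
            f"   M {r['male_mean']:6.1f} ± {r['male_sd']:4.1f}"
        )
        if math.isfinite(r["p"]):
            base += f"   p={r['p']:.3f}  ES={r['es']:.2f} ({r['magnitude']})"
        lines.append(base)
    lines.append("Correlations with field skiing speed")
    for _, r in report.correlations.iterrows():
        lines.append(
            f"  {r['sex']:<6} {r['variable']:<16} r={r['r']:+.2f}  p={r['p']:.3f}"
        )
    lines.append("Blockwise regressions on field skiing speed")
    for sex, models in report.regressions.items():
        for name, part in models.items():
            inc = ", ".join(
                f"{p}={100 * d:.0f}%" for p, d in zip(part.predictors, part.delta_r2)
            )
            lines.append(
                f"  {sex:<6} {name}: R²={part.total_r2:.2f} (p={part.p_value:.3f}); {inc}"
            )
    if report.exclusions:
        lines.append("Exclusions")
        for aid, reason in report.exclusions:
            lines.append(f"  {aid}: {reason}")
    return "\n".join(lines)
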