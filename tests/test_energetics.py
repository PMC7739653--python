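"""Treadmill power, metabolic-rate conversion, gross efficiency and the
time-trial energy partition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biaperf.energetics import (
    O2_EQUIVALENT_ML_PER_J,
    compute_aerobic_metabolic_rate,
    compute_aod,
    compute_gross_efficiency,
    compute_power_output,
    compute_tt_energetics,
    integrate_mr_ae_trapezoid,
    mean_tt_vo2,
    select_reference_stage,
)
from biaperf.types import InputError, StageRecord, TreadmillProtocol


def stage(rer, **kw):
    defaults = dict(speed_kmh=10.0, vo2_L_min=3.0, lactate_mmol=2.0)
    defaults.update(kw)
    return StageRecord(rer=rer, **defaults)


class TestPowerOutput:
    def test_female_tt_chain(self, female_protocol):
        po = compute_power_output(4.8, 62.8, female_protocol)
        assert po == pytest.approx(246.6, abs=0.1)
        assert po / 62.8 == pytest.approx(3.9, abs=0.05)

    def test_male_tt_chain(self, male_protocol):
        po = compute_power_output(5.1, 74.8, male_protocol)
        assert po == pytest.approx(374.2, abs=0.1)
        assert po / 74.8 == pytest.approx(5.0, abs=0.05)

    def test_zero_speed_gives_zero_power(self, female_protocol):
        assert compute_power_output(0.0, 70.0, female_protocol) == 0.0

    @pytest.mark.parametrize("speed,mass", [(-1.0, 70.0), (4.0, 0.0), (4.0, -5.0)])
    def test_invalid_inputs_raise(self, speed, mass, female_protocol):
        with pytest.raises(InputError):
            compute_power_output(speed, mass, female_protocol)

    @settings(derandomize=True, max_examples=50)
    @given(
        v=st.floats(0.1, 10.0),
        m=st.floats(40.0, 100.0),
        scale=st.floats(1.01, 2.0),
    )
    def test_linear_in_speed_and_mass(self, v, m, scale):
        proto = TreadmillProtocol(incline_deg=3.5, mu_r=0.0224)
        base = compute_power_output(v, m, proto)
        assert compute_power_output(v * scale, m, proto) == pytest.approx(base * scale)
        assert compute_power_output(v, m * scale, proto) == pytest.approx(base * scale)

    def test_monotone_in_incline_and_rolling_resistance(self):
        v, m = 4.0, 70.0
        pos = [
            compute_power_output(v, m, TreadmillProtocol(incline_deg=a, mu_r=0.0224))
            for a in (1.0, 3.5, 6.0, 10.0)
        ]
        assert all(b > a for a, b in zip(pos, pos[1:]))
        po_lo = compute_power_output(v, m, TreadmillProtocol(incline_deg=3.5, mu_r=0.01))
        po_hi = compute_power_output(v, m, TreadmillProtocol(incline_deg=3.5, mu_r=0.03))
        assert po_hi > po_lo


class TestAerobicMetabolicRate:
    def test_carbohydrate_equivalent(self):
        assert compute_aerobic_metabolic_rate(1.0, 1.0) == pytest.approx(348.67, abs=0.01)

    def test_fat_dominated_equivalent(self):
        assert compute_aerobic_metabolic_rate(1.0, 0.70) == pytest.approx(325.65, abs=0.01)

    def test_zero_uptake(self):
        assert compute_aerobic_metabolic_rate(0.0, 0.9) == 0.0

    def test_rer_above_one_rejected_unless_clamped(self):
        with pytest.raises(InputError):
            compute_aerobic_metabolic_rate(2.0, 1.05)
        clamped = compute_aerobic_metabolic_rate(2.0, 1.05, clamp_rer=True)
        assert clamped == compute_aerobic_metabolic_rate(2.0, 1.0)

    def test_dimensional_check_kj_per_litre(self):
        # at RER = 1.00 the conversion implies 20.92 kJ per litre of O2
        w = compute_aerobic_metabolic_rate(1.0, 1.0)
        kj_per_litre = w * 60.0 / 1000.0
        assert kj_per_litre == pytest.approx(20.92, rel=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        vo2=st.floats(0.5, 6.0), rer1=st.floats(0.6, 0.99), drer=st.floats(0.001, 0.1)
    )
    def test_monotone_in_vo2_and_rer(self, vo2, rer1, drer):
        rer2 = min(rer1 + drer, 1.0)
        assert compute_aerobic_metabolic_rate(vo2 * 1.1, rer1) > (
            compute_aerobic_metabolic_rate(vo2, rer1)
        )
        assert compute_aerobic_metabolic_rate(vo2, rer2) > (
            compute_aerobic_metabolic_rate(vo2, rer1)
        )


class TestGrossEfficiency:
    def test_reference_chain(self):
        assert compute_gross_efficiency(3.9, 23.5) == pytest.approx(16.6, abs=0.01)

    def test_trivial_cases(self):
        assert compute_gross_efficiency(0.0, 300.0) == 0.0
        assert compute_gross_efficiency(100.0, 500.0) == 20.0

    def test_nonpositive_denominator_raises(self):
        with pytest.raises(InputError):
            compute_gross_efficiency(100.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(po=st.floats(0.5, 500.0), ge=st.floats(5.01, 29.99))
    def test_round_trip_identity(self, po, ge):
        mr_req = po / (ge / 100.0)
        assert compute_gross_efficiency(po, mr_req) == pytest.approx(ge, rel=1e-12)


class TestReferenceStage:
    def test_picks_closest_rer_below_one(self):
        stages = [stage(r) for r in (0.88, 0.95, 0.99, 1.03)]
        assert select_reference_stage(stages).rer == 0.99

    def test_exact_one_is_eligible(self):
        stages = [stage(0.90), stage(1.00)]
        assert select_reference_stage(stages).rer == 1.00

    def test_all_above_one_raises(self):
        with pytest.raises(InputError, match="no valid reference stage"):
            select_reference_stage([stage(1.02), stage(1.05)])

    def test_tie_breaks_to_latest_stage(self):
        stages = [
            stage(0.98, stage_index=1),
            stage(0.98, stage_index=2),
            stage(0.90, stage_index=3),
        ]
        assert select_reference_stage(stages).stage_index == 2


class TestTimeTrialEnergetics:
    def test_female_mean_partition_chain(self):
        # MR_ae of 18.1 W/kg corresponds to a mean TT V̇O₂ of 18.1/0.348667
        mean_vo2 = 18.1 / (4184.0 * 5.0 / 60.0 / 1000.0)
        n = 19
        series = [mean_vo2] * n
        res = compute_tt_energetics(190.0, series, 16.6, 3.9)
        assert res.mr_req_W_per_kg == pytest.approx(23.5, abs=0.05)
        assert res.mr_an_W_per_kg == pytest.approx(5.4, abs=0.05)
        assert res.e_an_pct == pytest.approx(23.0, abs=0.1)
        assert res.e_ae_pct == pytest.approx(77.0, abs=0.1)

    def test_partition_invariants(self):
        res = compute_tt_energetics(190.0, [50.0] * 19, 16.6, 3.9)
        assert res.mr_ae_W_per_kg + res.mr_an_W_per_kg == pytest.approx(
            res.mr_req_W_per_kg, abs=1e-9
        )
        assert res.e_ae_pct + res.e_an_pct == pytest.approx(100.0, abs=1e-9)
        assert res.e_req_J_per_kg == pytest.approx(
            res.e_ae_J_per_kg + res.e_an_J_per_kg, abs=1e-9
        )

    def test_fully_aerobic_limit(self):
        # choose PO so that MR_req equals MR_ae exactly: MR_an = 0, AOD = 0
        mean_vo2 = 50.0
        mr_ae = 4184.0 * (mean_vo2 / 1000.0) * 5.0 / 60.0
        ge = 17.0
        po = mr_ae * ge / 100.0
        res = compute_tt_energetics(180.0, [mean_vo2] * 18, ge, po)
        assert res.mr_an_W_per_kg == pytest.approx(0.0, abs=1e-12)
        assert res.e_an_pct == pytest.approx(0.0, abs=1e-9)
        assert res.aod_mL_per_kg == pytest.approx(0.0, abs=1e-9)
        assert not res.anaerobic_negative

    def test_submaximal_trial_flagged_not_fatal(self):
        res = compute_tt_energetics(190.0, [60.0] * 19, 20.0, 3.0)
        assert res.mr_an_W_per_kg < 0
        assert res.anaerobic_negative

    def test_partial_last_sample_weighting(self):
        # 185 s = 18 full samples + one 5-s sample
        series = [50.0] * 18 + [60.0]
        mean = mean_tt_vo2(series, 185.0)
        assert mean == pytest.approx((50.0 * 180.0 + 60.0 * 5.0) / 185.0)

    def test_onset_exclusion_flag(self):
        series = [30.0, 45.0] + [55.0] * 17
        full = mean_tt_vo2(series, 190.0)
        skipped = mean_tt_vo2(series, 190.0, skip_onset_samples=2)
        assert skipped == pytest.approx(55.0)
        assert skipped > full

    def test_ge_zero_raises(self):
        with pytest.raises(InputError):
            compute_tt_energetics(190.0, [50.0] * 19, 0.0, 3.9)

    def test_trapezoid_oracle_matches_mean_shortcut_on_plateau(self):
        # plateau kinetics: mono-exponential rise then flat
        t_fin = 190.0
        tau, vmax, f0 = 25.0, 55.6, 0.4
        ts = np.arange(0.0, t_fin, 10.0)
        series = [
            vmax
            * (
                (t1 - t0)
                - (1 - f0) * tau * (math.exp(-t0 / tau) - math.exp(-t1 / tau))
            )
            / (t1 - t0)
            for t0, t1 in zip(ts, np.minimum(ts + 10.0, t_fin))
        ]
        res = compute_tt_energetics(t_fin, series, 16.6, 3.9)
        e_trap = integrate_mr_ae_trapezoid(series, t_fin)
        assert e_trap == pytest.approx(res.e_ae_J_per_kg, rel=0.005)


class TestAod:
    def test_male_chain(self):
        assert compute_aod(6.1 * 198.0) == pytest.approx(57.7, abs=0.05)

    def test_female_chain_within_rounding(self):
        assert abs(compute_aod(5.4 * 190.0) - 49.2) <= 0.3

    def test_zero_and_sign(self):
        assert compute_aod(0.0) == 0.0
        assert compute_aod(-100.0) == pytest.approx(-100.0 * O2_EQUIVALENT_ML_PER_J)

    def test_nonfinite_raises(self):
        with pytest.raises(InputError):
            compute_aod(float("nan"))
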