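"""Weir energetics, steady-state search, session energy, VO2peak rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsekit.calorimetry import (
    adjudicate_vo2peak,
    find_steady_state,
    intensity_metrics,
    session_energy,
    weir_ree,
)
from pulsekit.core import GasTrace, QualityError
from pulsekit.synthetic import GasGenSpec, generate_gas_trace


def flat_trace(n=20, vo2=250.0, vco2=200.0, phase=None):
    return GasTrace(
        t_min=np.arange(n) + 0.5,
        vo2_ml_min=np.full(n, vo2),
        vco2_ml_min=np.full(n, vco2),
        phase=None if phase is None else np.array([phase] * n, dtype=object),
    )


class TestWeir:
    def test_hand_value(self):
        # 1.44 * (3.94*250 + 1.11*200) = 1.44 * 1207
        assert weir_ree(250.0, 200.0) == pytest.approx(1738.08)

    def test_nonpositive_vo2_rejected(self):
        with pytest.raises(ValueError):
            weir_ree(0.0, 100.0)

    @given(vo2=st.floats(50, 5000), vco2=st.floats(0, 5000),
           c=st.floats(1.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_linearity_and_monotonicity(self, vo2, vco2, c):
        assert weir_ree(c * vo2, c * vco2) == pytest.approx(
            c * weir_ree(vo2, vco2), rel=1e-12)
        assert weir_ree(c * vo2, vco2) > weir_ree(vo2, vco2)


class TestSteadyState:
    def test_selects_embedded_window(self):
        trace = generate_gas_trace(GasGenSpec(cv_inside=0.02, steady_start_min=8,
                                              steady_len_min=6, seed=2))
        (lo, hi), ree = find_steady_state(trace)
        assert lo >= 8 and hi <= 14  # inside the embedded segment
        assert ree == pytest.approx(trace.meta["truth"]["ree_kcal_day"],
                                    rel=0.05)

    def test_no_steady_state_error(self):
        rng = np.random.default_rng(0)
        n = 20
        swing = np.where(np.arange(n) % 2 == 0, 1.25, 0.75)
        trace = GasTrace(t_min=np.arange(n) + 0.5,
                         vo2_ml_min=250 * swing,
                         vco2_ml_min=200 * swing)
        with pytest.raises(QualityError, match="steady"):
            find_steady_state(trace)

    def test_lowest_ree_rule(self):
        """Two compliant windows: the lower-REE one wins."""
        n = 15
        vo2 = np.full(n, 260.0)
        vo2[10:15] = 245.0  # second, lower-flow plateau
        trace = GasTrace(t_min=np.arange(n) + 0.5, vo2_ml_min=vo2,
                         vco2_ml_min=0.8 * vo2)
        (lo, hi), ree = find_steady_state(trace)
        assert (lo, hi) == (10.0, 15.0)
        assert ree == pytest.approx(weir_ree(245.0, 0.8 * 245.0))

    def test_never_uses_discarded_first_five_minutes(self):
        trace = generate_gas_trace(GasGenSpec(steady_start_min=5, seed=3))
        (lo, _), _ = find_steady_state(trace)
        assert lo >= 5.0

    def test_rer_gate(self):
        trace = flat_trace(vo2=250.0, vco2=270.0)  # RER 1.08 > 1.0
        with pytest.raises(QualityError):
            find_steady_state(trace)


class TestSessionEnergy:
    def test_constant_phase_tee(self):
        trace = flat_trace(n=45, vo2=1000.0, vco2=900.0, phase="class")
        res = session_energy(trace, ree_kcal_day=1700.0, phase="class")
        assert res.tee_kcal == pytest.approx(45 * 1.44 * (3940 + 999) / 1440)

    def test_aee_formula(self):
        trace = flat_trace(n=45, vo2=1000.0, vco2=900.0, phase="class")
        res = session_energy(trace, ree_kcal_day=1700.0, phase="class")
        assert res.aee_kcal == pytest.approx(
            res.tee_kcal - (res.ree_over_session_kcal + 0.1 * res.tee_kcal))

    def test_aee_identity_machine_precision(self):
        trace = flat_trace(n=30, vo2=800.0, vco2=700.0, phase="class")
        res = session_energy(trace, ree_kcal_day=1650.0, phase="class")
        assert res.aee_kcal + 0.1 * res.tee_kcal + res.ree_over_session_kcal \
            == pytest.approx(res.tee_kcal, abs=1e-12)

    def test_resting_trace_near_zero_aee(self):
        """TEE ~ REE/0.9 over the phase makes AEE an algebraic zero."""
        ree = weir_ree(250.0, 200.0)
        trace = flat_trace(n=60, vo2=250.0 / 0.9, vco2=200.0 / 0.9,
                           phase="rest")
        res = session_energy(trace, ree_kcal_day=ree, phase="rest")
        assert res.aee_kcal == pytest.approx(0.0, abs=1e-9)

    def test_missing_phase_named(self):
        trace = flat_trace(phase="rest")
        with pytest.raises(ValueError, match="class"):
            session_energy(trace, 1700.0, phase="class")


class TestIntensityMetrics:
    def test_anchor_points(self):
        trace = GasTrace(t_min=np.arange(3) + 0.5,
                         vo2_ml_min=np.array([250.0, 1625.0, 3000.0]),
                         vco2_ml_min=np.array([200.0, 1300.0, 2400.0]),
                         hr_bpm=np.array([60.0, 120.0, 180.0]))
        m = intensity_metrics(trace, rest_vo2_ml_min=250.0, rest_hr_bpm=60.0,
                              hrmax_bpm=180.0, vo2peak_ml_min=3000.0)
        assert m["mets"][0] == pytest.approx(1.0)
        assert m["pct_vo2_reserve"].tolist() == pytest.approx([0.0, 50.0, 100.0])
        assert m["pct_hr_reserve"].tolist() == pytest.approx([0.0, 50.0, 100.0])
        assert not m["out_of_range"].any()

    def test_out_of_range_flagged_not_clipped(self):
        trace = GasTrace(t_min=[0.5], vo2_ml_min=[4000.0], vco2_ml_min=[3000.0])
        m = intensity_metrics(trace, rest_vo2_ml_min=250.0,
                              vo2peak_ml_min=3000.0)
        assert m["pct_vo2_reserve"][0] > 100.0
        assert m["out_of_range"][0]

    def test_max_below_rest_rejected(self):
        trace = flat_trace(n=3)
        with pytest.raises(ValueError):
            intensity_metrics(trace, rest_vo2_ml_min=250.0,
                              vo2peak_ml_min=200.0)


class TestVO2Peak:
    def make_streams(self, n=18, vo2_top=40.0, hr_top=160.0, rer_top=1.15,
                     rpe_top=19.0):
        vo2 = np.linspace(15.0, vo2_top, n)
        hr = np.linspace(90.0, hr_top, n)
        rer = np.linspace(0.85, rer_top, n)
        rpe = np.linspace(8.0, rpe_top, n)
        return vo2, hr, rer, rpe

    def test_two_criteria_accepted(self):
        """RER 1.15 + RPE 19, HR only ~80% predicted, no plateau: accepted."""
        vo2, hr, rer, rpe = self.make_streams(hr_top=0.8 * (220 - 25))
        res = adjudicate_vo2peak(vo2, hr, rer, rpe, age_years=25.0)
        assert res.accepted
        assert sum(res.criteria_met.values()) == 2
        assert res.vo2peak_ml_kg_min == pytest.approx(40.0)

    def test_one_criterion_rejected(self):
        vo2, hr, rer, rpe = self.make_streams(hr_top=0.8 * (220 - 25),
                                              rer_top=1.12, rpe_top=15.0)
        res = adjudicate_vo2peak(vo2, hr, rer, rpe, age_years=25.0)
        assert not res.accepted
        assert sum(res.criteria_met.values()) == 1

    def test_plateau_criterion(self):
        vo2, hr, rer, rpe = self.make_streams(rer_top=0.95, rpe_top=12.0,
                                              hr_top=120.0)
        res = adjudicate_vo2peak(vo2, hr, rer, rpe, age_years=25.0,
                                 stage_delta_vo2_ml_kg_min=1.4)
        assert res.criteria_met["vo2_plateau"]

    def test_peak_in_last_minute_and_mass_conversion(self):
        vo2 = np.concatenate([np.linspace(15, 45, 12), np.full(6, 41.0)])
        res = adjudicate_vo2peak(vo2, np.full(18, 150.0), np.full(18, 1.0),
                                 np.full(18, 15.0), age_years=30.0,
                                 body_mass_kg=70.0)
        assert res.vo2peak_ml_kg_min == pytest.approx(41.0)  # last 60 s only
        assert res.vo2peak_l_min == pytest.approx(41.0 * 70 / 1000)

    def test_short_test_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            adjudicate_vo2peak(np.full(3, 30.0), np.full(3, 150.0),
                               np.full(3, 1.0), np.full(3, 15.0), age_years=30.0)
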