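"""Mixed-model stage: REML fit, Satterthwaite F tests, effect sizes,
Tukey post hocs and Welch comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pulsekit.crossover import (
    eta_benchmark,
    fit_crossover_model,
    noncentral_f_power,
    omega_squared,
    partial_eta_squared,
    tukey_posthoc,
    welch_compare,
)
from pulsekit.synthetic import TrialGenSpec, generate_trial_table


class TestEffectSizes:
    @pytest.mark.parametrize(
        "F, df1, df2, expected",
        [(4.48, 2, 43, 0.13), (3.34, 2, 43, 0.09), (3.80, 3, 326, 0.02)],
    )
    def test_omega_squared_published_triple(self, F, df1, df2, expected):
        assert round(omega_squared(F, df1, df2), 2) == expected

    def test_omega_null_point(self):
        assert omega_squared(1.0, 5, 40) == 0.0

    def test_partial_eta(self):
        assert partial_eta_squared(0.0, 2, 43) == 0.0
        assert partial_eta_squared(4.48, 2, 43) == pytest.approx(0.172, abs=5e-4)

    @pytest.mark.parametrize("value, label",
                             [(0.03, "small"), (0.1, "medium"), (0.3, "large")])
    def test_benchmarks(self, value, label):
        assert eta_benchmark(value) == label

    @given(f1=st.floats(0.0, 50.0), f2=st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_f(self, f1, f2):
        lo, hi = sorted((f1, f2))
        assert omega_squared(hi, 3, 40) >= omega_squared(lo, 3, 40)
        assert partial_eta_squared(hi, 3, 40) >= partial_eta_squared(lo, 3, 40)


@pytest.fixture(scope="module")
def table():
    return generate_trial_table(TrialGenSpec(seed=42))


@pytest.fixture(scope="module")
def fit(table):
    return fit_crossover_model(table)


@pytest.fixture(scope="module")
def fit_shifted():
    # condition-level shift: BIKE lowered by 6 units
    effects = tuple((("BIKE", tp, g), -6.0)
                    for tp in ("rest", "10", "20", "30")
                    for g in ("young", "middle"))
    return fit_crossover_model(
        generate_trial_table(TrialGenSpec(seed=7, effect_map=effects)))


class TestMixedModel:
    def test_matches_statsmodels_reml(self, table, fit):
        """Variance components and fixed effects agree with MixedLM."""
        smf = pytest.importorskip("statsmodels.formula.api")
        m = smf.mixedlm(
            "outcome ~ C(condition, Sum)*C(timepoint, Sum)*C(group, Sum)",
            table, groups="participant").fit(reml=True)
        assert fit.sigma2 == pytest.approx(float(m.scale), rel=1e-4)
        assert fit.tau2 == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.beta[0] == pytest.approx(float(m.params["Intercept"]),
                                            rel=1e-6)

    def test_location_invariance(self, table, fit):
        shifted = table.copy()
        shifted["outcome"] = shifted["outcome"] + 1000.0
        fit2 = fit_crossover_model(shifted)
        for term in ("condition", "condition:timepoint:group"):
            f1, *_ = fit.term_f_test(term)
            f2, *_ = fit2.term_f_test(term)
            assert f2 == pytest.approx(f1, rel=1e-6)

    def test_group_term_equals_classical_anova(self, table, fit):
        """Balanced design: mixed-model F for the between term equals the
        one-way ANOVA F on participant means."""
        means = table.groupby(["participant", "group"], observed=True)[
            "outcome"].mean().reset_index()
        a = means.loc[means.group == "middle", "outcome"]
        b = means.loc[means.group == "young", "outcome"]
        f_classical = float(stats.f_oneway(a, b).statistic)
        f_mixed, df1, df2, _ = fit.term_f_test("group")
        assert df1 == 1
        assert f_mixed == pytest.approx(f_classical, rel=1e-4)
        assert df2 == pytest.approx(len(means) - 2, rel=0.02)

    def test_effect_reports_complete(self, fit):
        reports = {r.term: r for r in fit.effect_reports()}
        assert set(reports) == {
            "condition", "timepoint", "group",
            "condition:timepoint", "condition:group", "timepoint:group",
            "condition:timepoint:group",
        }
        r = reports["condition:timepoint"]
        assert r.df1 == 9
        assert 0.0 <= r.p <= 1.0
        assert r.partial_eta_sq == pytest.approx(
            partial_eta_squared(r.F, r.df1, r.df2))

    def test_power_for_injected_group_time_shift(self):
        """A -8 group-by-time shift (sd 5, n 12/group) is recovered as a
        significant timepoint:group interaction with high simulated power."""
        effects = tuple(((c, "10", "young"), -8.0)
                        for c in ("CON", "BIKE", "PP", "GT"))
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            df = generate_trial_table(TrialGenSpec(seed=3000 + s,
                                                   effect_map=effects))
            f = fit_crossover_model(df)
            _, _, _, p = f.term_f_test("timepoint:group")
            hits += p < 0.05
        assert hits / n_rep > 0.8

    def test_covariate_accepted(self, table):
        t = table.copy()
        rng = np.random.default_rng(0)
        t["vo2peak"] = rng.normal(40, 8, len(t))
        f = fit_crossover_model(t, covariates=["vo2peak"])
        assert "vo2peak" in f.term_slices

    def test_missing_column_error(self):
        with pytest.raises(ValueError, match="lacks columns"):
            fit_crossover_model(pd.DataFrame({"participant": [1, 2]}))


class TestTukey:
    def test_contrast_count(self, fit_shifted):
        reports = tukey_posthoc(fit_shifted, "condition")
        assert len(reports) == 4 * 3 // 2
        reports2 = tukey_posthoc(fit_shifted, "condition:group")
        assert len(reports2) == 8 * 7 // 2

    def test_adjusted_p_at_least_raw(self, fit_shifted):
        for rep in tukey_posthoc(fit_shifted, "condition"):
            assert rep.p_tukey >= rep.p_raw - 1e-12

    def test_shifted_level_has_smallest_p(self, fit_shifted):
        reports = tukey_posthoc(fit_shifted, "condition")
        best = min(reports, key=lambda r: r.p_tukey)
        assert "BIKE" in best.contrast
        assert best.p_tukey < 0.01

    def test_ci_contains_estimate(self, fit_shifted):
        for rep in tukey_posthoc(fit_shifted, "condition"):
            assert rep.ci_low <= rep.estimate <= rep.ci_high

    def test_identical_means_p_near_one(self):
        fit = fit_crossover_model(generate_trial_table(TrialGenSpec(seed=55)))
        reports = tukey_posthoc(fit, "timepoint")
        assert max(r.p_tukey for r in reports) > 0.5

    def test_unknown_term_error(self, fit_shifted):
        with pytest.raises(KeyError):
            tukey_posthoc(fit_shifted, "bogus")


class TestWelch:
    def test_identical_samples(self):
        x = np.arange(10.0)
        rep = welch_compare(x, x)
        assert rep.mean_diff == 0.0
        assert rep.p > 0.99

    def test_published_group_means_difference(self):
        """Samples constructed at the printed VO2peak group means
        (2.06 vs 2.78 L/min) give exactly their -0.72 difference."""
        rng = np.random.default_rng(1)

        def sample(mean, sd, n=12):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        rep = welch_compare(sample(2.06, 0.80), sample(2.78, 0.85))
        assert rep.mean_diff == pytest.approx(-0.72, abs=1e-12)
        assert rep.ci_low < -0.72 < rep.ci_high

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 2, 12)
        rep = welch_compare(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert rep.t == pytest.approx(float(ref.statistic))
        assert rep.p == pytest.approx(float(ref.pvalue))

    def test_nonnormal_triggers_mannwhitney(self):
        rng = np.random.default_rng(3)
        a = rng.exponential(1.0, 40) ** 3
        b = rng.exponential(1.5, 40) ** 3
        rep = welch_compare(a, b)
        assert rep.mannwhitney_p is not None

    def test_degenerate_equal_constants(self):
        rep = welch_compare([5.0, 5.0, 5.0], [5.0, 5.0])
        assert rep.p == 1.0

    def test_power_matches_noncentral_t_oracle(self):
        """MC power of the Welch test at a 1-sd shift (n 12/12) matches the
        noncentral-t closed form within 2 points."""
        n, shift, reps = 12, 1.0, 4000
        rng = np.random.default_rng(4)
        rej = 0
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(shift, 1, n)
            rej += stats.ttest_ind(a, b, equal_var=False).pvalue < 0.05
        mc_power = rej / reps
        df = 2 * n - 2
        nc = shift / np.sqrt(2 / n)
        tcrit = stats.t.isf(0.025, df)
        power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        assert mc_power == pytest.approx(power, abs=0.02)


def test_noncentral_f_power_monotone():
    p1 = noncentral_f_power(0.154, 3, 60, n_total=22)
    p2 = noncentral_f_power(0.154, 3, 60, n_total=100)
    assert 0 < p1 < p2 < 1
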