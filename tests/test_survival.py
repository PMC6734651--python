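import math

import numpy as np
import pandas as pd
import pytest

from boolmark import (
    HIGH,
    LOW,
    MISSING,
    assign_marker_groups,
    chemo_interaction,
    cox_fit,
    five_year_rate,
    km_estimate,
    logrank_test,
    stage_subset_analysis,
    survival_at,
)


def _exp_cohort(n, log_hr, seed, censor_frac=0.3, h0=0.02):
    """Exponential survival with a binary covariate and uniform censoring."""
    rng = np.random.default_rng(seed)
    group = rng.random(n) < 0.5
    hazard = h0 * np.exp(log_hr * group)
    t = rng.exponential(1.0 / hazard)
    c = rng.uniform(0, np.quantile(t, 1 - censor_frac) * 2, n) if censor_frac > 0 else np.full(n, np.inf)
    return np.minimum(t, c), (t <= c).astype(int), group.astype(int)


class TestAssignMarkerGroups:
    CALLS = pd.Series([LOW, HIGH, HIGH, LOW, MISSING],
                      index=[f"P{i}" for i in range(5)])
    VIM = pd.Series([HIGH, HIGH, LOW, LOW, HIGH],
                    index=[f"P{i}" for i in range(5)])

    def test_two_group_from_marker_alone(self):
        labels = assign_marker_groups(self.CALLS, mode="two")
        assert labels["P0"] == "marker_low" and labels["P1"] == "marker_high"
        assert pd.isna(labels["P4"])  # missing call excluded

    def test_three_group_quadrants(self):
        labels = assign_marker_groups(self.CALLS, self.VIM, mode="three")
        assert labels["P0"] == "marker_low_vim_high"
        assert labels["P1"] == "marker_high_vim_high"
        assert labels["P2"] == "marker_high_vim_low"
        assert labels["P3"] == "OTHER"  # the sparse low-low quadrant

    def test_three_group_requires_vim(self):
        with pytest.raises(ValueError):
            assign_marker_groups(self.CALLS, mode="three")


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5.0, 10.0, 15.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_hand_product_limit_example(self):
        # 5+ censored, 10 event (3 at risk), 15+ censored, 20 event (1 at risk)
        curve = km_estimate([5, 10, 15, 20], [0, 1, 0, 1])
        assert survival_at(curve, 10) == pytest.approx(2 / 3)
        assert survival_at(curve, 20) == pytest.approx(0.0)
        assert survival_at(curve, 12) == pytest.approx(2 / 3)  # flat between events

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 100)
        curve = km_estimate(t, np.ones(100, dtype=int))
        for q in (2.0, 5.0, 12.0):
            assert survival_at(curve, q) == pytest.approx((t > q).mean())

    def test_survival_monotone_and_bounded(self):
        t, e, _ = _exp_cohort(150, 0.0, seed=2)
        curve = km_estimate(t, e)
        assert curve.survival[0] <= 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_empty_or_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([1.0, -2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        t = np.array([3.0, 6.0, 9.0, 12.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.array([0] * 4 + [1] * 4)
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_planted_hazard_ratio_detected(self):
        """HR = 3 at n = 200/arm with ~30% censoring: p < 0.001 every seed."""
        for seed in range(20):
            t, e, g = _exp_cohort(400, math.log(3.0), seed=100 + seed)
            _, p = logrank_test(t, e, g)
            assert p < 0.001

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestCoxFit:
    def test_identical_survival_hr_near_one(self):
        t = np.array([3.0, 6.0, 9.0, 12.0, 15.0, 18.0] * 2)
        e = np.array([1, 0, 1, 1, 0, 1] * 2)
        g = np.array([0] * 6 + [1] * 6)
        df = pd.DataFrame({"t": t, "e": e, "g": g})
        table, _ = cox_fit(df, "t", "e", ["g"])
        assert table.loc["g", "hr"] == pytest.approx(1.0, abs=1e-6)
        assert table.loc["g", "ci_low"] < 1.0 < table.loc["g", "ci_high"]

    @pytest.mark.parametrize("beta", [0.0, math.log(1.37), math.log(4.05)])
    def test_coefficient_recovery_low_bias(self, beta):
        """Mean signed error of beta-hat < 0.05 on exponential data, n=2000."""
        errors = []
        for seed in range(25):
            t, e, g = _exp_cohort(2000, beta, seed=500 + seed)
            df = pd.DataFrame({"t": t, "e": e, "g": g})
            table, _ = cox_fit(df, "t", "e", ["g"])
            errors.append(table.loc["g", "coef"] - beta)
        assert abs(np.mean(errors)) < 0.05

    def test_no_events_errors(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0], "e": [0, 0, 0, 0], "g": [0, 1, 0, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, "t", "e", ["g"])


class TestChemoInteraction:
    @staticmethod
    def _factorial_cohort(n, hr10, hr01, hr11, seed, h0=0.02):
        rng = np.random.default_rng(seed)
        m = (rng.random(n) < 0.5).astype(int)
        c = (rng.random(n) < 0.5).astype(int)
        hr = np.select(
            [(m == 1) & (c == 0), (m == 0) & (c == 1), (m == 1) & (c == 1)],
            [hr10, hr01, hr11],
            default=1.0,
        )
        t = rng.exponential(1.0 / (h0 * hr))
        cens = rng.uniform(0, 2 * np.median(t), n)
        return pd.DataFrame(
            {"t": np.minimum(t, cens), "e": (t <= cens).astype(int), "m": m, "c": c}
        )

    def test_multiplicative_null_and_reri_identity(self):
        """Exactly multiplicative hazards (HR10=2, HR01=1.5): the product-term
        coefficient centres on 0 and RERI centres on (2-1)(1.5-1) = 0.5."""
        coefs, reris = [], []
        for seed in range(10):
            df = self._factorial_cohort(1200, 2.0, 1.5, 3.0, seed=seed)
            res = chemo_interaction(df, "t", "e", "m", "c")
            coefs.append(res.multiplicative_coef)
            reris.append(res.reri)
        assert abs(np.mean(coefs)) < 0.1
        assert np.mean(reris) == pytest.approx(0.5, abs=0.25)

    def test_additive_hazards_reri_ci_covers_zero(self):
        """Exactly additive hazards (HR11 = HR10 + HR01 - 1): RERI = 0, the
        delta-method CI should cover 0 in most replicates."""
        covered = 0
        for seed in range(20):
            df = self._factorial_cohort(1000, 2.0, 1.5, 2.5, seed=50 + seed)
            res = chemo_interaction(df, "t", "e", "m", "c")
            covered += res.reri_ci[0] <= 0.0 <= res.reri_ci[1]
        assert covered >= 16  # nominal 95%, allow sampling noise

    def test_no_effect_data_both_measures_null(self):
        df = self._factorial_cohort(1500, 1.0, 1.0, 1.0, seed=99)
        res = chemo_interaction(df, "t", "e", "m", "c")
        assert res.multiplicative_p > 0.05
        assert res.reri_ci[0] <= 0.0 <= res.reri_ci[1]

    def test_relabel_invariance_of_multiplicative_p(self):
        df = self._factorial_cohort(800, 2.0, 1.5, 4.0, seed=7)
        a = chemo_interaction(df, "t", "e", "m", "c")
        b = chemo_interaction(df, "t", "e", "c", "m")
        assert a.multiplicative_p == pytest.approx(b.multiplicative_p, rel=1e-6)

    def test_empty_cell_errors(self):
        df = self._factorial_cohort(100, 2.0, 1.5, 3.0, seed=1)
        df = df[~((df["m"] == 1) & (df["c"] == 1))]
        with pytest.raises(ValueError, match="cell"):
            chemo_interaction(df, "t", "e", "m", "c")


class TestStageSubsetAnalysis:
    @staticmethod
    def _clinical(n=400, seed=4):
        rng = np.random.default_rng(seed)
        low = rng.random(n) < 0.3
        hazard = 0.01 * np.exp(math.log(2.5) * low)
        t = rng.exponential(1.0 / hazard)
        c = rng.uniform(0, 120, n)
        clin = pd.DataFrame(
            {
                "dfs_months": np.minimum(t, c),
                "dfs_event": (t <= c).astype(int),
                "stage": rng.choice(["I", "II", "III"], n, p=[0.2, 0.5, 0.3]),
            },
            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        )
        groups = pd.Series(np.where(low, "low", "high"), index=clin.index)
        return clin, groups

    def test_full_stage_set_equals_unrestricted(self):
        clin, groups = self._clinical()
        res = stage_subset_analysis(clin, groups, {"I", "II", "III"})
        chi2, p = logrank_test(clin["dfs_months"].to_numpy(), clin["dfs_event"].to_numpy(),
                               groups.to_numpy())
        assert res["logrank_chi2"] == pytest.approx(chi2)
        assert res["n"] == len(clin)

    def test_stage_uniform_effect_direction_preserved(self):
        clin, groups = self._clinical()
        res = stage_subset_analysis(clin, groups, {"II"})
        assert res["five_year_rates"]["low"] < res["five_year_rates"]["high"]

    def test_empty_stage_set_errors(self):
        clin, groups = self._clinical()
        with pytest.raises(ValueError):
            stage_subset_analysis(clin, groups, set())


class TestFiveYearRate:
    def test_reads_curve_at_sixty_months(self):
        t = np.array([30.0, 50.0, 70.0, 90.0])
        e = np.array([1, 1, 1, 1])
        assert five_year_rate(t, e) == pytest.approx(0.5)
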