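"""Association tests, Kaplan-Meier, log-rank and Cox fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from tsrnomo.stats import (
    ConvergenceError,
    association_test,
    cox_fit,
    fisher_exact,
    km_estimate,
    logrank_test,
    pearson_chi2,
    subgroup_forest,
)
from tsrnomo.synthetic import CohortSpec, generate_cohort


class TestPearson:
    @pytest.mark.parametrize(
        "table,p",
        [
            ([[74, 60], [73, 33]], 0.031),  # menopausal status by TSR group
            ([[87, 62], [60, 31]], 0.244),  # age group by TSR group
            ([[26, 25], [121, 68]], 0.090),  # HER2 amplification by TSR group
        ],
    )
    def test_published_association_p_values(self, table, p):
        """Counts from the clinico-pathological table reproduce its P values."""
        assert pearson_chi2(table)[2] == pytest.approx(p, abs=5e-4)

    def test_proportional_table_is_null(self):
        chi2, df, p = pearson_chi2([[20, 10], [40, 20]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 3, 11]])
        base = pearson_chi2(t)[0]
        assert pearson_chi2(t[:, [2, 0, 1]])[0] == pytest.approx(base)
        assert pearson_chi2(t[[1, 0]])[0] == pytest.approx(base)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            pearson_chi2([[1, 2]])


class TestFisher:
    @staticmethod
    def _enumerate_p(table):
        """Exact two-sided P by full enumeration over fixed margins."""
        (a, b), (c, d) = table
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2

        def prob(x):
            return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

        p_obs = prob(a)
        return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                   if prob(x) <= p_obs * (1 + 1e-9))

    @pytest.mark.parametrize("table", [[[1, 9], [11, 3]], [[3, 7], [5, 2]], [[8, 2], [1, 5]]])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact(table) == pytest.approx(self._enumerate_p(table), rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_transposition_invariance(self):
        t = [[2, 8], [9, 4]]
        assert fisher_exact(t) == pytest.approx(fisher_exact(np.transpose(t)))

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])

    def test_fallback_rule(self):
        # min expected count 10*11/23 = 4.78 < 5 -> exact test
        assert association_test([[1, 9], [10, 3]])["test"] == "fisher"
        assert association_test([[74, 60], [73, 33]])["test"] == "pearson"


class TestKaplanMeier:
    def test_all_events_simple_ladder(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        curve = km_estimate([4, 5, 6], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_hand_computed_mixed_fixture(self):
        """10 subjects, censoring interleaved: matches the product limit."""
        time = [2, 3, 3, 5, 6, 8, 10, 12, 12, 15]
        event = [1, 0, 1, 1, 0, 1, 0, 1, 0, 0]
        curve = km_estimate(time, event)
        # hand computation: 9/10, *8/9, *6/7, *4/5, *2/3 at t=2,3,5,8,12
        assert curve.at(2) == pytest.approx(0.9)
        assert curve.at(3) == pytest.approx(0.8)
        assert curve.at(5) == pytest.approx(0.9 * (8 / 9) * (6 / 7))
        assert curve.at(8) == pytest.approx(0.9 * (8 / 9) * (6 / 7) * (4 / 5))
        assert curve.at(60) == pytest.approx(0.9 * (8 / 9) * (6 / 7) * (4 / 5) * (2 / 3))

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 50).round(2)
        curve = km_estimate(t, np.ones(50, dtype=int))
        for q in (2.0, 5.0, 12.0):
            assert curve.at(q) == pytest.approx((t > q).mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    @staticmethod
    def _two_group_oracle(t1, e1, t2, e2):
        """Direct hypergeometric-variance formula at each event time."""
        t = np.concatenate([t1, t2])
        e = np.concatenate([e1, e2])
        g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
        O = E = V = 0.0
        for tj in np.unique(t[e == 1]):
            at = t >= tj
            n, n1 = at.sum(), (at & (g == 0)).sum()
            d = ((t == tj) & (e == 1)).sum()
            d1 = ((t == tj) & (e == 1) & (g == 0)).sum()
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
        return (O - E) ** 2 / V

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        t1, t2 = rng.exponential(10, 40), rng.exponential(16, 35)
        e1 = (t1 < 20).astype(int)
        e2 = (t2 < 20).astype(int)
        chi2, df, p = logrank_test([(t1, e1), (t2, e2)])
        assert df == 1
        assert chi2 == pytest.approx(self._two_group_oracle(t1, e1, t2, e2), abs=1e-10)

    def test_identical_groups_null(self):
        t = np.arange(1, 21, dtype=float)
        e = np.ones(20, dtype=int)
        chi2, _, p = logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        groups = [(rng.exponential(s, 30), np.ones(30, dtype=int)) for s in (5, 10, 20)]
        a = logrank_test(groups)[0]
        b = logrank_test(groups[::-1])[0]
        assert a == pytest.approx(b)

    def test_errors(self):
        with pytest.raises(ValueError):
            logrank_test([(np.ones(5), np.zeros(5, dtype=int))])
        with pytest.raises(ValueError):
            logrank_test([(np.ones(5), np.zeros(5, int)), (np.ones(5), np.zeros(5, int))])


class TestCox:
    def test_null_effect_coefficient_near_zero(self):
        rng = np.random.default_rng(7)
        n = 1000
        df = pd.DataFrame({
            "x": rng.choice(["a", "b"], n),
            "time_months": rng.exponential(40, n).clip(max=60),
            "event": 0,
        })
        df["event"] = (df["time_months"] < 60).astype(int)
        m = cox_fit(df, ["x"])
        assert abs(m.coefficients["x"]["b"]) < 0.1

    def test_parameter_recovery_large_cohort(self, cohort2000):
        spec = CohortSpec(n_patients=2000, seed=3)
        refs = {"t_stage": "T1", "n_status": "neg", "grade": "I", "er": "neg",
                "pr": "neg", "her2": "non-amp", "tsr_group": "high"}
        m = cox_fit(cohort2000, list(refs), references=refs)
        for cov, levels in m.coefficients.items():
            for lvl, beta in levels.items():
                if lvl == refs[cov]:
                    continue
                assert beta == pytest.approx(spec.betas[cov][lvl], abs=0.15)

    def test_zero_variance_covariate_dropped(self, cohort240):
        df = cohort240.assign(constant="x")
        with pytest.warns(UserWarning, match="zero variance"):
            m = cox_fit(df, ["constant", "n_status"])
        assert m.dropped == ["constant"]
        assert "n_status" in m.coefficients

    def test_breslow_agrees_with_efron_without_ties(self):
        """On tie-free data the two partial likelihoods coincide."""
        rng = np.random.default_rng(5)
        n = 300
        x = rng.choice(["lo", "hi"], n)
        lam = 0.02 * np.where(x == "hi", 2.0, 1.0)
        t = rng.exponential(1 / lam)  # continuous -> no ties
        df = pd.DataFrame({"x": x, "time_months": t, "event": 1})
        b = cox_fit(df, ["x"], ties="breslow").coefficients["x"]["lo"]
        e = cox_fit(df, ["x"], ties="efron").coefficients["x"]["lo"]
        assert b == pytest.approx(e, abs=1e-4)

    def test_forward_backward_keep_signal_drop_noise(self, cohort2000):
        rng = np.random.default_rng(0)
        df = cohort2000.assign(noise=rng.choice(["u", "v"], len(cohort2000)))
        fwd = cox_fit(df, ["n_status", "noise"], selection="forward")
        assert "n_status" in fwd.coefficients and "noise" not in fwd.coefficients
        bwd = cox_fit(df, ["n_status", "noise"], selection="backward")
        assert "n_status" in bwd.coefficients and "noise" not in bwd.coefficients

    def test_separation_diagnosed(self):
        df = pd.DataFrame({
            "x": ["a"] * 10 + ["b"] * 10,
            "time_months": list(range(1, 11)) + list(range(50, 60)),
            "event": [1] * 10 + [0] * 10,
        })
        with pytest.raises((ConvergenceError, ValueError)):
            cox_fit(df, ["x"])

    def test_baseline_survival_is_reference_pattern(self, cohort240):
        m = cox_fit(cohort240, ["n_status"], references={"n_status": "neg"})
        # reference-pattern prediction equals the baseline itself
        s = m.predict_survival({"n_status": "neg"}, 36.0)
        assert s == pytest.approx(m.baseline_survival_at(36.0))


class TestSubgroupForest:
    def test_single_stratum_matches_cox_fit(self, cohort240):
        df = cohort240.assign(all="everyone")
        forest = subgroup_forest(df, "all")
        m = cox_fit(cohort240, ["tsr_group"], references={"tsr_group": "high"})
        assert forest.loc[0, "HR"] == pytest.approx(m.hazard_ratios["tsr_group"]["low"])

    def test_duplicated_stratum_identical_rows(self, cohort240):
        df = pd.concat([cohort240.assign(s="A"), cohort240.assign(s="B")])
        forest = subgroup_forest(df, "s")
        assert forest.loc[0, "HR"] == pytest.approx(forest.loc[1, "HR"])

    def test_eventless_stratum_flagged(self, cohort240):
        df = cohort240.copy()
        df.loc[df["grade"] == "I", "event"] = 0
        with pytest.warns(UserWarning, match="undefined|no events"):
            forest = subgroup_forest(df, "grade")
        row = forest[forest["subgroup"] == "grade=I"].iloc[0]
        assert np.isnan(row["HR"])

    def test_pooled_estimate_recovers_generating_hr(self, cohort2000):
        forest = subgroup_forest(cohort2000.assign(all="all"), "all")
        row = forest.iloc[0]
        assert row["lo95"] <= 0.643 <= row["hi95"]
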