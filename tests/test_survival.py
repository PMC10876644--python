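"""Survival analysis: hand-computed product-limit and log-rank examples,
brute-force partial-likelihood and cutpoint oracles, classifier tie rules."""

import math

import numpy as np
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from ddherd.survival import (
    cox_fit,
    km_estimator,
    logrank_test,
    normalize_protocol_batches,
    optimal_cutpoint,
    select_covariates,
    top_fraction_classifier,
)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimator([1, 2, 3], [0, 0, 0])
        assert km.at(3.5) == 1.0

    def test_hand_product_limit_all_events(self):
        km = km_estimator([2, 4, 6], [1, 1, 1])
        assert km.at(2) == pytest.approx(2 / 3)
        assert km.at(4) == pytest.approx(1 / 3)
        assert km.at(6) == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        # censored at 4: S stays 2/3 until the last subject's event at 6
        km = km_estimator([2, 4, 6], [1, 0, 1])
        assert km.at(2) == pytest.approx(2 / 3)
        assert km.at(5) == pytest.approx(2 / 3)
        assert km.at(6) == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(2.0, 80)
        km = km_estimator(t, np.ones(80))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km.at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([1, 0, 2], [1, 1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        # alternating event times 1..6, all events; hand O-E accumulation:
        # O_A = 3, E_A = 0.5+0.4+0.5+1/3+0.5 = 2.2333, V = 1.21222
        t = [1, 3, 5, 2, 4, 6]
        e = [1] * 6
        g = list("AAABBB")
        stat, p = logrank_test(t, e, g)
        oe = 3 - (0.5 + 0.4 + 0.5 + 1 / 3 + 0.5)
        v = 0.25 + 0.24 + 0.25 + 4 / 18 + 0.25
        assert stat == pytest.approx(oe**2 / v, abs=1e-9)
        assert p == pytest.approx(0.4862, abs=1e-3)

    def test_group_relabeling_invariance(self, rng):
        t = rng.exponential(1, 30) + 0.01
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = rng.integers(0, 2, 30)
        s1, _ = logrank_test(t, e, g)
        s2, _ = logrank_test(t, e, 1 - g)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_monotone_time_transform_invariance(self, rng):
        t = rng.exponential(1, 30) + 0.01
        e = rng.integers(0, 2, 30)
        e[:3] = 1
        g = rng.integers(0, 2, 30)
        s1, _ = logrank_test(t, e, g)
        s2, _ = logrank_test(np.exp(t), e, g)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_requires_two_groups_and_events(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], ["a", "b"])


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        import pandas as pd

        n = 3000
        df = pd.DataFrame(
            {
                "t": rng.exponential(5, n) + 1e-6,
                "e": np.ones(n, dtype=int),
                "x": rng.integers(0, 2, n),
            }
        )
        fit = cox_fit(df, "t", "e", ["x"])
        assert fit.converged
        assert fit.hazard_ratio("x") == pytest.approx(1.0, abs=0.1)

    def test_brute_force_partial_likelihood_oracle(self):
        import pandas as pd

        # small non-separable instance; Cox estimate must maximize the
        # Breslow/Efron partial likelihood (no ties, so they coincide)
        df = pd.DataFrame(
            {
                "t": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "e": [1, 1, 1, 1, 1, 1],
                "x": [1, 0, 1, 0, 0, 1],
            }
        )

        def neg_log_pl(beta):
            order = np.argsort(df["t"].to_numpy())
            x = df["x"].to_numpy()[order]
            ll = 0.0
            for i in range(len(x)):
                risk = x[i:]
                ll += beta * x[i] - math.log(np.exp(beta * risk).sum())
            return -ll

        grid = np.linspace(-3, 3, 20001)
        beta_star = grid[np.argmin([neg_log_pl(b) for b in grid])]
        fit = cox_fit(df, "t", "e", ["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(beta_star, abs=1e-3)

    def test_recovery_of_unit_log_hazard(self):
        import pandas as pd

        hits = 0
        n_seeds = 25
        for s in range(n_seeds):
            r = np.random.default_rng(s)
            x = r.integers(0, 2, 1000)
            t = r.exponential(1 / (0.1 * np.exp(1.0 * x))) + 1e-9
            df = pd.DataFrame({"t": t, "e": np.ones(1000, int), "x": x})
            coef = cox_fit(df, "t", "e", ["x"]).summary.loc["x", "coef"]
            hits += abs(coef - 1.0) <= 0.1
        assert hits / n_seeds >= 0.9

    def test_ci_brackets_hazard_ratio(self, rng):
        import pandas as pd

        x = rng.integers(0, 2, 300)
        t = rng.exponential(1 / (0.2 * np.exp(0.7 * x))) + 1e-9
        df = pd.DataFrame({"t": t, "e": np.ones(300, int), "x": x})
        fit = cox_fit(df, "t", "e", ["x"])
        row = fit.summary.loc["x"]
        assert row["ci_lower"] <= row["hazard_ratio"] <= row["ci_upper"]
        assert row["hazard_ratio"] == pytest.approx(math.exp(row["coef"]))

    def test_constant_covariate_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"t": [1.0, 2.0], "e": [1, 1], "x": [1, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, "t", "e", ["x"])

    def test_univariable_screen_selects_informative_covariate(self, rng):
        import pandas as pd

        n = 400
        x = rng.integers(0, 2, n)
        noise = rng.normal(size=n)
        t = rng.exponential(1 / (0.1 * np.exp(1.2 * x))) + 1e-9
        df = pd.DataFrame({"t": t, "e": np.ones(n, int), "x": x, "z": noise})
        chosen = select_covariates(df, [("t", "e")], ["x", "z"])
        assert "x" in chosen


class TestOptimalCutpoint:
    def test_separable_hazard_groups_recover_gap(self, rng):
        low = rng.uniform(0, 1, 40)
        high = rng.uniform(3, 4, 40)
        values = np.concatenate([low, high])
        hazard = np.where(values > 2, 1.0, 0.05)
        t = rng.exponential(1 / hazard) + 1e-9
        r = optimal_cutpoint(values, t, np.ones(80, int))
        assert 1.0 < r.cutpoint < 3.0

    def test_exhaustive_split_oracle_on_small_instances(self):
        for s in range(8):
            rng = np.random.default_rng(s)
            n = int(rng.integers(15, 41))
            v = rng.normal(size=n)
            t = rng.exponential(1 / np.where(v > 0, 0.5, 0.15)) + 1e-9
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            r = optimal_cutpoint(v, t, e, minprop=0.1)
            best = None
            for c in r.candidates["cutpoint"]:
                hi = v > c
                res = lifelines_logrank(t[hi], t[~hi], e[hi], e[~hi])
                z = math.sqrt(res.test_statistic)
                if best is None or z > best[1] + 1e-12:
                    best = (c, z)
            assert r.cutpoint == pytest.approx(best[0])
            assert abs(r.standardized_statistic) == pytest.approx(best[1], abs=1e-8)

    def test_minprop_floor_respected(self, rng):
        v = np.concatenate([rng.uniform(0, 1, 50), [100.0] * 3])
        t = rng.exponential(1, 53) + 1e-9
        r = optimal_cutpoint(v, t, np.ones(53, int), minprop=0.4)
        n_high = (v > r.cutpoint).sum()
        assert min(n_high, 53 - n_high) >= 0.4 * 53

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([1.0] * 10, np.arange(1, 11.0), np.ones(10, int))


class TestTopFraction:
    def test_ceiling_rule_at_published_cohort_size(self, rng):
        values = rng.normal(size=682)
        r = top_fraction_classifier(values, 0.136)
        assert r.labels.sum() == 93  # ceil(0.136 * 682) = ceil(92.75)

    def test_minimum_one_positive(self, rng):
        r = top_fraction_classifier(rng.normal(size=50), 0.001)
        assert r.labels.sum() == 1

    def test_all_tied_values_all_positive(self):
        r = top_fraction_classifier([5.0] * 8, 0.25)
        assert r.labels.all()
        assert r.achieved_fraction == 1.0


class TestProtocolNormalization:
    def test_single_protocol_is_pure_log_transform(self, rng):
        x = rng.uniform(0, 50, 30)
        out = normalize_protocol_batches(x, np.array(["dUTP"] * 30))
        assert np.allclose(out, np.log2(x + 0.1))

    def test_log_space_offset_removed(self, rng):
        base = rng.uniform(1, 50, 200)
        expr = np.concatenate([base, base * 2.0])  # +1 in log2 space
        labels = np.array(["dUTP"] * 200 + ["TruSeq"] * 200)
        out = normalize_protocol_batches(expr, labels)
        assert out[:200].mean() == pytest.approx(out[200:].mean(), abs=1e-9)

    def test_zero_expression_finite(self):
        out = normalize_protocol_batches(
            np.array([0.0, 1.0]), np.array(["dUTP", "dUTP"])
        )
        assert np.isfinite(out).all()
        assert out[0] == pytest.approx(math.log2(0.1))

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_protocol_batches([1.0], ["TruSeq"], "dUTP")
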