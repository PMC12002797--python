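"""Linking statistics: outliers, FDR, Spearman, Wilcoxon, OLS, mixed logit."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from socialddm.glmm import GenerosityGLMM, fit_generosity_glmm
from socialddm.stats import (
    benjamini_hochberg,
    linking_regression,
    partial_spearman,
    remove_outliers_3sd,
    spearman,
    spearman_fdr,
    weight_condition_contrasts,
)
from tests.conftest import simulate_glmm_trials


class TestOutliers:
    def test_single_extreme_point_removed(self):
        x = np.zeros(50)
        x[-1] = 100.0
        kept, removed = remove_outliers_3sd(x)
        assert list(removed) == [49]
        assert len(kept) == 49

    def test_constant_vector_untouched(self):
        kept, removed = remove_outliers_3sd(np.full(10, 3.3))
        assert len(kept) == 10 and len(removed) == 0

    def test_within_one_sd_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 30)
        kept, removed = remove_outliers_3sd(x)
        assert len(removed) == 0

    def test_single_pass_not_iterated(self):
        # after removing the big outlier the next-largest point would fall
        # outside 3 SD of the *reduced* sample; single-pass keeps it
        x = np.concatenate([np.zeros(60), [4.0, 100.0]])
        kept, removed = remove_outliers_3sd(x)
        assert len(removed) == 1
        assert 4.0 in kept


class TestBH:
    def test_textbook_vector(self):
        # brute-force BH on (0.01..0.06): all adjusted to 0.06
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        np.testing.assert_allclose(adj, [0.06] * 6)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.uniform(0, 1, 8)
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            running = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                running = min(running, p[i] * m / (rank_idx + 1))
                brute[i] = running
            np.testing.assert_allclose(benjamini_hochberg(p), brute)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 12)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8, 9.7, 0.1, 2.2, 7.1])
        r, _ = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r, _ = spearman(x, -x)
        assert r == pytest.approx(-1.0)

    def test_six_point_table_against_rank_formula(self):
        # hand-checkable table, no ties: r = 1 - 6*sum(d^2)/(n(n^2-1))
        x = np.array([86.0, 97, 99, 100, 101, 103])
        y = np.array([0.0, 20, 28, 27, 50, 29])
        d = sps.rankdata(x) - sps.rankdata(y)
        expected = 1 - 6 * np.sum(d**2) / (6 * 35)
        r, p = spearman(x, y)
        assert r == pytest.approx(expected)

    def test_exact_permutation_p_small_n(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        r, p = spearman(x, y)
        # enumerate all 720 permutations independently
        rx = sps.rankdata(x) - 3.5
        ry = sps.rankdata(y) - 3.5
        obs = abs(rx @ ry)
        count = sum(
            abs(rx @ ry[list(perm)]) >= obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert p == pytest.approx(count / 720)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10))

    def test_family_fdr_and_screening(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.3, 30)
        x_out = x.copy()
        x_out[0] = 40.0  # wrecked by one outlier unless screened
        out = spearman_fdr({"a": (x_out, y), "b": (x, -y)})
        assert out.loc[out["pair"] == "a", "n"].item() == 29
        assert out.loc[out["pair"] == "a", "r"].item() > 0.8
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()


class TestPartialSpearman:
    def test_control_explains_y(self):
        rng = np.random.default_rng(6)
        c = rng.normal(0, 1, 40)
        x = rng.normal(0, 1, 40)
        r, _ = partial_spearman(x, c, c)
        assert abs(r) < 0.15

    def test_x_equals_y(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 40)
        c = rng.normal(0, 1, 40)
        r, p = partial_spearman(x, x, c)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_uncorrelated_control_reduces_to_plain(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        c = rng.normal(0, 1, 200)
        r_plain, _ = spearman(x, y)
        r_part, _ = partial_spearman(x, y, c)
        assert abs(r_part - r_plain) < 0.05

    def test_constant_control_falls_back(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0, 0.5, 20)
        with pytest.warns(UserWarning, match="constant control"):
            r, _ = partial_spearman(x, y, np.ones(20))
        assert r == pytest.approx(spearman(x, y)[0])

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "x": rng.normal(0, 1, 35), "c": rng.normal(0, 1, 35),
        })
        df["y"] = 0.6 * df["x"] + 0.4 * df["c"] + rng.normal(0, 0.5, 35)
        ours, _ = partial_spearman(df["x"], df["y"], df["c"])
        ref = pg.partial_corr(df, x="x", y="y", covar="c", method="spearman")
        assert ours == pytest.approx(float(ref["r"].iloc[0]), abs=0.02)


class TestWilcoxonContrasts:
    def _weights(self, n, rng, self_merit_shift=0.0):
        base = {
            f"{attr}_{manip}_{lvl}": rng.normal(0.5, 0.2, n)
            for attr in ("self", "other", "fairness")
            for manip in ("merit", "need") for lvl in ("high", "low")
        }
        base["self_merit_high"] = base["self_merit_low"] + self_merit_shift \
            + rng.normal(0, 0.05, n)
        return pd.DataFrame(base)

    def test_identical_pairs_p_one(self):
        rng = np.random.default_rng(11)
        w = self._weights(15, rng)
        for manip in ("merit", "need"):
            w[f"fairness_{manip}_high"] = w[f"fairness_{manip}_low"]
        out = weight_condition_contrasts(w)
        fair = out[out["attribute"] == "fairness"]
        assert (fair["p"] == 1.0).all()
        assert fair["undefined"].all()

    def test_power_at_n28(self):
        # every subject weighs self-payoff less under high merit
        rng = np.random.default_rng(12)
        w = self._weights(28, rng, self_merit_shift=-0.3)
        out = weight_condition_contrasts(w)
        row = out[(out["attribute"] == "self") & (out["manipulation"] == "merit")]
        assert row["p_fdr"].item() < 0.05
        assert row["median_diff"].item() < 0

    def test_null_p_uniform(self):
        # KS test on wilcoxon p-values over 500 null replicates
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(500):
            d = rng.normal(0, 1, 20)
            ps.append(sps.wilcoxon(d, method="approx").pvalue)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestLinkingRegression:
    def test_zero_noise_interpolation(self):
        rng = np.random.default_rng(14)
        s = rng.normal(0, 1, 25)
        r = rng.normal(0, 1, 25)
        y = 0.5 + 0.2 * s + 0.3 * r
        out = linking_regression(y, s, r)
        assert out["coef"]["S_merit"] == pytest.approx(0.2, abs=1e-9)
        assert out["coef"]["rTPJ"] == pytest.approx(0.3, abs=1e-9)
        assert out["r2"] == pytest.approx(1.0)

    def test_collinearity_flag(self):
        rng = np.random.default_rng(15)
        s = rng.normal(0, 1, 25)
        out = linking_regression(rng.normal(0, 1, 25), s, 2.0 * s)
        assert out["collinearity_flag"]

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(16)
        s = rng.normal(0, 1, 25)
        r = rng.normal(0, 1, 25)
        y = 0.2 * s + 0.3 * r + rng.normal(0, 0.4, 25)
        out = linking_regression(y, s, r)
        ref = sm.OLS(y, sm.add_constant(np.column_stack([s, r]))).fit()
        assert out["coef"]["S_merit"] == pytest.approx(ref.params[1])
        assert out["p"]["rTPJ"] == pytest.approx(ref.pvalues[2])


class TestGLMM:
    def test_reduces_to_plain_logistic_without_re(self):
        # sigma pinned at (near) zero: fixed effects match a GLM fit
        trials = simulate_glmm_trials(12, 150, beta_need=0.5,
                                      beta_merit_high=0.4, re_sd=0.0, seed=20)
        m = GenerosityGLMM(interaction=False).fit(trials)
        assert m.re_sd_ < 0.1
        X = np.column_stack([
            np.ones(len(trials)),
            (trials["need_level"] == "high").astype(float),
            (trials["partner_merit"] == "unknown").astype(float),
            (trials["partner_merit"] == "high").astype(float),
        ])
        glm = sm.GLM(trials["generous"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(m.fe_params_.to_numpy(), glm.params, atol=2e-3)

    def test_estimates_and_lrt_structure(self):
        trials = simulate_glmm_trials(
            20, 300, beta_need=0.4, beta_merit_high=0.6,
            beta_merit_unknown=0.5, re_sd=0.8, seed=21,
        )
        rep = fit_generosity_glmm(trials)
        assert rep["fixed_effects"]["need_high"] == pytest.approx(0.4, abs=0.2)
        assert rep["re_sd"] == pytest.approx(0.8, abs=0.3)
        assert rep["lrt_full_vs_null"]["p"] < 1e-6
        assert rep["lrt_interaction"]["df"] == 2
        lo, hi = rep["ci95"]["need_high"]
        assert lo < rep["fixed_effects"]["need_high"] < hi
        assert 0 < rep["r2_marginal"] <= rep["r2_conditional"] < 1

    def test_missing_level_raises(self):
        trials = simulate_glmm_trials(5, 60, seed=22)
        with pytest.raises(ValueError, match="levels"):
            GenerosityGLMM().fit(trials[trials["partner_merit"] != "high"])
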