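import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ancestrx import PredictorSet, fit_model, nested_f_test
from ancestrx.association import (
    ethnicity_aligned_dimensions,
    run_model_grid,
    summarize_grid,
)
from ancestrx.treatment_effects import TreatmentEffects, TreatmentEffectSet


def pset(label, arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"x{j}" for j in range(arr.shape[1])]
    idx = pd.Index([f"S{i}" for i in range(len(arr))], name="subject")
    return PredictorSet(label, pd.DataFrame(arr, index=idx, columns=names))


def series(values):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=[f"S{i}" for i in range(len(values))],
    )


class TestFitModel:
    def test_exact_linear_relationship(self, rng):
        x = rng.standard_normal((30, 3))
        y = x @ [1.0, -2.0, 0.5] + 4.0
        res = fit_model(series(y), pset("custom", x))
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_engineered_r2_gives_f_from_formula(self, rng):
        """n=10, k=2, R^2=1/2 by construction -> F = 0.25/(0.5/7) = 3.5."""
        n, k = 10, 2
        x = rng.standard_normal((n, k))
        design = np.column_stack([np.ones(n), x])
        q, _ = np.linalg.qr(design)
        fitted = design @ [0.0, 1.0, 1.0]
        fitted = fitted - fitted.mean()
        resid = rng.standard_normal(n)
        resid = resid - q @ (q.T @ resid)  # orthogonal to intercept and x
        resid *= np.linalg.norm(fitted) / np.linalg.norm(resid)
        y = fitted + resid  # SSR = SSE -> R^2 = 0.5 exactly
        res = fit_model(series(y), pset("custom", x))
        assert res.r2 == pytest.approx(0.5, abs=1e-12)
        assert res.f == pytest.approx(3.5, abs=1e-9)
        assert res.df1 == 2 and res.df2 == 7

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal((40, 4))
        y = x[:, 0] + rng.standard_normal(40)
        res = fit_model(series(y), pset("custom", x))
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.r2 == pytest.approx(ref.rsquared, abs=1e-12)
        assert res.f == pytest.approx(ref.fvalue, abs=1e-9)
        assert res.p == pytest.approx(ref.f_pvalue, abs=1e-12)

    def test_null_pvalues_are_uniform(self):
        """Independent outcome: model-fit p ~ Uniform(0,1) across 200 seeds."""
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((1000, 5))
            y = rng.standard_normal(1000)
            pvals.append(fit_model(series(y), pset("custom", x)).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.standard_normal((20, 2))
        x = np.column_stack([x, x[:, 0] * 2.0])
        with pytest.raises(ValueError, match="x2"):
            fit_model(series(rng.standard_normal(20)), pset("custom", x))

    def test_too_few_cases_rejected(self, rng):
        x = rng.standard_normal((4, 3))
        with pytest.raises(ValueError, match="too few"):
            fit_model(series(rng.standard_normal(4)), pset("custom", x))

    def test_constant_predictor_rejected(self, rng):
        x = np.column_stack([rng.standard_normal(10), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="constant"):
            pset("custom", x)


class TestNestedFTest:
    def fit_pair(self, rng, n=50, k_full=5, k_red=3):
        x = rng.standard_normal((n, k_full))
        y = x[:, 0] - 0.5 * x[:, 3] + rng.standard_normal(n)
        full = fit_model(series(y), pset("full", x))
        red = fit_model(series(y), pset("red", x[:, :k_red],
                                        names=[f"x{j}" for j in range(k_red)]))
        return y, x, full, red

    def test_matches_brute_force_rss_oracle(self, rng):
        """Partial F equals the textbook RSS computation to 1e-10."""
        n = 50
        y, x, full, red = self.fit_pair(rng, n=n)
        f_stat, q, df2, p = nested_f_test(full, red)

        def rss(cols):
            d = np.column_stack([np.ones(n), cols])
            beta, _, _, _ = np.linalg.lstsq(d, y, rcond=None)
            return np.sum((y - d @ beta) ** 2)

        rss_f, rss_r = rss(x), rss(x[:, :3])
        f_oracle = ((rss_r - rss_f) / 2) / (rss_f / (n - 5 - 1))
        assert f_stat == pytest.approx(f_oracle, abs=1e-10)
        assert q == 2 and df2 == n - 6
        assert p == pytest.approx(stats.f.sf(f_oracle, 2, n - 6), abs=1e-12)

    def test_no_incremental_fit_gives_zero_f(self, rng):
        """Extra predictors that explain nothing beyond x0: delta R^2 = 0."""
        n = 30
        x = rng.standard_normal((n, 3))
        y = x[:, 0]  # fully explained by the reduced model already
        full = fit_model(series(y), pset("full", x))
        red = fit_model(series(y), pset("red", x[:, :1], names=["x0"]))
        f_stat, _, _, p = nested_f_test(full, red)
        assert f_stat == pytest.approx(0.0, abs=1e-6)

    def test_non_nested_rejected(self, rng):
        x = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        a = fit_model(series(y), pset("a", x[:, :2], names=["x0", "x1"]))
        b = fit_model(series(y), pset("b", x[:, 1:], names=["x1", "x2"]))
        with pytest.raises(ValueError, match="not nested"):
            nested_f_test(a, b)


def make_effect_set(effects_by_combo):
    out = TreatmentEffectSet()
    for (drug, outcome), eff in effects_by_combo.items():
        out[(drug, outcome)] = TreatmentEffects(
            drug=drug, outcome=outcome, effects=eff, spec=None,
            n_subjects=len(eff), mean_observations=4.0,
        )
    return out


class TestModelGrid:
    def setup_scores_ethnicity(self, rng, n=150):
        scores = pd.DataFrame(
            rng.standard_normal((n, 5)),
            index=pd.Index([f"S{i:03d}" for i in range(n)], name="subject"),
            columns=[f"MDS{k}" for k in range(1, 6)],
        )
        # ethnicity driven by MDS1/MDS2 so dimensions 1-2 are "aligned"
        labels = (scores["MDS1"] > 0).astype(int) + (scores["MDS2"] > 0.5).astype(int)
        eth = pd.DataFrame(
            {
                "eth_european": (labels == 0).astype(float),
                "eth_african": (labels == 1).astype(float),
                "eth_hispanic": (labels == 2).astype(float),
            },
            index=scores.index,
        )
        # a sprinkle of "other" keeps the indicators non-collinear
        eth.iloc[::17] = 0.0
        return scores, eth

    def test_single_combination_yields_four_models(self, rng):
        scores, eth = self.setup_scores_ethnicity(rng)
        y = pd.Series(rng.standard_normal(len(scores)), index=scores.index)
        effects = make_effect_set({("d", "o"): y})
        results, comparisons = run_model_grid(effects, scores, eth)
        assert sorted(results["model"]) == ["M1", "M2", "M3", "M4"]
        assert len(comparisons) == 3

    def test_full_model_dominates_nested_models(self, rng):
        scores, eth = self.setup_scores_ethnicity(rng)
        y = pd.Series(
            scores["MDS1"] + rng.standard_normal(len(scores)), index=scores.index
        )
        results, _ = run_model_grid(make_effect_set({("d", "o"): y}), scores, eth)
        r2 = results.set_index("model")["R2"]
        assert r2["M1"] >= max(r2["M2"], r2["M3"], r2["M4"]) - 1e-12

    def test_identical_cases_across_models(self, rng):
        scores, eth = self.setup_scores_ethnicity(rng)
        y = pd.Series(rng.standard_normal(len(scores)), index=scores.index)
        y.iloc[:10] = np.nan  # missing effects must drop from all four fits
        results, _ = run_model_grid(make_effect_set({("d", "o"): y}), scores, eth)
        assert results["n"].nunique() == 1
        assert results["n"].iloc[0] == len(scores) - 10

    def test_redundant_ethnicity_adds_nothing(self, rng):
        """Effects driven by MDS only: dropping ethnicity barely moves R."""
        scores, eth = self.setup_scores_ethnicity(rng, n=300)
        y = pd.Series(
            2.0 * scores["MDS1"] - scores["MDS2"]
            + 0.1 * rng.standard_normal(len(scores)),
            index=scores.index,
        )
        _, comparisons = run_model_grid(make_effect_set({("d", "o"): y}), scores, eth)
        comp = comparisons.set_index("comparison")["delta_R"].abs()
        assert comp["2 vs. 1 (drop 3 Ethnicity)"] < 0.01

    def test_cryptic_signal_shows_in_mds_not_ethnicity(self, rng):
        """Signal on a dimension uncorrelated with ethnicity: dropping the 5
        MDS dimensions costs much more R than dropping ethnicity."""
        scores, eth = self.setup_scores_ethnicity(rng, n=300)
        y = pd.Series(
            2.0 * scores["MDS5"] + 0.5 * rng.standard_normal(len(scores)),
            index=scores.index,
        )
        _, comparisons = run_model_grid(make_effect_set({("d", "o"): y}), scores, eth)
        comp = comparisons.set_index("comparison")["delta_R"].abs()
        assert comp["3 vs. 1 (drop 5 MDS)"] > 10 * comp["2 vs. 1 (drop 3 Ethnicity)"]

    def test_small_combinations_skipped_not_dropped(self, rng):
        scores, eth = self.setup_scores_ethnicity(rng)
        tiny = pd.Series(rng.standard_normal(5), index=scores.index[:5])
        ok = pd.Series(rng.standard_normal(len(scores)), index=scores.index)
        results, _ = run_model_grid(
            make_effect_set({("d1", "o"): tiny, ("d2", "o"): ok}), scores, eth
        )
        assert (results[results["drug"] == "d1"]["model"] == "skipped").all()
        assert set(results[results["drug"] == "d2"]["model"]) == {"M1", "M2", "M3", "M4"}

    def test_aligned_dimensions_found(self, rng):
        scores, eth = self.setup_scores_ethnicity(rng, n=400)
        aligned = ethnicity_aligned_dimensions(scores, eth)
        assert "MDS1" in aligned and "MDS2" in aligned

    def test_summary_has_mean_and_quartiles(self, rng):
        scores, eth = self.setup_scores_ethnicity(rng)
        y = pd.Series(rng.standard_normal(len(scores)), index=scores.index)
        results, _ = run_model_grid(make_effect_set({("d", "o"): y}), scores, eth)
        summary = summarize_grid(results)
        assert set(summary.columns) == {"model", "mean", "q1", "q3"}
        assert len(summary) == 4
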