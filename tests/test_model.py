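import numpy as np
import pandas as pd
import pytest

from histodti.phantoms import CohortSpec, ResponseSpec, generate_cohort
from histodti.model import (
    PREDICTORS, SingularDesignError, adjusted_r2, f_statistic, fit_multivariate,
    loao_cv, loro_cv, pearson_univariate, q_squared, univariate_table,
)


def noiseless_cohort(seed=0, b=(0.8, -300.0, 150.0, 0.5, -0.4), c=0.3):
    spec = CohortSpec(seed=seed, responses={"y": ResponseSpec(b=b, c=c, noise_sd=0.0)})
    return generate_cohort(spec), np.asarray(b), c


class TestFit:
    def test_noiseless_interpolation(self):
        table, b, c = noiseless_cohort()
        fit = fit_multivariate(table, "y", ci=False)
        assert fit.R2 == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(fit.b, b, atol=1e-8)
        assert fit.c == pytest.approx(c, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        table = generate_cohort(CohortSpec(seed=1))
        fit = fit_multivariate(table, "AI_myelin", ci=False)
        X = sm.add_constant(table[list(PREDICTORS)].to_numpy())
        ref = sm.OLS(table["AI_myelin"].to_numpy(), X).fit()
        assert fit.R2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert fit.R2_adj == pytest.approx(ref.rsquared_adj, rel=1e-10)
        assert fit.F == pytest.approx(ref.fvalue, rel=1e-8)
        assert np.allclose(fit.b, ref.params[1:], rtol=1e-8)

    def test_closed_form_identities(self):
        table = generate_cohort(CohortSpec(seed=2))
        fit = fit_multivariate(table, "AI_myelin", ci=False)
        n, p = fit.n, len(fit.predictors)
        assert fit.R2_adj == pytest.approx(1 - (1 - fit.R2) * (n - 1) / (n - p - 1))
        assert fit.F == pytest.approx((fit.R2 / p) / ((1 - fit.R2) / (n - p - 1)))

    def test_printed_consistency_adjusted_r2(self):
        """Published multivariate fits at n = 68, p = 5 follow the closed form
        (tolerance reflects the 3-decimal rounding of the published R^2)."""
        assert adjusted_r2(0.822, 68, 5) == pytest.approx(0.807, abs=1e-3)
        assert adjusted_r2(0.855, 68, 5) == pytest.approx(0.843, abs=1e-3)

    def test_permuted_response_yields_null_fit(self):
        """Shuffling y should leave R^2 near its null expectation p/(n-1)."""
        rng = np.random.default_rng(0)
        table = generate_cohort(CohortSpec(seed=3))
        r2s, fs = [], []
        n, p = 68, 5
        f_crit = 2.35  # F(5, 62) upper 5% point
        for _ in range(200):
            shuffled = table.copy()
            shuffled["AI_myelin"] = rng.permutation(shuffled["AI_myelin"].to_numpy())
            fit = fit_multivariate(shuffled, "AI_myelin", ci=False)
            r2s.append(fit.R2)
            fs.append(fit.F)
        assert np.mean(r2s) == pytest.approx(p / (n - 1), abs=0.03)
        assert np.mean(np.asarray(fs) < f_crit) >= 0.90

    def test_ad_inclusion_raises_named_singularity(self):
        table, _, _ = noiseless_cohort()
        with pytest.raises(SingularDesignError, match="AD = 3\\*MD - 2\\*RD"):
            fit_multivariate(table, "y", predictors=("FA", "AD", "RD", "MD", "CP", "CS"))

    def test_cl_inclusion_raises_named_singularity(self):
        table, _, _ = noiseless_cohort()
        with pytest.raises(SingularDesignError, match="CL = 1 - CP - CS"):
            fit_multivariate(table, "y", predictors=("FA", "RD", "MD", "CL", "CP", "CS"))

    def test_r2_ci_brackets_estimate(self):
        table = generate_cohort(CohortSpec(seed=4))
        fit = fit_multivariate(table, "AI_myelin", n_boot=400, seed=0)
        lo, hi = fit.R2_ci
        assert lo <= fit.R2 <= hi
        assert 0 <= lo and hi <= 1

    def test_missing_rows_dropped_listwise(self):
        table = generate_cohort(CohortSpec(seed=5))
        table.loc[table.index[:3], "AI_myelin"] = np.nan
        fit = fit_multivariate(table, "AI_myelin", ci=False)
        assert fit.n == 65


class TestPearson:
    def test_exact_linear_relation(self):
        table, _, _ = noiseless_cohort()
        table["z"] = 2.0 * table["FA"]
        r, ci, r2, p = pearson_univariate(table, "z", "FA")
        assert r == pytest.approx(1.0)

    def test_r_squared_consistency(self):
        table = generate_cohort(CohortSpec(seed=6))
        r, ci, r2, p = pearson_univariate(table, "AI_myelin", "FA")
        assert r2 == pytest.approx(r ** 2)
        assert ci[0] <= r <= ci[1]

    def test_null_sampling_band_at_n68(self):
        """Independent x, y at n = 68: |R| < 0.24 (the two-sided 5% point of
        the null distribution) with frequency consistent with 95%."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(size=68)
            y = rng.normal(size=68)
            hits += abs(np.corrcoef(x, y)[0, 1]) < 0.24
        assert 0.93 <= hits / n_sim <= 0.975

    def test_zero_variance_rejected(self):
        table, _, _ = noiseless_cohort()
        table["const"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            pearson_univariate(table, "y", "const")

    def test_univariate_grid_has_family_q(self):
        table = generate_cohort(CohortSpec(seed=7))
        grid = univariate_table(table, ["AI_myelin"])
        assert len(grid) == 5
        assert np.all(grid["q"] >= grid["p"] - 1e-12)


def _q2_oracle(y, yhat):
    """Independent brute-force evaluation of the cross-validated Q^2 formula."""
    y = list(map(float, y))
    yhat = list(map(float, yhat))
    kj = len(y)
    ybar = sum(y) / kj
    num = sum((a - b) ** 2 for a, b in zip(y, yhat)) / kj
    den = sum((a - ybar) ** 2 for a in y) / kj
    return 1 - num / den


class TestCrossValidation:
    def test_noiseless_cohort_perfect_cv(self):
        table, _, _ = noiseless_cohort()
        cv = loao_cv(table, "y")
        assert cv.R_cv == pytest.approx(1.0, abs=1e-8)
        assert cv.Q2 == pytest.approx(1.0, abs=1e-10)

    def test_mean_prediction_gives_q2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert q_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_q2_matches_independent_oracle(self):
        table = generate_cohort(CohortSpec(seed=8))
        cv = loao_cv(table, "AI_myelin")
        folds = cv.per_fold_predictions
        assert cv.Q2 == pytest.approx(_q2_oracle(folds["y_true"], folds["y_pred"]))

    def test_loao_folds_hold_out_whole_animals(self):
        table = generate_cohort(CohortSpec(seed=9))
        cv = loao_cv(table, "AI_myelin")
        assert len(cv.per_fold_predictions) == 68
        assert cv.per_fold_predictions["fold"].nunique() == 17

    def test_needs_three_animals(self):
        table = generate_cohort(CohortSpec(seed=0))
        two = table[table["animal_id"].isin(["A00", "A01"])]
        with pytest.raises(ValueError, match="3 animals"):
            loao_cv(two, "AI_myelin")

    def test_loro_noiseless_all_regions_perfect(self):
        table, _, _ = noiseless_cohort()
        res = loro_cv(table, "y")
        assert set(res.per_region) == {"cc", "layerV", "layerVI", "CA3b"}
        for r in res.per_region.values():
            assert r == pytest.approx(1.0, abs=1e-6)
        assert res.pooled_R == pytest.approx(1.0, abs=1e-6)

    def test_loro_two_regions_symmetric_folds(self):
        table, _, _ = noiseless_cohort()
        sub = table[table["region"].isin(["cc", "CA3b"])]
        res = loro_cv(sub, "y")
        folds = res.per_fold_predictions
        assert set(folds["fold"]) == {"cc", "CA3b"}
        assert (folds["fold"] == "cc").sum() == (folds["fold"] == "CA3b").sum() == 17

    def test_loro_degrades_on_extrapolated_region(self):
        """A region with disjoint predictor support and a different local
        relation loses held-out accuracy while the interpolating regions keep
        theirs (the rationale for retaining the damaged subfield)."""
        rng = np.random.default_rng(2)
        rows = []
        for k in range(17):
            for region, lo in (("cc", 0.0), ("layerV", 0.3), ("layerVI", 0.6),
                               ("CA3b", 3.0)):
                x = np.concatenate([rng.uniform(lo, lo + 0.4, 1),
                                    rng.uniform(0, 0.01, 4)])  # near-inert extras
                # shared relation y = x1 except in the held-apart region,
                # where the slope reverses
                y = float(x[0]) if region != "CA3b" else float(10.0 - 2.0 * x[0])
                rows.append(dict(animal_id=f"A{k}", region=region,
                                 **dict(zip(PREDICTORS, x)), y=y + rng.normal(0, 0.01)))
        table = pd.DataFrame(rows)
        res = loro_cv(table, "y")
        others = [res.per_region[r] for r in ("cc", "layerV", "layerVI")]
        assert min(others) > 0.7
        assert res.per_region["CA3b"] < 0.0 < min(others)

    def test_null_cohort_q2_nonpositive_on_average(self):
        q2s = []
        for seed in range(60):
            table = generate_cohort(CohortSpec(seed=seed, responses={
                "y": ResponseSpec(b=(0.0,) * 5, c=1.0, noise_sd=0.05)}))
            q2s.append(loao_cv(table, "y").Q2)
        assert np.mean(q2s) <= 0.0
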