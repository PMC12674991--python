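import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from transcompr import (
    ALL_COVARIATE_SPECS,
    CovariateSpec,
    fit_pc_glm,
    multi_pc_collinearity_check,
    run_lasso_stability,
    select_pcs,
)
from transcompr._lasso import lambda_grid, logistic_lasso_path
from transcompr.pca import HumanScores


def make_scores(rng, n=42, n_pc=6, effect_pc=None, effect=0.0, prefix="T2D PC"):
    cols = [f"{prefix}{i + 1}" for i in range(n_pc)]
    X = rng.standard_normal((n, n_pc))
    y = np.array([0] * (n - n // 2 - 4) + [1] * (n // 2 + 4))[:n]
    rng.shuffle(y)
    if effect_pc is not None:
        X[y == 1, effect_pc] += effect
    idx = [f"s{i}" for i in range(n)]
    return HumanScores(
        scores=pd.DataFrame(X, index=idx, columns=cols),
        outcome=pd.Series(y, index=idx),
        sex=pd.Series(rng.choice(["F", "M"], n), index=idx),
        age=pd.Series(rng.uniform(65, 95, n), index=idx),
    )


class TestLassoSolver:
    def test_matches_sklearn_when_all_penalized(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        n, p = 60, 8
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:2] = [1.5, -1.0]
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        pf = np.ones(p)
        lams = lambda_grid(X, y, pf)
        ic, co = logistic_lasso_path(X, y, lams, pf, max_outer=50, max_inner=200, tol=1e-10)
        for k in (5, 12, 20):
            sk = LogisticRegression(
                l1_ratio=1,
                C=1.0 / (n * lams[k]),
                solver="liblinear",
                tol=1e-10,
                max_iter=20000,
                intercept_scaling=1e4,
            ).fit(X, y)
            assert np.abs(co[k] - sk.coef_[0]).max() < 1e-4
            assert np.array_equal(co[k] != 0, sk.coef_[0] != 0)

    def test_huge_penalty_zeroes_all_penalized(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 6))
        y = (rng.random(40) < 0.5).astype(float)
        pf = np.ones(6)
        pf[5] = 0.0  # unpenalized covariate stays free
        lams = np.array([1e3])
        _, co = logistic_lasso_path(X, y, lams, pf)
        assert np.all(co[0, :5] == 0.0)

    def test_tiny_penalty_approaches_unpenalized_fit(self):
        rng = np.random.default_rng(2)
        n, p = 200, 4
        X = rng.standard_normal((n, p))
        beta = np.array([1.0, -0.8, 0.5, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        pf = np.ones(p)
        lams = np.logspace(0, -5, 25)
        ic, co = logistic_lasso_path(X, y, lams, pf, max_outer=50, max_inner=200, tol=1e-9)
        mle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.abs(co[-1] - mle.params[1:]).max() < 1e-2

    def test_unpenalized_covariate_survives_where_penalized_die(self):
        rng = np.random.default_rng(3)
        n = 80
        X = rng.standard_normal((n, 3))
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * X[:, 2]))).astype(float)
        pf = np.array([1.0, 1.0, 0.0])
        lams = lambda_grid(X, y, pf)
        _, co = logistic_lasso_path(X, y, lams, pf)
        assert co[0, 0] == 0 and co[0, 1] == 0
        assert co[0, 2] != 0


class TestStabilitySelection:
    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(4)
        scores = make_scores(rng, effect_pc=1, effect=1.5)
        a = run_lasso_stability(scores, CovariateSpec(), rounds=15, seed=9)
        b = run_lasso_stability(scores, CovariateSpec(), rounds=15, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_frequencies_equivariant_under_column_relabeling(self):
        rng = np.random.default_rng(5)
        scores = make_scores(rng, effect_pc=2, effect=1.5)
        base = run_lasso_stability(scores, CovariateSpec(), rounds=15, seed=3)
        perm = list(scores.scores.columns[::-1])
        permuted = HumanScores(
            scores.scores[perm], scores.outcome, scores.sex, scores.age
        )
        out = run_lasso_stability(permuted, CovariateSpec(), rounds=15, seed=3)
        assert dict(out["frequency"]) == dict(base["frequency"])

    def test_strong_pc_outranks_noise(self):
        rng = np.random.default_rng(6)
        scores = make_scores(rng, effect_pc=0, effect=2.0)
        freq = run_lasso_stability(
            scores, CovariateSpec(sex=True, age=True), rounds=25, seed=1
        )
        assert freq["frequency"].idxmax() == "T2D PC1"
        assert freq.loc["T2D PC1", "frequency"] > 50

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(7)
        scores = make_scores(rng)
        scores.outcome[:] = 1
        with pytest.raises(ValueError):
            run_lasso_stability(scores, CovariateSpec(), rounds=5, seed=0)


class TestSelectPcs:
    def make_freq(self, values):
        idx = [f"PC{i + 1}" for i in range(len(values))]
        return pd.DataFrame(
            {"count": values, "frequency": values}, index=pd.Index(idx, name="pc")
        )

    def test_threshold_is_strictly_greater(self):
        freqs = {"pcs": self.make_freq([50, 51, 49])}
        out = select_pcs(freqs)
        assert not out.loc["PC1", "selected_pcs"]
        assert out.loc["PC2", "selected_pcs"]
        assert not out.loc["PC3", "selected_pcs"]

    def test_consistency_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(8)
        tables = {
            name: self.make_freq(rng.integers(0, 101, 10))
            for name in ("a", "b", "c", "d")
        }
        out = select_pcs(tables)
        sets = {
            name: {pc for pc in t.index if t.loc[pc, "frequency"] > 50}
            for name, t in tables.items()
        }
        inter = set.intersection(*sets.values())
        union = set.union(*sets.values())
        assert set(out.index[out["consistent"]]) == inter
        assert set(out.index[out["selected_any"]]) == union
        for pc in out.index:
            assert out.loc[pc, "n_models_selected"] == sum(
                pc in s for s in sets.values()
            )


class TestPcGlm:
    def test_recovers_known_coefficient(self):
        # logistic truth beta=1.5 at n=500; average estimate over replicates
        rng = np.random.default_rng(9)
        estimates = []
        for _ in range(100):
            n = 500
            x = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x))).astype(int)
            idx = [f"s{i}" for i in range(n)]
            scores = HumanScores(
                scores=pd.DataFrame({"T2D PC1": x}, index=idx),
                outcome=pd.Series(y, index=idx),
                sex=pd.Series(["F"] * n, index=idx),
                age=pd.Series(rng.uniform(65, 95, n), index=idx),
            )
            estimates.append(fit_pc_glm(scores, "T2D PC1")["coef"])
        assert abs(np.mean(estimates) - 1.5) < 0.3

    def test_separation_flagged(self):
        rng = np.random.default_rng(10)
        n = 40
        x = rng.standard_normal(n)
        y = (x > 0).astype(int)  # outcome is a deterministic threshold
        idx = [f"s{i}" for i in range(n)]
        scores = HumanScores(
            scores=pd.DataFrame({"T2D PC1": x}, index=idx),
            outcome=pd.Series(y, index=idx),
            sex=pd.Series(["M"] * n, index=idx),
            age=pd.Series(rng.uniform(65, 95, n), index=idx),
        )
        row = fit_pc_glm(scores, "T2D PC1")
        assert row["separation"]
        assert np.isnan(row["model_p"])

    def test_covariate_model_includes_requested_terms(self):
        rng = np.random.default_rng(11)
        scores = make_scores(rng, effect_pc=0, effect=1.0)
        row = fit_pc_glm(scores, "T2D PC1", CovariateSpec(sex=True, age=True))
        assert row["covariates"] == "pcs+sex+age"
        assert np.isfinite(row["model_p"])


class TestCollinearity:
    def test_orthogonal_columns_have_unit_vif(self):
        rng = np.random.default_rng(12)
        # orthonormal columns that are also mean-zero (VIF regressions are
        # centered), built by orthogonalizing against the constant vector
        base = np.column_stack([np.ones(60), rng.standard_normal((60, 3))])
        q = np.linalg.qr(base)[0][:, 1:]
        idx = [f"s{i}" for i in range(60)]
        scores = HumanScores(
            scores=pd.DataFrame(q, index=idx, columns=["A PC1", "A PC2", "A PC3"]),
            outcome=pd.Series([0, 1] * 30, index=idx),
            sex=pd.Series(["F"] * 60, index=idx),
            age=pd.Series(np.linspace(65, 95, 60), index=idx),
        )
        out = multi_pc_collinearity_check(scores, ["A PC1", "A PC2", "A PC3"])
        assert np.abs(out["vif"] - 1.0).max() < 1e-6

    def test_duplicated_column_flags_infinite_vif(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(30)
        idx = [f"s{i}" for i in range(30)]
        scores = HumanScores(
            scores=pd.DataFrame({"A PC1": x, "A PC2": x}, index=idx),
            outcome=pd.Series([0, 1] * 15, index=idx),
            sex=pd.Series(["F"] * 30, index=idx),
            age=pd.Series(np.linspace(65, 95, 30), index=idx),
        )
        out = multi_pc_collinearity_check(scores, ["A PC1", "A PC2"])
        assert np.isinf(out["vif"]).all()

    def test_vif_matches_r_squared_identity(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((50, 4))
        X[:, 3] = X[:, 0] * 0.7 + rng.standard_normal(50) * 0.5
        cols = [f"A PC{i + 1}" for i in range(4)]
        idx = [f"s{i}" for i in range(50)]
        scores = HumanScores(
            scores=pd.DataFrame(X, index=idx, columns=cols),
            outcome=pd.Series([0, 1] * 25, index=idx),
            sex=pd.Series(["F"] * 50, index=idx),
            age=pd.Series(np.linspace(65, 95, 50), index=idx),
        )
        out = multi_pc_collinearity_check(scores, cols).set_index("pc")
        Xc = X - X.mean(axis=0)
        for j, pc in enumerate(cols):
            others = np.delete(Xc, j, axis=1)
            xj = Xc[:, j]
            bhat = np.linalg.lstsq(others, xj, rcond=None)[0]
            r2 = 1 - ((xj - others @ bhat) ** 2).sum() / (xj**2).sum()
            assert abs(out.loc[pc, "vif"] - 1 / (1 - r2)) < 1e-8
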