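import numpy as np
import pandas as pd
import pytest

from transcompr import (
    ExpressionMatrix,
    HomologMap,
    align_homologs,
    fit_group_pca,
    mouse_vs_human_variance_table,
    project_human,
    variance_explained_in_human,
)
from transcompr.pca import orient_to_human_outcome

from conftest import random_expr


def make_aligned(rng, n_genes=200, n_per_group=3, mouse_values=None):
    """An aligned z-scored pair with a 6-mouse T2D+control cohort."""
    samples = [f"ctl{i}" for i in range(n_per_group)] + [
        f"t2d{i}" for i in range(n_per_group)
    ]
    vals = (
        mouse_values
        if mouse_values is not None
        else rng.standard_normal((n_genes, 2 * n_per_group))
    )
    mouse = ExpressionMatrix(
        pd.DataFrame(vals, index=[f"m{i:04d}" for i in range(n_genes)], columns=samples),
        species="mouse",
        state="log2",
    )
    human = random_expr(rng, n_genes, 10, prefix="H", state="log2")
    pairs = [(f"m{i:04d}", f"H{i:04d}") for i in range(n_genes)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": ["control"] * n_per_group + ["T2D"] * n_per_group,
        }
    ).set_index("sample_id", drop=False)
    return align_homologs(mouse, human, HomologMap(pairs)), meta


class TestFitGroupPCA:
    def test_six_samples_cap_at_five_pcs(self):
        rng = np.random.default_rng(0)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D")
        assert pca.k_computed <= 5
        assert 1 <= pca.k_retained <= 5

    def test_rank_one_fixture_retains_single_pc(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(50)
        s = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        vals = np.outer(u, s)
        aligned, meta = make_aligned(rng, n_genes=50, mouse_values=vals)
        pca = fit_group_pca(aligned, meta, "T2D")
        assert pca.k_retained == 1
        assert pca.var_fraction[0] == pytest.approx(1.0)

    def test_matches_dense_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(2)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D", cum_var_threshold=1.0)
        X = aligned.mouse.values.T
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for i in range(pca.k_computed):
            q, v = pca.loadings[:, i], Vt[i]
            sign = np.sign(q @ v)
            assert np.abs(q - sign * v).max() < 1e-8
            assert np.abs(pca.mouse_scores[:, i] - sign * U[:, i] * s[i]).max() < 1e-8

    def test_orthonormal_loadings_and_reconstruction(self):
        rng = np.random.default_rng(3)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D", cum_var_threshold=1.0)
        Q = pca.loadings
        assert np.abs(Q.T @ Q - np.eye(Q.shape[1])).max() < 1e-8
        X = aligned.mouse.values.T
        recon = pca.mouse_scores @ Q.T + pca.center
        assert np.abs(X - recon).max() < 1e-8

    def test_variance_fractions_nonincreasing(self):
        rng = np.random.default_rng(4)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D")
        assert (np.diff(pca.var_fraction) <= 1e-12).all()
        assert pca.var_fraction.sum() <= 1 + 1e-8

    def test_unknown_disease_is_error(self):
        rng = np.random.default_rng(5)
        aligned, meta = make_aligned(rng)
        with pytest.raises(ValueError):
            fit_group_pca(aligned, meta, "ALS")
        with pytest.raises(ValueError, match="AD"):
            fit_group_pca(aligned, meta, "AD")  # absent from this metadata


class TestProjectHuman:
    def test_mouse_subgroup_projects_to_its_own_scores(self):
        rng = np.random.default_rng(6)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D", cum_var_threshold=1.0)
        as_human = ExpressionMatrix(
            pd.DataFrame(
                aligned.mouse.values, index=pca.human_genes, columns=pca.sample_ids
            ),
            species="human",
            state="log2",
        )
        scores = project_human(as_human, pca)
        assert np.abs(scores.to_numpy() - pca.mouse_scores).max() < 1e-8

    def test_center_row_maps_to_zero(self):
        rng = np.random.default_rng(7)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D")
        one = ExpressionMatrix(
            pd.DataFrame(
                pca.center[:, None], index=pca.human_genes, columns=["center"]
            ),
            species="human",
            state="log2",
        )
        assert np.abs(project_human(one, pca).to_numpy()).max() < 1e-10

    def test_matches_triple_loop_product(self):
        rng = np.random.default_rng(8)
        aligned, meta = make_aligned(rng, n_genes=40)
        pca = fit_group_pca(aligned, meta, "T2D")
        scores = project_human(aligned.human, pca).to_numpy()
        X = aligned.human.values.T
        for s in range(X.shape[0]):
            for i in range(pca.k_retained):
                acc = 0.0
                for g in range(X.shape[1]):
                    acc += (X[s, g] - pca.center[g]) * pca.loadings[g, i]
                assert abs(scores[s, i] - acc) < 1e-10

    def test_projection_is_linear(self):
        rng = np.random.default_rng(9)
        aligned, meta = make_aligned(rng, n_genes=60)
        pca = fit_group_pca(aligned, meta, "T2D")
        h = aligned.human

        def proj_centered(arr):
            em = ExpressionMatrix(
                pd.DataFrame(arr + pca.center[:, None], index=h.genes,
                             columns=[f"x{i}" for i in range(arr.shape[1])]),
                species="human", state="log2",
            )
            return project_human(em, pca).to_numpy()

        a, b = 2.0, -0.5
        X1 = rng.standard_normal((60, 4))
        X2 = rng.standard_normal((60, 4))
        lhs = proj_centered(a * X1 + b * X2)
        rhs = a * proj_centered(X1) + b * proj_centered(X2)
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_gene_mismatch_names_first_offender(self):
        rng = np.random.default_rng(10)
        aligned, meta = make_aligned(rng, n_genes=20)
        pca = fit_group_pca(aligned, meta, "T2D")
        wrong = aligned.human.data.copy()
        wrong.index = ["WRONG"] + list(wrong.index[1:])
        em = ExpressionMatrix(wrong, species="human", state="log2")
        with pytest.raises(ValueError, match="WRONG"):
            project_human(em, pca)


class TestVarianceExplained:
    def test_single_pc_fraction_is_one(self):
        rng = np.random.default_rng(11)
        u = rng.standard_normal(50)
        vals = np.outer(u, [0, 1, 2, 3, 4, 5.0])
        aligned, meta = make_aligned(rng, n_genes=50, mouse_values=vals)
        pca = fit_group_pca(aligned, meta, "T2D")
        assert pca.k_retained == 1
        frac = variance_explained_in_human(aligned.human, pca)
        assert frac[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(12)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D")
        frac = variance_explained_in_human(aligned.human, pca)
        assert abs(frac.sum() - 1.0) < 1e-10

    def test_numerators_match_naive_quadratic_form(self):
        rng = np.random.default_rng(13)
        aligned, meta = make_aligned(rng, n_genes=50)
        pca = fit_group_pca(aligned, meta, "T2D")
        frac = variance_explained_in_human(aligned.human, pca)
        X = aligned.human.values.T
        nums = []
        for i in range(pca.k_retained):
            acc = 0.0
            for s in range(X.shape[0]):
                acc += float(X[s] @ pca.loadings[:, i]) ** 2
            nums.append(acc)
        nums = np.asarray(nums)
        assert np.abs(frac - nums / nums.sum()).max() < 1e-9

    def test_invariant_to_sign_flips(self):
        rng = np.random.default_rng(14)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D")
        before = variance_explained_in_human(aligned.human, pca)
        flips = np.ones(pca.k_computed)
        flips[0] = -1
        pca.flip(flips)
        after = variance_explained_in_human(aligned.human, pca)
        assert np.abs(before - after).max() < 1e-12


class TestVarianceTable:
    def test_identical_matrices_give_unit_ratios(self):
        # with the human matrix equal to the centered mouse subgroup and all
        # PCs retained, Eq-style human fractions equal the mouse fractions
        rng = np.random.default_rng(15)
        aligned, meta = make_aligned(rng)
        pca = fit_group_pca(aligned, meta, "T2D", cum_var_threshold=1.0)
        X = aligned.mouse.values.T
        Xc = (X - X.mean(axis=0)).T
        human = ExpressionMatrix(
            pd.DataFrame(Xc, index=pca.human_genes, columns=pca.sample_ids),
            species="human",
            state="log2",
        )
        table = mouse_vs_human_variance_table({"T2D": pca}, human)
        assert np.abs(table["human_to_mouse_ratio"] - 1.0).max() < 1e-8

    def test_row_count_is_sum_of_retained(self, fitted):
        total = sum(p.k_retained for p in fitted.pcas.values())
        assert len(fitted.variance_table) == total

    def test_translatable_factor_dominates_human_fraction(self, fitted, small_sim):
        from transcompr.simulate import match_translatable_pc

        truth = small_sim[4]
        t = fitted.variance_table
        for model in ("T2D", "ADxT2D"):
            pc = match_translatable_pc(fitted.pcas[model], truth)
            sub = t[t["disease_model"] == model].set_index("pc")
            assert sub.loc[pc, "human_var_fraction"] == sub["human_var_fraction"].max()


class TestOrientation:
    def test_flips_make_ad_mean_at_least_control_mean(self, fitted):
        scores = fitted.human_scores
        y = scores.outcome.to_numpy()
        for col in scores.pc_labels:
            v = scores.scores[col].to_numpy()
            assert v[y == 1].mean() >= v[y == 0].mean() - 1e-12

    def test_orientation_recorded(self, fitted):
        for model, flips in fitted.orientation.items():
            assert set(flips) <= {1.0, -1.0}
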