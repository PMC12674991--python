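"""The TransComp-R model object and its fitted results.

``TransCompR`` is constructed from the raw species matrices, their sample
tables and a homolog map; ``fit()`` runs preprocessing, the per-disease
mouse PCAs, human projection, LASSO stability selection under the four
covariate configurations, and the per-PC logistic GLMs, returning a
``TransCompRResults`` that carries every stage's output and offers the
interpretation steps (GSEA, sex-stratified testing, extreme-loading
extraction) as methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gsea import EnrichmentResult, gsea_preranked, rank_by_loading
from .io import ExpressionMatrix, GeneSetCollection, HomologMap
from .pca import (
    DISEASE_MODELS,
    HumanScores,
    PCAModel,
    build_human_scores,
    fit_group_pca,
    mouse_vs_human_variance_table,
    orient_to_human_outcome,
)
from .posthoc import (
    SexStratResult,
    extreme_loading_genes,
    score_ordered_heatmap_matrix,
    sex_stratified_test,
)
from .preprocess import (
    AlignedPair,
    align_homologs,
    filter_human_subjects,
    log2_transform,
    zscore_aligned_pair,
)
from .selection import (
    ALL_COVARIATE_SPECS,
    CovariateSpec,
    glm_table,
    multi_pc_collinearity_check,
    run_lasso_stability,
    select_pcs,
)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


class TransCompR:
    """Translatable components regression across mouse disease models.

    Parameters
    ----------
    mouse, human : ExpressionMatrix
        Gene-by-sample matrices in ``raw`` or ``log2`` state.
    mouse_meta, human_meta : pandas.DataFrame
        Sample tables (``sample_id``, ``condition``, and for humans
        ``sex``, ``age``, ``region``).
    homologs : HomologMap
        One-to-one mouse/human gene pairs defining the shared feature
        space.
    disease_models : sequence of str
        Which mouse cohorts get their own PCA (each with the controls).
    cum_var_threshold : float
        Retain the smallest number of PCs reaching this cumulative
        variance fraction (at most n_samples - 1).
    min_age, region : filters applied to human subjects before modeling;
        pass ``min_age=None`` / ``region=None`` to skip.
    log2_offset : float
        Pseudocount for the log transform of ``raw`` matrices.
    """

    def __init__(
        self,
        mouse: ExpressionMatrix,
        human: ExpressionMatrix,
        mouse_meta: pd.DataFrame,
        human_meta: pd.DataFrame,
        homologs: HomologMap,
        *,
        disease_models: Sequence[str] = DISEASE_MODELS,
        cum_var_threshold: float = 0.80,
        min_age: float | None = 65.0,
        region: str | None = "hippocampus",
        log2_offset: float = 1.0,
    ) -> None:
        self.mouse = mouse
        self.human = human
        self.mouse_meta = mouse_meta
        self.human_meta = human_meta
        self.homologs = homologs
        self.disease_models = tuple(disease_models)
        self.cum_var_threshold = cum_var_threshold
        self.min_age = min_age
        self.region = region
        self.log2_offset = log2_offset

    @classmethod
    def from_files(
        cls,
        mouse_path,
        human_path,
        mouse_meta_path,
        human_meta_path,
        homolog_path,
        **kwargs,
    ) -> "TransCompR":
        from .io import read_expression_matrix, read_homolog_map, read_sample_table

        return cls(
            read_expression_matrix(mouse_path, species="mouse"),
            read_expression_matrix(human_path, species="human"),
            read_sample_table(mouse_meta_path),
            read_sample_table(human_meta_path),
            read_homolog_map(homolog_path),
            **kwargs,
        )

    def _preprocess(self) -> tuple[AlignedPair, pd.DataFrame]:
        mouse = log2_transform(self.mouse, self.log2_offset)
        human = log2_transform(self.human, self.log2_offset)
        human_meta = self.human_meta
        if self.min_age is not None or self.region is not None:
            human, human_meta = filter_human_subjects(
                human,
                human_meta,
                min_age=self.min_age if self.min_age is not None else -np.inf,
                region=self.region,
            )
        pair = align_homologs(mouse, human, self.homologs)
        return zscore_aligned_pair(pair), human_meta

    def fit(
        self,
        rounds: int = 100,
        folds: int = 5,
        seed: int = 0,
        frequency_threshold: float = 50.0,
        covariate_specs: Sequence[CovariateSpec] = ALL_COVARIATE_SPECS,
        penalize_covariates: bool = False,
        glm_alpha: float = 0.05,
        n_lambdas: int = 30,
    ) -> "TransCompRResults":
        """Run preprocessing, PCA, projection, stability selection and GLMs.

        The master seed is split into an independent stream per covariate
        configuration so adding or removing one does not perturb the
        others.  Deterministic for a fixed seed.
        """
        pair, human_meta = self._preprocess()
        pcas = {
            m: fit_group_pca(pair, self.mouse_meta, m, self.cum_var_threshold)
            for m in self.disease_models
        }
        scores = build_human_scores(pcas, pair.human, human_meta)
        oriented, flips = orient_to_human_outcome(pcas, scores.scores, scores.outcome)
        scores = HumanScores(oriented, scores.outcome, scores.sex, scores.age)

        ss = np.random.SeedSequence(seed)
        spec_seeds = {
            spec.name: _child_seed(child)
            for spec, child in zip(covariate_specs, ss.spawn(len(covariate_specs)))
        }
        freqs = {
            spec.name: run_lasso_stability(
                scores,
                spec,
                rounds=rounds,
                folds=folds,
                seed=spec_seeds[spec.name],
                n_lambdas=n_lambdas,
                penalize_covariates=penalize_covariates,
            )
            for spec in covariate_specs
        }
        selection = select_pcs(freqs, threshold=frequency_threshold)
        carried = list(selection.index[selection["selected_any"]])
        glms = glm_table(scores, carried) if carried else pd.DataFrame(
            columns=[
                "pc", "covariates", "coef", "se", "wald_p", "model_p",
                "significant", "separation",
            ]
        )
        variance = mouse_vs_human_variance_table(pcas, pair.human)
        collinearity = (
            multi_pc_collinearity_check(scores, carried) if len(carried) >= 2 else None
        )
        return TransCompRResults(
            model=self,
            aligned=pair,
            human_meta=human_meta,
            pcas=pcas,
            human_scores=scores,
            orientation={m: f.tolist() for m, f in flips.items()},
            frequency_tables=freqs,
            selection=selection,
            glm_results=glms,
            variance_table=variance,
            collinearity=collinearity,
            params={
                "rounds": rounds,
                "folds": folds,
                "seed": seed,
                "spec_seeds": spec_seeds,
                "frequency_threshold": frequency_threshold,
                "cum_var_threshold": self.cum_var_threshold,
                "glm_alpha": glm_alpha,
                "covariate_specs": [s.name for s in covariate_specs],
                "penalize_covariates": penalize_covariates,
            },
        )


@dataclass
class TransCompRResults:
    """Fitted TransComp-R: estimates, diagnostics and interpretation."""

    model: TransCompR
    aligned: AlignedPair
    human_meta: pd.DataFrame
    pcas: dict[str, PCAModel]
    human_scores: HumanScores
    orientation: dict[str, list[float]]
    frequency_tables: dict[str, pd.DataFrame]
    selection: pd.DataFrame
    glm_results: pd.DataFrame
    variance_table: pd.DataFrame
    collinearity: pd.DataFrame | None
    params: dict = field(default_factory=dict)

    @property
    def carried_pcs(self) -> list[str]:
        """PCs whose frequency exceeded the threshold in any covariate model."""
        return list(self.selection.index[self.selection["selected_any"]])

    @property
    def consistent_pcs(self) -> list[str]:
        """PCs selected under every covariate model."""
        return list(self.selection.index[self.selection["consistent"]])

    @property
    def significant_pcs(self) -> list[str]:
        """Carried PCs whose simple (covariate-free) GLM model p < alpha."""
        alpha = self.params.get("glm_alpha", 0.05)
        g = self.glm_results
        if g.empty:
            return []
        simple = g[g["covariates"] == "pcs"]
        return list(simple.loc[simple["model_p"] < alpha, "pc"])

    def _pca_for(self, pc_label: str) -> tuple[PCAModel, int]:
        model, pc = pc_label.rsplit(" PC", 1)
        return self.pcas[model], int(pc)

    def rank_by_loading(self, pc_label: str) -> pd.Series:
        pca, pc = self._pca_for(pc_label)
        return rank_by_loading(pca, pc)

    def gsea(
        self,
        collection: GeneSetCollection,
        pcs: Sequence[str] | None = None,
        nperm: int = 10000,
        seed: int = 0,
        min_size: int = 5,
        max_size: int = 500,
    ) -> dict[str, EnrichmentResult]:
        """Preranked GSEA of each (default: significant) PC's loadings."""
        pcs = list(pcs) if pcs is not None else self.significant_pcs
        ss = np.random.SeedSequence(seed)
        out = {}
        for pc_label, child in zip(pcs, ss.spawn(len(pcs))):
            out[pc_label] = gsea_preranked(
                self.rank_by_loading(pc_label),
                collection,
                nperm=nperm,
                seed=_child_seed(child),
                min_size=min_size,
                max_size=max_size,
            )
        return out

    def sex_stratified(
        self, pcs: Sequence[str] | None = None, alpha: float = 0.05
    ) -> dict[str, SexStratResult]:
        pcs = list(pcs) if pcs is not None else self.significant_pcs
        return {pc: sex_stratified_test(self.human_scores, pc, alpha) for pc in pcs}

    def extreme_genes(self, pc_label: str, k: int = 25) -> tuple[list[str], list[str]]:
        pca, pc = self._pca_for(pc_label)
        return extreme_loading_genes(pca, pc, k)

    def heatmap_matrix(
        self, pc_label: str, k: int = 25
    ) -> tuple[pd.DataFrame, list[str]]:
        top, bottom = self.extreme_genes(pc_label, k)
        return score_ordered_heatmap_matrix(
            self.aligned.human, self.human_scores, pc_label, top + bottom
        )

    def summary(self) -> str:
        """Human-readable account of the fit."""
        lines = []
        w = lines.append
        w("TransComp-R results")
        w("=" * 67)
        n_h = len(self.human_scores.subjects)
        n_ad = int(self.human_scores.outcome.sum())
        w(
            f"Human subjects: {n_h} ({n_ad} AD / {n_h - n_ad} control), "
            f"genes aligned: {len(self.aligned.gene_index)}"
        )
        for m, pca in self.pcas.items():
            cum = float(np.cumsum(pca.var_fraction)[pca.k_retained - 1])
            w(
                f"  {m:>7} cohort: n={len(pca.sample_ids)}, retained "
                f"{pca.k_retained} PCs ({cum:.1%} cumulative variance)"
            )
        thr = self.params.get("frequency_threshold", 50.0)
        w(f"LASSO stability (selected if frequency > {thr:g} of 100):")
        freq_cols = [c for c in self.selection.columns if c.startswith("freq_")]
        shown = self.selection[self.selection["selected_any"]]
        if shown.empty:
            w("  no PC exceeded the selection threshold")
        for pc, row in shown.iterrows():
            marks = ", ".join(
                f"{c[5:]}={row[c]:.0f}" for c in freq_cols
            )
            tag = "consistent" if row["consistent"] else f"{row['n_models_selected']}/4 models"
            w(f"  {pc}: {marks} [{tag}]")
        if not self.glm_results.empty:
            w("Per-PC GLM (simple model; LRT p vs intercept-only):")
            simple = self.glm_results[self.glm_results["covariates"] == "pcs"]
            for _, r in simple.iterrows():
                star = " *" if r["significant"] else ""
                w(
                    f"  {r['pc']}: coef={r['coef']:+.4f} (se {r['se']:.4f}), "
                    f"model p={r['model_p']:.4g}{star}"
                )
        sig = self.significant_pcs
        w(f"Translatable PCs (GLM p < {self.params.get('glm_alpha', 0.05)}): "
          + (", ".join(sig) if sig else "none"))
        return "\n".join(lines)
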