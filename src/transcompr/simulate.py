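"""Paired mouse/human synthetic transcriptomes with planted cross-species
structure.

Expression is a log-scale Gaussian factor model, X = S W + mu + eps.  The
two species share the factor loadings over homolog-paired genes, so a
latent factor is a direction that exists in both transcriptomes.  Disease
enters as factor-score shifts:

* T2D and ADxT2D mice are shifted on the *translatable* factor, which
  also separates human AD from control (with sex-specific human effect
  sizes, so a female-only human effect is expressible);
* AD-model mice are shifted on a different factor that humans do not
  express (their scores on it are zero), so components from the AD-only
  mice do not predict human disease — the motivating structure in which
  the metabolic models, not the AD model, translate.

The translatable factor is quiescent in mice unless disease drives it
(baseline mouse score sd ``mouse_translatable_baseline_sd``, small): an
axis perturbed by the metabolic insult, not ordinary mouse-to-mouse
variability.  Without this, every cohort's PCA — including the AD-only
cohort's — would capture the human-outcome-linked direction as background
variance and all three models would translate.

A planted gene set carries boosted positive loadings on the translatable
factor, giving GSEA a known enrichment target; decoy sets are random draws
from the gene universe.  Mice are all male, as in typical amyloid knock-in
cohorts; the human cohort mirrors a post-filter hippocampal series
(24 control / 18 AD, roughly sex-balanced, ages 65-95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection
from .pca import PCAModel

MOUSE_DISEASES = ("AD", "T2D", "ADxT2D")


@dataclass
class SimConfig:
    """Generator parameters; defaults state the emulated study design."""

    n_genes: int = 2000
    n_mouse_per_condition: int = 3
    n_human_control: int = 24
    n_human_ad: int = 18
    n_latent_factors: int = 4
    translatable_factor: int = 0
    mouse_ad_factor: int = 1
    delta_mouse: float = 3.0
    delta_female: float = 2.0
    delta_male: float = 2.0
    loading_sparsity: float = 0.2
    planted_set_size: int = 50
    planted_boost: float = 3.0
    n_decoy_sets: int = 19
    noise_sd: float = 1.0
    mouse_translatable_baseline_sd: float = 0.2
    baseline_mean: float = 7.0
    frac_female_control: float = 11 / 24
    frac_female_ad: float = 9 / 18
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_mouse_per_condition, self.n_human_control, self.n_human_ad
        ) < 2:
            raise ValueError("all cohort sizes must be at least 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.loading_sparsity < 1:
            raise ValueError("loading_sparsity must lie in (0, 1)")
        if self.planted_set_size > self.n_genes:
            raise ValueError("planted set does not fit within n_genes")
        if self.n_latent_factors < 2:
            raise ValueError("need at least two latent factors")
        for f in (self.translatable_factor, self.mouse_ad_factor):
            if not 0 <= f < self.n_latent_factors:
                raise ValueError(f"factor index {f} out of range")
        if self.translatable_factor == self.mouse_ad_factor:
            raise ValueError("translatable and AD-only factors must differ")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    config: SimConfig
    loadings: np.ndarray           # n_factors x n_genes, shared across species
    mouse_factor_scores: pd.DataFrame
    human_factor_scores: pd.DataFrame
    planted_genes_human: list[str]
    planted_genes_mouse: list[str]
    gene_sets: GeneSetCollection = field(repr=False, default=None)
    planted_set_name: str = "PLANTED_TRANSLATABLE"

    def __post_init__(self) -> None:
        if self.loadings.shape != (self.config.n_latent_factors, self.config.n_genes):
            raise ValueError("loading matrix dimensions inconsistent with config")


def _mouse_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    ids, conds = [], []
    for cond in ("control",) + MOUSE_DISEASES:
        for i in range(cfg.n_mouse_per_condition):
            ids.append(f"mouse_{cond}_{i + 1}")
            conds.append(cond)
    return ids, conds


def generate_paired_datasets(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw one paired dataset; bitwise deterministic for a fixed seed.

    Returns ``(mouse_expr, mouse_meta, human_expr, human_meta, truth)``.
    Matrices are produced in the ``log2`` state (the factor model lives on
    log scale), so preprocessing skips the log transform.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mouse_genes = [f"m_gene{i:05d}" for i in range(cfg.n_genes)]
    human_genes = [f"H_GENE{i:05d}" for i in range(cfg.n_genes)]

    # sparse shared loadings; the planted set gets strong positive loadings
    # on the translatable factor so its members crowd one end of the ranking
    W = rng.standard_normal((cfg.n_latent_factors, cfg.n_genes))
    W *= rng.random((cfg.n_latent_factors, cfg.n_genes)) < cfg.loading_sparsity
    planted_idx = rng.choice(cfg.n_genes, size=cfg.planted_set_size, replace=False)
    W[cfg.translatable_factor, planted_idx] = cfg.planted_boost * np.abs(
        rng.standard_normal(cfg.planted_set_size)
    )

    mouse_ids, mouse_conds = _mouse_ids(cfg)
    S_m = rng.standard_normal((len(mouse_ids), cfg.n_latent_factors))
    S_m[:, cfg.translatable_factor] *= cfg.mouse_translatable_baseline_sd
    conds = np.asarray(mouse_conds)
    S_m[np.isin(conds, ["T2D", "ADxT2D"]), cfg.translatable_factor] += cfg.delta_mouse
    S_m[conds == "AD", cfg.mouse_ad_factor] += cfg.delta_mouse

    n_h = cfg.n_human_control + cfg.n_human_ad
    human_ids = [f"subj_{i + 1:03d}" for i in range(n_h)]
    human_cond = ["control"] * cfg.n_human_control + ["AD"] * cfg.n_human_ad
    n_f_ctl = int(round(cfg.frac_female_control * cfg.n_human_control))
    n_f_ad = int(round(cfg.frac_female_ad * cfg.n_human_ad))
    sexes = (
        ["F"] * n_f_ctl
        + ["M"] * (cfg.n_human_control - n_f_ctl)
        + ["F"] * n_f_ad
        + ["M"] * (cfg.n_human_ad - n_f_ad)
    )
    ages = rng.uniform(65.0, 95.0, size=n_h)
    S_h = rng.standard_normal((n_h, cfg.n_latent_factors))
    S_h[:, cfg.mouse_ad_factor] = 0.0  # the AD-mouse factor is absent from humans
    is_ad = np.asarray(human_cond) == "AD"
    is_f = np.asarray(sexes) == "F"
    S_h[is_ad & is_f, cfg.translatable_factor] += cfg.delta_female
    S_h[is_ad & ~is_f, cfg.translatable_factor] += cfg.delta_male

    baseline = cfg.baseline_mean + rng.standard_normal(cfg.n_genes)
    X_m = S_m @ W + baseline + cfg.noise_sd * rng.standard_normal(
        (len(mouse_ids), cfg.n_genes)
    )
    X_h = S_h @ W + baseline + cfg.noise_sd * rng.standard_normal((n_h, cfg.n_genes))

    mouse_expr = ExpressionMatrix(
        pd.DataFrame(X_m.T, index=mouse_genes, columns=mouse_ids),
        species="mouse",
        state="log2",
    )
    human_expr = ExpressionMatrix(
        pd.DataFrame(X_h.T, index=human_genes, columns=human_ids),
        species="human",
        state="log2",
    )
    mouse_meta = pd.DataFrame(
        {
            "sample_id": mouse_ids,
            "condition": mouse_conds,
            "sex": "M",
            "age": np.nan,
            "region": "hippocampus",
        }
    ).set_index("sample_id", drop=False)
    human_meta = pd.DataFrame(
        {
            "sample_id": human_ids,
            "condition": human_cond,
            "sex": sexes,
            "age": ages,
            "region": "hippocampus",
        }
    ).set_index("sample_id", drop=False)

    planted_h = sorted(human_genes[i] for i in planted_idx)
    sets = {"PLANTED_TRANSLATABLE": planted_h}
    for d in range(cfg.n_decoy_sets):
        decoy_idx = rng.choice(cfg.n_genes, size=cfg.planted_set_size, replace=False)
        sets[f"DECOY_{d + 1:02d}"] = sorted(human_genes[i] for i in decoy_idx)
    collection = GeneSetCollection(sets, source="synthetic")

    factor_cols = [f"factor_{k}" for k in range(cfg.n_latent_factors)]
    truth = SyntheticTruth(
        config=cfg,
        loadings=W,
        mouse_factor_scores=pd.DataFrame(S_m, index=mouse_ids, columns=factor_cols),
        human_factor_scores=pd.DataFrame(S_h, index=human_ids, columns=factor_cols),
        planted_genes_human=planted_h,
        planted_genes_mouse=sorted(mouse_genes[i] for i in planted_idx),
        gene_sets=collection,
    )
    return mouse_expr, mouse_meta, human_expr, human_meta, truth


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Which (disease model, factor) signals the pipeline should recover.

    One row per mouse disease model: the factor its mice are shifted on,
    whether that factor carries a human outcome effect ("translatable"),
    whether the human effect is female-only, and the gene set expected to
    enrich on the translatable factor.
    """
    cfg = truth.config
    rows = []
    for model in MOUSE_DISEASES:
        factor = (
            cfg.mouse_ad_factor if model == "AD" else cfg.translatable_factor
        )
        on_translatable = factor == cfg.translatable_factor
        human_effect = on_translatable and (cfg.delta_female != 0 or cfg.delta_male != 0)
        rows.append(
            {
                "disease_model": model,
                "shifted_factor": factor,
                "translatable": bool(human_effect and cfg.delta_mouse != 0),
                "female_only": bool(
                    human_effect and cfg.delta_female != 0 and cfg.delta_male == 0
                ),
                "expected_gene_set": truth.planted_set_name if on_translatable else "",
            }
        )
    return pd.DataFrame(rows)


def match_translatable_pc(pca: PCAModel, truth: SyntheticTruth, factor: int | None = None) -> int:
    """1-based retained-PC index best aligned with a true factor's loadings.

    Alignment is |Pearson correlation| between the PC loading vector and
    the factor's generative loadings restricted to the PCA's gene index.
    """
    if factor is None:
        factor = truth.config.translatable_factor
    gene_pos = {g: i for i, g in enumerate(
        [f"H_GENE{i:05d}" for i in range(truth.config.n_genes)]
    )}
    idx = [gene_pos[g] for g in pca.human_genes]
    w = truth.loadings[factor, idx]
    best, best_r = 1, -1.0
    for i in range(pca.k_retained):
        q = pca.loadings[:, i]
        r = abs(float(np.corrcoef(q, w)[0, 1]))
        if r > best_r:
            best, best_r = i + 1, r
    return best
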