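"""Per-disease-cohort PCA, human projection and variance explained in human.

One PCA is fitted per mouse disease model on that model's mice together
with the control mice.  Human subjects are then projected into each mouse
PC space (after subtracting the mouse subgroup's per-gene center, so that
projecting the mouse subgroup itself reproduces its PCA scores exactly).
The variance a mouse PC explains in the *human* data is the quadratic form

    f_i = (q_i' X' X q_i) / sum_j diag(Q' X' X Q)_jj

with X the human samples-by-genes matrix and Q the retained loadings; the
fractions are relative to the retained set and sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .preprocess import AlignedPair

DISEASE_MODELS = ("AD", "T2D", "ADxT2D")


@dataclass
class PCAModel:
    """PCA of one mouse disease cohort (disease + control mice).

    ``loadings`` has unit-norm orthonormal columns over the aligned gene
    index; ``mouse_scores`` are the cohort sample coordinates; ``center``
    is the per-gene mean subtracted before decomposition.  ``k_retained``
    is the smallest k whose cumulative variance fraction reaches the
    threshold, never more than n_samples - 1.
    """

    disease_model: str
    mouse_genes: list[str]
    human_genes: list[str]
    sample_ids: list[str]
    loadings: np.ndarray          # genes x k_computed
    mouse_scores: np.ndarray      # samples x k_computed
    center: np.ndarray            # per-gene means over the subgroup
    var_fraction: np.ndarray      # per-PC fraction of subgroup variance
    k_retained: int
    cum_var_threshold: float = 0.80
    orientation: np.ndarray = field(default=None)  # +1/-1 per computed PC

    def __post_init__(self) -> None:
        if self.orientation is None:
            self.orientation = np.ones(self.loadings.shape[1])
        g = np.asarray(self.loadings)
        gram = g.T @ g
        if not np.allclose(gram, np.eye(g.shape[1]), atol=1e-8):
            raise ValueError("loading columns are not orthonormal")
        if np.any(np.diff(self.var_fraction) > 1e-12):
            raise ValueError("variance fractions must be nonincreasing")
        if self.var_fraction.sum() > 1 + 1e-8:
            raise ValueError("variance fractions sum above 1")

    @property
    def k_computed(self) -> int:
        return self.loadings.shape[1]

    @property
    def retained_loadings(self) -> np.ndarray:
        return self.loadings[:, : self.k_retained]

    def pc_labels(self, retained_only: bool = True) -> list[str]:
        k = self.k_retained if retained_only else self.k_computed
        return [f"{self.disease_model} PC{i + 1}" for i in range(k)]

    def flip(self, flips: np.ndarray) -> None:
        """Apply per-PC sign flips (+1/-1) to loadings and scores in place."""
        flips = np.asarray(flips, dtype=float)
        self.loadings = self.loadings * flips
        self.mouse_scores = self.mouse_scores * flips
        self.orientation = self.orientation * flips


@dataclass
class HumanScores:
    """Human subjects' coordinates in the mouse PC spaces, with covariates.

    ``scores`` columns are labelled ``"<model> PC<i>"`` across all disease
    models; ``outcome`` is 0 (control) / 1 (AD).  Sex/age may be unknown
    for individual subjects but every subject must have an outcome.
    """

    scores: pd.DataFrame
    outcome: pd.Series
    sex: pd.Series
    age: pd.Series

    def __post_init__(self) -> None:
        idx = self.scores.index
        for s in (self.outcome, self.sex, self.age):
            if not idx.equals(s.index):
                raise ValueError("covariate index does not match score index")
        if self.outcome.isna().any():
            raise ValueError("missing outcome for some subjects")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be coded 0 (control) / 1 (AD)")

    @property
    def subjects(self) -> list[str]:
        return list(self.scores.index)

    @property
    def pc_labels(self) -> list[str]:
        return list(self.scores.columns)


def build_human_scores(
    pcas: dict[str, PCAModel],
    human: ExpressionMatrix,
    meta: pd.DataFrame,
) -> HumanScores:
    """Project humans into every fitted mouse PC space and attach covariates."""
    cols = [project_human(human, pca) for pca in pcas.values()]
    scores = pd.concat(cols, axis=1)
    meta = meta.loc[scores.index]
    bad = sorted(set(meta["condition"]) - {"control", "AD"})
    if bad:
        raise ValueError(f"human conditions must be control/AD, found {bad}")
    outcome = (meta["condition"] == "AD").astype(int)
    return HumanScores(
        scores=scores,
        outcome=outcome,
        sex=meta["sex"],
        age=meta["age"].astype(float),
    )


def fit_group_pca(
    aligned: AlignedPair,
    meta: pd.DataFrame,
    disease_model: str,
    cum_var_threshold: float = 0.80,
) -> PCAModel:
    """Fit the PCA for one disease model's mice plus controls.

    The subgroup matrix is re-centered per gene before singular value
    decomposition (the full-cohort z-scoring leaves subgroup means
    nonzero).  With n subgroup samples at most n-1 PCs carry variance.
    """
    if disease_model not in DISEASE_MODELS:
        raise ValueError(f"unknown disease model {disease_model!r}")
    cond = meta["condition"]
    wanted = meta.index[(cond == disease_model) | (cond == "control")]
    sample_ids = [s for s in aligned.mouse.samples if s in set(wanted)]
    n_dis = int((meta.loc[sample_ids, "condition"] == disease_model).sum())
    n_ctl = len(sample_ids) - n_dis
    if n_dis < 2 or n_ctl < 2:
        raise ValueError(
            f"disease model {disease_model!r}: need >=2 disease and >=2 control "
            f"mice, found {n_dis} and {n_ctl}"
        )
    sub = aligned.mouse.subset_samples(sample_ids)
    X = sub.values.T  # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(len(sample_ids) - 1, Xc.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    var = s**2
    var_fraction = var / var.sum()
    cum = np.cumsum(var_fraction)
    k_retained = int(np.searchsorted(cum, cum_var_threshold - 1e-12) + 1)
    k_retained = min(k_retained, k)
    return PCAModel(
        disease_model=disease_model,
        mouse_genes=list(aligned.mouse.genes),
        human_genes=list(aligned.human.genes),
        sample_ids=sample_ids,
        loadings=Vt.T,
        mouse_scores=U * s,
        center=center,
        var_fraction=var_fraction,
        k_retained=k_retained,
        cum_var_threshold=cum_var_threshold,
    )


def project_human(human: ExpressionMatrix, pca: PCAModel) -> pd.DataFrame:
    """Project human subjects into a mouse PC space.

    Scores are ``(X_h - center) @ Q`` with the mouse subgroup center, one
    column per retained PC, labelled ``"<model> PC<i>"``.  The human gene
    index must equal the PCA's (human-side) gene index exactly.
    """
    if human.genes != pca.human_genes:
        for i, (a, b) in enumerate(zip(human.genes, pca.human_genes)):
            if a != b:
                raise ValueError(
                    f"gene index mismatch at row {i}: {a!r} != {b!r}"
                )
        raise ValueError(
            f"gene index length mismatch: {len(human.genes)} != "
            f"{len(pca.human_genes)}"
        )
    X = human.values.T  # subjects x genes
    scores = (X - pca.center) @ pca.retained_loadings
    return pd.DataFrame(scores, index=human.samples, columns=pca.pc_labels())


def variance_explained_in_human(human: ExpressionMatrix, pca: PCAModel) -> np.ndarray:
    """Fraction of human variance along each retained mouse PC.

    Computed as ||X q_i||^2 normalized over the retained set, so the
    fractions sum to one.  Raises if the retained loadings are rank
    deficient.
    """
    if human.genes != pca.human_genes:
        raise ValueError("gene index mismatch between human matrix and PCA")
    Q = pca.retained_loadings
    if np.linalg.matrix_rank(Q) < Q.shape[1]:
        raise ValueError("retained loadings are rank deficient")
    X = human.values.T
    M = X @ Q  # subjects x k
    num = (M**2).sum(axis=0)
    return num / num.sum()


def mouse_vs_human_variance_table(
    pcas: dict[str, PCAModel], human: ExpressionMatrix
) -> pd.DataFrame:
    """Per (disease model, PC): mouse variance fraction, human fraction, ratio."""
    rows = []
    for model, pca in pcas.items():
        human_frac = variance_explained_in_human(human, pca)
        for i in range(pca.k_retained):
            mouse_frac = float(pca.var_fraction[i])
            rows.append(
                {
                    "disease_model": model,
                    "pc": i + 1,
                    "label": f"{model} PC{i + 1}",
                    "mouse_var_fraction": mouse_frac,
                    "human_var_fraction": float(human_frac[i]),
                    "human_to_mouse_ratio": float(human_frac[i]) / mouse_frac,
                }
            )
    return pd.DataFrame(rows)


def orient_to_human_outcome(
    pcas: dict[str, PCAModel],
    human_scores: pd.DataFrame,
    outcome: pd.Series,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Fix the SVD sign ambiguity against the human outcome.

    Each retained PC is flipped so the mean human AD score is >= the mean
    control score; the flips applied are returned per model so downstream
    output can record the orientation.  This gives "enriched toward AD" a
    fixed meaning for GSEA and plotting; it does not affect selection,
    which is sign-invariant.
    """
    y = outcome.loc[human_scores.index].to_numpy()
    flips_by_model: dict[str, np.ndarray] = {}
    oriented = human_scores.copy()
    for model, pca in pcas.items():
        flips = np.ones(pca.k_computed)
        for i, label in enumerate(pca.pc_labels()):
            col = human_scores[label].to_numpy()
            if col[y == 1].mean() < col[y == 0].mean():
                flips[i] = -1.0
                oriented[label] = -col
        pca.flip(flips)
        flips_by_model[model] = flips
    return oriented, flips_by_model
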