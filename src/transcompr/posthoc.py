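"""Post-hoc interpretation: extreme loading genes, score-ordered expression
matrices, and the sex-by-disease stratified comparison of PC scores.

The stratified comparison splits human subjects into female-AD,
female-control, male-AD and male-control and runs all six pairwise
Mann-Whitney tests per PC, Benjamini-Hochberg adjusted as one family per
PC.  Because stratified groups are small, the U null distribution is
enumerated exactly (over all group assignments of the pooled values, which
handles ties correctly) whenever the smaller group has at most
``EXACT_MAX`` subjects, and the tie-corrected normal approximation is used
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .pca import HumanScores, PCAModel

EXACT_MAX = 8

GROUPS = ("F-AD", "F-control", "M-AD", "M-control")
#: the four biologically framed contrasts (within-sex disease, within-status sex)
HEADLINE_PAIRS = (
    ("F-AD", "F-control"),
    ("M-AD", "M-control"),
    ("F-AD", "M-AD"),
    ("F-control", "M-control"),
)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y: concordant pairs plus half the tied pairs."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mannwhitney_u(x, y, exact_max: int = EXACT_MAX) -> dict:
    """Two-sided Mann-Whitney U test with an exact small-sample path.

    For min(n1, n2) <= ``exact_max`` the null is enumerated over all
    C(n1+n2, n1) assignments of the pooled observations to the first
    group; otherwise scipy's tie-corrected normal approximation (with
    continuity correction) is used.  Returns U (of the first group), the
    two-sided p and the method used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    u_obs = _u_statistic(x, y)
    if min(n1, n2) <= exact_max:
        pooled = np.concatenate([x, y])
        n = n1 + n2
        # rank-based U over assignments: U = sum of group-1 ranks - n1(n1+1)/2
        ranks = stats.rankdata(pooled)
        total = 0
        at_most = 0
        at_least = 0
        offset = n1 * (n1 + 1) / 2.0
        for combo in combinations(range(n), n1):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if u <= u_obs + 1e-9:
                at_most += 1
            if u >= u_obs - 1e-9:
                at_least += 1
        p = min(1.0, 2.0 * min(at_most, at_least) / total)
        method = "exact"
    else:
        _, p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
        p = float(p)
        method = "asymptotic"
    return {"U": u_obs, "p": p, "method": method, "n1": n1, "n2": n2}


def extreme_loading_genes(
    pca: PCAModel, pc: int, k: int = 25
) -> tuple[list[str], list[str]]:
    """Human genes with the k largest and k smallest loadings on a PC.

    Ties broken lexicographically; the two lists are disjoint (requires
    ``2k <= gene count``).
    """
    n = len(pca.human_genes)
    if 2 * k > n:
        raise ValueError(f"k={k} too large for {n} genes")
    if not 1 <= pc <= pca.k_computed:
        raise ValueError(f"PC {pc} out of range 1..{pca.k_computed}")
    vals = pca.loadings[:, pc - 1]
    genes = np.asarray(pca.human_genes, dtype=object)
    desc = np.lexsort((genes, -vals))
    asc = np.lexsort((genes, vals))
    top = list(genes[desc[:k]])
    bottom = list(genes[asc[:k]])
    return top, bottom


def score_ordered_heatmap_matrix(
    human: ExpressionMatrix,
    scores: HumanScores,
    pc: str,
    genes: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Expression submatrix with subjects ordered by ascending PC score.

    Rows follow ``genes`` as given (conventionally top-loading block then
    bottom block); columns run from the most negative to the most positive
    score on ``pc``.  Values are untouched — the output is a pure
    selection/permutation of the input.  Raises on a gene missing from the
    human index.
    """
    missing = [g for g in genes if g not in set(human.genes)]
    if missing:
        raise ValueError(f"genes absent from human matrix: {missing[:5]}")
    col_scores = scores.scores[pc]
    order = list(col_scores.sort_values(kind="stable").index)
    mat = human.data.loc[genes, order]
    return mat, order


@dataclass
class SexStratResult:
    """Six pairwise Mann-Whitney comparisons of one PC across sex x status."""

    pc: str
    table: pd.DataFrame          # one row per pair
    group_summary: pd.DataFrame  # n, mean, IQR per group
    alpha: float = 0.05

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"].fillna(False)]
        return list(zip(sig["group1"], sig["group2"]))


def sex_stratified_test(
    scores: HumanScores, pc: str, alpha: float = 0.05
) -> SexStratResult:
    """All pairwise sex-by-disease comparisons of one PC's scores.

    The BH family is the six pairs within this PC.  A pair with a group of
    fewer than two subjects is reported NA and excluded from the family.
    Group summaries report the mean and interquartile range.
    """
    if pc not in scores.scores.columns:
        raise KeyError(f"unknown PC column {pc!r}")
    vals = scores.scores[pc]
    sex = scores.sex
    outcome = scores.outcome
    groups: dict[str, np.ndarray] = {}
    for label in GROUPS:
        s, cond = label.split("-")
        mask = (sex == s) & (outcome == (1 if cond == "AD" else 0))
        groups[label] = vals[mask].to_numpy()
    summary = pd.DataFrame(
        {
            "group": list(GROUPS),
            "n": [len(groups[g]) for g in GROUPS],
            "mean": [groups[g].mean() if len(groups[g]) else np.nan for g in GROUPS],
            "iqr": [
                float(np.subtract(*np.percentile(groups[g], [75, 25])))
                if len(groups[g])
                else np.nan
                for g in GROUPS
            ],
        }
    )
    rows = []
    for g1, g2 in combinations(GROUPS, 2):
        row = {
            "pc": pc,
            "group1": g1,
            "group2": g2,
            "headline": (g1, g2) in HEADLINE_PAIRS or (g2, g1) in HEADLINE_PAIRS,
        }
        if len(groups[g1]) < 2 or len(groups[g2]) < 2:
            row.update({"U": np.nan, "p": np.nan, "method": "NA"})
        else:
            row.update(mannwhitney_u(groups[g1], groups[g2]))
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    padj = np.full(len(table), np.nan)
    if ok.any():
        padj[ok.to_numpy()] = np.maximum(
            multipletests(table.loc[ok, "p"].to_numpy(), method="fdr_bh")[1],
            table.loc[ok, "p"].to_numpy(),
        )
    table["padj"] = padj
    table["significant"] = pd.array(
        [None if np.isnan(p) else bool(p < alpha) for p in padj], dtype="boolean"
    )
    return SexStratResult(pc=pc, table=table, group_summary=summary, alpha=alpha)
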