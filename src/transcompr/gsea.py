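"""Preranked gene set enrichment analysis on PC loadings.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
running-sum statistic: walking down the ranked list, the sum rises by
|metric|^w (normalized over the set's hits) at each set member and falls
by 1/(N - n_hits) at each non-member; the ES is the signed extremum.  The
null is gene-label permutation — random same-size sets from the universe —
which is the convention for preranked input, where no sample replicates
exist to permute.  NES normalizes by the mean |null ES| of the same sign,
and p-values are one-sided within sign with a +1 pseudocount.  No p-value
floor is applied beyond the permutation resolution 1/(nperm+1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .pca import PCAModel

logger = logging.getLogger(__name__)


def rank_by_loading(pca: PCAModel, pc: int) -> pd.Series:
    """Human-gene loadings of PC ``pc`` (1-based), sorted for GSEA.

    Descending by loading; ties broken by gene id lexicographically so the
    ranking is deterministic.  Uses the model's stored orientation, under
    which larger scores mean "toward AD".
    """
    if not 1 <= pc <= pca.k_computed:
        raise ValueError(f"PC {pc} out of range 1..{pca.k_computed}")
    vals = pca.loadings[:, pc - 1]
    genes = np.asarray(pca.human_genes, dtype=object)
    order = np.lexsort((genes, -vals))
    return pd.Series(vals[order], index=genes[order], name=f"{pca.disease_model} PC{pc}")


def _check_ranked(ranked: pd.Series) -> None:
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate gene ids")
    if np.any(np.diff(ranked.to_numpy()) > 1e-12):
        raise ValueError("ranked list is not sorted in descending order")


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and full running sum of one gene set against a ranked list.

    The ES is the signed extremum of the running sum; when the positive
    and negative extrema tie in magnitude the positive one is taken.
    Genes absent from the ranked universe are ignored.  Raises if the
    intersection is empty.
    """
    _check_ranked(ranked)
    hits = ranked.index.isin(set(gene_set))
    n_hits = int(hits.sum())
    N = len(ranked)
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hits == N:
        raise ValueError("gene set covers the whole universe")
    w = np.abs(ranked.to_numpy()) ** weight_exponent
    steps = np.where(hits, w / w[hits].sum(), -1.0 / (N - n_hits))
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(es), running


def leading_edge(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> list[str]:
    """Set members driving the ES extremum ("core enrichment genes").

    For a positive ES: members ranked at or before the running-sum maximum;
    for a negative ES: members at or after the minimum.  Order follows the
    ranked list.
    """
    es, running = enrichment_score(ranked, gene_set, weight_exponent)
    hits = ranked.index.isin(set(gene_set))
    idx = np.flatnonzero(hits)
    if es >= 0:
        cut = int(np.argmax(running))
        keep = idx[idx <= cut]
    else:
        cut = int(np.argmin(running))
        keep = idx[idx >= cut]
    return list(ranked.index[keep])


def _null_es(
    metric_w: np.ndarray, k: int, nperm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``nperm`` random k-gene sets, vectorized over permutations.

    Works from sorted hit positions: with cumulative hit weights c_i and
    miss step d, the running sum just after hit i is c_i - m_i*d and just
    before it is c_{i-1} - m_i*d, where m_i counts misses before the hit;
    all extrema of the running sum occur at these points.
    """
    N = len(metric_w)
    d = 1.0 / (N - k)
    out = np.empty(nperm)
    # chunk the (nperm x N) random-key matrix to bound memory
    chunk = max(1, int(2e7) // N)
    done = 0
    while done < nperm:
        m = min(chunk, nperm - done)
        keys = rng.random((m, N))
        pos = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
        w = metric_w[pos]
        cw = np.cumsum(w, axis=1)
        cw /= cw[:, -1:]
        misses = pos - np.arange(k)[None, :]
        at_hit = cw - misses * d
        before_hit = np.concatenate(
            [np.zeros((m, 1)), cw[:, :-1]], axis=1
        ) - misses * d
        top = at_hit.max(axis=1)
        bot = before_hit.min(axis=1)
        out[done : done + m] = np.where(top >= -bot, top, bot)
        done += m
    return out


@dataclass
class EnrichmentResult:
    """Per-set GSEA statistics for one ranked list against one collection."""

    table: pd.DataFrame
    nperm: int
    seed: int
    min_size: int = 5
    max_size: int = 500
    weight_exponent: float = 1.0
    source: str = ""
    skipped: list[str] = field(default_factory=list)

    def significant(self, fdr: float = 0.25) -> pd.DataFrame:
        return self.table[self.table["padj"] < fdr]


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    nperm: int = 10000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Permutation GSEA of every admissible set in a collection.

    Sets are filtered to ``[min_size, max_size]`` members after
    intersection with the ranked universe; Benjamini-Hochberg adjustment
    is applied across the sets tested in this call (i.e. per collection),
    so run KEGG and Hallmark separately.
    """
    _check_ranked(ranked)
    if nperm < 100:
        warnings.warn(f"nperm={nperm} gives very coarse p-values", stacklevel=2)
    universe = set(ranked.index)
    metric_w = np.abs(ranked.to_numpy()) ** weight_exponent
    rng = np.random.default_rng(seed)
    rows = []
    skipped = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.sets.items():
        inter = [g for g in members if g in universe]
        if not inter:
            logger.info("set %r does not intersect the universe; skipped", name)
            skipped.append(name)
            continue
        k = len(inter)
        if not min_size <= k <= max_size:
            skipped.append(name)
            continue
        es, _ = enrichment_score(ranked, inter, weight_exponent)
        if k not in null_cache:
            null_cache[k] = _null_es(metric_w, k, nperm, rng)
        null = null_cache[k]
        same_sign = null > 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        flag = n_same == 0
        if flag:
            pval = 1.0 / (nperm + 1)
            nes = np.nan
        else:
            pval = (1 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            nes = es / np.abs(null[same_sign]).mean()
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "pval": pval,
                "no_same_sign_null": flag,
                "leading_edge": leading_edge(ranked, inter, weight_exponent),
            }
        )
    if not rows:
        raise ValueError("no gene set passes the size filter")
    table = pd.DataFrame(rows)
    table["padj"] = np.maximum(
        multipletests(table["pval"].to_numpy(), method="fdr_bh")[1],
        table["pval"].to_numpy(),
    )
    table = table[
        ["set", "size", "es", "nes", "pval", "padj", "no_same_sign_null", "leading_edge"]
    ]
    return EnrichmentResult(
        table=table,
        nperm=nperm,
        seed=seed,
        min_size=min_size,
        max_size=max_size,
        weight_exponent=weight_exponent,
        source=sets.source,
        skipped=skipped,
    )


def leading_edge_overlap(edges: dict[str, list[str]]) -> pd.DataFrame:
    """Inclusion-exclusion partition of leading-edge gene lists.

    Given one gene list per label (e.g. per translatable PC), returns one
    row per nonempty label combination with the genes belonging to exactly
    that combination; cell sizes therefore sum to the union size.
    """
    if len(edges) < 2:
        raise ValueError("need at least two leading-edge lists")
    labels = list(edges)
    membership: dict[str, frozenset] = {}
    for lab in labels:
        for g in edges[lab]:
            membership[g] = membership.get(g, frozenset()) | {lab}
    rows: dict[frozenset, list[str]] = {}
    for g, labs in membership.items():
        rows.setdefault(labs, []).append(g)
    out = []
    for labs, genes in rows.items():
        out.append(
            {
                "labels": tuple(sorted(labs, key=labels.index)),
                "n_labels": len(labs),
                "n_genes": len(genes),
                "genes": sorted(genes),
            }
        )
    return (
        pd.DataFrame(out)
        .sort_values(["n_labels", "labels"], ascending=[False, True])
        .reset_index(drop=True)
    )
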