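"""Filtering, normalization and homolog alignment.

The two species' matrices are brought onto a shared, homolog-paired gene
index: human subjects are filtered to the analyzed brain region and an age
floor, both matrices are log2 transformed (if not already on log scale),
rows are restricted to one-to-one homolog pairs present on both sides, and
each gene is z-scored within its own species' matrix.  Z-scoring is
deliberately per species, never pooled: cross-species location/scale
differences are nuisance, not signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, HomologMap

logger = logging.getLogger(__name__)


@dataclass
class AlignedPair:
    """Mouse and human matrices with row *i* of each holding homolog pair *i*."""

    mouse: ExpressionMatrix
    human: ExpressionMatrix
    gene_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        n = len(self.gene_index)
        if self.mouse.shape[0] != n or self.human.shape[0] != n:
            raise ValueError("matrix row counts do not match gene_index length")
        if self.mouse.genes != [m for m, _ in self.gene_index]:
            raise ValueError("mouse row order does not match gene_index")
        if self.human.genes != [h for _, h in self.gene_index]:
            raise ValueError("human row order does not match gene_index")


def filter_human_subjects(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    min_age: float = 65.0,
    region: str | None = "hippocampus",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Retain human samples with age >= ``min_age`` in the given brain region.

    The age boundary is inclusive (subjects *below* the floor are removed).
    Region matching is case-insensitive; pass ``region=None`` to skip the
    region filter.  Samples with missing age are removed.  Sample order is
    preserved.  Raises if no sample survives.
    """
    meta = meta.loc[[s for s in expr.samples if s in meta.index]]
    keep = meta["age"].to_numpy(dtype=float) >= float(min_age)
    if region is not None:
        keep &= meta["region"].str.lower().to_numpy() == region.lower()
    kept_ids = list(meta.index[keep])
    if not kept_ids:
        raise ValueError(
            f"no human samples survive age>={min_age}, region={region!r}"
        )
    n_removed = len(expr.samples) - len(kept_ids)
    if n_removed:
        logger.info("removed %d human samples by age/region filter", n_removed)
    return expr.subset_samples(kept_ids), meta.loc[kept_ids]


def align_homologs(
    mouse_expr: ExpressionMatrix,
    human_expr: ExpressionMatrix,
    hmap: HomologMap,
) -> AlignedPair:
    """Restrict both matrices to homolog pairs present in both gene lists.

    Row ordering follows the homolog map restricted to survivors.  Raises
    if fewer than two gene pairs survive.
    """
    mouse_genes = set(mouse_expr.genes)
    human_genes = set(human_expr.genes)
    pairs = [
        (m, h) for m, h in hmap.pairs if m in mouse_genes and h in human_genes
    ]
    if len(pairs) < 2:
        raise ValueError(
            f"only {len(pairs)} homolog pairs present in both matrices"
        )
    mouse_sub = mouse_expr.subset_genes([m for m, _ in pairs])
    human_sub = human_expr.subset_genes([h for _, h in pairs])
    return AlignedPair(mouse_sub, human_sub, pairs)


def log2_transform(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset) with a configurable pseudocount.

    A no-op (with a log message) when the matrix is already on log scale.
    Raises with coordinates when a shifted value is nonpositive.
    """
    if expr.state == "log2":
        logger.info("matrix already log2; skipping transform")
        return expr
    if expr.state != "raw":
        raise ValueError(f"cannot log2-transform a {expr.state} matrix")
    shifted = expr.values + offset
    if (shifted <= 0).any():
        i, j = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"nonpositive value after offset at gene {expr.genes[i]!r}, "
            f"sample {expr.samples[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(shifted), index=expr.data.index, columns=expr.data.columns
    )
    return ExpressionMatrix(out, species=expr.species, state="log2")


def zscore_per_gene(
    expr: ExpressionMatrix, drop_zero_variance: bool = True
) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sd 1 (sample sd, ddof=1).

    Zero-variance genes are dropped with a logged list (they carry no
    contrast and would divide by zero).  Raises if every gene is
    zero-variance.
    """
    if expr.state != "log2":
        raise ValueError(f"zscore expects a log2 matrix, got state={expr.state!r}")
    vals = expr.values
    means = vals.mean(axis=1, keepdims=True)
    sds = vals.std(axis=1, ddof=1, keepdims=True)
    zero = (sds[:, 0] == 0) | ~np.isfinite(sds[:, 0])
    if zero.all():
        raise ValueError("all genes have zero variance")
    if zero.any():
        if not drop_zero_variance:
            raise ValueError(
                f"{int(zero.sum())} zero-variance genes and drop_zero_variance=False"
            )
        dropped = [g for g, z in zip(expr.genes, zero) if z]
        logger.info("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
    z = (vals[~zero] - means[~zero]) / sds[~zero]
    out = pd.DataFrame(
        z, index=expr.data.index[~zero], columns=expr.data.columns
    )
    return ExpressionMatrix(out, species=expr.species, state="zscored")


def zscore_aligned_pair(pair: AlignedPair) -> AlignedPair:
    """Z-score both species of an aligned pair, keeping rows paired.

    A gene dropped for zero variance in one species takes its homolog
    partner with it, so row *i* still means pair *i* afterwards.
    """
    mouse_z = zscore_per_gene(pair.mouse)
    human_z = zscore_per_gene(pair.human)
    kept_m = set(mouse_z.genes)
    kept_h = set(human_z.genes)
    pairs = [(m, h) for m, h in pair.gene_index if m in kept_m and h in kept_h]
    if len(pairs) < 2:
        raise ValueError("fewer than two gene pairs survive z-scoring")
    return AlignedPair(
        mouse_z.subset_genes([m for m, _ in pairs]),
        human_z.subset_genes([h for _, h in pairs]),
        pairs,
    )
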