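"""Readers, writers and shared domain types.

All tabular interchange is tab-separated UTF-8.  Gene identifiers are
treated as opaque strings: no symbol normalization or ortholog-database
lookup is attempted, which keeps the pipeline accession-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOUSE_CONDITIONS = ("control", "AD", "T2D", "ADxT2D")
HUMAN_CONDITIONS = ("control", "AD")
STATES = ("raw", "log2", "zscored")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression table.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns.
    species : str
        ``"mouse"`` or ``"human"``.
    state : str
        Processing state: ``"raw"``, ``"log2"`` or ``"zscored"``.
    """

    data: pd.DataFrame
    species: str
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        self.validate()

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier {dup!r}")
        if self.state == "zscored":
            vals = self.data.to_numpy()
            means = vals.mean(axis=1)
            sds = vals.std(axis=1, ddof=1)
            if np.abs(means).max(initial=0.0) > 1e-8:
                raise ValueError("state=zscored but some gene mean exceeds 1e-8")
            if np.abs(sds - 1.0).max(initial=0.0) > 1e-6:
                raise ValueError("state=zscored but some gene sd deviates from 1")

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        em = ExpressionMatrix.__new__(ExpressionMatrix)
        em.data = self.data[list(samples)]
        em.species = self.species
        em.state = self.state
        return em

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        em = ExpressionMatrix.__new__(ExpressionMatrix)
        em.data = self.data.loc[list(genes)]
        em.species = self.species
        em.state = self.state
        return em


@dataclass
class HomologMap:
    """One-to-one mouse/human homolog pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        mouse = [m for m, _ in self.pairs]
        human = [h for _, h in self.pairs]
        if len(set(mouse)) != len(mouse) or len(set(human)) != len(human):
            raise ValueError("homolog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mouse_genes(self) -> list[str]:
        return [m for m, _ in self.pairs]

    @property
    def human_genes(self) -> list[str]:
        return [h for _, h in self.pairs]


@dataclass
class GeneSetCollection:
    """Named gene sets (human gene identifiers), e.g. KEGG or Hallmark."""

    sets: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                # deduplicate preserving order
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)


def read_expression_matrix(path, species: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header = samples).

    Raises on duplicate gene ids (naming the gene) and on non-numeric body
    cells (naming the coordinates).  Row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    try:
        numeric = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at gene {gene!r}, "
                        f"sample {sample!r} in {path}"
                    ) from None
        raise
    return ExpressionMatrix(numeric, species=species, state="raw")


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample metadata table.

    Required columns: ``sample_id``, ``condition``.  Optional ``sex``
    (``F``/``M``/``unknown``), ``age`` (years) and ``region`` are filled
    with ``unknown``/NaN when absent.  Condition strings are validated
    against the allowed vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValueError(f"sample table {path} lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in {path}")
    bad = sorted(set(df["condition"]) - set(MOUSE_CONDITIONS))
    if bad:
        raise ValueError(
            f"unknown condition value(s) {bad} in {path}; "
            f"allowed: {list(MOUSE_CONDITIONS)}"
        )
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    df["sex"] = df["sex"].fillna("unknown")
    if "age" not in df.columns:
        df["age"] = np.nan
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if "region" not in df.columns:
        df["region"] = "unknown"
    df["region"] = df["region"].fillna("unknown")
    return df.set_index("sample_id", drop=False)


def write_sample_table(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_homolog_map(path) -> HomologMap:
    """Read a two-column (mouse_gene, human_gene) TSV.

    Rows violating one-to-one-ness are dropped entirely — when a gene on
    either side occurs in several rows, *all* of its rows go, since keeping
    a representative would silently pick an ortholog the data cannot
    justify.  The number of dropped rows is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"homolog map {path} needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["mouse_gene", "human_gene"]
    keep = (~df["mouse_gene"].duplicated(keep=False)) & (
        ~df["human_gene"].duplicated(keep=False)
    )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d homolog rows violating one-to-one mapping", n_dropped)
    df = df[keep]
    if df.empty:
        raise ValueError(f"homolog map {path} empty after one-to-one filtering")
    return HomologMap(list(df.itertuples(index=False, name=None)))


def write_homolog_map(hmap: HomologMap, path) -> None:
    pd.DataFrame(hmap.pairs, columns=["mouse_gene", "human_gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a standard GMT file: name, description, members... per line.

    Duplicate members within a set are deduplicated; empty sets dropped;
    a line with fewer than three fields is a hard error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *members = fields
            members = [m for m in dict.fromkeys(members) if m]
            if not members:
                continue
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, source=source or str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
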