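"""Reading, writing and pre-filtering of expression matrices, trait tables
and gene sets.

All tabular interchange is tab-delimited UTF-8 with a header row. Gene and
sample identifiers are case-preserved and matched case-sensitively.
Expression values are assumed already normalized and on the log2 scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("coexmod")

# Stable warning codes used across the package (logged, never raised).
W_DROPPED_MISSING_ROWS = "W101"   # rows dropped for excess missingness
W_UNMAPPED_PROBES = "W102"        # probes without a gene mapping dropped
W_ALL_CONSTANT = "W103"           # variance filter on an all-constant matrix
W_DUPLICATE_SET_GENES = "W104"    # duplicate genes inside a GMT set


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression.

    Parameters
    ----------
    data
        DataFrame indexed by gene ID with sample IDs as columns. Missing
        values are allowed up to ``1 - min_present_frac`` per row.
    metadata
        Optional key -> value strings (e.g. GEO series-matrix header lines).
    min_present_frac
        Minimum fraction of non-missing values required per gene row.
    """

    data: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)
    min_present_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise DataValidationError(f"duplicate gene IDs: {dups}")
        if self.data.columns.duplicated().any():
            dups = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise DataValidationError(f"duplicate sample IDs: {dups}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 3:
            raise DataValidationError(
                f"need at least 2 genes and 3 samples, got {self.data.shape}"
            )
        vals = self.data.to_numpy(dtype=float)
        present = 1.0 - np.isnan(vals).mean(axis=1)
        bad = present < self.min_present_frac
        if bad.any():
            logger.warning(
                "%s dropping %d/%d gene rows with < %.0f%% present values",
                W_DROPPED_MISSING_ROWS, int(bad.sum()), len(bad),
                100 * self.min_present_frac,
            )
            self.data = self.data.loc[~bad]
            if self.data.shape[0] < 2:
                raise DataValidationError("fewer than 2 genes after missingness filter")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[genes].copy(), dict(self.metadata),
                                self.min_present_frac)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[samples].copy(), dict(self.metadata),
                                self.min_present_frac)


@dataclass
class TraitTable:
    """Per-sample traits: binary {0,1}, categorical (e.g. donor pair) or
    continuous (e.g. log2 expression of an anchor gene used as a trait)."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise DataValidationError("duplicate sample IDs in trait table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def check_against(self, expr: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(expr.sample_ids)
        if missing:
            raise DataValidationError(
                f"trait samples absent from expression matrix: {sorted(missing)}"
            )

    def binary(self, name: str) -> pd.Series:
        col = self.data[name]
        vals = set(pd.unique(col.dropna()))
        if not vals <= {0, 1, 0.0, 1.0}:
            raise DataValidationError(f"trait {name!r} is not coded {{0,1}}: {vals}")
        return col.astype(int)


@dataclass
class GeneSetCollection:
    """Named gene sets (membership lists) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise DataValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _validate_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    # coercion NaN where source was non-missing = non-numeric cell
    src_missing = df.isna() | df.astype(str).isin(["", "NA", "NaN", "nan", "null"])
    bad = out.isna() & ~src_missing
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return out


def read_expression(path: str, dialect: str = "tsv",
                    min_present_frac: float = 0.8) -> ExpressionMatrix:
    """Read an expression matrix from a TSV file or a GEO series-matrix file.

    The ``tsv`` dialect expects a header row of sample IDs with the first
    column holding gene IDs. The ``geo_series_matrix`` dialect treats lines
    beginning with ``!`` as key/value metadata and reads the table between
    the series-matrix begin/end markers; metadata is kept on the returned
    object.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        meta: dict[str, str] = {}
    elif dialect == "geo_series_matrix":
        meta = {}
        rows: list[list[str]] = []
        in_table = False
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("!series_matrix_table_begin"):
                    in_table = True
                    continue
                if line.startswith("!series_matrix_table_end"):
                    in_table = False
                    continue
                if line.startswith("!"):
                    parts = line[1:].split("\t", 1)
                    key = parts[0]
                    val = parts[1].strip().strip('"') if len(parts) > 1 else ""
                    meta[key] = val
                    continue
                if in_table and line:
                    rows.append([f.strip().strip('"') for f in line.split("\t")])
        if not rows:
            raise DataValidationError(f"{path}: no series-matrix table found")
        header, *body = rows
        df = pd.DataFrame(body, columns=header).set_index(header[0])
        df.index.name = "gene_id"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataValidationError(f"{path}: empty expression table")
    df.index = df.index.astype(str)
    df = _validate_numeric(df, path)
    return ExpressionMatrix(df, metadata=meta, min_present_frac=min_present_frac)


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    """Write an expression TSV (10 significant digits, round-trip safe)."""
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_traits(path: str) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df)


def write_traits(traits: TraitTable, path: str) -> None:
    df = traits.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...``."""
    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            dedup = list(dict.fromkeys(genes))
            if len(dedup) < len(genes):
                logger.warning("%s gene set %r lists %d duplicate gene(s)",
                               W_DUPLICATE_SET_GENES, name, len(genes) - len(dedup))
            if name in sets:
                raise DataValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = dedup
            descs[name] = desc
    if n_lines == 0:
        raise DataValidationError(f"{path}: empty GMT file")
    return GeneSetCollection(sets, descs)


def write_gmt(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Probe collapse and variance filter
# ---------------------------------------------------------------------------

def collapse_probes(expr: ExpressionMatrix, probe2gene: dict[str, str],
                    rule: str = "max_mean") -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    For genes with several probes, keeps the probe with the largest row mean
    (``max_mean``) or the largest row variance (``max_variance``). Probes
    with no mapping are dropped (count logged).
    """
    if not probe2gene:
        raise DataValidationError("empty probe-to-gene mapping")
    if rule not in ("max_mean", "max_variance"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    probes = expr.data.index
    mapped = [p for p in probes if p in probe2gene]
    n_dropped = len(probes) - len(mapped)
    if n_dropped:
        logger.warning("%s dropped %d unmapped probe(s)", W_UNMAPPED_PROBES, n_dropped)
    sub = expr.data.loc[mapped]
    if rule == "max_mean":
        score = sub.mean(axis=1, skipna=True)
    else:
        score = sub.var(axis=1, ddof=1, skipna=True)
    genes = pd.Series([probe2gene[p] for p in mapped], index=sub.index)
    # pick, per gene, the probe with max score; stable tie-break by probe ID
    order = pd.DataFrame({"gene": genes, "score": score}).sort_index()
    best = order.sort_values(["gene", "score"], ascending=[True, False],
                             kind="stable").drop_duplicates("gene")
    out = sub.loc[best.index].copy()
    out.index = [probe2gene[p] for p in best.index]
    out = out.sort_index()
    return ExpressionMatrix(out, dict(expr.metadata), expr.min_present_frac)


def filter_top_variable(expr: ExpressionMatrix, fraction: float = 0.2,
                        metric: str = "variance") -> ExpressionMatrix:
    """Keep the ``ceil(fraction * n_genes)`` most variable gene rows.

    Ties are broken deterministically by gene ID (lexicographic); surviving
    genes keep their original row order.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if metric == "variance":
        score = expr.data.var(axis=1, ddof=1, skipna=True)
    elif metric == "mad":
        med = expr.data.median(axis=1, skipna=True)
        score = (expr.data.sub(med, axis=0)).abs().median(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n_keep = math.ceil(fraction * expr.n_genes)
    if float(score.max() - score.min()) == 0.0 and fraction < 1:
        logger.warning("%s all rows have identical %s; ties broken by gene ID",
                       W_ALL_CONSTANT, metric)
    ranking = pd.DataFrame({"score": score, "gene": score.index})
    ranking = ranking.sort_values(["score", "gene"], ascending=[False, True],
                                  kind="stable")
    keep = set(ranking.index[:n_keep])
    out = expr.data.loc[[g for g in expr.gene_ids if g in keep]].copy()
    return ExpressionMatrix(out, dict(expr.metadata), expr.min_present_frac)
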