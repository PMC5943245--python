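"""Expression-matrix input/output and gene-set handling.

The universal in-memory container is :class:`ExpressionMatrix`: a genes x
samples table of log-scale expression values with an attached sample ->
cohort map.  Values may be missing (NaN); downstream correlation code works
on pairwise-complete observations.  Gene symbols are case-normalized to
uppercase on ingest because public cohort tables are inconsistent about
symbol case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_NA_TOKENS = {"", "na", "n/a", "nan", "null", "none", "."}


@dataclass
class GeneSet:
    """An ordered, duplicate-free list of gene symbols."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [g.upper() for g in self.genes]
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        dupes = _duplicates(self.genes)
        if dupes:
            raise ValueError(f"gene set {self.name!r} has duplicate symbols: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in set(self.genes)


@dataclass
class ExpressionMatrix:
    """Log-scale gene x sample expression values with cohort labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol (rows) and sample id (columns).
        Missing observations are NaN.
    cohort_of
        Map sample id -> cohort label (e.g. ``"healthy"``, ``"TNBC"``).
        Samples absent from the map are simply unlabelled.
    scale_note
        Free text recording the transform applied (e.g. ``"log2(x+1)"``).
    log_base
        Base of the log scale of ``values`` (used to de-log medians into
        linear-scale fold changes); ``None`` if the scale is unknown/linear.
    """

    values: pd.DataFrame
    cohort_of: dict[str, str] = field(default_factory=dict)
    scale_note: str = "unspecified"
    log_base: float | None = 2.0

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.upper()
        self.values.index.name = "gene"
        self.values.columns = self.values.columns.astype(str)
        dupes = _duplicates(list(self.values.index))
        if dupes:
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        dupes = _duplicates(list(self.values.columns))
        if dupes:
            raise ValueError(f"duplicate sample identifiers: {dupes}")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_in(self, cohort: str) -> list[str]:
        """Sample ids labelled with ``cohort``, in matrix column order."""
        return [s for s in self.sample_ids if self.cohort_of.get(s) == cohort]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(
            self.values[list(sample_ids)].copy(),
            {s: c for s, c in self.cohort_of.items() if s in set(sample_ids)},
            self.scale_note,
            self.log_base,
        )

    def zero_variance_genes(self, sample_ids: list[str] | None = None) -> list[str]:
        """Genes with no variance (or <2 observations) over the given samples."""
        df = self.values if sample_ids is None else self.values[list(sample_ids)]
        sd = df.std(axis=1, ddof=1)
        flagged = sd.isna() | (sd == 0.0)
        return list(df.index[flagged])


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in items:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    orientation: str = "genes_in_rows",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The file must have one header row and one identifier column.  The GCT
    dialect (``#1.2`` first line, two-line header, ``Description`` column)
    is detected and accepted.  ``orientation`` says whether genes are rows
    (default) or columns.  Non-numeric cells raise with their location;
    recognized missing-value tokens (empty, NA, NaN, null) become NaN.
    """
    if orientation not in ("genes_in_rows", "genes_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        raw = pd.read_csv(path, sep=sep, skiprows=2, index_col=0, dtype=str)
        raw = raw.drop(columns=[c for c in raw.columns if c.lower() == "description"])
    else:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "genes_in_columns":
        raw = raw.T
    raw.index = raw.index.astype(str).str.upper()
    dupes = _duplicates(list(raw.index))
    if dupes:
        raise ValueError(f"duplicate gene identifiers in {path.name}: {dupes}")
    dupes = _duplicates(list(raw.columns))
    if dupes:
        raise ValueError(f"duplicate sample identifiers in {path.name}: {dupes}")

    def _parse(v):
        # python float() parses exactly (round-trip safe), unlike the fast
        # csv float path
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        if v.strip().lower() in _NA_TOKENS:
            return np.nan
        return float(v)

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col]
        try:
            values[col] = cell.map(_parse).astype(float)
        except ValueError:
            for gene, v in cell.items():
                try:
                    _parse(v)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell at gene {gene!r}, sample {col!r}: {v!r}"
                    ) from None
    return ExpressionMatrix(values, scale_note=f"as read from {path.name}")


def write_expression_table(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    # %.17g round-trips IEEE doubles exactly
    m.values.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list: one symbol per line, '#' comments ignored."""
    path = Path(path)
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return GeneSet(name or path.stem, genes)


def write_gene_list(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {gs.name}\n")
        for g in gs.genes:
            fh.write(g + "\n")


def read_cohort_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read clinical/cohort metadata keyed by sample id (first column)."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dupes = _duplicates(list(df.index))
    if dupes:
        raise ValueError(f"duplicate sample ids in cohort table: {dupes}")
    return df


def cohort_map_from_table(table: pd.DataFrame, column: str = "cohort") -> dict[str, str]:
    if column not in table.columns:
        raise KeyError(f"column {column!r} not in cohort table")
    col = table[column].dropna()
    return {str(s): str(v) for s, v in col.items()}


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log_transform(
    m: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log_base(x + pseudocount) of a linear-scale matrix.

    Refuses negative input: already-logged data must not be re-logged.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    if (m.values < 0).any().any():
        bad = m.values.lt(0).any(axis=1)
        raise ValueError(
            "negative values present (already log-scale?): "
            f"{list(m.values.index[bad])[:5]}"
        )
    out = np.log(m.values + pseudocount) / np.log(base)
    note = f"log{base:g}(x+{pseudocount:g})"
    return ExpressionMatrix(out, dict(m.cohort_of), note, float(base))


def subset_genes(m: ExpressionMatrix, gs: GeneSet) -> ExpressionMatrix:
    """Rows of ``m`` for genes in ``gs``, preserving gene-set order.

    Gene-set members absent from the matrix are reported via a warning
    (never silently dropped); an empty intersection is an error.
    """
    present = [g for g in gs.genes if g in m.values.index]
    missing = [g for g in gs.genes if g not in m.values.index]
    if not present:
        raise ValueError(f"no genes of set {gs.name!r} present in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) of set {gs.name!r} absent from matrix: {missing}",
            stacklevel=2,
        )
    return ExpressionMatrix(
        m.values.loc[present].copy(), dict(m.cohort_of), m.scale_note, m.log_base
    )
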