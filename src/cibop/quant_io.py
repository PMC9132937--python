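"""Reading and writing protein-group tables, sample designs, and gene sets.

Consumes MaxQuant ``proteinGroups.txt``-style tab-separated tables (one row
per protein group, intensity columns prefixed ``"Intensity "``, ``Reverse``
and ``Potential contaminant`` marker columns holding ``"+"``) and writes a
canonical TSV dialect that round-trips exactly.  The column-name patterns are
pluggable so non-MaxQuant tables can be ingested.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    FormatError,
    IntensityMatrix,
    TermCollection,
    fold_symbol,
    validate_design,
    validate_meta,
)

log = logging.getLogger(__name__)

#: identifiers whose presence in the protein-group id or gene symbol marks
#: the biotin-ligase bait entry (V5-TurboID constructs derive from BirA)
DEFAULT_BAIT_IDENTIFIERS = frozenset({"TURBOID", "V5-TURBOID", "BIRA"})

#: endogenously biotinylated carboxylases that bind streptavidin in every
#: sample regardless of genotype (gene symbols, case-folded)
ENDOGENOUS_BIOTIN_SYMBOLS = frozenset({"PC", "PCCA", "PCCB", "MCCC1", "MCCC2", "ACACA", "ACACB"})


@dataclass
class TableDialect:
    """Column-name conventions of a protein-group table."""

    id_column: str = "Protein IDs"
    gene_column: str = "Gene names"
    intensity_prefix: str = "Intensity "
    reverse_column: str = "Reverse"
    contaminant_column: str = "Potential contaminant"
    flag_true: str = "+"
    bait_identifiers: frozenset[str] = field(default_factory=lambda: DEFAULT_BAIT_IDENTIFIERS)


MAXQUANT = TableDialect()

#: dialect written by :func:`write_protein_groups`; fixed column names so
#: that write(read(x)) round-trips byte-identically
CANONICAL = TableDialect(
    id_column="protein_group_id",
    gene_column="gene_symbol",
    intensity_prefix="Intensity ",
    reverse_column="is_reverse",
    contaminant_column="is_contaminant",
)


def _first_symbol(cell: str) -> str:
    """Protein groups may list several symbols separated by semicolons;
    set analyses use the first."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ""
    return str(cell).split(";")[0].strip()


def _tokens(cell) -> set[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return set()
    return {fold_symbol(t) for t in re.split(r"[;,\s]+", str(cell)) if t}


def read_protein_groups(
    path, dialect: TableDialect = MAXQUANT
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Read a protein-group TSV into a linear-scale matrix plus metadata.

    Intensity zeros become missing values (the LFQ convention: MaxQuant
    writes 0 when a protein was not quantified in a run).  Reverse/
    contaminant flags are parsed from their marker columns when present and
    default to False otherwise.  The bait is detected by matching the
    dialect's identifier list against the protein id and gene-symbol tokens.

    Returns ``(matrix, meta)`` where ``meta`` is indexed by protein_group_id
    with columns gene_symbol / is_reverse / is_contaminant / is_bait /
    is_endogenous_biotin.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect.id_column not in df.columns:
        raise FormatError(f"identifier column {dialect.id_column!r} not found in {path}")
    intensity_cols = [c for c in df.columns if c.startswith(dialect.intensity_prefix)]
    if not intensity_cols:
        raise FormatError(
            f"no intensity columns (prefix {dialect.intensity_prefix!r}) in {path}"
        )
    ids = df[dialect.id_column].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise FormatError(f"duplicate protein identifiers: {dups}")

    values = (
        df[intensity_cols]
        .apply(pd.to_numeric, errors="raise")
        .set_axis([c[len(dialect.intensity_prefix):] for c in intensity_cols], axis=1)
    )
    values.index = ids
    values = values.mask(values == 0)  # zero intensity == not quantified
    values.index.name = "protein_group_id"

    def _flag(col: str) -> pd.Series:
        if col in df.columns:
            return df[col].fillna("").str.strip().eq(dialect.flag_true)
        return pd.Series(False, index=df.index)

    gene_cells = (
        df[dialect.gene_column] if dialect.gene_column in df.columns
        else pd.Series("", index=df.index)
    )
    symbols = gene_cells.map(_first_symbol)
    bait_ids = {fold_symbol(b) for b in dialect.bait_identifiers}
    is_bait = [
        bool((_tokens(i) | _tokens(g)) & bait_ids)
        for i, g in zip(ids, gene_cells)
    ]
    is_endog = [
        bool(_tokens(g) & ENDOGENOUS_BIOTIN_SYMBOLS) for g in gene_cells
    ]
    meta = pd.DataFrame(
        {
            "gene_symbol": symbols.to_numpy(),
            "is_reverse": _flag(dialect.reverse_column).to_numpy(),
            "is_contaminant": _flag(dialect.contaminant_column).to_numpy(),
            "is_bait": is_bait,
            "is_endogenous_biotin": is_endog,
        },
        index=pd.Index(ids, name="protein_group_id"),
    )
    meta = validate_meta(meta)
    return IntensityMatrix(values, scale="linear"), meta


def write_protein_groups(path, matrix: IntensityMatrix, meta: pd.DataFrame) -> None:
    """Write matrix+meta as canonical TSV (missing values as 0 on the linear
    scale, empty cells on log2) that :func:`read_protein_groups` with the
    CANONICAL dialect reads back unchanged."""
    out = pd.DataFrame(index=matrix.protein_ids)
    out["protein_group_id"] = matrix.protein_ids
    out["gene_symbol"] = meta.loc[matrix.protein_ids, "gene_symbol"]
    for col in ("is_reverse", "is_contaminant"):
        out[col] = np.where(meta.loc[matrix.protein_ids, col], "+", "")
    vals = matrix.values
    if matrix.scale == "linear":
        vals = vals.fillna(0.0)
    for s in matrix.sample_ids:
        out[f"Intensity {s}"] = vals[s]
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_design(path) -> pd.DataFrame:
    """Read a sample-design TSV/CSV (sample_id, genotype, driver, region,
    mouse_id, tech_rep)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    design = pd.read_csv(path, sep=sep, dtype=str).set_index("sample_id")
    design["tech_rep"] = design["tech_rep"].astype(int)
    return validate_design(design)


def write_design(path, design: pd.DataFrame) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def filter_flagged(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    drop_reverse: bool = True,
    drop_contaminant: bool = True,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Drop reverse-decoy and contaminant rows.

    The bait row is always retained: the upstream search sometimes flags the
    ligase construct as a contaminant, but it is the normalisation anchor and
    must survive (a warning is logged when a flag is overridden).
    """
    meta = meta.loc[matrix.protein_ids]
    drop = pd.Series(False, index=meta.index)
    if drop_reverse:
        drop |= meta["is_reverse"]
    if drop_contaminant:
        drop |= meta["is_contaminant"]
    rescued = drop & meta["is_bait"]
    if rescued.any():
        log.warning(
            "bait row %s carries a reverse/contaminant flag; retained anyway",
            list(meta.index[rescued]),
        )
        drop &= ~meta["is_bait"]
    n = int(drop.sum())
    if n:
        log.info("filter_flagged removed %d of %d rows", n, len(meta))
    keep = meta.index[~drop]
    return matrix.subset_rows(keep), meta.loc[keep]


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform a linear-scale matrix; missing stays missing."""
    if matrix.scale != "linear":
        raise FormatError(f"expected linear scale, got {matrix.scale!r}")
    vals = matrix.values
    bad = vals.le(0)
    if bad.any().any():
        cells = [(r, c) for r, c in zip(*np.nonzero(bad.to_numpy()))]
        named = [(vals.index[r], vals.columns[c]) for r, c in cells[:10]]
        raise FormatError(f"nonpositive intensities at cells {named}")
    return IntensityMatrix(np.log2(vals), scale="log2", imputed=matrix.imputed.copy())


def unlog2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Inverse of :func:`log2_transform`."""
    if matrix.scale != "log2":
        raise FormatError(f"expected log2 scale, got {matrix.scale!r}")
    return IntensityMatrix(2.0 ** matrix.values, scale="linear", imputed=matrix.imputed.copy())


def read_gmt(path) -> TermCollection:
    """Read gene sets in GMT format (term, description, tab-separated
    symbols).  Symbols are case-folded; duplicate symbols within a line are
    deduplicated; empty terms are dropped with a warning."""
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line has <2 fields")
            term, desc, *symbols = fields
            folded = frozenset(fold_symbol(s) for s in symbols if s.strip())
            if not folded:
                log.warning("%s:%d: term %r has no symbols; dropped", path, lineno, term)
                continue
            terms[term] = folded
            descriptions[term] = desc
    return TermCollection(terms, descriptions)


def read_symbol_list(path) -> list[str]:
    """Read a one-symbol-per-line background or annotation list (case-folded,
    deduplicated, order preserved)."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            s = fold_symbol(line.strip())
            if s:
                seen.setdefault(s)
    return list(seen)
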