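"""Core in-memory containers shared across the pipeline.

The pipeline moves three things between stages: a protein-group intensity
matrix (proteins x samples, with explicit missingness), per-protein metadata
(flags for decoy/contaminant entries, the TurboID bait, and endogenously
biotinylated carboxylases), and a per-sample experimental design (genotype,
Cre driver, brain region, mouse, technical replicate).  All three are thin
wrappers around pandas objects with validation at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("labeled", "control")

#: brain regions used throughout: cortex, hippocampus, striatum/thalamus,
#: pons/medulla, cerebellum, plus whole-brain for non-regional designs
REGIONS = ("CTX", "HIP", "ST", "PM", "CB", "whole")

DRIVERS = ("hSyn", "Camk2a", "Aldh1l1", "none")


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


class ConfigurationError(ValueError):
    """Raised when parameters are outside their valid domain."""


def fold_symbol(symbol: str) -> str:
    """Case-fold a gene symbol for set operations.

    Mouse symbols (Gfap) and human-cased lists (GFAP, AKT1) refer to the
    same genes; all set arithmetic in the pipeline happens on upper-cased
    symbols.
    """
    return str(symbol).strip().upper()


@dataclass
class IntensityMatrix:
    """Protein-group intensity matrix with explicit missingness.

    Parameters
    ----------
    values
        proteins x samples DataFrame; ``NaN`` encodes a missing value.
    scale
        ``"linear"`` (raw summed peptide intensity) or ``"log2"``.
    imputed
        Boolean mask, same shape as ``values``, marking cells filled by
        imputation.  Imputed positions must have been missing beforehand
        and now hold values.
    """

    values: pd.DataFrame
    scale: str = "linear"
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein identifiers: {dups}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            if self.imputed.shape != self.values.shape:
                raise FormatError("imputed mask shape differs from values")
            self.imputed = self.imputed.astype(bool)
            self.imputed.index = self.values.index
            self.imputed.columns = self.values.columns
            if (self.imputed.to_numpy() & self.values.isna().to_numpy()).any():
                raise FormatError("imputed mask marks cells that are still missing")

    # -- convenience ---------------------------------------------------
    @property
    def missing(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.scale, self.imputed.copy())

    def subset_rows(self, ids) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[ids], self.scale, self.imputed.loc[ids]
        )

    def subset_columns(self, ids) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[:, ids], self.scale, self.imputed.loc[:, ids]
        )


META_COLUMNS = (
    "gene_symbol",
    "is_reverse",
    "is_contaminant",
    "is_bait",
    "is_endogenous_biotin",
)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a protein-metadata frame (indexed by protein_group_id).

    Enforces: at most one bait row per dataset (the TurboID/V5 entry is the
    per-sample normalisation anchor, so two would be ambiguous) and that no
    entry is simultaneously a reverse decoy and the bait.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"protein metadata lacks columns {missing}")
    if not meta.index.is_unique:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate protein identifiers in metadata: {dups}")
    meta = meta.copy()
    for col in META_COLUMNS[1:]:
        meta[col] = meta[col].astype(bool)
    n_bait = int(meta["is_bait"].sum())
    if n_bait > 1:
        raise FormatError(f"{n_bait} bait rows found; expected at most one")
    if bool((meta["is_bait"] & meta["is_reverse"]).any()):
        raise FormatError("a row is flagged both bait and reverse decoy")
    return meta


def bait_id(meta: pd.DataFrame) -> str | None:
    """Return the protein_group_id of the bait row, or None."""
    hits = meta.index[meta["is_bait"]]
    return None if len(hits) == 0 else hits[0]


DESIGN_COLUMNS = ("genotype", "driver", "region", "mouse_id", "tech_rep")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-design frame (indexed by sample_id)."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"sample design lacks columns {missing}")
    if not design.index.is_unique:
        dups = design.index[design.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers in design: {dups}")
    bad = set(design["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(f"unknown genotypes {sorted(bad)}; expected {GENOTYPES}")
    return design


def check_congruence(matrix: IntensityMatrix, design: pd.DataFrame) -> None:
    """Every matrix column must have a design row; violations are errors,
    never silent subsetting."""
    missing = [s for s in matrix.sample_ids if s not in design.index]
    if missing:
        raise FormatError(f"samples missing from design: {missing}")


@dataclass
class TermCollection:
    """Named gene sets (e.g., GO terms) with case-folded symbols."""

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __getitem__(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id]

    def items(self):
        return self.terms.items()
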