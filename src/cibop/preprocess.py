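"""Valid-value filtering, down-shifted normal imputation, and bait
normalization.

These are the Perseus-equivalent preprocessing steps of streptavidin-
enrichment LFQ data, reimplemented:

* **Valid-value filtering** keeps protein groups quantified in at least *k*
  runs, either in total or within every design group.
* **Down-shifted imputation** models the left-censored missingness of LFQ
  data: for each sample with observed mean mu and standard deviation sigma,
  missing cells are drawn from ``Normal(mu - shift*sigma, (width*sigma)^2)``
  with the Perseus defaults width = 0.3, shift = 1.8.
* **Bait normalization** removes per-sample differences in labeling (driver
  activity, TurboID expression varies by brain region) by shifting every
  log2 column so the biotin-ligase bait lands on a common reference.  In
  log2 space this is an additive per-sample shift, i.e. a ratio to bait on
  the linear scale; it preserves all within-sample differences.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError, FormatError, IntensityMatrix, bait_id

log = logging.getLogger(__name__)


@dataclass
class FilterScheme:
    """Minimum-valid-value rule.

    mode
        ``"min-valid-total"``: at least ``k`` present values across all
        samples in scope.  ``"min-valid-per-group"``: at least ``k`` present
        values in *every* group defined by ``group_column`` of the design.
    """

    mode: str = "min-valid-total"
    k: int = 3
    group_column: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("min-valid-total", "min-valid-per-group"):
            raise ConfigurationError(f"unknown filter mode {self.mode!r}")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.mode == "min-valid-per-group" and not self.group_column:
            raise ConfigurationError("per-group filtering needs a group_column")


@dataclass
class ImputationParams:
    """Down-shifted normal imputation parameters.

    ``width`` and ``shift`` are multiples of the per-sample observed
    standard deviation; defaults are the Perseus values (0.3, 1.8).
    ``scope`` selects whether mu/sigma are estimated per sample (Perseus
    default) or once over the whole matrix.
    """

    width: float = 0.3
    shift: float = 1.8
    seed: int = 0
    scope: str = "per-sample"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("width must be > 0")
        if self.shift < 0:
            raise ConfigurationError("shift must be >= 0")
        if self.scope not in ("per-sample", "whole-matrix"):
            raise ConfigurationError(f"unknown imputation scope {self.scope!r}")


def filter_min_valid(
    matrix: IntensityMatrix, design: pd.DataFrame, scheme: FilterScheme
) -> IntensityMatrix:
    """Remove protein groups with too few quantified values."""
    if matrix.scale != "log2":
        raise FormatError("filter_min_valid expects a log2-scale matrix")
    present = matrix.values.notna()
    if scheme.mode == "min-valid-total":
        if scheme.k > matrix.n_samples:
            raise ConfigurationError(
                f"k={scheme.k} exceeds sample count {matrix.n_samples}"
            )
        keep = present.sum(axis=1) >= scheme.k
    else:
        groups = design.loc[matrix.sample_ids, scheme.group_column]
        counts = present.T.groupby(groups.to_numpy()).sum().T
        small = [g for g in counts.columns if (groups == g).sum() < scheme.k]
        if small:
            raise ConfigurationError(
                f"k={scheme.k} exceeds the size of groups {small}"
            )
        keep = (counts >= scheme.k).all(axis=1)
    n_removed = int((~keep).sum())
    log.info(
        "filter_min_valid (%s, k=%d): removed %d of %d rows",
        scheme.mode, scheme.k, n_removed, matrix.n_proteins,
    )
    return matrix.subset_rows(matrix.protein_ids[keep])


def _sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample stream: sub-seed = (master, crc32(sample_id)).

    Subsetting or reordering samples therefore never changes another
    sample's imputed draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(sample_id.encode())])
    )


def impute_downshift(
    matrix: IntensityMatrix, params: ImputationParams
) -> IntensityMatrix:
    """Fill missing cells with draws from the down-shifted normal.

    Present values are never altered; the imputed mask records every filled
    position.  A sample with fewer than two observed values has an undefined
    standard deviation and is an error.
    """
    if matrix.scale != "log2":
        raise FormatError("impute_downshift expects a log2-scale matrix")
    values = matrix.values.copy()
    imputed = matrix.imputed.copy()
    arr = values.to_numpy()

    if params.scope == "whole-matrix":
        obs = arr[~np.isnan(arr)]
        if obs.size < 2:
            raise FormatError("fewer than 2 observed values in matrix")
        mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
        rng = np.random.default_rng(params.seed)
        for j, s in enumerate(values.columns):
            miss = np.isnan(arr[:, j])
            if miss.any():
                arr[miss, j] = rng.normal(
                    mu - params.shift * sigma, params.width * sigma, miss.sum()
                )
                imputed.iloc[miss, j] = True
    else:
        thin = [s for s in values.columns if values[s].notna().sum() < 2]
        if thin:
            raise FormatError(f"samples with <2 observed values: {thin}")
        for j, s in enumerate(values.columns):
            col = arr[:, j]
            miss = np.isnan(col)
            if not miss.any():
                continue
            obs = col[~miss]
            mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
            rng = _sample_rng(params.seed, str(s))
            arr[miss, j] = rng.normal(
                mu - params.shift * sigma, params.width * sigma, miss.sum()
            )
            imputed.iloc[miss, j] = True

    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    n = int(imputed.to_numpy().sum()) - int(matrix.imputed.to_numpy().sum())
    log.info("impute_downshift: filled %d cells", n)
    return IntensityMatrix(out, scale="log2", imputed=imputed)


def normalize_to_bait(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    reference: str | float = "grand-mean",
    samples=None,
) -> IntensityMatrix:
    """Shift each sample so the bait (TurboID) row is constant.

    For sample *j* with bait log2 value ``b_j`` and reference *r* (default:
    mean of ``b_j`` over the in-scope samples), every value becomes
    ``x_ij - (b_j - r)``.  Samples outside ``samples`` (e.g., control
    genotypes where the bait is structurally absent) are left untouched and
    flagged in the log; comparisons mixing normalized and exempt columns
    should be interpreted accordingly.
    """
    if matrix.scale != "log2":
        raise FormatError("normalize_to_bait expects a log2-scale matrix")
    bid = bait_id(meta)
    if bid is None or bid not in matrix.protein_ids:
        raise FormatError("bait row absent from matrix; cannot normalize")
    scope = list(matrix.sample_ids) if samples is None else list(samples)
    exempt = [s for s in matrix.sample_ids if s not in scope]
    if exempt:
        log.warning("bait normalization exempts samples %s", exempt)
    bait = matrix.values.loc[bid, scope]
    if bait.isna().any():
        missing = list(bait.index[bait.isna()])
        raise FormatError(f"bait intensity missing in samples {missing}")
    r = float(bait.mean()) if reference == "grand-mean" else float(reference)
    shifted = matrix.values.copy()
    shifted.loc[:, scope] = shifted.loc[:, scope] - (bait - r)
    return IntensityMatrix(shifted, scale="log2", imputed=matrix.imputed.copy())
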