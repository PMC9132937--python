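"""Multiplex bead immunoassay (Luminex) processing.

Two assay modes are processed side by side:

* **standard** — capture antibody, biotinylated detection antibody,
  streptavidin-fluorophore: reports *total* analyte abundance.
* **adapted** — the biotinylated detection antibody is omitted, so the
  streptavidin-fluorophore reports only analytes biotinylated in vivo by
  the cell-type-restricted ligase: the *cell-type-derived* signal.

Processing: per-analyte background subtraction (clipped at zero —
fluorescence cannot be negative), the adapted/standard signal ratio
("cell-type-derived fraction"; >= 50% calls the analyte predominantly
cell-type derived), control-animal subtraction of the adapted signal and
division by the regional bait abundance taken from the MS pipeline, and an
avidin-blocking control check (blocking should abolish the adapted signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError, FormatError

log = logging.getLogger(__name__)

PANELS = ("cytokine-32", "MAPK", "Akt/mTOR")


@dataclass
class LuminexPlate:
    """Analyte x sample median-fluorescence matrix for one assay mode."""

    fluorescence: pd.DataFrame
    mode: str = "standard"
    panel: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "adapted"):
            raise ConfigurationError(f"unknown assay mode {self.mode!r}")
        if (self.fluorescence < 0).any().any():
            raise FormatError("negative fluorescence values")

    @property
    def analytes(self) -> pd.Index:
        return self.fluorescence.index

    @property
    def samples(self) -> pd.Index:
        return self.fluorescence.columns

    def copy(self) -> "LuminexPlate":
        return LuminexPlate(self.fluorescence.copy(), self.mode, self.panel)


def _check_aligned(a: LuminexPlate, b: LuminexPlate, what: str) -> None:
    if set(a.analytes) != set(b.analytes):
        raise ConfigurationError(f"{what}: analyte panels differ")
    if set(a.samples) != set(b.samples):
        raise ConfigurationError(f"{what}: sample sets differ")


def subtract_background(plate: LuminexPlate, blank_level) -> LuminexPlate:
    """Subtract per-analyte blank fluorescence, clipping at zero.

    ``blank_level`` is a scalar, dict, or Series per analyte (e.g., from
    blank wells).  Clip events are logged.
    """
    if np.isscalar(blank_level):
        blanks = pd.Series(float(blank_level), index=plate.analytes)
    else:
        blanks = pd.Series(blank_level).astype(float)
        missing = [a for a in plate.analytes if a not in blanks.index]
        if missing:
            raise ConfigurationError(f"no blank level for analytes {missing}")
        blanks = blanks.loc[plate.analytes]
    out = plate.fluorescence.sub(blanks, axis=0)
    n_clip = int((out < 0).to_numpy().sum())
    if n_clip:
        log.info("subtract_background: clipped %d negative cells to 0", n_clip)
    return LuminexPlate(out.clip(lower=0.0), plate.mode, plate.panel)


def neuron_derived_fraction(
    standard_plate: LuminexPlate,
    adapted_plate: LuminexPlate,
    sample_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Cell-type-derived fraction of each analyte: adapted / standard.

    Both plates must be background-subtracted and share analytes/samples.
    The per-well ratio is averaged per analyte (optionally within sample
    groups given as a sample -> group Series); wells with zero standard
    signal have an undefined fraction and are excluded (flagged via
    ``n_defined``).  ``predominant_origin`` is ``"cell-type"`` when the
    fraction is >= 0.5, else ``"non-cell-type"``.
    """
    _check_aligned(standard_plate, adapted_plate, "neuron_derived_fraction")
    std = standard_plate.fluorescence
    adp = adapted_plate.fluorescence[std.columns].loc[std.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = adp.where(std > 0) / std.where(std > 0)

    def _summarize(r: pd.DataFrame, label: str) -> pd.DataFrame:
        frac = r.mean(axis=1, skipna=True)
        n_def = r.notna().sum(axis=1)
        origin = np.where(
            n_def == 0, "undefined",
            np.where(frac >= 0.5, "cell-type", "non-cell-type"),
        )
        return pd.DataFrame(
            {
                "group": label,
                "fraction": frac.where(n_def > 0),
                "n_defined": n_def,
                "predominant_origin": origin,
            },
            index=r.index,
        )

    if sample_groups is None:
        return _summarize(ratio, "all")
    parts = [
        _summarize(ratio[list(cols)], g)
        for g, cols in sample_groups.groupby(sample_groups).groups.items()
    ]
    return pd.concat(parts)


def normalize_adapted(
    adapted_labeled: LuminexPlate,
    adapted_control: LuminexPlate,
    bait_abundance_per_region: pd.Series | dict,
    region_of_labeled: pd.Series,
    region_of_control: pd.Series,
) -> pd.DataFrame:
    """Control-subtracted, bait-normalized cell-type-derived analyte levels.

    Per analyte and region: the mean adapted signal of control animals is
    subtracted from the mean adapted signal of labeled animals (clipped at
    zero, clips logged), then divided by the region's relative bait
    abundance from the MS pipeline (linear scale) to correct for regional
    differences in ligase expression.  Returns an analyte x region matrix
    ready for hierarchical clustering.
    """
    if set(adapted_labeled.analytes) != set(adapted_control.analytes):
        raise ConfigurationError("normalize_adapted: analyte panels differ")
    bait = pd.Series(bait_abundance_per_region).astype(float)

    def _region_means(plate: LuminexPlate, region_of: pd.Series) -> pd.DataFrame:
        missing = [s for s in plate.samples if s not in region_of.index]
        if missing:
            raise ConfigurationError(f"samples without region labels: {missing}")
        return plate.fluorescence.T.groupby(region_of.loc[plate.samples]).mean().T

    lab = _region_means(adapted_labeled, region_of_labeled)
    ctl = _region_means(adapted_control, region_of_control)
    regions = [r for r in lab.columns if r in set(ctl.columns)]
    if not regions:
        raise ConfigurationError("no shared regions between labeled and control")
    no_bait = [r for r in regions if r not in bait.index]
    if no_bait:
        raise ConfigurationError(f"regions missing bait abundance: {no_bait}")
    diff = lab[regions] - ctl.loc[lab.index, regions]
    n_clip = int((diff < 0).to_numpy().sum())
    if n_clip:
        log.info("normalize_adapted: clipped %d negative cells to 0", n_clip)
    return diff.clip(lower=0.0).div(bait.loc[regions], axis=1)


def blocking_control_check(
    adapted_blocked: LuminexPlate,
    adapted_unblocked: LuminexPlate,
    tolerance: float = 0.1,
) -> dict:
    """Avidin-blocking control: blocking biotinylated epitopes should
    abolish the adapted signal.

    Per analyte, the residual fraction is mean(blocked) / mean(unblocked)
    (undefined when the unblocked signal is zero).  The dataset passes when
    the median residual over defined analytes is <= ``tolerance``.
    """
    _check_aligned(adapted_blocked, adapted_unblocked, "blocking_control_check")
    blk = adapted_blocked.fluorescence.mean(axis=1)
    unb = adapted_unblocked.fluorescence.loc[blk.index].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        residual = blk.where(unb > 0) / unb.where(unb > 0)
    defined = residual.dropna()
    median = float(defined.median()) if len(defined) else float("nan")
    return {
        "residual_fraction": residual,
        "median_residual": median,
        "n_defined": int(len(defined)),
        "passes": bool(len(defined)) and median <= tolerance,
        "tolerance": tolerance,
    }


def read_plate(path, mode: str, panel: str = "") -> LuminexPlate:
    """Read a wide TSV/CSV plate (analyte rows x sample columns)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return LuminexPlate(df.astype(float), mode=mode, panel=panel)


def write_plate(path, plate: LuminexPlate) -> None:
    plate.fluorescence.to_csv(path, sep="\t", index_label="analyte", float_format="%.6f")
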