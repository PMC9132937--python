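"""Synthetic proximity-labeling datasets with known ground truth.

The generator emulates the statistical structure that the downstream
analysis assumes for streptavidin-enrichment LFQ data:

* labeled and control genotypes, with the biotin-ligase bait present only
  in labeled samples at a region-dependent level (ligase expression varies
  with driver activity across brain regions);
* an endogenously biotinylated carboxylase background present at equal
  expectation in both genotypes (what the control pulldown captures);
* a planted fraction of truly cell-type-enriched proteins, elevated by
  ``delta_enrich`` log2 units in labeled samples, a subset of which carry an
  additional region-specific effect of ``delta_region`` log2 units;
* a shared per-sample labeling-efficiency factor in labeled samples
  (regional bait offset plus mouse-level ligase variability) that scales
  every ligase-labeled protein together with the bait itself — the
  structure that bait normalization exists to remove;
* additive Gaussian noise on the log2 scale (log-normal on the linear
  scale, the standard LFQ assumption), partitioned into mouse-level and
  technical components so that a single replicate's within-group residual
  sd equals ``noise_sd``, with technical replicates resampled around the
  same mouse-level mean at technical sd ``noise_sd / 2``;
* intensity-dependent (missing-not-at-random) dropout via a logistic in
  log2 intensity, applied as a separate step so the pre-dropout matrix is
  available as ground truth.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` streams (base means, effect assignment,
noise), so subsetting one stage never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigurationError, IntensityMatrix, validate_meta

log = logging.getLogger(__name__)

DEFAULT_REGIONS = ("CTX", "HIP", "ST", "PM", "CB")

#: cohort-style default: technical replicates for labeled samples in every
#: region except hippocampus (2 mice x 5 regions -> 18 labeled columns)
DEFAULT_TECH_REPS = {"CTX": 2, "HIP": 1, "ST": 2, "PM": 2, "CB": 2}


@dataclass
class SynthMSConfig:
    """Configuration of the synthetic MS dataset.

    ``tech_reps`` is the number of technical replicates per labeled sample,
    either a single int or a per-region mapping; control samples never have
    technical replicates.  ``bait_log2_by_region`` must cover every region.
    """

    n_proteins: int = 2000
    regions: tuple[str, ...] = DEFAULT_REGIONS
    mice_per_group: int = 2
    tech_reps: int | dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TECH_REPS))
    frac_enriched: float = 0.10
    delta_enrich: float = 3.0
    frac_regional: float = 0.15
    delta_region: float = 2.5
    base_mean: float = 24.0
    base_sd: float = 2.0
    noise_sd: float = 0.5
    bait_log2_by_region: dict[str, float] = field(
        default_factory=lambda: {"CTX": 27.0, "HIP": 27.0, "ST": 26.5, "PM": 25.5, "CB": 25.5}
    )
    n_endogenous: int = 5
    dropout_midpoint: float = 20.0
    dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_enriched", "frac_regional"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("n_proteins", "mice_per_group"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_endogenous < 0:
            raise ConfigurationError("n_endogenous must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.dropout_slope <= 0:
            raise ConfigurationError("dropout_slope must be > 0")
        missing = [r for r in self.regions if r not in self.bait_log2_by_region]
        if missing:
            raise ConfigurationError(f"bait_log2_by_region lacks regions {missing}")
        reps = self.tech_reps
        if isinstance(reps, dict):
            bad = [r for r in self.regions if reps.get(r, 1) < 1]
        else:
            bad = [] if reps >= 1 else list(self.regions)
        if bad:
            raise ConfigurationError(f"tech_reps must be >= 1 (violated for {bad})")

    def reps_for(self, region: str) -> int:
        if isinstance(self.tech_reps, dict):
            return int(self.tech_reps.get(region, 1))
        return int(self.tech_reps)


@dataclass
class SynthTruth:
    """Ground truth of a synthetic MS dataset."""

    enriched_ids: frozenset[str]
    regional_map: dict[str, str]      # protein -> region carrying the extra effect
    endogenous_ids: frozenset[str]
    bait_id: str
    true_means: pd.DataFrame          # proteins x "genotype:region" cell means (log2)

    def __post_init__(self) -> None:
        if not set(self.regional_map) <= set(self.enriched_ids):
            raise ConfigurationError("regional proteins must be a subset of enriched")
        if self.bait_id in self.enriched_ids or self.bait_id in self.endogenous_ids:
            raise ConfigurationError("bait cannot be an enriched/endogenous protein")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.true_means.index:
            rows.append(
                {
                    "protein_group_id": pid,
                    "is_enriched": pid in self.enriched_ids,
                    "region_effect": self.regional_map.get(pid, ""),
                    "is_endogenous": pid in self.endogenous_ids,
                    "is_bait": pid == self.bait_id,
                }
            )
        return pd.DataFrame(rows).set_index("protein_group_id")


BAIT_ROW_ID = "TURBOID"


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named child streams from one master seed (fixed spawn order)."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("base", "assign", "noise")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_ms_dataset(
    config: SynthMSConfig,
) -> tuple[IntensityMatrix, pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Generate a linear-scale intensity matrix plus design, metadata, truth.

    The matrix is fully observed (pre-dropout); chain
    :func:`cibop.quant_io.log2_transform` and :func:`apply_dropout` to add
    missing-not-at-random missingness.  The bait row is missing in control
    columns (structurally absent, not low).
    """
    rngs = _streams(config.seed)
    regions = list(config.regions)

    protein_ids = [f"P{i+1:05d}" for i in range(config.n_proteins)]
    endo_ids = [f"ENDO{i+1:02d}" for i in range(config.n_endogenous)]
    all_ids = protein_ids + endo_ids + [BAIT_ROW_ID]

    # planted effects
    n_enr = int(round(config.frac_enriched * config.n_proteins))
    assign = rngs["assign"]
    enriched = list(assign.choice(protein_ids, size=n_enr, replace=False))
    n_reg = int(round(config.frac_regional * n_enr))
    regional = list(assign.choice(enriched, size=n_reg, replace=False)) if n_reg else []
    region_of = {pid: regions[assign.integers(len(regions))] for pid in regional}

    base = rngs["base"].normal(config.base_mean, config.base_sd, len(all_ids))
    base_of = dict(zip(all_ids, base))

    # design: labeled mice with per-region technical replicates, controls without
    design_rows = []
    for geno, prefix in (("labeled", "L"), ("control", "C")):
        for m in range(1, config.mice_per_group + 1):
            for r in regions:
                reps = config.reps_for(r) if geno == "labeled" else 1
                for t in range(1, reps + 1):
                    design_rows.append(
                        {
                            "sample_id": f"{prefix}{m}.{r}.r{t}",
                            "genotype": geno,
                            "driver": "Camk2a" if geno == "labeled" else "none",
                            "region": r,
                            "mouse_id": f"{prefix}{m}",
                            "tech_rep": t,
                        }
                    )
    design = pd.DataFrame(design_rows).set_index("sample_id")

    # true cell means per (genotype, region); labeled ligase-labeled rows
    # (everything except endogenous carboxylases) carry the centered
    # regional labeling-efficiency offset that scales with bait expression
    cells = [f"{g}:{r}" for g in ("labeled", "control") for r in regions]
    means = pd.DataFrame(index=pd.Index(all_ids, name="protein_group_id"),
                         columns=cells, dtype=float)
    enr_set = set(enriched)
    endo_set = set(endo_ids)
    bait_bar = float(np.mean([config.bait_log2_by_region[r] for r in regions]))
    labeling_offset = {r: config.bait_log2_by_region[r] - bait_bar for r in regions}
    is_labeled_row = np.array([p not in endo_set for p in all_ids])  # incl. bait
    for g in ("labeled", "control"):
        for r in regions:
            col = np.array([base_of[p] for p in all_ids])
            if g == "control":
                col = col - np.array(
                    [config.delta_enrich if p in enr_set else 0.0 for p in all_ids]
                )
            else:
                col = col + np.array(
                    [config.delta_region if region_of.get(p) == r else 0.0 for p in all_ids]
                )
                col = col + np.where(is_labeled_row, labeling_offset[r], 0.0)
            means[f"{g}:{r}"] = col
    means.loc[BAIT_ROW_ID, :] = np.nan
    for r in regions:
        means.loc[BAIT_ROW_ID, f"labeled:{r}"] = config.bait_log2_by_region[r]

    # noise partition: technical sd = noise_sd/2; mouse-level biological sd
    # and (labeled only) shared ligase-expression sd fill the remainder so
    # the marginal within-group residual of one replicate is noise_sd
    tech_sd = config.noise_sd / 2.0
    ligase_sd = config.noise_sd * np.sqrt(0.375)   # shared across labeled rows
    mouse_sd_labeled = config.noise_sd * np.sqrt(0.375)
    mouse_sd_control = config.noise_sd * np.sqrt(0.75)
    noise = rngs["noise"]
    log2vals = pd.DataFrame(index=means.index, columns=design.index, dtype=float)
    bait_pos = all_ids.index(BAIT_ROW_ID)
    for (geno, mouse, region), sub in design.groupby(
        ["genotype", "mouse_id", "region"], sort=False
    ):
        cell = means[f"{geno}:{region}"].to_numpy()
        if geno == "labeled":
            eta = noise.normal(0.0, ligase_sd)  # one draw shared by labeled rows
            mouse_level = cell + np.where(is_labeled_row, eta, 0.0)
            protein_noise = noise.normal(0.0, mouse_sd_labeled, len(cell))
            protein_noise[bait_pos] = 0.0  # bait varies only via eta + technical
            mouse_level = mouse_level + protein_noise
        else:
            mouse_level = cell + noise.normal(0.0, mouse_sd_control, len(cell))
        for s in sub.index:
            log2vals[s] = mouse_level + noise.normal(0.0, tech_sd, len(cell))
    # bait structurally absent in controls (true zero, not noise-floor)
    control_cols = design.index[design["genotype"] == "control"]
    log2vals.loc[BAIT_ROW_ID, control_cols] = np.nan

    matrix = IntensityMatrix(2.0 ** log2vals, scale="linear")
    meta = validate_meta(
        pd.DataFrame(
            {
                "gene_symbol": [p for p in all_ids],
                "is_reverse": False,
                "is_contaminant": False,
                "is_bait": [p == BAIT_ROW_ID for p in all_ids],
                "is_endogenous_biotin": [p in set(endo_ids) for p in all_ids],
            },
            index=pd.Index(all_ids, name="protein_group_id"),
        )
    )
    truth = SynthTruth(
        enriched_ids=frozenset(enriched),
        regional_map=region_of,
        endogenous_ids=frozenset(endo_ids),
        bait_id=BAIT_ROW_ID,
        true_means=means,
    )
    return matrix, design, meta, truth


def logistic(x):
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def apply_dropout(
    matrix: IntensityMatrix, midpoint: float, slope: float, seed: int
) -> IntensityMatrix:
    """Censor values missing-not-at-random on a log2-scale matrix.

    Each present value *x* is independently set missing with probability
    ``logistic((midpoint - x) / slope)``: monotone non-increasing in
    intensity, 0.5 at the midpoint, a hard threshold in the slope -> 0
    limit.  Cell count is conserved; only the missing mask changes, and
    whole columns are never removed.
    """
    if slope <= 0:
        raise ConfigurationError("dropout slope must be > 0")
    if matrix.scale != "log2":
        raise ConfigurationError("apply_dropout expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy(float).copy()
    present = ~np.isnan(vals)
    p_miss = np.zeros_like(vals)
    p_miss[present] = logistic((midpoint - vals[present]) / slope)
    drop = present & (rng.random(vals.shape) < p_miss)
    vals[drop] = np.nan
    log.info("apply_dropout: censored %d of %d present cells", drop.sum(), present.sum())
    out = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return IntensityMatrix(out, scale="log2")


@dataclass
class SynthLuminexConfig:
    """Configuration of matched synthetic immunoassay plates.

    ``analytes`` maps analyte name -> (total abundance in fluorescence
    units, cell-type-derived fraction in [0, 1]).  ``bait_rel_abundance``
    is the per-region relative ligase level (linear scale) that multiplies
    the cell-type-derived signal in the adapted assay.
    """

    analytes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "IL-6": (800.0, 0.2),
            "TNF-a": (600.0, 0.7),
            "pErk": (1500.0, 0.8),
            "pAkt": (1200.0, 0.6),
            "pGSK3b": (900.0, 0.75),
            "MCP-1": (700.0, 0.15),
        }
    )
    regions: tuple[str, ...] = ("CTX", "ST", "PM", "CB")
    bait_rel_abundance: dict[str, float] = field(
        default_factory=lambda: {"CTX": 1.3, "ST": 1.1, "PM": 0.8, "CB": 0.8}
    )
    wells_per_region: int = 3
    plate_noise_cv: float = 0.1
    blank_level: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for a, (ab, fr) in self.analytes.items():
            if not 0.0 <= fr <= 1.0:
                raise ConfigurationError(f"fraction for {a} outside [0, 1]")
            if ab < 0:
                raise ConfigurationError(f"abundance for {a} negative")
        if self.blank_level < 0:
            raise ConfigurationError("blank_level must be >= 0")
        if self.plate_noise_cv < 0:
            raise ConfigurationError("plate_noise_cv must be >= 0")
        if self.wells_per_region < 1:
            raise ConfigurationError("wells_per_region must be >= 1")
        missing = [r for r in self.regions if r not in self.bait_rel_abundance]
        if missing:
            raise ConfigurationError(f"bait_rel_abundance lacks regions {missing}")


def generate_luminex_dataset(config: SynthLuminexConfig):
    """Generate (standard, adapted-labeled, adapted-control) plates + truth.

    Expected signals per analyte *a*, region *g*:

    * standard (labeled animals):  ``abundance_a + blank``
    * adapted labeled: ``fraction_a * abundance_a * bait_rel_g + blank``
    * adapted control: ``blank``

    with multiplicative noise of the configured CV (truncated at zero).
    Standard and adapted-labeled plates share well ids (same animals);
    control wells are separate animals.
    """
    from .luminex import LuminexPlate

    rng = np.random.default_rng(config.seed)
    analytes = list(config.analytes)
    abundance = np.array([config.analytes[a][0] for a in analytes])
    fraction = np.array([config.analytes[a][1] for a in analytes])

    def _noisy(expected: np.ndarray) -> np.ndarray:
        factor = 1.0 + config.plate_noise_cv * rng.standard_normal(expected.shape)
        return np.clip(expected * factor, 0.0, None)

    lab_wells, ctl_wells, std_cols, adl_cols, adc_cols = [], [], [], [], []
    for g in config.regions:
        for w in range(1, config.wells_per_region + 1):
            lab_wells.append((g, f"{g}.L{w}"))
            ctl_wells.append((g, f"{g}.C{w}"))
    std = {}
    adl = {}
    adc = {}
    for g, well in lab_wells:
        std[well] = _noisy(abundance + config.blank_level)
        adl[well] = _noisy(
            fraction * abundance * config.bait_rel_abundance[g] + config.blank_level
        )
    for g, well in ctl_wells:
        adc[well] = _noisy(np.full(len(analytes), config.blank_level))

    idx = pd.Index(analytes, name="analyte")
    standard = LuminexPlate(pd.DataFrame(std, index=idx), mode="standard")
    adapted_labeled = LuminexPlate(pd.DataFrame(adl, index=idx), mode="adapted")
    adapted_control = LuminexPlate(pd.DataFrame(adc, index=idx), mode="adapted")
    truth = pd.DataFrame(
        {
            "abundance": abundance,
            "cell_type_fraction": fraction,
        },
        index=idx,
    )
    return standard, adapted_labeled, adapted_control, truth


@dataclass
class RecoveryMetrics:
    """How well downstream calls recover the planted truth."""

    sensitivity: float
    specificity: float
    fdr: float
    sensitivity_defined: bool
    fdr_defined: bool
    n_true: int
    n_calls: int
    n_true_positive: int
    n_false_positive: int
    n_correct_region: int = 0
    n_misassigned: int = 0


def score_recovery(truth: SynthTruth, calls, universe=None) -> RecoveryMetrics:
    """Score enrichment or regional-signature calls against the truth.

    ``calls`` may be a classified enrichment table (rows with
    ``class == "enriched_A"`` count as calls), a
    :class:`~cibop.regional.RegionalSignatureSet` (scored per region), or a
    plain collection of protein ids.  The bait and endogenous-biotin rows
    are excluded from the positive set by definition (they are truly
    present in pulldowns but are not cell-type-enriched targets).  An empty
    truth yields an undefined-sensitivity flag, never a silent zero; an
    empty call set an undefined FDR.
    """
    from .regional import RegionalSignatureSet

    excluded = {truth.bait_id} | set(truth.endogenous_ids)
    region_correct = 0
    misassigned = 0
    if isinstance(calls, RegionalSignatureSet):
        called: set[str] = set()
        owner: dict[str, str] = {}
        for region in calls.regions:
            for pid in calls.proteins(region):
                called.add(pid)
                owner[pid] = region
        true_pos = set(truth.regional_map)
        for pid, region in truth.regional_map.items():
            if pid in owner:
                if owner[pid] == region:
                    region_correct += 1
                else:
                    misassigned += 1
    elif isinstance(calls, pd.DataFrame):
        if "class" not in calls.columns:
            raise ConfigurationError("enrichment table must be classified first")
        called = set(calls.index[calls["class"] == "enriched_A"])
        true_pos = set(truth.enriched_ids)
    else:
        called = set(calls)
        true_pos = set(truth.enriched_ids)

    called -= excluded
    if universe is None:
        universe = set(truth.true_means.index)
    universe = set(universe) - excluded
    unknown = called - universe
    if unknown:
        raise ConfigurationError(f"calls outside the dataset: {sorted(unknown)[:5]}")

    tp = len(called & true_pos)
    fp = len(called - true_pos)
    negatives = universe - true_pos
    tn = len(negatives - called)
    sens_defined = len(true_pos) > 0
    fdr_defined = len(called) > 0
    return RecoveryMetrics(
        sensitivity=tp / len(true_pos) if sens_defined else float("nan"),
        specificity=tn / len(negatives) if negatives else float("nan"),
        fdr=fp / len(called) if fdr_defined else float("nan"),
        sensitivity_defined=sens_defined,
        fdr_defined=fdr_defined,
        n_true=len(true_pos),
        n_calls=len(called),
        n_true_positive=tp,
        n_false_positive=fp,
        n_correct_region=region_correct,
        n_misassigned=misassigned,
    )
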