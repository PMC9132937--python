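"""End-to-end orchestration of the synthetic demonstration pipeline.

``run_pipeline`` chains every stage on a synthetic dataset with known
ground truth: simulate -> log2 -> missing-not-at-random dropout ->
valid-value filter -> down-shifted imputation -> bait normalization ->
labeled-vs-control enrichment -> core regional signatures -> gene-set
over-representation -> immunoassay processing -> joint feature x region
matrix.  Every output table carries a provenance header (config hash and
seed) and re-running with an identical config reproduces byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, luminex, ora, preprocess, quant_io, regional
from .containers import ConfigurationError, TermCollection
from .synthetic_data import (
    SynthLuminexConfig,
    SynthMSConfig,
    apply_dropout,
    generate_luminex_dataset,
    generate_ms_dataset,
    score_recovery,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Thresholds default to the study constants: 2-fold enrichment, 4-fold
    core regional signatures, p <= 0.05 unadjusted, Z > 1.96 for gene-set
    over-representation, five K-means clusters, imputation width 0.3 /
    shift 1.8.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    ms: SynthMSConfig = field(default_factory=SynthMSConfig)
    lum: SynthLuminexConfig = field(default_factory=SynthLuminexConfig)
    filter_mode: str = "min-valid-total"
    filter_k: int = 3
    impute_width: float = 0.3
    impute_shift: float = 1.8
    fc_enrich: float = 2.0
    fc_core: float = 4.0
    p_threshold: float = 0.05
    z_threshold: float = 1.96
    k_clusters: int = 5
    region_groups: dict[str, list[str]] | None = None
    gmt_path: str | None = None
    background_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("fc_enrich", "fc_core", "p_threshold", "z_threshold", "k_clusters"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ms = SynthMSConfig(**raw.pop("ms", {}))
        lum = SynthLuminexConfig(**raw.pop("lum", {}))
        return cls(ms=ms, lum=lum, **raw)

    def digest(self) -> str:
        def _enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, (tuple, set, frozenset)):
                return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
            raise TypeError(str(type(obj)))

        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # hash the computation, not the destination
        blob = json.dumps(payload, sort_keys=True, default=_enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(path: Path, df: pd.DataFrame, header: list[str], index_label: str) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.8g")


def _synthetic_terms(truth, meta, seed: int) -> TermCollection:
    """Gene sets over the synthetic symbol universe: the planted enriched
    set (which over-representation should flag), plus random decoy terms."""
    rng = np.random.default_rng(seed)
    universe = [s for s in meta["gene_symbol"] if s]
    terms = {"planted_enriched": frozenset(truth.enriched_ids)}
    for i in range(5):
        size = int(rng.integers(20, 60))
        terms[f"decoy_{i+1}"] = frozenset(rng.choice(universe, size=size, replace=False))
    return TermCollection(terms, {t: t for t in terms})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a result bundle and writes TSV artifacts.

    Any stage failure aborts with the stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.digest()}", f"seed={config.seed}"]
    bundle: dict = {"out_dir": str(out)}
    stage = "simulate"
    try:
        matrix, design, meta, truth = generate_ms_dataset(
            dataclasses.replace(config.ms, seed=config.seed)
        )
        quant_io.write_protein_groups(out / "protein_groups.tsv", matrix, meta)
        quant_io.write_design(out / "design.tsv", design)
        _write(out / "truth.tsv", truth.to_frame(), header, "protein_group_id")

        stage = "log2+dropout"
        logm = quant_io.log2_transform(matrix)
        logm = apply_dropout(
            logm, config.ms.dropout_midpoint, config.ms.dropout_slope, config.seed + 1
        )

        stage = "filter"
        scheme = preprocess.FilterScheme(mode=config.filter_mode, k=config.filter_k)
        logm = preprocess.filter_min_valid(logm, design, scheme)

        stage = "impute"
        params = preprocess.ImputationParams(
            width=config.impute_width, shift=config.impute_shift, seed=config.seed + 2
        )
        logm = preprocess.impute_downshift(logm, params)

        stage = "normalize"
        labeled = list(design.index[design["genotype"] == "labeled"])
        norm = preprocess.normalize_to_bait(logm, meta, samples=labeled)

        stage = "enrichment"
        table = enrichment.two_group_test(
            norm, design, {"genotype": "labeled"}, {"genotype": "control"}
        )
        table = enrichment.classify(table, config.fc_enrich, config.p_threshold)
        table = enrichment.volcano_export(
            table, out / "enrichment.tsv", out / "volcano.png",
            title="labeled vs control",
        )
        rec = score_recovery(truth, table)
        bundle["enrichment_recovery"] = rec
        _write(
            out / "enrichment_recovery.tsv",
            pd.DataFrame([dataclasses.asdict(rec)]),
            header, "row",
        )

        stage = "regional"
        lab_matrix = norm.subset_columns(labeled)
        groups = config.region_groups or {
            "CTX_HIP": ["CTX", "HIP"], "ST": ["ST"], "PM": ["PM"], "CB": ["CB"]
        }
        sigs = regional.core_signatures(
            lab_matrix, design, groups, config.fc_core, config.p_threshold
        )
        sig_rows = []
        for region in sigs.regions:
            t = sigs.tables[region]
            for pid in t.index:
                sig_rows.append(
                    {"protein_group_id": pid, "region": region,
                     "log2_fc": t.loc[pid, "log2_fc"], "p_value": t.loc[pid, "p_value"]}
                )
        sig_df = pd.DataFrame(
            sig_rows, columns=["protein_group_id", "region", "log2_fc", "p_value"]
        ).set_index("protein_group_id")
        _write(out / "core_signatures.tsv", sig_df, header, "protein_group_id")
        clusters, centroids = regional.kmeans_profiles(
            lab_matrix, k=config.k_clusters, seed=config.seed
        )
        _write(out / "kmeans_clusters.tsv", clusters.to_frame(), header, "protein_group_id")
        scores, _, frac = regional.pca(lab_matrix)
        bundle["pca_variance_fractions"] = frac
        _write(out / "pca_scores.tsv", scores, header, "sample_id")

        stage = "ora"
        if config.gmt_path and config.background_path:
            terms = quant_io.read_gmt(config.gmt_path)
            background = quant_io.read_symbol_list(config.background_path)
        else:
            terms = _synthetic_terms(truth, meta, config.seed + 3)
            background = [s for s in meta["gene_symbol"] if s]
        hits = [
            meta.loc[pid, "gene_symbol"]
            for pid in table.index[table["class"] == "enriched_A"]
            if pid in meta.index
        ]
        ora_table = ora.run_ora(hits, background, terms, config.z_threshold)
        _write(out / "ora.tsv", ora_table, header, "term_id")
        bundle["ora"] = ora_table

        stage = "luminex"
        std, adl, adc, lum_truth = generate_luminex_dataset(
            dataclasses.replace(config.lum, seed=config.seed + 4)
        )
        blank = config.lum.blank_level
        std_b = luminex.subtract_background(std, blank)
        adl_b = luminex.subtract_background(adl, blank)
        adc_b = luminex.subtract_background(adc, blank)
        frac_tab = luminex.neuron_derived_fraction(std_b, adl_b)
        _write(out / "luminex_fractions.tsv", frac_tab, header, "analyte")
        region_of_l = pd.Series({s: s.split(".")[0] for s in adl_b.samples})
        region_of_c = pd.Series({s: s.split(".")[0] for s in adc_b.samples})
        bait_rel = pd.Series(config.lum.bait_rel_abundance)
        lum_norm = luminex.normalize_adapted(adl_b, adc_b, bait_rel, region_of_l, region_of_c)
        _write(out / "luminex_normalized.tsv", lum_norm, header, "analyte")
        bundle["luminex_fractions"] = frac_tab
        bundle["luminex_normalized"] = lum_norm

        stage = "integrate"
        shared = [g for g in lum_norm.columns if g in set(design["region"])]
        sig_means = {}
        region_samples = {
            g: [s for s in labeled if design.loc[s, "region"] == g] for g in shared
        }
        top = sig_df.sort_values("log2_fc", ascending=False).head(20).index
        for g in shared:
            sig_means[g] = norm.values.loc[top, region_samples[g]].mean(axis=1)
        joint, _ = regional.joint_signature_matrix(
            pd.DataFrame(sig_means), lum_norm[shared]
        )
        _write(out / "joint_matrix.tsv", joint, header, "feature")
        bundle["joint_matrix"] = joint
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle["truth"] = truth
    bundle["design"] = design
    bundle["enrichment"] = table
    bundle["signatures"] = sigs
    return bundle
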