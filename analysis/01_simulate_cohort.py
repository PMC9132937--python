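#!/usr/bin/env python
"""Simulate the study cohort: a streptavidin-enrichment LFQ dataset with a
region-dependent TurboID bait (2 labeled + 2 control mice, five brain
regions, technical replicates for labeled samples except hippocampus ->
18 labeled columns), plus matched standard/adapted immunoassay plates.

Writes the raw tables that the downstream drivers consume to
results/data/, together with the planted ground truth.
"""

from pathlib import Path

from cibop import quant_io
from cibop.luminex import write_plate
from cibop.synthetic_data import (
    SynthLuminexConfig,
    SynthMSConfig,
    generate_luminex_dataset,
    generate_ms_dataset,
)

SEED = 20220525
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ms_cfg = SynthMSConfig(seed=SEED)
    matrix, design, meta, truth = generate_ms_dataset(ms_cfg)
    quant_io.write_protein_groups(OUT / "protein_groups.tsv", matrix, meta)
    quant_io.write_design(OUT / "design.tsv", design)
    truth.to_frame().to_csv(OUT / "truth.tsv", sep="\t")

    lum_cfg = SynthLuminexConfig(seed=SEED + 1)
    std, adl, adc, lum_truth = generate_luminex_dataset(lum_cfg)
    write_plate(OUT / "luminex_standard.tsv", std)
    write_plate(OUT / "luminex_adapted_labeled.tsv", adl)
    write_plate(OUT / "luminex_adapted_control.tsv", adc)
    lum_truth.to_csv(OUT / "luminex_truth.tsv", sep="\t")

    n_lab = int((design["genotype"] == "labeled").sum())
    print(f"simulated {matrix.n_proteins} protein groups x {matrix.n_samples} samples "
          f"({n_lab} labeled columns)")
    print(f"planted: {len(truth.enriched_ids)} enriched, "
          f"{len(truth.regional_map)} with a regional effect, "
          f"{len(truth.endogenous_ids)} endogenous-biotin background proteins")
    print(f"immunoassay plates: {len(lum_cfg.analytes)} analytes x "
          f"{len(lum_cfg.regions)} regions, CV {lum_cfg.plate_noise_cv}")


if __name__ == "__main__":
    main()
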