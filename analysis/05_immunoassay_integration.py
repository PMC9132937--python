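#!/usr/bin/env python
"""Process the adapted/standard immunoassay plates and integrate them with
the MS regional signatures: background subtraction, cell-type-derived
fraction with the >=50% origin rule, control subtraction and bait
normalization using regional bait abundance taken from the MS matrix, and
the joint z-scored feature x region matrix with a seeded 2-D embedding.

Reads results/data/ and results/processed/, writes results/luminex/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cibop import quant_io
from cibop.containers import IntensityMatrix, bait_id
from cibop.luminex import (
    neuron_derived_fraction,
    normalize_adapted,
    read_plate,
    subtract_background,
)
from cibop.regional import hca, joint_signature_matrix, tsne_embedder
from cibop.synthetic_data import SynthLuminexConfig

SEED = 20220525
DATA = Path("results/data")
PROC = Path("results/processed")
OUT = Path("results/luminex")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    blank = SynthLuminexConfig().blank_level
    std = subtract_background(read_plate(DATA / "luminex_standard.tsv", "standard"), blank)
    adl = subtract_background(
        read_plate(DATA / "luminex_adapted_labeled.tsv", "adapted"), blank
    )
    adc = subtract_background(
        read_plate(DATA / "luminex_adapted_control.tsv", "adapted"), blank
    )

    fractions = neuron_derived_fraction(std, adl)
    fractions.to_csv(OUT / "cell_type_fractions.tsv", sep="\t")
    truth = pd.read_csv(DATA / "luminex_truth.tsv", sep="\t", index_col=0)
    for analyte, row in fractions.iterrows():
        print(f"  {analyte}: adapted/standard = {row['fraction']:.2f} "
              f"({row['predominant_origin']}; planted "
              f"{truth.loc[analyte, 'cell_type_fraction']:.2f})")

    # regional bait abundance from MS: linear ratio to the grand mean of
    # the bait's per-region log2 intensity (pre-normalization)
    raw_ms, meta = quant_io.read_protein_groups(
        DATA / "protein_groups.tsv", quant_io.CANONICAL
    )
    design = quant_io.read_design(DATA / "design.tsv")
    bait_row = np.log2(raw_ms.values.loc[bait_id(meta)])
    labeled = design.index[design["genotype"] == "labeled"]
    per_region = bait_row[labeled].groupby(design.loc[labeled, "region"]).mean()
    bait_rel = 2.0 ** (per_region - per_region.mean())

    region_of = lambda plate: pd.Series({s: s.split(".")[0] for s in plate.samples})
    normalized = normalize_adapted(adl, adc, bait_rel, region_of(adl), region_of(adc))
    normalized.to_csv(OUT / "normalized_by_region.tsv", sep="\t")
    _, order = hca(normalized, axis="rows")
    print(f"bait-normalized analyte x region matrix written; analyte clustering "
          f"order: {order}")

    sig = pd.read_csv(Path("results/regional/core_signatures.tsv"),
                      sep="\t", index_col=0)
    raw_proc, _ = quant_io.read_protein_groups(
        PROC / "matrix_normalized_log2.tsv", quant_io.CANONICAL
    )
    proc = IntensityMatrix(raw_proc.values, scale="log2")
    shared = [g for g in normalized.columns if g in set(design["region"])]
    top = sig.sort_values("log2_fc", ascending=False).head(20).index
    means = {
        g: proc.values.loc[top, [s for s in labeled if design.loc[s, "region"] == g]]
        .mean(axis=1)
        for g in shared
    }
    joint, coords = joint_signature_matrix(
        pd.DataFrame(means), normalized[shared], embedder=tsne_embedder(seed=SEED)
    )
    joint.to_csv(OUT / "joint_feature_matrix.tsv", sep="\t")
    coords.to_csv(OUT / "joint_embedding.tsv", sep="\t")
    print(f"joint matrix: {joint.shape[0]} features (proteins + analytes) x "
          f"{joint.shape[1]} regions; embedding written")


if __name__ == "__main__":
    main()
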