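import numpy as np
import pandas as pd
import pytest

from cibop.containers import IntensityMatrix


@pytest.fixture
def toy_protein_groups(tmp_path):
    """5-row MaxQuant-style table: 2 intensity columns, one reverse hit,
    one contaminant, a bait row detectable by its V5-TurboID token."""
    rows = [
        # id, genes, Reverse, contaminant, I s1, I s2
        ("P1", "Gfap", "", "", "1024", "2048"),
        ("P2", "Actb;Actg1", "", "+", "512", "0"),
        ("REV__P3", "Rev1", "+", "", "256", "128"),
        ("P4", "V5-TurboID", "", "", "65536", "32768"),
        ("P5", "Pc", "", "", "0", "64"),
    ]
    lines = ["Protein IDs\tGene names\tReverse\tPotential contaminant\tIntensity s1\tIntensity s2"]
    lines += ["\t".join(r) for r in rows]
    path = tmp_path / "proteinGroups.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "T1\tfirst\tA\tB\tC\n"
        "T2\tsecond\tgfap\tGFAP\tACTB\n"   # duplicate after case-folding
        "T3\tthird\tX\tY\n"
    )
    return path


def make_matrix(values, samples=None, scale="log2", prefix="P"):
    """Small IntensityMatrix from a 2-D list/array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i+1}" for i in range(arr.shape[0])]
    cols = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    return IntensityMatrix(pd.DataFrame(arr, index=idx, columns=cols), scale=scale)


def make_design(samples, genotypes=None, regions=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "genotype": genotypes or ["labeled"] * n,
            "driver": ["Camk2a"] * n,
            "region": regions or ["whole"] * n,
            "mouse_id": [f"m{i+1}" for i in range(n)],
            "tech_rep": [1] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )


@pytest.fixture
def simple_meta():
    def _make(ids, bait=None, endogenous=()):
        return pd.DataFrame(
            {
                "gene_symbol": list(ids),
                "is_reverse": False,
                "is_contaminant": False,
                "is_bait": [i == bait for i in ids],
                "is_endogenous_biotin": [i in set(endogenous) for i in ids],
            },
            index=pd.Index(ids, name="protein_group_id"),
        )

    return _make
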