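"""Regional signatures, clustering, PCA, UPGMA, overlaps, integration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cibop.containers import ConfigurationError, FormatError
from cibop.regional import (
    RegionalSignatureSet,
    annotate_with_list,
    core_signatures,
    correlation_distance,
    hca,
    joint_signature_matrix,
    kmeans_profiles,
    overlap_with_background,
    pca,
    zscore_rows,
)
from conftest import make_design, make_matrix


def _regional_design(regions, per_region=2):
    samples, labels = [], []
    for r in regions:
        for i in range(per_region):
            samples.append(f"{r}.{i+1}")
            labels.append(r)
    return samples, make_design(samples, regions=labels)


class TestCoreSignatures:
    def test_constant_protein_in_no_signature(self):
        samples, design = _regional_design(["A", "B", "C"])
        vals = np.vstack([
            np.full(6, 24.0),
            [27.0, 27.1, 24.0, 24.1, 24.0, 23.9],  # high in A
        ])
        m = make_matrix(vals, samples=samples)
        sigs = core_signatures(m, design, fc_core=4.0)
        assert all("P1" not in sigs.proteins(r) for r in sigs.regions)

    def test_planted_zero_noise_single_region(self):
        # one protein +3 log2 in region A, zero noise: appears in A only
        samples, design = _regional_design(["A", "B", "C", "D"])
        base = np.full(8, 24.0)
        planted = base.copy()
        planted[:2] += 3.0
        jitter = np.tile([0.0, 0.01], 4)  # avoid zero pooled variance
        m = make_matrix(np.vstack([planted + jitter, base + jitter]), samples=samples)
        sigs = core_signatures(m, design, fc_core=4.0)
        assert sigs.proteins("A") == ["P1"]
        assert all(not sigs.proteins(r) for r in ["B", "C", "D"])

    def test_multi_region_qualifier_goes_to_max_fold(self):
        # high in A and B (both >=4-fold over the pooled rest), highest in A
        regions = ["A"] * 3 + ["B"] * 3 + ["C"] * 10
        samples = [f"s{i}" for i in range(len(regions))]
        design = make_design(samples, regions=regions)
        jitter = 0.01 * np.arange(len(regions))
        row = np.array([30.0] * 3 + [29.0] * 3 + [20.0] * 10) + jitter
        other = np.full(len(regions), 24.0) + jitter
        m = make_matrix(np.vstack([row, other]), samples=samples)
        sigs = core_signatures(m, design, fc_core=4.0)
        assert "P1" in sigs.proteins("A")
        assert "P1" not in sigs.proteins("B")
        assert "P1" in sigs.multi_assigned

    def test_small_region_error(self):
        samples, design = _regional_design(["A", "B"])
        design = design.iloc[:-1]
        m = make_matrix(np.ones((3, 3)), samples=samples[:-1])
        with pytest.raises(ConfigurationError):
            core_signatures(m, design)

    def test_merged_region_groups(self):
        samples, design = _regional_design(["CTX", "HIP", "PM"])
        vals = np.vstack([
            [28, 28.1, 28, 27.9, 24, 24.1],  # high in CTX+HIP jointly
        ])
        m = make_matrix(vals, samples=samples)
        sigs = core_signatures(
            m, design, {"CTX_HIP": ["CTX", "HIP"], "PM": ["PM"]}, fc_core=4.0
        )
        assert sigs.proteins("CTX_HIP") == ["P1"]


class TestKmeans:
    def test_planted_two_group_recovery(self):
        rng = np.random.default_rng(0)
        profile_a = np.array([2.0, 2.0, -2.0, -2.0])
        profile_b = -profile_a
        rows = [profile_a + rng.normal(0, 0.1, 4) for _ in range(15)]
        rows += [profile_b + rng.normal(0, 0.1, 4) for _ in range(15)]
        m = make_matrix(np.array(rows) + 24.0)
        labels, centroids = kmeans_profiles(m, k=2, seed=1)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        assert centroids.shape == (2, 4)

    def test_identical_rows_flagged(self, caplog):
        m = make_matrix(np.tile([1.0, 2.0, 3.0], (6, 1)))
        with caplog.at_level("WARNING"):
            labels, _ = kmeans_profiles(m, k=3, seed=0)
        assert len(labels) == 6
        assert any("centroid" in r.message or "clusters" in r.message
                   for r in caplog.records)

    def test_k_exceeds_rows_error(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(ConfigurationError):
            kmeans_profiles(m, k=5)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(24, 2, (40, 6)))
        a, _ = kmeans_profiles(m, k=5, seed=9)
        b, _ = kmeans_profiles(m, k=5, seed=9)
        assert a.equals(b)


class TestPCA:
    def test_collinear_points(self):
        # samples (1,1), (2,2), (3,3) in protein space: PC1 carries all variance
        m = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        _, _, frac = pca(m)
        assert abs(frac[0] - 1.0) < 1e-12

    def test_diagonal_covariance_fractions(self):
        # two orthogonal centered features with variance ratio 2:1
        a = np.array([1.0, -1.0, 1.0, -1.0]) / 2
        b = np.array([1.0, 1.0, -1.0, -1.0]) / 2
        m = make_matrix(np.vstack([np.sqrt(2) * a, b]) + 24.0)
        _, _, frac = pca(m)
        assert np.allclose(frac, [2 / 3, 1 / 3], atol=1e-12)

    def test_fraction_properties(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(24, 2, (30, 8)))
        scores, loadings, frac = pca(m)
        assert abs(frac.sum() - 1.0) < 1e-9
        assert (np.diff(frac) <= 1e-12).all()
        assert scores.shape[0] == 8
        # sign convention: largest-|loading| per component positive
        for c in loadings.columns:
            col = loadings[c].to_numpy()
            assert col[np.abs(col).argmax()] > 0

    def test_too_few_samples(self):
        with pytest.raises(ConfigurationError):
            pca(make_matrix([[1.0], [2.0]]))


def brute_force_upgma(dist):
    """Reference UPGMA on a labelled distance matrix: repeatedly merge the
    closest pair, averaging distances weighted by cluster sizes."""
    clusters = {i: [i] for i in range(len(dist))}
    d = {(i, j): dist[i][j] for i in range(len(dist)) for j in range(len(dist)) if i < j}
    merges = []
    next_id = len(dist)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = len(clusters[i]), len(clusters[j])
        merges.append((i, j, h, ni + nj))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        new_d = {}
        for (a, b), v in d.items():
            if i in (a, b) or j in (a, b):
                continue
            new_d[(a, b)] = v
        for c in clusters:
            if c == next_id:
                continue
            di = d.get((min(i, c), max(i, c)))
            dj = d.get((min(j, c), max(j, c)))
            new_d[(c, next_id)] = (ni * di + nj * dj) / (ni + nj)
        d = new_d
        next_id += 1
    return merges


class TestHCA:
    def test_correlated_pair_merges_first(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        vals = np.column_stack([x, 2 * x + 1, rng.normal(size=10), -x])
        d = correlation_distance(pd.DataFrame(vals, columns=list("abcd")))
        assert d.loc["a", "b"] < 1e-12           # perfectly correlated
        assert abs(d.loc["a", "d"] - 2.0) < 1e-12  # perfectly anticorrelated
        Z, order = hca(pd.DataFrame(vals, columns=list("abcd")))
        first = sorted(Z[0, :2].astype(int))
        assert first == [0, 1]

    def test_constant_item_error(self):
        vals = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(FormatError, match="constant"):
            correlation_distance(pd.DataFrame(vals, columns=["a", "b"]))

    def test_four_item_hand_upgma(self):
        # hand-built distance matrix (embedded via data is awkward; check
        # the linkage against the brute-force reference directly)
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(12, 4))
        df = pd.DataFrame(vals, columns=list("abcd"))
        d = correlation_distance(df)
        Z, _ = hca(df)
        ref = brute_force_upgma(d.to_numpy().tolist())
        for row, (i, j, h, size) in zip(Z, ref):
            assert sorted(row[:2].astype(int)) == sorted((i, j))
            assert abs(row[2] - h) < 1e-10
            assert int(row[3]) == size

    @pytest.mark.parametrize("n_items", [3, 4, 5, 6])
    def test_brute_force_oracle_random_suite(self, n_items):
        rng = np.random.default_rng(100 + n_items)
        for _ in range(25):
            vals = rng.normal(size=(10, n_items))
            df = pd.DataFrame(vals, columns=[f"i{k}" for k in range(n_items)])
            d = correlation_distance(df)
            Z, _ = hca(df)
            ref = brute_force_upgma(d.to_numpy().tolist())
            heights = Z[:, 2]
            assert (np.diff(heights) >= -1e-12).all()  # monotone merges
            for row, (i, j, h, size) in zip(Z, ref):
                assert sorted(row[:2].astype(int)) == sorted((i, j))
                assert abs(row[2] - h) < 1e-10


def _sig(table_map):
    tables = {
        region: pd.DataFrame(
            {"log2_fc": 3.0, "t_stat": 5.0, "p_value": 0.001},
            index=pd.Index(ids, name="protein_group_id"),
        )
        for region, ids in table_map.items()
    }
    return RegionalSignatureSet(tables, fc_core=4.0, p_threshold=0.05)


class TestOverlap:
    def test_reported_style_fraction(self):
        # 549 enriched-core symbols of which 419 shared -> 76.3%
        enriched = [f"G{i}" for i in range(549)]
        background = enriched[:419] + [f"H{i}" for i in range(300)]
        summary = overlap_with_background(
            _sig({"CTX_HIP": enriched}), _sig({"CTX_HIP": background})
        )
        row = summary.loc["CTX_HIP"]
        assert row["n_enriched_core"] == 549
        assert row["n_intersection"] == 419
        assert round(row["percent_overlap"], 1) == 76.3

    def test_identical_sets_100(self):
        ids = ["A", "B", "C"]
        s = overlap_with_background(_sig({"R": ids}), _sig({"R": ids}))
        assert s.loc["R", "percent_overlap"] == 100.0
        assert s.loc["R", "exclusive_to_enriched"] == ""

    def test_disjoint_sets_0(self):
        s = overlap_with_background(_sig({"R": ["A", "B"]}), _sig({"R": ["C"]}))
        assert s.loc["R", "percent_overlap"] == 0.0
        assert s.loc["R", "exclusive_to_enriched"] == "A;B"

    def test_case_insensitive(self):
        s = overlap_with_background(_sig({"R": ["Gfap"]}), _sig({"R": ["GFAP"]}))
        assert s.loc["R", "percent_overlap"] == 100.0

    def test_region_mismatch_error(self):
        with pytest.raises(ConfigurationError):
            overlap_with_background(_sig({"R1": ["A"]}), _sig({"R2": ["A"]}))


class TestAnnotate:
    def test_counting(self):
        proteins = [f"G{i}" for i in range(10)]
        ref = ["G1", "G2", "X", "Y"]
        tab = annotate_with_list(proteins, ref)
        assert len(tab) == 2

    def test_disjoint_and_identical(self):
        assert annotate_with_list(["A"], ["B"]).empty
        assert len(annotate_with_list(["A", "B"], ["a", "b"])) == 2

    def test_empty_reference_error(self):
        with pytest.raises(ConfigurationError):
            annotate_with_list(["A"], [])


class TestJointMatrix:
    def test_zscore_identity(self):
        rng = np.random.default_rng(4)
        regions = ["CTX", "ST", "PM", "CB"]
        prot = pd.DataFrame(rng.normal(24, 2, (3, 4)),
                            index=["P1", "P2", "P3"], columns=regions)
        lum = pd.DataFrame(rng.normal(500, 100, (2, 4)),
                           index=["IL-6", "pErk"], columns=regions)
        joint, coords = joint_signature_matrix(prot, lum)
        assert joint.shape == (5, 4)
        assert np.allclose(joint.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(joint.std(axis=1, ddof=0), 1, atol=1e-9)
        assert coords is None

    def test_single_region_error(self):
        prot = pd.DataFrame({"CTX": [1.0]}, index=["P1"])
        lum = pd.DataFrame({"CTX": [2.0]}, index=["IL-6"])
        with pytest.raises(ConfigurationError):
            joint_signature_matrix(prot, lum)

    def test_constant_feature_dropped(self, caplog):
        regions = ["A", "B", "C"]
        prot = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"], columns=regions)
        lum = pd.DataFrame([[5.0, 5.0, 5.0]], index=["IL-6"], columns=regions)
        with caplog.at_level("WARNING"):
            joint, _ = joint_signature_matrix(prot, lum)
        assert list(joint.index) == ["P1"]

    def test_embedder_shape_contract(self):
        rng = np.random.default_rng(6)
        regions = ["A", "B", "C", "D"]
        prot = pd.DataFrame(rng.normal(size=(4, 4)),
                            index=list("wxyz"), columns=regions)
        lum = pd.DataFrame(rng.normal(size=(2, 4)),
                           index=["m", "n"], columns=regions)
        joint, coords = joint_signature_matrix(
            prot, lum, embedder=lambda X: np.zeros((X.shape[0], 2))
        )
        assert coords.shape == (6, 2)


def test_zscore_rows_error_mode():
    df = pd.DataFrame([[1.0, 1.0, 1.0]], index=["P1"])
    with pytest.raises(FormatError):
        zscore_rows(df, on_constant="error")
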