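"""Synthetic-data generator: planted structure, dropout model, recovery
scoring, determinism, monotonicity."""

import numpy as np
import pandas as pd
import pytest

from cibop.containers import ConfigurationError
from cibop import quant_io
from cibop.enrichment import classify, two_group_test
from cibop.synthetic_data import (
    SynthLuminexConfig,
    SynthMSConfig,
    SynthTruth,
    apply_dropout,
    generate_luminex_dataset,
    generate_ms_dataset,
    logistic,
    score_recovery,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"frac_enriched": 1.5},
        {"frac_regional": -0.1},
        {"n_proteins": 0},
        {"mice_per_group": 0},
        {"noise_sd": -1.0},
        {"dropout_slope": 0.0},
        {"bait_log2_by_region": {"CTX": 26.0}},  # misses other regions
        {"tech_reps": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SynthMSConfig(n_proteins=kwargs.pop("n_proteins", 10), **kwargs)

    def test_luminex_validation(self):
        with pytest.raises(ConfigurationError):
            SynthLuminexConfig(analytes={"X": (100.0, 1.5)})
        with pytest.raises(ConfigurationError):
            SynthLuminexConfig(blank_level=-1.0)


class TestGenerateMS:
    def test_cohort_design_column_counts(self):
        """Default design mirrors the transgenic cohort: 2 labeled mice with
        technical replicates in all regions except hippocampus -> 18 labeled
        columns; controls have no technical replicates."""
        m, design, meta, truth = generate_ms_dataset(SynthMSConfig(n_proteins=50, seed=0))
        assert (design["genotype"] == "labeled").sum() == 18
        assert (design["genotype"] == "control").sum() == 10
        assert m.n_samples == 28

    def test_zero_noise_means_exact(self):
        cfg = SynthMSConfig(n_proteins=40, noise_sd=0.0, seed=1)
        m, design, meta, truth = generate_ms_dataset(cfg)
        logv = np.log2(m.values)
        for (geno, region), sub in design.groupby(["genotype", "region"]):
            got = logv[sub.index].mean(axis=1)
            want = truth.true_means[f"{geno}:{region}"]
            mask = want.notna()
            assert np.allclose(got[mask], want[mask], atol=1e-9)

    def test_bait_structure(self):
        m, design, meta, truth = generate_ms_dataset(SynthMSConfig(n_proteins=30, seed=2))
        ctl = design.index[design["genotype"] == "control"]
        lab = design.index[design["genotype"] == "labeled"]
        assert m.values.loc[truth.bait_id, ctl].isna().all()
        assert m.values.loc[truth.bait_id, lab].notna().all()
        assert meta.loc[truth.bait_id, "is_bait"]

    def test_endogenous_equal_expectation(self):
        cfg = SynthMSConfig(n_proteins=30, noise_sd=0.0, seed=3)
        _, _, _, truth = generate_ms_dataset(cfg)
        for pid in truth.endogenous_ids:
            lab = truth.true_means.loc[pid, [c for c in truth.true_means if c.startswith("labeled")]]
            ctl = truth.true_means.loc[pid, [c for c in truth.true_means if c.startswith("control")]]
            assert np.allclose(lab.to_numpy(), ctl.to_numpy())

    def test_truth_invariants(self):
        _, _, _, truth = generate_ms_dataset(SynthMSConfig(n_proteins=100, seed=4))
        assert set(truth.regional_map) <= set(truth.enriched_ids)
        assert truth.bait_id not in truth.enriched_ids
        assert not (truth.enriched_ids & truth.endogenous_ids)

    def test_determinism_bit_identical(self):
        cfg = SynthMSConfig(n_proteins=60, seed=9)
        a = generate_ms_dataset(cfg)
        b = generate_ms_dataset(cfg)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        assert a[3].enriched_ids == b[3].enriched_ids
        c = generate_ms_dataset(SynthMSConfig(n_proteins=60, seed=10))
        assert not a[0].values.equals(c[0].values)

    def test_zero_noise_recovery_at_any_threshold(self):
        """With no noise and no dropout every planted effect is recovered."""
        cfg = SynthMSConfig(
            n_proteins=100, regions=("whole",), tech_reps=1, mice_per_group=2,
            noise_sd=0.0, frac_regional=0.0,
            bait_log2_by_region={"whole": 26.0}, seed=5,
        )
        m, design, meta, truth = generate_ms_dataset(cfg)
        logm = quant_io.log2_transform(m)
        logm = logm.subset_rows([i for i in logm.protein_ids if i != truth.bait_id])
        tab = classify(
            two_group_test(logm, design, {"genotype": "labeled"}, {"genotype": "control"})
        )
        rec = score_recovery(truth, tab)
        assert rec.sensitivity == 1.0 and rec.fdr == 0.0


class TestApplyDropout:
    def _log_matrix(self, values):
        from conftest import make_matrix

        return make_matrix(values)

    def test_hard_threshold_limit(self):
        m = self._log_matrix(np.linspace(18, 26, 50)[None, :].T.reshape(50, 1))
        out = apply_dropout(m, midpoint=22.0, slope=1e-9, seed=0)
        vals = out.values.to_numpy()[:, 0]
        orig = m.values.to_numpy()[:, 0]
        assert np.isnan(vals[orig < 22.0 - 1e-6]).all()
        assert ~np.isnan(vals[orig >= 22.0]).any()

    def test_midpoint_half_missing(self):
        n = 100_000
        m = self._log_matrix(np.full((n, 1), 20.0))
        out = apply_dropout(m, midpoint=20.0, slope=1.0, seed=1)
        rate = out.missing.to_numpy().mean()
        se = np.sqrt(0.25 / n)
        assert abs(rate - 0.5) < 4 * se

    def test_closed_form_logistic_rate(self):
        # at midpoint + 2*slope the missing probability is logistic(-2)
        n = 100_000
        m = self._log_matrix(np.full((n, 1), 24.0))
        out = apply_dropout(m, midpoint=22.0, slope=1.0, seed=2)
        p = float(logistic(-2.0))
        rate = out.missing.to_numpy().mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 3 * se

    def test_conservation_and_no_column_loss(self):
        rng = np.random.default_rng(3)
        m = self._log_matrix(rng.normal(21, 2, (500, 6)))
        out = apply_dropout(m, midpoint=21.0, slope=1.0, seed=3)
        assert out.values.shape == m.values.shape
        assert list(out.sample_ids) == list(m.sample_ids)
        present = out.values.notna()
        # only removes values; present cells keep their exact value
        kept = present.to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[kept], m.values.to_numpy()[kept]
        )

    def test_monotone_in_intensity(self):
        n = 50_000
        lo = self._log_matrix(np.full((n, 1), 19.0))
        hi = self._log_matrix(np.full((n, 1), 23.0))
        r_lo = apply_dropout(lo, 21.0, 1.0, seed=4).missing.to_numpy().mean()
        r_hi = apply_dropout(hi, 21.0, 1.0, seed=4).missing.to_numpy().mean()
        assert r_lo > r_hi

    def test_invalid_slope(self):
        m = self._log_matrix([[20.0]])
        with pytest.raises(ConfigurationError):
            apply_dropout(m, 20.0, 0.0, seed=0)


class TestScoreRecovery:
    def _truth(self, enriched, endogenous=(), bait="TURBOID", universe=None):
        ids = list(universe or (list(enriched) + list(endogenous) + [bait]))
        means = pd.DataFrame(index=pd.Index(ids), columns=["labeled:whole"], data=24.0)
        return SynthTruth(
            enriched_ids=frozenset(enriched),
            regional_map={},
            endogenous_ids=frozenset(endogenous),
            bait_id=bait,
            true_means=means,
        )

    def test_perfect_calls(self):
        truth = self._truth({"P1", "P2"}, universe=["P1", "P2", "P3", "TURBOID"])
        rec = score_recovery(truth, {"P1", "P2"})
        assert rec.sensitivity == 1.0 and rec.fdr == 0.0 and rec.specificity == 1.0

    def test_empty_calls_fdr_undefined(self):
        truth = self._truth({"P1"}, universe=["P1", "P2", "TURBOID"])
        rec = score_recovery(truth, set())
        assert rec.sensitivity == 0.0
        assert not rec.fdr_defined and np.isnan(rec.fdr)

    def test_one_false_positive_of_nine(self):
        enriched = {f"P{i}" for i in range(1, 9)}  # 8 true
        universe = [f"P{i}" for i in range(1, 20)] + ["TURBOID"]
        truth = self._truth(enriched, universe=universe)
        calls = set(enriched) | {"P15"}
        rec = score_recovery(truth, calls)
        assert rec.n_calls == 9
        assert abs(rec.fdr - 1 / 9) < 1e-12

    def test_empty_truth_flagged(self):
        truth = self._truth(set(), universe=["P1", "TURBOID"])
        rec = score_recovery(truth, {"P1"})
        assert not rec.sensitivity_defined and np.isnan(rec.sensitivity)

    def test_bait_and_endogenous_excluded(self):
        truth = self._truth({"P1"}, endogenous={"E1"},
                            universe=["P1", "P2", "E1", "TURBOID"])
        rec = score_recovery(truth, {"P1", "E1", "TURBOID"})
        assert rec.n_calls == 1 and rec.fdr == 0.0


class TestMonotonicity:
    def test_sensitivity_nondecreasing_in_effect_size(self):
        """Mean enrichment-call sensitivity (20 seeds) never decreases as
        the planted effect grows."""
        def mean_sens(delta):
            out = []
            for seed in range(20):
                cfg = SynthMSConfig(
                    n_proteins=300, regions=("whole",), tech_reps=1,
                    mice_per_group=3, frac_enriched=0.1, delta_enrich=delta,
                    frac_regional=0.0, noise_sd=0.5,
                    bait_log2_by_region={"whole": 26.0}, seed=seed,
                )
                m, d, meta, t = generate_ms_dataset(cfg)
                lm = quant_io.log2_transform(m)
                lm = lm.subset_rows([i for i in lm.protein_ids if i != t.bait_id])
                tab = classify(two_group_test(
                    lm, d, {"genotype": "labeled"}, {"genotype": "control"}
                ))
                out.append(score_recovery(t, tab).sensitivity)
            return np.mean(out)

        sens = [mean_sens(d) for d in (1.0, 2.0, 3.0)]
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] > 0.95


class TestGenerateLuminex:
    def test_fraction_one_adapted_equals_standard(self):
        cfg = SynthLuminexConfig(
            analytes={"X": (500.0, 1.0)}, regions=("CTX",),
            bait_rel_abundance={"CTX": 1.0}, wells_per_region=4,
            plate_noise_cv=0.0, blank_level=0.0, seed=0,
        )
        std, adl, adc, _ = generate_luminex_dataset(cfg)
        assert np.allclose(std.fluorescence.to_numpy(), adl.fluorescence.to_numpy())
        assert np.allclose(adc.fluorescence.to_numpy(), 0.0)

    def test_fraction_zero_matches_control_in_expectation(self):
        cfg = SynthLuminexConfig(
            analytes={"X": (500.0, 0.0)}, regions=("CTX",),
            bait_rel_abundance={"CTX": 1.0}, wells_per_region=400,
            plate_noise_cv=0.1, blank_level=100.0, seed=1,
        )
        _, adl, adc, _ = generate_luminex_dataset(cfg)
        m_l = adl.fluorescence.to_numpy().mean()
        m_c = adc.fluorescence.to_numpy().mean()
        assert abs(m_l - m_c) < 3 * 100.0 * 0.1 / np.sqrt(400) * 2

    def test_determinism(self):
        cfg = SynthLuminexConfig(seed=5)
        a = generate_luminex_dataset(cfg)
        b = generate_luminex_dataset(cfg)
        for pa, pb in zip(a[:3], b[:3]):
            assert pa.fluorescence.equals(pb.fluorescence)
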