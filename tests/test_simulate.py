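"""Synthetic cohort generator: generative arithmetic, determinism, recovery."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from fhtwohit import epi, twohit, vaf
from fhtwohit import simulate as sim
from fhtwohit.simulate import (
    GroundTruthLabel,
    Mechanism,
    SimulationConfig,
    VariantOrigin,
)


def _config(**kw):
    defaults = dict(n_samples=1, purity_range=(0.8, 0.8), depth_mean=150.0, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            _config(mechanism_weights={Mechanism.SNV_PLUS_LOH: 0.5})

    def test_purity_bounds(self):
        with pytest.raises(ValueError):
            _config(purity_range=(0.0, 0.8))
        with pytest.raises(ValueError):
            _config(purity_range=(0.9, 0.8))

    def test_depth_minimum(self):
        with pytest.raises(ValueError):
            _config(depth_mean=0.5)

    def test_biallelic_label_consistency(self):
        with pytest.raises(ValueError):
            GroundTruthLabel("S", Mechanism.BIALLELIC_DELETION, 0.8, 1, VariantOrigin.NONE)
        with pytest.raises(ValueError):
            GroundTruthLabel("S", Mechanism.BIALLELIC_DELETION, 0.8, 0, VariantOrigin.SOMATIC)


class TestSimulateSample:
    def test_noiseless_biallelic_deletion(self):
        """CN 0 at purity 0.8 leaves only the normal-cell signal: log2(0.2)."""
        cfg = _config(log2_noise_sd=0.0)
        label = GroundTruthLabel("S", Mechanism.BIALLELIC_DELETION, 0.8, 0, VariantOrigin.NONE)
        variants, segments = sim.simulate_sample(cfg, label)
        target = [v for v in variants if v.gene == "FH"]
        assert target == []
        gene_segs = [s for s in segments if s.overlaps(cfg.target_gene)]
        assert len(gene_segs) == 1
        assert gene_segs[0].log2_ratio == pytest.approx(math.log2(0.2), abs=1e-12)

    def test_somatic_loh_vaf_converges_to_purity(self):
        cfg = _config(depth_mean=200_000, log2_noise_sd=0.0)
        label = GroundTruthLabel("S", Mechanism.SNV_PLUS_LOH, 0.8, 1, VariantOrigin.SOMATIC)
        variants, _ = sim.simulate_sample(cfg, label)
        target = [v for v in variants if v.gene == "FH"]
        assert len(target) == 1
        assert target[0].vaf == pytest.approx(0.8, abs=0.01)

    def test_germline_loh_expected_vaf(self):
        """Germline het with LOH at purity 0.8: expected VAF 0.9."""
        cfg = _config(depth_mean=200_000, log2_noise_sd=0.0)
        label = GroundTruthLabel("S", Mechanism.GERMLINE_PLUS_LOH, 0.8, 1, VariantOrigin.GERMLINE)
        variants, _ = sim.simulate_sample(cfg, label)
        target = [v for v in variants if v.gene == "FH"]
        assert target[0].vaf == pytest.approx(0.9, abs=0.01)

    def test_heterogeneous_sample_depresses_vaf_and_log2(self):
        cfg = _config(depth_mean=200_000, log2_noise_sd=0.0)
        label = GroundTruthLabel("S", Mechanism.HETEROGENEOUS, 0.8, 1, VariantOrigin.SOMATIC)
        variants, segments = sim.simulate_sample(cfg, label)
        target = [v for v in variants if v.gene == "FH"][0]
        gene_seg = [s for s in segments if s.overlaps(cfg.target_gene)][0]
        assert target.vaf == pytest.approx(0.4, abs=0.01)  # purity * subclone fraction
        mono = math.log2(0.6)
        biall = math.log2(0.2)
        assert biall < gene_seg.log2_ratio < mono

    def test_empirical_vaf_mean_within_three_se(self):
        """1,000 replicate somatic-LOH samples at TP 0.8: mean VAF ~ 0.8."""
        cfg = _config(depth_mean=150, log2_noise_sd=0.0)
        label = GroundTruthLabel("S", Mechanism.SNV_PLUS_LOH, 0.8, 1, VariantOrigin.SOMATIC)
        rng = np.random.default_rng(123)
        vafs = []
        for _ in range(1000):
            variants, _ = sim.simulate_sample(cfg, label, rng)
            vafs.append([v for v in variants if v.gene == "FH"][0].vaf)
        se = np.std(vafs, ddof=1) / math.sqrt(len(vafs))
        assert abs(np.mean(vafs) - 0.8) <= 3 * se


class TestSimulateCohort:
    def test_empty_cohort(self):
        tables = sim.simulate_cohort(_config(n_samples=0))
        assert tables.variants.empty and tables.segments.empty and tables.labels.empty

    def test_quota_assignment_pins_cohort_composition(self):
        """13 samples at weights 8/13 and 5/13: exactly 8 carry a target SNV."""
        cfg = _config(
            n_samples=13,
            mechanism_weights={
                Mechanism.SNV_PLUS_LOH: 8 / 13,
                Mechanism.BIALLELIC_DELETION: 5 / 13,
            },
        )
        tables = sim.simulate_cohort(cfg)
        with_snv = tables.variants.query("gene == 'FH'")["sample_id"].nunique()
        assert with_snv == 8
        assert (tables.labels.mechanism == "biallelic_deletion").sum() == 5

    def test_same_seed_bit_identical(self):
        cfg = _config(n_samples=10, purity_range=(0.7, 0.9), seed=99)
        a, b = sim.simulate_cohort(cfg), sim.simulate_cohort(cfg)
        assert a.variants.equals(b.variants)
        assert a.segments.equals(b.segments)
        assert a.labels.equals(b.labels)

    def test_background_and_passenger_records_present(self):
        cfg = _config(n_samples=4)
        tables = sim.simulate_cohort(cfg)
        assert (tables.variants.gene == "TP53").any()
        assert (tables.segments.chrom != "chr1").any()

    def test_noiseless_end_to_end_mechanism_recovery(self):
        """With no log2 noise and deep coverage, the two-hit classifier plus
        origin call recover every non-heterogeneous label exactly."""
        cfg = SimulationConfig(
            n_samples=40,
            purity_range=(0.8, 0.8),
            depth_mean=10_000,
            log2_noise_sd=0.0,
            seed=7,
            mechanism_weights={
                Mechanism.SNV_PLUS_LOH: 0.4,
                Mechanism.BIALLELIC_DELETION: 0.3,
                Mechanism.HETEROGENEOUS: 0.1,
                Mechanism.GERMLINE_PLUS_LOH: 0.2,
            },
        )
        tables = sim.simulate_cohort(cfg)
        expected = {
            "snv_plus_loh": ("snv_plus_loh", "somatic"),
            "biallelic_deletion": ("biallelic_deletion", "none"),
            "germline_plus_loh": ("snv_plus_loh", "germline"),
        }
        for label in tables.ground_truth:
            vs = [v for v in tables.variant_calls if v.sample_id == label.sample_id]
            ss = [s for s in tables.segment_calls if s.sample_id == label.sample_id]
            call = twohit.classify_sample(vs, ss, cfg.target_gene, purity=0.8)
            if label.mechanism is Mechanism.HETEROGENEOUS:
                assert call.heterogeneity_flag
                continue
            gene_vs = [v for v in vs if v.gene == "FH"]
            origin = (
                vaf.classify_origin(gene_vs[0], purity=0.8).favored_origin.value
                if gene_vs
                else "none"
            )
            assert (call.status.value, origin) == expected[label.mechanism.value]

    def test_passenger_vafs_recover_purity(self):
        cfg = _config(n_samples=30, depth_mean=5000, n_passengers=2)
        tables = sim.simulate_cohort(cfg)
        passengers = tables.variants.query("gene == 'TP53'")["vaf"]
        est = vaf.purity_from_somatic_het(passengers.tolist())
        assert est.mean == pytest.approx(0.8, abs=0.02)


class TestPopulationTable:
    def test_zero_carrier_freq_gives_zero_counts(self):
        recs = sim.simulate_population_table(20, 0.0, 10_000, seed=0)
        assert all(r.allele_count == 0 for r in recs if r.is_pathogenic)

    def test_only_pathogenic_classes_contribute(self):
        recs = sim.simulate_population_table(20, 1 / 3000, 100_000, seed=1)
        assert any(not r.is_pathogenic for r in recs)
        assert all(r.acmg_class in (4, 5) for r in recs if r.is_pathogenic)

    def test_recovery_within_three_se_over_100_seeds(self):
        truth = 1 / 3000
        ests = [
            epi.carrier_frequency(sim.simulate_population_table(50, truth, 50_000, seed=s))
            for s in range(100)
        ]
        se_mean = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - truth) <= 3 * se_mean

    def test_cohort_size_validated(self):
        with pytest.raises(ValueError):
            sim.simulate_population_table(10, 1e-3, 0, seed=0)


class TestToyFixtures:
    def test_transcript_is_well_formed(self, toy):
        t = toy.transcript
        assert len(t.cds_sequence) % 3 == 0
        assert t.cds_sequence.startswith("ATG")
        assert t.cds_sequence[-3:] in ("TAA", "TAG", "TGA")
        assert "*" not in t.protein_sequence
        assert len(t.exons) >= 3

    def test_helix_spacing_exact(self, toy):
        d = np.linalg.norm(np.diff(toy.structure.coords, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.01)

    def test_tight_triple_tighter_than_random_expectation(self, toy):
        s = toy.structure
        obs = pdist(s.coords[[r - 1 for r in toy.tight_triple]]).mean()
        all_triples = [
            pdist(s.coords[list(c)]).mean()
            for c in combinations(range(len(s)), 3)
        ]
        assert obs < np.mean(all_triples)

    def test_fixtures_deterministic(self):
        a = sim.make_toy_fixtures(seed=4)
        b = sim.make_toy_fixtures(seed=4)
        assert a.transcript.cds_sequence == b.transcript.cds_sequence
        assert np.array_equal(a.structure.coords, b.structure.coords)
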