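"""log2 copy-ratio interpretation: CN conversion, sizes, recurrence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhtwohit import cnv
from fhtwohit.cnv import CnSegment, GeneInterval


@pytest.mark.parametrize(
    "cn, purity, expected",
    [
        (2, 0.3, 0.0),
        (2, 1.0, 0.0),
        (1, 0.8, math.log2(0.6)),
        (0, 1.0, math.log2(1e-3)),  # floored ratio, prints as -9.97
    ],
)
def test_expected_log2(cn, purity, expected):
    assert cnv.expected_log2(cn, purity) == pytest.approx(expected, abs=1e-12)


def test_expected_log2_floor_prints_as_minus_9_97():
    assert round(cnv.expected_log2(0, 1.0), 2) == -9.97


def test_expected_log2_validation():
    with pytest.raises(ValueError):
        cnv.expected_log2(1, 0.8, ploidy=0)
    with pytest.raises(ValueError):
        cnv.expected_log2(-1, 0.8)


@pytest.mark.parametrize(
    "log2, purity, expected_cn",
    [
        (-0.85, 0.8, 1),
        (-9.97, 0.8, 0),
        # (2^-1.87 * 2 - 0.4) / 0.8 ~ 0.18 -> rounds to 0, in tension with a
        # monoallelic printed call: the two-hit classifier's flag case
        (-1.87, 0.8, 0),
        (-1.02, 0.8, 1),
        (0.0, 0.8, 2),
        (0.46, 0.8, 3),
    ],
)
def test_log2_to_cn(log2, purity, expected_cn):
    assert cnv.log2_to_cn(log2, purity) == expected_cn


@pytest.mark.parametrize("cn", range(7))
@pytest.mark.parametrize("purity", [0.2, 0.5, 0.8, 1.0])
def test_noiseless_round_trip(cn, purity):
    assert cnv.log2_to_cn(cnv.expected_log2(cn, purity), purity) == cn


@pytest.mark.parametrize(
    "start, end, kb",
    [
        (241661127, 241677014, 15.9),
        (241680481, 243088226, 1407.7),
        (206482721, 249240121, 42757.4),
    ],
)
def test_segment_size_kb(start, end, kb):
    seg = CnSegment("S", "chr1", start, end, -1.0)
    assert cnv.segment_size_kb(seg) == kb


def test_degenerate_segment_rejected():
    with pytest.raises(ValueError):
        CnSegment("S", "chr1", 100, 100, -1.0)
    with pytest.raises(ValueError):
        CnSegment("S", "chr1", 100, 50, -1.0)


@given(
    start=st.integers(1, 10**8),
    length=st.integers(100, 10**7),
    shift=st.integers(0, 10**6),
)
@settings(max_examples=100, deadline=None)
def test_segment_size_translation_invariant_and_positive(start, length, shift):
    a = CnSegment("S", "chr1", start, start + length, 0.0)
    b = CnSegment("S", "chr1", start + shift, start + shift + length, 0.0)
    assert cnv.segment_size_kb(a) == cnv.segment_size_kb(b) > 0


class TestSummarizeLosses:
    def test_reference_cohort_extremes_and_median(self, reference_cohort):
        summary = cnv.summarize_losses(
            reference_cohort.segments, reference_cohort.gene
        )
        assert summary.n_segments == 14
        assert summary.min_kb == 15.9
        assert summary.max_kb == 42757.4
        # printed median 4,897.1 vs coordinate-recomputed 4,897.2
        assert summary.median_kb == pytest.approx(4897.1, abs=0.2)

    def test_per_sample_cn_is_minimum_over_segments(self, reference_cohort):
        summary = cnv.summarize_losses(
            reference_cohort.segments, reference_cohort.gene
        )
        assert summary.cn_at_gene["S12"] == 0
        assert summary.cn_at_gene["S06"] == 1

    def test_single_segment_collapses_statistics(self):
        seg = CnSegment("S", "chr1", 241661127, 241677014, -1.0, integer_cn=1)
        gene = GeneInterval("FH", "chr1", 241660903, 241683844)
        summary = cnv.summarize_losses([seg], gene)
        assert summary.min_kb == summary.max_kb == summary.median_kb == 15.9

    def test_empty_input(self):
        gene = GeneInterval("FH", "chr1", 241660903, 241683844)
        summary = cnv.summarize_losses([], gene)
        assert summary.n_segments == 0 and summary.min_kb is None


def _loss_segments(sample_ids, gene, log2=-0.8):
    return [
        CnSegment(s, gene.chrom, gene.start - 1000, gene.end + 1000, log2)
        for s in sample_ids
    ]


def _neutral_segments(sample_ids, gene):
    return [
        CnSegment(s, gene.chrom, gene.start - 1000, gene.end + 1000, 0.0)
        for s in sample_ids
    ]


class TestRecurrence:
    gene_a = GeneInterval("A", "chr1", 1000, 2000)
    gene_b = GeneInterval("B", "chr2", 1000, 2000)

    def test_identical_cohorts_give_p_one(self):
        cases = _loss_segments([f"c{i}" for i in range(5)], self.gene_a)
        controls = _loss_segments([f"k{i}" for i in range(5)], self.gene_a)
        df = cnv.recurrence_test(cases, controls, [self.gene_a, self.gene_b])
        assert (df["p_adjusted"] == 1.0).all()

    def test_exclusive_deletion_matches_hand_fisher(self):
        """13/13 cases vs 0/15 controls deleted: p is the hypergeometric point mass."""
        cases = _loss_segments([f"c{i}" for i in range(13)], self.gene_a)
        controls = _neutral_segments([f"k{i}" for i in range(15)], self.gene_a)
        genes = [self.gene_a, self.gene_b]
        df = cnv.recurrence_test(cases, controls, genes).set_index("gene")
        # only the most extreme table has probability <= observed
        p_exact = 1 / math.comb(28, 13)
        assert df.loc["A", "p_value"] == pytest.approx(p_exact, rel=1e-9)
        assert df.loc["A", "p_adjusted"] == pytest.approx(2 * p_exact, rel=1e-9)
        assert df.loc["A", "p_adjusted"] < 0.05
        assert df.loc["B", "p_adjusted"] == 1.0

    def test_no_affected_samples_anywhere(self):
        cases = _neutral_segments(["c1", "c2"], self.gene_a)
        controls = _neutral_segments(["k1", "k2"], self.gene_a)
        df = cnv.recurrence_test(cases, controls, [self.gene_a])
        assert (df["p_value"] == 1.0).all()

    def test_pvalues_in_unit_interval_and_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        genes = [GeneInterval(f"G{i}", "chr1", 1 + 10_000 * i, 5_000 + 10_000 * i) for i in range(6)]
        cases, controls = [], []
        for i, g in enumerate(genes):
            hit_cases = rng.choice(8, size=rng.integers(0, 8), replace=False)
            for c in hit_cases:
                cases.append(CnSegment(f"c{c}", g.chrom, g.start, g.end, -0.8))
        cases += _neutral_segments([f"c{i}" for i in range(8)], genes[0])
        controls += _neutral_segments([f"k{i}" for i in range(8)], genes[0])
        df = cnv.recurrence_test(cases, controls, genes)
        assert df["p_value"].between(0, 1).all()
        assert (df["p_adjusted"] >= df["p_value"] - 1e-15).all()

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            cnv.recurrence_test(
                _loss_segments(["c"], self.gene_a),
                _loss_segments(["k"], self.gene_a),
                [],
            )

    def test_gain_direction(self):
        cases = [
            CnSegment(f"c{i}", self.gene_a.chrom, self.gene_a.start, self.gene_a.end, 0.5)
            for i in range(6)
        ]
        controls = _neutral_segments([f"k{i}" for i in range(6)], self.gene_a)
        df = cnv.recurrence_test(cases, controls, [self.gene_a], direction="gain")
        assert df.loc[0, "case_affected"] == 6
        assert df.loc[0, "p_value"] < 0.05


def test_parse_region_call():
    seg = cnv.parse_region_call("chr1:g.241661127_241677014×1", sample_id="S05")
    assert (seg.chrom, seg.start, seg.end, seg.integer_cn) == ("chr1", 241661127, 241677014, 1)
    seg2 = cnv.parse_region_call("chr1:g.100_200x0")
    assert seg2.integer_cn == 0
    with pytest.raises(ValueError):
        cnv.parse_region_call("chr1:241661127-241677014")
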