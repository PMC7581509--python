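"""Bundled reference inputs: a published 13-tumor FH-deficient uterine
leiomyoma panel-sequencing summary and the population figures used by the
epidemiological chain.

These are desk-scale printed values (allele read counts, HGVS-style
copy-number region calls with log2 ratios, curated pathogenic-set
composition, prevalence and screening figures) — the inputs every worked
example and regression test in this package runs on.  No read-level data are
included.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cnv import CnSegment, GeneInterval, parse_region_call
from .vaf import Consequence, VariantCall

__all__ = [
    "FH_GENE_HG19",
    "ReferenceCohort",
    "fh_ul_cohort",
    "EPI_FIGURES",
]

#: FH gene interval (1q43, hg19), 1-based inclusive.
FH_GENE_HG19 = GeneInterval("FH", "chr1", 241_660_903, 241_683_844)

# (sample, hgvs_c, consequence, alt_reads, total_reads, printed_vaf)
_SNV_ROWS = [
    ("S01", "c.944T>C p.(Leu315Pro)", "missense", 137, 178, 0.767),
    ("S02", "c.587A>C p.(His196Pro)", "missense", 108, 140, 0.771),
    ("S03", "c.379-2A>G p.0?", "splice", 110, 141, 0.780),
    ("S05", "c.587A>T p.(His196Leu)", "missense", 74, 167, 0.443),
    ("S06", "c.457delG p.(Val153*)", "frameshift", 153, 193, 0.793),
    ("S07", "c.824G>C p.(Gly275Ala)", "missense", 10, 19, 0.526),
    ("S09", "c.1236G>A p.(Met412Ile)", "missense", 104, 136, 0.765),
    ("S10", "c.817G>A p.(Ala273Thr)", "missense", 93, 154, 0.604),
]

# (sample, region-call string, printed log2)
_SEG_ROWS = [
    ("S01", "chr1:g.208278362_244894272x1", -0.77),
    ("S02", "chr1:g.221246882_247101663x1", -0.85),
    ("S03", "chr1:g.237286185_242686882x1", -1.26),
    ("S04", "chr1:g.237694880_243690241x0", -9.97),
    ("S05", "chr1:g.241661127_241677014x1", -1.87),
    ("S06", "chr1:g.206682236_249240121x1", -1.02),
    ("S07", "chr1:g.206482721_249240121x1", -0.87),
    ("S09", "chr1:g.208078846_249240121x1", -1.08),
    ("S10", "chr1:g.237490532_241884194x1", -0.90),
    ("S11", "chr1:g.240082627_242686882x0", -5.88),
    ("S12", "chr1:g.241661127_241677014x0", -9.97),
    ("S12", "chr1:g.241680481_243088226x0", -5.35),
    ("S14", "chr1:g.241266127_244292257x0", -5.31),
    ("S16", "chr1:g.238701877_242084866x0", -9.97),
]

#: VAFs of the two clonal somatic TP53 hits in sample S04 (purity anchors).
_TP53_VAFS = [0.408, 0.370]

_ALL_SAMPLES = [
    "S01", "S02", "S03", "S04", "S05", "S06", "S07",
    "S09", "S10", "S11", "S12", "S14", "S16",
]

#: The six residues of the likely-somatic missense variants (transcript
#: numbering), and the three forming the reported tight spatial cluster.
MISSENSE_RESIDUES = [315, 196, 275, 412, 273, 196]
CLUSTER_RESIDUES = [315, 275, 273]
#: Two independently reported oligomerization-defective missense residues
#: used in the colocalization analysis.
COLOCALIZATION_RESIDUES = [308, 318]


@dataclass
class ReferenceCohort:
    variants: list[VariantCall]
    segments: list[CnSegment]
    sample_ids: list[str]
    tp53_vafs: list[float]
    gene: GeneInterval

    @property
    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": v.sample_id,
                    "gene": v.gene,
                    "hgvs_c": v.hgvs_c,
                    "consequence": v.consequence.value,
                    "alt_reads": v.alt_reads,
                    "total_reads": v.total_reads,
                    "vaf": v.vaf,
                }
                for v in self.variants
            ]
        )

    @property
    def segment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": s.sample_id,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "log2": s.log2_ratio,
                    "integer_cn": s.integer_cn,
                }
                for s in self.segments
            ]
        )


def fh_ul_cohort(use_printed_vaf: bool = True) -> ReferenceCohort:
    """The 13-sample FH-deficient UL reference cohort.

    With ``use_printed_vaf`` each variant carries the printed three-decimal
    allele fraction (validated against its read counts to within rounding);
    otherwise the VAF is recomputed exactly from the counts.  Segment records
    keep both the printed log2 ratio and the printed integer CN call.
    """
    variants = []
    for sid, hgvs, csq, alt, total, vaf in _SNV_ROWS:
        variants.append(
            VariantCall(
                sample_id=sid,
                chrom="chr1",
                pos=FH_GENE_HG19.start,  # per-variant genomic position not printed
                ref="N",
                alt="N",
                alt_reads=alt,
                total_reads=total,
                vaf=vaf if use_printed_vaf else None,
                gene="FH",
                hgvs_c=hgvs,
                consequence=Consequence(csq),
            )
        )
    segments = [
        parse_region_call(text, sample_id=sid, log2_ratio=log2)
        for sid, text, log2 in _SEG_ROWS
    ]
    return ReferenceCohort(
        variants=variants,
        segments=segments,
        sample_ids=list(_ALL_SAMPLES),
        tp53_vafs=list(_TP53_VAFS),
        gene=FH_GENE_HG19,
    )


#: Published figures for the carrier-frequency / epidemiology chain:
#: curated pathogenic-set composition, carrier-frequency bounds from two
#: population databases, UL prevalence and FH-deficient share, and the
#: morphology-based screening series (5 carriers in 2,060 screened).
EPI_FIGURES = {
    "pathogenic_counts": {
        "truncating": 130,
        "splice": 36,
        "missense": 104,
        "inframe_indel": 10,
    },
    "carrier_freq_low": 1 / 3247,   # gnomAD-derived bound
    "carrier_freq_high": 1 / 2563,  # BRAVO-derived bound
    "prev_ul": 0.70,
    "prop_fhd_ul_low": 0.004,
    "prop_fhd_ul_high": 0.016,
    "screen_hits": 5,
    "screen_n": 2060,
    "n_cases": 13,
}
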