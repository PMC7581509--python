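"""Synthetic tumor cohorts, population tables, and toy transcript/structure
fixtures with the statistical structure the downstream analyses assume.

The cohort generator is the generative inverse of the analysis models: for a
sample of purity TP it draws binomial read counts at the model-implied VAF
(``TP + (1 - TP) * z`` under LOH, ``TP / 2`` for clonal heterozygous
passengers) and Gaussian-noise log2 ratios around the purity-mixture copy
ratio implied by the integer copy number at the target gene.  Every sample
carries a ground-truth label (mechanism, purity, copy number, variant
origin), so downstream recovery is directly testable.

Defaults mirror the motivating study design: a 13-sample cohort with
mechanism quota 8/13 SNV + LOH and 5/13 biallelic deletion, purity centered
on 0.8, per-variant depth Poisson around 150 (floored at the DP >= 10 filter
boundary), and log2 noise matching the spread of observed monoallelic
losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .cnv import RATIO_FLOOR, CnSegment, GeneInterval
from .saturation import DomainMap, TranscriptModel
from .structure import StructureModel
from .vaf import Consequence, VariantCall, expected_vaf

__all__ = [
    "Mechanism",
    "VariantOrigin",
    "SimulationConfig",
    "GroundTruthLabel",
    "CohortTables",
    "ToyFixtures",
    "FH_GENE",
    "simulate_sample",
    "simulate_cohort",
    "simulate_population_table",
    "make_toy_fixtures",
    "make_helix_structure",
]

#: Target-gene interval used by default (FH on 1q43, hg19).
FH_GENE = GeneInterval("FH", "chr1", 241_660_903, 241_683_844)

#: Passenger-variant locus (TP53-like, chr17) for purity cross-checks.
_PASSENGER_GENE = GeneInterval("TP53", "chr17", 7_571_720, 7_590_868)

_MIN_DEPTH = 10


class Mechanism(str, Enum):
    SNV_PLUS_LOH = "snv_plus_loh"
    BIALLELIC_DELETION = "biallelic_deletion"
    HETEROGENEOUS = "heterogeneous"
    GERMLINE_PLUS_LOH = "germline_plus_loh"


class VariantOrigin(str, Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    NONE = "none"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic cohort."""

    n_samples: int = 13
    purity_range: tuple[float, float] = (0.75, 0.85)
    depth_mean: float = 150.0
    mechanism_weights: dict[Mechanism, float] = field(
        default_factory=lambda: {
            Mechanism.SNV_PLUS_LOH: 8 / 13,
            Mechanism.BIALLELIC_DELETION: 5 / 13,
            Mechanism.HETEROGENEOUS: 0.0,
            Mechanism.GERMLINE_PLUS_LOH: 0.0,
        }
    )
    log2_noise_sd: float = 0.15
    seed: int = 0
    target_gene: GeneInterval = FH_GENE
    #: tumor-cell fraction of the SNV-bearing subclone in heterogeneous samples
    subclone_fraction: float = 0.5
    n_passengers: int = 1
    n_background_segments: int = 2
    assignment: str = "quota"  # or "multinomial"

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be >= 0, got {self.n_samples}")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity range must lie in (0, 1], got {self.purity_range}")
        if self.depth_mean < 1:
            raise ValueError(f"depth_mean must be >= 1, got {self.depth_mean}")
        total = sum(self.mechanism_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mechanism weights must sum to 1, got {total}")
        if any(w < 0 for w in self.mechanism_weights.values()):
            raise ValueError("mechanism weights must be non-negative")
        if not 0.0 < self.subclone_fraction < 1.0:
            raise ValueError("subclone_fraction must be in (0, 1)")
        if self.assignment not in ("quota", "multinomial"):
            raise ValueError(f"assignment must be 'quota' or 'multinomial'")


@dataclass(frozen=True)
class GroundTruthLabel:
    sample_id: str
    mechanism: Mechanism
    true_purity: float
    true_cn_at_gene: int
    variant_origin: VariantOrigin

    def __post_init__(self) -> None:
        if not 0.0 < self.true_purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.true_purity}")
        if self.true_cn_at_gene < 0:
            raise ValueError("true CN must be >= 0")
        if self.mechanism == Mechanism.BIALLELIC_DELETION and (
            self.true_cn_at_gene != 0 or self.variant_origin != VariantOrigin.NONE
        ):
            raise ValueError(
                "biallelic_deletion implies CN 0 at the gene and no SNV/indel"
            )


def _label_for(sample_id: str, mechanism: Mechanism, purity: float) -> GroundTruthLabel:
    origin = {
        Mechanism.SNV_PLUS_LOH: VariantOrigin.SOMATIC,
        Mechanism.HETEROGENEOUS: VariantOrigin.SOMATIC,
        Mechanism.GERMLINE_PLUS_LOH: VariantOrigin.GERMLINE,
        Mechanism.BIALLELIC_DELETION: VariantOrigin.NONE,
    }[mechanism]
    cn = 0 if mechanism == Mechanism.BIALLELIC_DELETION else 1
    return GroundTruthLabel(sample_id, mechanism, purity, cn, origin)


def _draw_depth(rng: np.random.Generator, depth_mean: float) -> int:
    return max(_MIN_DEPTH, int(rng.poisson(depth_mean)))


def _draw_snv_site(rng: np.random.Generator, gene: GeneInterval) -> tuple[int, str, str]:
    pos = int(rng.integers(gene.start, gene.end + 1))
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    return pos, str(ref), str(alt)


def _noisy_log2(rng: np.random.Generator, ratio: float, sd: float) -> float:
    noise = rng.normal(0.0, sd) if sd > 0 else 0.0
    return math.log2(max(RATIO_FLOOR, ratio)) + noise


def _segment_bounds(
    rng: np.random.Generator, gene: GeneInterval
) -> tuple[int, int]:
    pad_left = int(rng.integers(5_000, 5_000_000))
    pad_right = int(rng.integers(5_000, 5_000_000))
    return max(1, gene.start - pad_left), gene.end + pad_right


def simulate_sample(
    config: SimulationConfig,
    label: GroundTruthLabel,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantCall], list[CnSegment]]:
    """Generate one sample's variant and segment calls from its ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    purity = label.true_purity
    if config.depth_mean < 1:
        raise ValueError("depth must be positive")
    gene = config.target_gene
    variants: list[VariantCall] = []
    segments: list[CnSegment] = []
    sid = label.sample_id
    mech = label.mechanism

    # --- target-gene SNV/indel ---------------------------------------------
    if mech in (Mechanism.SNV_PLUS_LOH, Mechanism.GERMLINE_PLUS_LOH, Mechanism.HETEROGENEOUS):
        if mech == Mechanism.SNV_PLUS_LOH:
            vaf_true = expected_vaf(purity, 0.0)
        elif mech == Mechanism.GERMLINE_PLUS_LOH:
            vaf_true = expected_vaf(purity, 0.5)
        else:  # subclonal SNV: present in one of the two tumor subclones
            vaf_true = purity * config.subclone_fraction
        depth = _draw_depth(rng, config.depth_mean)
        alt_reads = int(rng.binomial(depth, vaf_true))
        pos, ref, alt = _draw_snv_site(rng, gene)
        csq_choices = [Consequence.MISSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE]
        consequence = csq_choices[int(rng.choice(3, p=[0.75, 0.125, 0.125]))]
        variants.append(
            VariantCall(
                sample_id=sid,
                chrom=gene.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                alt_reads=alt_reads,
                total_reads=depth,
                gene=gene.symbol,
                consequence=Consequence(consequence),
            )
        )

    # --- target-gene copy-number segment -----------------------------------
    ploidy = 2
    if mech == Mechanism.HETEROGENEOUS:
        # two equal tumor subclones: one CN 1 (carrying the SNV), one CN 0
        # (independent second deletion), on top of the shared initial loss
        f = config.subclone_fraction
        tumor_cn = f * 1 + (1 - f) * 0
    else:
        tumor_cn = label.true_cn_at_gene
    ratio = (purity * tumor_cn + (1 - purity) * ploidy) / ploidy
    start, end = _segment_bounds(rng, gene)
    segments.append(
        CnSegment(
            sample_id=sid,
            chrom=gene.chrom,
            start=start,
            end=end,
            log2_ratio=_noisy_log2(rng, ratio, config.log2_noise_sd),
            n_markers=int(rng.integers(50, 500)),
        )
    )

    # --- passenger somatic heterozygous variants (purity anchors) ----------
    for _ in range(config.n_passengers):
        depth = _draw_depth(rng, config.depth_mean)
        vaf_true = purity / 2.0  # clonal het in tumor, absent in normal
        alt_reads = int(rng.binomial(depth, vaf_true))
        pos, ref, alt = _draw_snv_site(rng, _PASSENGER_GENE)
        variants.append(
            VariantCall(
                sample_id=sid,
                chrom=_PASSENGER_GENE.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                alt_reads=alt_reads,
                total_reads=depth,
                gene=_PASSENGER_GENE.symbol,
                consequence=Consequence.MISSENSE,
            )
        )

    # --- neutral background segments ----------------------------------------
    for i in range(config.n_background_segments):
        chrom = f"chr{int(rng.integers(2, 23))}"
        start = int(rng.integers(1_000_000, 50_000_000))
        end = start + int(rng.integers(100_000, 10_000_000))
        segments.append(
            CnSegment(
                sample_id=sid,
                chrom=chrom,
                start=start,
                end=end,
                log2_ratio=_noisy_log2(rng, 1.0, config.log2_noise_sd),
                n_markers=int(rng.integers(50, 500)),
            )
        )
    return variants, segments


@dataclass
class CohortTables:
    variants: pd.DataFrame
    segments: pd.DataFrame
    labels: pd.DataFrame
    variant_calls: list[VariantCall]
    segment_calls: list[CnSegment]
    ground_truth: list[GroundTruthLabel]


_VARIANT_COLS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "alt_reads", "total_reads", "vaf", "gene", "hgvs_c", "consequence",
]
_SEGMENT_COLS = ["sample", "chrom", "start", "end", "log2", "n_markers"]
_LABEL_COLS = ["sample_id", "mechanism", "true_purity", "true_cn_at_gene", "variant_origin"]


def _quota_counts(weights: dict[Mechanism, float], n: int) -> dict[Mechanism, int]:
    """Largest-remainder apportionment of n samples over mechanism weights."""
    mechs = list(weights)
    exact = {m: weights[m] * n for m in mechs}
    counts = {m: int(math.floor(exact[m])) for m in mechs}
    short = n - sum(counts.values())
    for m in sorted(mechs, key=lambda m: exact[m] - counts[m], reverse=True)[:short]:
        counts[m] += 1
    return counts


def simulate_cohort(config: SimulationConfig) -> CohortTables:
    """Generate a fully labelled cohort; fixed seeds reproduce bit-identically."""
    rng = np.random.default_rng(config.seed)
    mechs = list(config.mechanism_weights)
    if config.assignment == "quota":
        counts = _quota_counts(config.mechanism_weights, config.n_samples)
        assigned: list[Mechanism] = [m for m in mechs for _ in range(counts[m])]
    else:
        probs = [config.mechanism_weights[m] for m in mechs]
        assigned = [mechs[i] for i in rng.choice(len(mechs), size=config.n_samples, p=probs)]

    lo, hi = config.purity_range
    variants: list[VariantCall] = []
    segments: list[CnSegment] = []
    labels: list[GroundTruthLabel] = []
    for i, mech in enumerate(assigned):
        sid = f"S{i + 1:03d}"
        purity = float(rng.uniform(lo, hi)) if hi > lo else lo
        label = _label_for(sid, mech, purity)
        v, s = simulate_sample(config, label, rng)
        variants.extend(v)
        segments.extend(s)
        labels.append(label)

    vdf = pd.DataFrame(
        [
            {
                "sample_id": v.sample_id, "chrom": v.chrom, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "alt_reads": v.alt_reads,
                "total_reads": v.total_reads, "vaf": v.vaf, "gene": v.gene,
                "hgvs_c": v.hgvs_c, "consequence": v.consequence.value,
            }
            for v in variants
        ],
        columns=_VARIANT_COLS,
    )
    sdf = pd.DataFrame(
        [
            {
                "sample": s.sample_id, "chrom": s.chrom, "start": s.start,
                "end": s.end, "log2": s.log2_ratio, "n_markers": s.n_markers,
            }
            for s in segments
        ],
        columns=_SEGMENT_COLS,
    )
    ldf = pd.DataFrame(
        [
            {
                "sample_id": l.sample_id, "mechanism": l.mechanism.value,
                "true_purity": l.true_purity, "true_cn_at_gene": l.true_cn_at_gene,
                "variant_origin": l.variant_origin.value,
            }
            for l in labels
        ],
        columns=_LABEL_COLS,
    )
    return CohortTables(vdf, sdf, ldf, variants, segments, labels)


def simulate_population_table(
    n_variants: int,
    true_carrier_freq: float,
    cohort_size: int,
    seed: Optional[int] = None,
    n_benign: Optional[int] = None,
) -> list["PopulationVariantRecord"]:
    """Synthesize a population-variant table with a known carrier frequency.

    The target carrier frequency is split equally over ``n_variants``
    pathogenic (ACMG 4/5) variants; allele counts are binomial draws at the
    implied per-allele frequency, so the summed estimator recovers the truth
    in expectation.  Benign/VUS records (ACMG 1-3) with non-trivial allele
    counts are interleaved and must not contribute downstream.
    """
    from .epi import PopulationVariantRecord, VariantCategory

    if cohort_size < 1:
        raise ValueError(f"cohort_size must be >= 1, got {cohort_size}")
    if n_variants < 1:
        raise ValueError(f"n_variants must be >= 1, got {n_variants}")
    if not 0.0 <= true_carrier_freq <= 0.01:
        raise ValueError(
            f"true_carrier_freq must be in [0, 0.01], got {true_carrier_freq}"
        )
    rng = np.random.default_rng(seed)
    an = 2 * cohort_size
    per_allele_freq = (true_carrier_freq / n_variants) / 2.0
    cats = list(VariantCategory)
    cat_probs = [0.464, 0.129, 0.371, 0.036]
    records: list[PopulationVariantRecord] = []
    pos = 241_660_000
    for i in range(n_variants):
        ac = int(rng.binomial(an, per_allele_freq))
        pos += int(rng.integers(1, 200))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        records.append(
            PopulationVariantRecord(
                chrom="chr1",
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                allele_count=ac,
                allele_number=an,
                hom_count=0,
                acmg_class=int(rng.choice([4, 5])),
                category=cats[int(rng.choice(4, p=cat_probs))],
            )
        )
    if n_benign is None:
        n_benign = n_variants // 2
    for i in range(n_benign):
        ac = int(rng.binomial(an, 1e-3))
        pos += int(rng.integers(1, 200))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        records.append(
            PopulationVariantRecord(
                chrom="chr1",
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                allele_count=ac,
                allele_number=an,
                hom_count=0,
                acmg_class=int(rng.choice([1, 2, 3])),
                category=cats[int(rng.choice(4, p=cat_probs))],
            )
        )
    return records


# ---------------------------------------------------------------------------
# toy transcript / structure fixtures
# ---------------------------------------------------------------------------

#: Ideal alpha-helix geometry: 100 degrees twist and 1.5 A rise per residue;
#: the radius is solved so consecutive Calpha atoms sit exactly 3.8 A apart.
_HELIX_TWIST = math.radians(100.0)
_HELIX_RISE = 1.5
_CA_SPACING = 3.8
_HELIX_RADIUS = math.sqrt(_CA_SPACING**2 - _HELIX_RISE**2) / (2.0 * math.sin(_HELIX_TWIST / 2.0))

# codons avoiding stops; chosen per amino acid for reverse translation
_STOPS = {"TAA", "TAG", "TGA"}


def make_helix_structure(
    n_residues: int,
    chain: str = "A",
    amino_acids: Optional[Sequence[str]] = None,
) -> StructureModel:
    """Ideal-helix Cα trace with exact 3.8 Å consecutive spacing."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    i = np.arange(n_residues)
    coords = np.column_stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TWIST * i),
            _HELIX_RADIUS * np.sin(_HELIX_TWIST * i),
            _HELIX_RISE * i,
        ]
    )
    aas = list(amino_acids) if amino_acids is not None else ["A"] * n_residues
    return StructureModel(
        residue_ids=[(chain, int(k) + 1) for k in i],
        coords=coords,
        amino_acids=aas,
    )


@dataclass
class ToyFixtures:
    transcript: TranscriptModel
    structure: StructureModel
    domains: DomainMap
    #: three consecutive residues forming a deliberately tight spatial triple
    tight_triple: tuple[int, int, int]
    genomic_sequence: str


def make_toy_fixtures(seed: int = 0, n_residues: int = 60) -> ToyFixtures:
    """Toy multi-exon transcript, ideal-helix structure, and domain map.

    The transcript has four exons, a CDS of ``3 * (n_residues + 1)`` bases
    (start codon through stop codon, no internal stops), embedded in a random
    genomic sequence; the structure is an ideal helix over the protein's
    residues with residues 5-7 designated as the tight clustering triple.
    """
    if n_residues < 12:
        raise ValueError("toy protein must have at least 12 residues")
    rng = np.random.default_rng(seed)

    # random codons, no stops; first codon ATG, final codon TAA
    codons = ["ATG"]
    bases = list("ACGT")
    while len(codons) < n_residues:
        codon = "".join(rng.choice(bases, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    cds = "".join(codons)

    # four exons separated by >=30 bp introns in a toy genomic context
    cds_len = len(cds)
    cuts = sorted(rng.choice(np.arange(3, cds_len - 3), size=3, replace=False))
    pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [cds_len])]
    flank = 25
    genomic_parts: list[str] = ["".join(rng.choice(bases, size=flank))]
    exons: list[tuple[int, int]] = []
    cursor = flank
    for j, piece in enumerate(pieces):
        exons.append((cursor + 1, cursor + len(piece)))
        genomic_parts.append(piece)
        cursor += len(piece)
        intron_len = int(rng.integers(30, 80))
        if j < len(pieces) - 1:
            genomic_parts.append("".join(rng.choice(bases, size=intron_len)))
            cursor += intron_len
    genomic_parts.append("".join(rng.choice(bases, size=flank)))
    genome = "".join(genomic_parts)

    transcript = TranscriptModel.from_genomic(
        genome, exons, strand="+", id="TOY-1", chrom="chrT"
    )

    protein = transcript.protein_sequence
    structure = make_helix_structure(len(protein), amino_acids=list(protein))

    third = len(protein) // 3
    domains = DomainMap(
        domains=[
            ("TransPep", 1, max(2, third // 3)),
            ("Lyase", max(2, third // 3) + 1, 2 * third),
            ("FumC-C", 2 * third + 4, len(protein)),
        ]
    )
    return ToyFixtures(
        transcript=transcript,
        structure=structure,
        domains=domains,
        tight_triple=(5, 6, 7),
        genomic_sequence=genome,
    )
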