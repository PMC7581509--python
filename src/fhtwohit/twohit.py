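"""Per-sample integration of small variants and copy-number calls at a target
gene into a two-hit tumor-suppressor status.

The decision table follows the Knudson two-hit logic for a recessive tumor
suppressor: an SNV/indel on one allele with loss of the other
(``snv_plus_loh``), loss of both alleles (``biallelic_deletion``), a single
hit of either kind, or none.  Copy state at the gene is the purity-corrected
integer CN of the deepest overlapping segment (pre-set integer calls are
honored when present).

Intratumoral heterogeneity leaves two signatures that the classifier flags:
(a) a deletion log2 ratio strictly between the clonal biallelic expectation
at the assumed purity and the monoallelic band — deeper than one clonal lost
allele, shallower than two — and (b) a target-gene SNV whose implied somatic
purity (its VAF, under the LOH model) sits far below the cohort purity.
Either signature means distinct subclones likely carry different second hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .cnv import CnSegment, GeneInterval, expected_log2, log2_to_cn
from .vaf import DEFAULT_PURITY, VariantCall, apply_read_filters

__all__ = [
    "TwoHitStatus",
    "TwoHitCall",
    "CohortSummary",
    "Bands",
    "classify_sample",
    "summarize_cohort",
]


class TwoHitStatus(str, Enum):
    SNV_PLUS_LOH = "snv_plus_loh"
    BIALLELIC_DELETION = "biallelic_deletion"
    SINGLE_HIT = "single_hit"
    NONE = "none"


@dataclass(frozen=True)
class Bands:
    """log2 copy-ratio bands used by the heterogeneity flag.

    The monoallelic band brackets observed single-allele losses at purity
    ~0.8; ``biallelic_max`` is where unambiguous biallelic losses start.  The
    flag gap is bounded below by whichever is higher of ``biallelic_max`` and
    the purity-implied clonal biallelic expectation, so a clean clonal
    biallelic deletion never flags.
    """

    mono_low: float = -1.5
    mono_high: float = -0.3
    biallelic_max: float = -2.5
    #: VAF deficit below cohort purity that flags a subclonal SNV.
    het_vaf_margin: float = 0.3


@dataclass
class TwoHitCall:
    sample_id: str
    status: TwoHitStatus
    hit1: Optional[str] = None
    hit2: Optional[str] = None
    heterogeneity_flag: bool = False
    notes: list[str] = field(default_factory=list)
    cn_at_gene: Optional[int] = None
    deepest_log2: Optional[float] = None


def _describe_variant(v: VariantCall) -> str:
    label = v.hgvs_c or f"{v.chrom}:{v.pos}{v.ref}>{v.alt}"
    return f"{v.consequence.value} {label} (VAF {v.vaf:.3f})"


def _describe_segment(s: CnSegment, cn: int) -> str:
    return f"{s.chrom}:g.{s.start}_{s.end}x{cn} (log2 {s.log2_ratio:.2f})"


def classify_sample(
    variants: Iterable[VariantCall],
    segments: Iterable[CnSegment],
    gene: GeneInterval,
    purity: float = DEFAULT_PURITY,
    bands: Bands = Bands(),
    ploidy: int = 2,
    sample_id: Optional[str] = None,
    prefiltered: bool = False,
) -> TwoHitCall:
    """Classify one sample's two-hit status at ``gene``.

    ``variants`` and ``segments`` are one sample's calls; records away from
    the target gene are ignored.  Unless ``prefiltered``, the standard DP/AF
    read filters are applied first.  Pre-set ``integer_cn`` values on
    segments are honored; otherwise CN is called from log2 at the stated
    purity.
    """
    variants = list(variants)
    if not prefiltered:
        variants = apply_read_filters(variants)
    gene_vars = [
        v
        for v in variants
        if v.gene == gene.symbol
        or (v.chrom == gene.chrom and gene.start <= v.pos <= gene.end)
    ]
    overlapping = [s for s in segments if s.overlaps(gene)]
    sid = sample_id
    if sid is None:
        for rec in gene_vars + overlapping:
            sid = rec.sample_id
            break
    call = TwoHitCall(sample_id=sid or "", status=TwoHitStatus.NONE)

    def seg_cn(s: CnSegment) -> int:
        if s.integer_cn is not None:
            return s.integer_cn
        return log2_to_cn(s.log2_ratio, purity, ploidy)

    deepest: Optional[CnSegment] = None
    cn = ploidy
    if overlapping:
        deepest = min(overlapping, key=lambda s: s.log2_ratio)
        call.deepest_log2 = deepest.log2_ratio
        cn = min(seg_cn(s) for s in overlapping)
    call.cn_at_gene = cn

    has_snv = bool(gene_vars)
    if len(gene_vars) > 1:
        call.notes.append(
            f"{len(gene_vars)} target-gene SNVs/indels present; only one expected"
        )
    snv = max(gene_vars, key=lambda v: v.vaf or 0.0) if has_snv else None

    # heterogeneity gap: deeper than clonal monoallelic, shallower than
    # clonal biallelic at this purity
    gap_low = max(bands.biallelic_max, expected_log2(0, purity, ploidy))
    log2 = deepest.log2_ratio if deepest is not None else None
    in_gap = log2 is not None and gap_low < log2 < bands.mono_low
    if in_gap:
        call.heterogeneity_flag = True
        call.notes.append(
            f"deletion log2 {log2:.2f} lies between the clonal biallelic "
            f"expectation ({gap_low:.2f}) and the monoallelic band "
            f"(>= {bands.mono_low}): subclonal second hits suspected"
        )

    if cn == 0 and not in_gap:
        call.status = TwoHitStatus.BIALLELIC_DELETION
        call.hit1 = _describe_segment(deepest, 0)
        call.hit2 = "second allele of the same deletion(s)"
        if has_snv:
            call.notes.append(
                "SNV/indel co-occurs with a biallelic deletion: "
                + _describe_variant(snv)
                + "; copy state dominates, anomaly surfaced"
            )
    elif cn == 0 and in_gap and not has_snv:
        # formula says biallelic but the log2 depth is ambiguous
        call.status = TwoHitStatus.BIALLELIC_DELETION
        call.hit1 = _describe_segment(deepest, 0)
        call.hit2 = "second allele of the same deletion(s)"
    elif has_snv and deepest is not None and (cn == 1 or in_gap):
        # an in-gap deletion with an SNV is read as the main clone's
        # monoallelic second hit plus subclonal extra events (flagged above)
        call.status = TwoHitStatus.SNV_PLUS_LOH
        call.hit1 = _describe_variant(snv)
        call.hit2 = _describe_segment(deepest, 1)
    elif cn < ploidy and deepest is not None:
        call.status = TwoHitStatus.SINGLE_HIT
        call.hit1 = _describe_segment(deepest, cn)
    elif has_snv:
        call.status = TwoHitStatus.SINGLE_HIT
        call.hit1 = _describe_variant(snv)
    else:
        call.status = TwoHitStatus.NONE

    if snv is not None and (snv.vaf or 0.0) < purity - bands.het_vaf_margin:
        call.heterogeneity_flag = True
        call.notes.append(
            f"SNV VAF {snv.vaf:.3f} implies somatic purity far below the "
            f"assumed {purity:.2f}: subclonal variant suspected"
        )
    return call


@dataclass
class CohortSummary:
    n_samples: int
    counts: dict[str, int]
    fractions: dict[str, float]
    snv_fraction: float  # fraction of samples whose first hit is an SNV/indel
    n_flagged: int


def summarize_cohort(calls: Sequence[TwoHitCall]) -> CohortSummary:
    """Cohort-level counts and fractions per two-hit status."""
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one two-hit call to summarize")
    counts = {s.value: 0 for s in TwoHitStatus}
    for c in calls:
        counts[c.status.value] += 1
    n = len(calls)
    fractions = {k: v / n for k, v in counts.items()}
    n_snv = sum(1 for c in calls if c.status == TwoHitStatus.SNV_PLUS_LOH)
    return CohortSummary(
        n_samples=n,
        counts=counts,
        fractions=fractions,
        snv_fraction=n_snv / n,
        n_flagged=sum(1 for c in calls if c.heterogeneity_flag),
    )
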