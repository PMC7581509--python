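"""Purity-corrected interpretation of log2 copy-ratio segments.

The expected copy ratio of a segment with integer tumor copy number ``cn`` in
a specimen of purity ``p`` (diploid normal admixture) is

    ratio = (p * cn + (1 - p) * ploidy) / ploidy

so a monoallelic loss (cn = 1) at p = 0.8 sits at log2(0.6) ~ -0.74 and a
biallelic loss (cn = 0) at log2(0.2) ~ -2.32.  Copy ratios are floored at
1e-3 (log2 ~ -9.97) before taking logs, which is where fully clonal biallelic
deletions in pure specimens land.  Inverting the same relation and rounding
half-away-from-zero converts observed log2 ratios back to integer copy
numbers.

Coordinates are 1-based inclusive throughout, matching HGVS-style
``chr1:g.start_end×N`` region notation; segment sizes are ``end - start``
reported in kilobases to 0.1 kb.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .vaf import DEFAULT_PURITY

__all__ = [
    "RATIO_FLOOR",
    "LOG2_FLOOR",
    "CnSegment",
    "GeneInterval",
    "LossSummary",
    "expected_log2",
    "log2_to_cn",
    "segment_size_kb",
    "summarize_losses",
    "recurrence_test",
    "parse_region_call",
]

#: Copy ratios below this are floored before log2; three independent fully
#: clonal biallelic deletions print as exactly -9.97 under this floor.
RATIO_FLOOR = 1e-3
LOG2_FLOOR = math.log2(RATIO_FLOOR)


@dataclass
class CnSegment:
    """A genomic interval with a log2 copy ratio and optional integer CN."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    integer_cn: Optional[int] = None
    n_markers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start, got {self.start}..{self.end}"
            )
        if self.integer_cn is not None and self.integer_cn < 0:
            raise ValueError(f"integer CN must be >= 0, got {self.integer_cn}")

    def overlaps(self, other: "GeneInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and self.end >= other.start

    def call(self, purity: float = DEFAULT_PURITY, ploidy: int = 2) -> int:
        """Set and return the purity-corrected integer copy number."""
        self.integer_cn = log2_to_cn(self.log2_ratio, purity, ploidy)
        return self.integer_cn


@dataclass(frozen=True)
class GeneInterval:
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene end must exceed start, got {self.start}..{self.end}")


def expected_log2(cn: int, purity: float, ploidy: int = 2) -> float:
    """Noiseless log2 copy ratio implied by integer CN at a given purity."""
    if cn < 0:
        raise ValueError(f"copy number must be >= 0, got {cn}")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    ratio = (purity * cn + (1.0 - purity) * ploidy) / ploidy
    return math.log2(max(RATIO_FLOOR, ratio))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def log2_to_cn(log2_ratio: float, purity: float, ploidy: int = 2) -> int:
    """Convert an observed log2 copy ratio to a purity-corrected integer CN.

    Inverse of :func:`expected_log2`: the normal-cell contribution
    ``(1 - purity)`` is subtracted from the observed ratio and the remainder
    rescaled by purity, then rounded half-away-from-zero and floored at 0.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    cn = ploidy * (2.0 ** log2_ratio - (1.0 - purity)) / purity
    return max(0, _round_half_away(cn))


def segment_size_kb(seg: CnSegment) -> float:
    """Segment size ``end - start`` in kilobases, reported to 0.1 kb."""
    return round((seg.end - seg.start) / 1000.0, 1)


@dataclass
class LossSummary:
    n_segments: int
    min_kb: Optional[float]
    max_kb: Optional[float]
    median_kb: Optional[float]
    sizes_kb: list[float]
    cn_at_gene: dict[str, int]  # per-sample minimum CN over gene-overlapping segments


def summarize_losses(
    segments: Iterable[CnSegment],
    gene: GeneInterval,
    purity: float = DEFAULT_PURITY,
    ploidy: int = 2,
) -> LossSummary:
    """Summarize gene-overlapping losses: size extremes/median and per-sample CN.

    Segments without a pre-set integer CN are called at the stated purity.
    Only segments with CN below ploidy (losses) contribute to the size
    statistics; per-sample CN is the minimum over all overlapping segments.
    """
    overlapping = [s for s in segments if s.overlaps(gene)]
    cn_at_gene: dict[str, int] = {}
    sizes: list[float] = []
    for seg in overlapping:
        cn = seg.integer_cn if seg.integer_cn is not None else log2_to_cn(
            seg.log2_ratio, purity, ploidy
        )
        cn_at_gene[seg.sample_id] = min(cn_at_gene.get(seg.sample_id, ploidy), cn)
        if cn < ploidy:
            sizes.append(segment_size_kb(seg))
    if not sizes:
        return LossSummary(0, None, None, None, [], cn_at_gene)
    return LossSummary(
        n_segments=len(sizes),
        min_kb=min(sizes),
        max_kb=max(sizes),
        median_kb=round(float(np.median(sizes)), 1),
        sizes_kb=sorted(sizes),
        cn_at_gene=cn_at_gene,
    )


def _affected_samples(
    segments: Sequence[CnSegment],
    gene: GeneInterval,
    direction: str,
    purity: float,
    ploidy: int,
) -> set[str]:
    hit = set()
    for seg in segments:
        if not seg.overlaps(gene):
            continue
        cn = seg.integer_cn if seg.integer_cn is not None else log2_to_cn(
            seg.log2_ratio, purity, ploidy
        )
        if (direction == "loss" and cn < ploidy) or (direction == "gain" and cn > ploidy):
            hit.add(seg.sample_id)
    return hit


def recurrence_test(
    case_segments: Sequence[CnSegment],
    control_segments: Sequence[CnSegment],
    genes: Sequence[GeneInterval],
    direction: str = "loss",
    purity: float = DEFAULT_PURITY,
    ploidy: int = 2,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Per-gene Fisher exact test of CN-loss (or gain) recurrence vs controls.

    A sample is affected at a gene when any overlapping segment has
    purity-corrected CN below (loss) or above (gain) the ploidy.  Each gene
    yields a 2x2 table (affected vs not, case vs control), a two-sided Fisher
    exact p-value and a multiplicity-adjusted p (Bonferroni by default).
    """
    if direction not in ("loss", "gain"):
        raise ValueError(f"direction must be 'loss' or 'gain', got {direction!r}")
    if not genes:
        raise ValueError("gene list must be non-empty")
    case_ids = {s.sample_id for s in case_segments}
    ctrl_ids = {s.sample_id for s in control_segments}
    if not case_ids or not ctrl_ids:
        raise ValueError("need at least one case and one control sample")

    rows = []
    for gene in genes:
        case_aff = _affected_samples(case_segments, gene, direction, purity, ploidy)
        ctrl_aff = _affected_samples(control_segments, gene, direction, purity, ploidy)
        table = [
            [len(case_aff), len(case_ids) - len(case_aff)],
            [len(ctrl_aff), len(ctrl_ids) - len(ctrl_aff)],
        ]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "gene": gene.symbol,
                "case_affected": len(case_aff),
                "case_total": len(case_ids),
                "control_affected": len(ctrl_aff),
                "control_total": len(ctrl_ids),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method=method)[1]
    return df


_REGION_RE = re.compile(
    r"^(?P<chrom>[\w.]+):g\.(?P<start>\d+)_(?P<end>\d+)[x×](?P<cn>\d+)$"
)


def parse_region_call(text: str, sample_id: str = "", log2_ratio: float = 0.0) -> CnSegment:
    """Parse an HGVS-style region call like ``chr1:g.241661127_241677014×1``."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region call {text!r}")
    seg = CnSegment(
        sample_id=sample_id,
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        log2_ratio=log2_ratio,
        integer_cn=int(m.group("cn")),
    )
    return seg
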