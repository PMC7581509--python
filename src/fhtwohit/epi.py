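"""Pathogenic-variant carrier frequency and epidemiological arithmetic.

Aggregates a curated population-variant table (allele counts/numbers with
ACMG classes) into a gene-level carrier frequency, and chains it with disease
prevalence figures: expected prevalence of the tumor subtype, expected
germline-carrier fraction among subtype cases (assuming independence of
carrier status and tumor occurrence), enrichment achieved by a screening
strategy, and exact binomial quantities for plausibility checks.

The default carrier-frequency estimator treats every pathogenic allele as one
carrier (rare-variant approximation): CF = sum_i AC_i / (AN_i / 2).  With
``count_hom_once`` homozygous individuals are counted once instead of twice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "VariantCategory",
    "PopulationVariantRecord",
    "EpiParams",
    "PathogenicSetSummary",
    "summarize_pathogenic_set",
    "carrier_frequency",
    "expected_prevalence",
    "germline_fraction_among_cases",
    "screening_enrichment",
    "prob_no_carriers",
    "binomial_tail",
    "normalize_variant_key",
]

#: ACMG classes treated as (likely) pathogenic.
PATHOGENIC_CLASSES = frozenset({4, 5})

INDEPENDENCE_NOTE = (
    "Assumes independence between carrier status and tumor-subtype occurrence."
)


class VariantCategory(str, Enum):
    TRUNCATING = "truncating"
    SPLICE = "splice"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"


@dataclass
class PopulationVariantRecord:
    """A curated variant with population allele counts and an ACMG class."""

    chrom: str
    pos: int
    ref: str
    alt: str
    allele_count: int
    allele_number: int
    hom_count: int = 0
    acmg_class: int = 3
    category: Optional[VariantCategory] = None
    hgvs_c: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError(
                f"need 0 <= AC <= AN, got AC={self.allele_count} AN={self.allele_number}"
            )
        if 2 * self.hom_count > self.allele_count:
            raise ValueError(
                f"2*hom_count ({2 * self.hom_count}) exceeds AC ({self.allele_count})"
            )
        if not 1 <= self.acmg_class <= 5:
            raise ValueError(f"ACMG class must be 1..5, got {self.acmg_class}")
        if isinstance(self.category, str):
            self.category = VariantCategory(self.category)

    @property
    def is_pathogenic(self) -> bool:
        return self.acmg_class in PATHOGENIC_CLASSES

    @property
    def key(self) -> tuple[str, int, str, str]:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class EpiParams:
    """Inputs to the epidemiological chain.

    prev_ul: lifetime prevalence of the tumor in the population;
    prop_fhd_ul: share of tumors that are FH-deficient;
    carrier_freq: population carrier frequency of pathogenic alleles;
    screen_hits/screen_n: carriers found / individuals screened.
    """

    prev_ul: float
    prop_fhd_ul: float
    carrier_freq: float
    screen_hits: int = 0
    screen_n: int = 1

    def __post_init__(self) -> None:
        for name in ("prev_ul", "prop_fhd_ul", "carrier_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.screen_hits <= self.screen_n:
            raise ValueError("need 0 <= screen_hits <= screen_n")


@dataclass
class PathogenicSetSummary:
    n_pathogenic: int
    counts: dict[str, int]
    percentages: dict[str, float]  # rounded to 0.1

    def combined_percentage(self, *categories: str) -> float:
        """Joint share of several categories, e.g. truncating + splice."""
        total = sum(self.counts.values())
        if total == 0:
            return 0.0
        return round(100.0 * sum(self.counts[c] for c in categories) / total, 1)


def summarize_pathogenic_set(
    records: Iterable[PopulationVariantRecord],
) -> PathogenicSetSummary:
    """Composition of the (likely) pathogenic set (ACMG 4/5) by category."""
    counts = {c.value: 0 for c in VariantCategory}
    for rec in records:
        if rec.is_pathogenic and rec.category is not None:
            counts[rec.category.value] += 1
    total = sum(counts.values())
    percentages = {
        k: round(100.0 * v / total, 1) if total else 0.0 for k, v in counts.items()
    }
    return PathogenicSetSummary(n_pathogenic=total, counts=counts, percentages=percentages)


def carrier_frequency(
    records: Iterable[PopulationVariantRecord],
    count_hom_once: bool = False,
) -> float:
    """Summed per-individual carrier frequency over pathogenic variants.

    Each variant contributes carriers / individuals = AC / (AN / 2); with
    ``count_hom_once`` homozygotes contribute one carrier, not two.  Records
    with AN = 0 are skipped with a warning.  Non-pathogenic records (ACMG
    class outside {4, 5}) never contribute.
    """
    cf = 0.0
    for rec in records:
        if not rec.is_pathogenic:
            continue
        if rec.allele_number == 0:
            warnings.warn(
                f"variant {rec.chrom}:{rec.pos}{rec.ref}>{rec.alt} has AN=0; skipped"
            )
            continue
        carriers = rec.allele_count
        if count_hom_once:
            carriers -= rec.hom_count
        cf += carriers / (rec.allele_number / 2.0)
    return cf


def expected_prevalence(prev_ul: float, prop_fhd_ul: float) -> float:
    """Expected population prevalence of the FH-deficient tumor subtype."""
    if not 0.0 <= prev_ul <= 1.0 or not 0.0 <= prop_fhd_ul <= 1.0:
        raise ValueError("prevalence inputs must be fractions in [0, 1]")
    return prev_ul * prop_fhd_ul


def germline_fraction_among_cases(
    carrier_freq: float, prev_fhd_ul: float
) -> tuple[float, bool]:
    """Expected fraction of subtype cases that carry a germline variant.

    Under independence of carrier status and tumor occurrence this is simply
    CF / prevalence.  Returns ``(fraction, ok)`` where ``ok`` is False when
    the ratio exceeds 1 (the independence assumption is then untenable).
    """
    if prev_fhd_ul <= 0:
        raise ValueError("prevalence of the subtype must be > 0")
    frac = carrier_freq / prev_fhd_ul
    return frac, frac <= 1.0


def screening_enrichment(k: int, n: int, carrier_freq: float) -> float:
    """Fold-enrichment of carriers in a screened series over the population."""
    if n <= 0:
        raise ValueError("screened cohort size must be > 0")
    if carrier_freq <= 0:
        raise ValueError("carrier frequency must be > 0")
    return (k / n) / carrier_freq


def prob_no_carriers(f: float, n: int) -> float:
    """Probability that none of n independent cases is a carrier: (1 - f)^n."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {f}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return (1.0 - f) ** n


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper binomial tail P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return float(
        sum(math.comb(n, i) * p**i * (1.0 - p) ** (n - i) for i in range(k, n + 1))
    )


def normalize_variant_key(
    chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, int, str, str]:
    """Left-aligned minimal representation of a variant key (VCF convention).

    Shared trailing bases are trimmed first, then shared leading bases with
    the position advanced, keeping at least one base on each side.  Assumes
    the record is already anchored as in a normalized VCF (full left
    alignment across repeat tracts requires the reference sequence and is out
    of scope here).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)
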