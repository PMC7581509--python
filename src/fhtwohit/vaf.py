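"""Tumor-purity / variant-allele-fraction model for germline-vs-somatic calls.

In a tumor-only sequencing design the allele fraction (VAF) of a variant is
the main evidence for whether it arose somatically or was inherited.  Under a
two-hit model with loss of heterozygosity (LOH) of the wild-type allele, every
tumor cell carries the variant, and the expected VAF is

    AF = TP + (1 - TP) * z

where ``TP`` is the tumor purity (fraction of tumor cells in the specimen) and
``z`` is the variant's initial zygosity in normal cells: 0 for a somatic
variant (absent from the admixed normal cells) and 0.5 for a germline
heterozygous variant (present on one of two alleles in every normal cell).

This linear form deliberately ignores the copy-number change in the
denominator (post-LOH tumor cells carry one allele at the locus, not two).
The copy-number-aware alternative,

    AF = (TP + (1 - TP) * 2 z) / (2 - TP)

is available behind the ``cn_aware`` flag and is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "SOMATIC_ZYGOSITY",
    "GERMLINE_ZYGOSITY",
    "DEFAULT_PURITY",
    "DEFAULT_TOLERANCE",
    "Consequence",
    "Origin",
    "VariantCall",
    "PurityVafModel",
    "OriginCall",
    "PurityEstimate",
    "expected_vaf",
    "required_purity",
    "purity_from_somatic_het",
    "classify_origin",
    "apply_read_filters",
]

#: Initial zygosity of a somatic variant in normal cells.
SOMATIC_ZYGOSITY = 0.0
#: Initial zygosity of a germline heterozygous variant in normal cells.
GERMLINE_ZYGOSITY = 0.5
#: Cohort-wide purity assumption used throughout unless overridden.
DEFAULT_PURITY = 0.8
#: Default residual-difference tolerance below which an origin call is ambiguous.
DEFAULT_TOLERANCE = 0.05

#: Read-level filters applied to raw calls: minimum coverage and allele fraction.
MIN_DEPTH = 10
MIN_VAF = 0.10


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Origin(str, Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    AMBIGUOUS = "ambiguous"


@dataclass
class VariantCall:
    """One sequenced small variant (SNV/indel) in one sample.

    ``vaf`` defaults to ``alt_reads / total_reads``; when supplied explicitly
    (e.g. a printed, rounded value) it must agree with the read counts to
    within 0.005, the precision of three printed decimals.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    total_reads: int
    vaf: Optional[float] = None
    gene: str = ""
    hgvs_c: Optional[str] = None
    consequence: Consequence = Consequence.OTHER

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValueError(
                f"alt_reads must satisfy 0 <= alt <= total, got "
                f"{self.alt_reads}/{self.total_reads}"
            )
        if isinstance(self.consequence, str):
            self.consequence = Consequence(self.consequence)
        if self.vaf is None:
            self.vaf = (
                self.alt_reads / self.total_reads if self.total_reads > 0 else 0.0
            )
        elif self.total_reads > 0:
            exact = self.alt_reads / self.total_reads
            if abs(self.vaf - exact) > 0.005:
                raise ValueError(
                    f"stated VAF {self.vaf} inconsistent with "
                    f"{self.alt_reads}/{self.total_reads} = {exact:.4f}"
                )


@dataclass(frozen=True)
class PurityVafModel:
    """Tumor purity plus initial-zygosity hypothesis; predicts VAF under LOH."""

    tumor_purity: float
    initial_zygosity: float = SOMATIC_ZYGOSITY

    def __post_init__(self) -> None:
        if not 0.0 < self.tumor_purity <= 1.0:
            raise ValueError(f"tumor purity must be in (0, 1], got {self.tumor_purity}")
        if self.initial_zygosity not in (SOMATIC_ZYGOSITY, GERMLINE_ZYGOSITY):
            raise ValueError(
                f"initial zygosity must be 0 (somatic) or 0.5 (germline het), "
                f"got {self.initial_zygosity}"
            )

    def expected_vaf(self, cn_aware: bool = False) -> float:
        return expected_vaf(self.tumor_purity, self.initial_zygosity, cn_aware=cn_aware)


def expected_vaf(purity: float, zygosity: float, cn_aware: bool = False) -> float:
    """Expected VAF of a variant whose wild-type allele is lost in tumor cells.

    Parameters
    ----------
    purity : fraction of tumor cells in (0, 1].
    zygosity : 0 (somatic) or 0.5 (germline heterozygous).
    cn_aware : if True, account for the single remaining allele in tumor cells
        (denominator ``2 - purity`` per diploid-equivalent); default keeps the
        linear form ``TP + (1 - TP) * z``.
    """
    model = PurityVafModel(purity, zygosity)  # validation
    tp, z = model.tumor_purity, model.initial_zygosity
    if cn_aware:
        return (tp + (1.0 - tp) * 2.0 * z) / (2.0 - tp)
    return tp + (1.0 - tp) * z


def required_purity(observed_vaf: float, zygosity: float) -> tuple[float, bool]:
    """Invert :func:`expected_vaf` for the purity required by a hypothesis.

    Returns ``(purity, feasible)``.  The algebraic inverse is returned even
    when it falls outside (0, 1] — an out-of-range requirement is exactly what
    makes a hypothesis untenable, so it is flagged rather than clamped.
    """
    if not 0.0 <= observed_vaf <= 1.0:
        raise ValueError(f"observed VAF must be in [0, 1], got {observed_vaf}")
    if zygosity == GERMLINE_ZYGOSITY:
        tp = 2.0 * observed_vaf - 1.0
    elif zygosity == SOMATIC_ZYGOSITY:
        tp = observed_vaf
    else:
        raise ValueError(f"zygosity must be 0 or 0.5, got {zygosity}")
    return tp, 0.0 < tp <= 1.0


@dataclass
class PurityEstimate:
    """Per-variant and mean purity from clonal somatic heterozygous variants."""

    per_variant: list[float]
    mean: float
    flagged: list[bool]  # True where the input VAF exceeded 0.5 (estimate > 1)


def purity_from_somatic_het(vafs: Sequence[float]) -> PurityEstimate:
    """Estimate tumor purity as twice the VAF of clonal somatic het variants.

    A clonal somatic variant heterozygous in tumor cells (no LOH) has expected
    VAF ``TP / 2``, so each VAF is doubled; e.g. 0.408 -> 0.816.
    """
    vafs = list(vafs)
    if not vafs:
        raise ValueError("need at least one VAF to estimate purity")
    per_variant = [2.0 * v for v in vafs]
    flagged = [v > 0.5 for v in vafs]
    return PurityEstimate(per_variant, float(np.mean(per_variant)), flagged)


@dataclass
class OriginCall:
    """Germline-vs-somatic call for one variant at an assumed purity."""

    variant: Union[VariantCall, float]
    favored_origin: Origin
    required_purity_germline: float
    required_purity_somatic: float
    germline_feasible: bool
    somatic_feasible: bool
    purity_assumed: float
    residual_somatic: float
    residual_germline: float


def classify_origin(
    variant: Union[VariantCall, float],
    purity: float = DEFAULT_PURITY,
    tolerance: float = DEFAULT_TOLERANCE,
    cn_aware: bool = False,
) -> OriginCall:
    """Call a variant somatic or germline from its VAF under an assumed purity.

    The hypothesis whose expected VAF (assuming LOH of the other allele) is
    closer to the observed VAF is favored; when the two absolute residuals
    differ by less than ``tolerance`` the call is ambiguous.  Required
    purities for both hypotheses are always reported.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    vaf = variant.vaf if isinstance(variant, VariantCall) else float(variant)
    exp_som = expected_vaf(purity, SOMATIC_ZYGOSITY, cn_aware=cn_aware)
    exp_ger = expected_vaf(purity, GERMLINE_ZYGOSITY, cn_aware=cn_aware)
    r_som = abs(vaf - exp_som)
    r_ger = abs(vaf - exp_ger)
    if abs(r_som - r_ger) < tolerance:
        origin = Origin.AMBIGUOUS
    elif r_som < r_ger:
        origin = Origin.SOMATIC
    else:
        origin = Origin.GERMLINE
    rp_ger, ger_ok = required_purity(vaf, GERMLINE_ZYGOSITY)
    rp_som, som_ok = required_purity(vaf, SOMATIC_ZYGOSITY)
    return OriginCall(
        variant=variant,
        favored_origin=origin,
        required_purity_germline=rp_ger,
        required_purity_somatic=rp_som,
        germline_feasible=ger_ok,
        somatic_feasible=som_ok,
        purity_assumed=purity,
        residual_somatic=r_som,
        residual_germline=r_ger,
    )


def apply_read_filters(
    variants: Iterable[VariantCall],
    min_depth: int = MIN_DEPTH,
    min_vaf: float = MIN_VAF,
) -> list[VariantCall]:
    """Standard coverage/allele-fraction filter: DP >= 10 and AF >= 10%."""
    return [
        v
        for v in variants
        if v.total_reads >= min_depth and (v.vaf or 0.0) >= min_vaf
    ]
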