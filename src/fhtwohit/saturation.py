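"""Saturation single-base mutagenesis of a coding transcript.

Enumerates every variant reachable by one base exchange in a CDS (3 per
coding base), classifies each by codon substitution under the standard
nuclear code, flags exon-terminal coding bases (whose substitution is likely
to disrupt splicing even when annotated as missense or synonymous), maps
variant residues onto protein domains, and tests domain enrichment of an
observed residue set with a one-sided Fisher exact (hypergeometric) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import fisher_exact

__all__ = [
    "SnvConsequence",
    "ExonTerminalFlag",
    "TranscriptModel",
    "CodingSnv",
    "DomainMap",
    "enumerate_coding_snvs",
    "annotate_domains",
    "domain_enrichment_test",
    "windowed_score_profile",
]

BASES = "ACGT"
#: Coding bases within this distance of an internal exon boundary are flagged
#: as splice-region-proximal (the exact terminal base separately).
SPLICE_REGION_BASES = 3


class SnvConsequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"


class ExonTerminalFlag(str, Enum):
    NONE = "none"
    FIRST_BASE = "first_base"
    LAST_BASE = "last_base"
    NEAR_TERMINAL = "near_terminal"


@dataclass
class TranscriptModel:
    """Coding transcript: exon structure plus strand-resolved CDS.

    ``exons`` are 1-based inclusive genomic intervals in genomic order;
    ``cds_sequence`` is the spliced coding sequence 5'->3' on the coding
    strand (already reverse-complemented for minus-strand transcripts).
    """

    id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    protein_sequence: str = ""
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds_sequence = self.cds_sequence.upper()
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"CDS length must be divisible by 3, got {len(self.cds_sequence)}"
            )
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be in increasing genomic order")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"exon end < start: {s}..{e}")
        translated = str(Seq(self.cds_sequence).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
        if "*" in translated:
            raise ValueError("CDS contains an internal stop codon")
        if not self.protein_sequence:
            self.protein_sequence = translated
        elif self.protein_sequence != translated:
            raise ValueError("protein_sequence does not match translated CDS")

    @classmethod
    def from_genomic(
        cls,
        chrom_sequence: str,
        exons: Sequence[tuple[int, int]],
        strand: str,
        id: str = "toy",
        chrom: str = "",
    ) -> "TranscriptModel":
        """Build a transcript by splicing exons out of a genomic sequence.

        Exons are 1-based inclusive on the forward strand; for minus-strand
        transcripts the spliced sequence is reverse-complemented.
        """
        spliced = "".join(chrom_sequence[s - 1 : e] for s, e in exons)
        if strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        return cls(id=id, strand=strand, exons=list(exons), cds_sequence=spliced, chrom=chrom)

    @property
    def exon_boundary_cds_positions(self) -> list[int]:
        """Cumulative CDS coordinate of the last base of each exon.

        For minus-strand transcripts exon lengths are taken in coding order
        (descending genomic order).
        """
        lengths = [e - s + 1 for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        return list(np.cumsum(lengths))

    def codon(self, protein_pos: int) -> str:
        return self.cds_sequence[(protein_pos - 1) * 3 : protein_pos * 3]

    def __len__(self) -> int:
        return len(self.cds_sequence)


@dataclass
class CodingSnv:
    """One single-base substitution in a CDS with its protein consequence."""

    cds_pos: int
    ref_base: str
    alt_base: str
    consequence: SnvConsequence
    protein_pos: int
    aa_ref: str
    aa_alt: str
    exon_terminal_flag: ExonTerminalFlag = ExonTerminalFlag.NONE
    domain: Optional[str] = None

    @property
    def hgvs_c(self) -> str:
        return f"c.{self.cds_pos}{self.ref_base}>{self.alt_base}"

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.aa_ref}{self.protein_pos}{self.aa_alt}"


@dataclass
class DomainMap:
    """Non-overlapping named residue intervals (1-based inclusive) on a protein."""

    domains: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        ordered = sorted(self.domains, key=lambda d: d[1])
        for (_, s1, e1), (_, s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError("domain intervals must not overlap")
        for name, s, e in self.domains:
            if e < s or s < 1:
                raise ValueError(f"bad domain interval {name}: {s}..{e}")

    def locate(self, residue: int) -> Optional[str]:
        for name, s, e in self.domains:
            if s <= residue <= e:
                return name
        return None

    def length(self, name: str) -> int:
        for n, s, e in self.domains:
            if n == name:
                return e - s + 1
        raise KeyError(name)


def _terminal_flag(cds_pos: int, boundaries: Sequence[int], cds_len: int) -> ExonTerminalFlag:
    """Flag coding bases at or near internal exon boundaries.

    ``boundaries`` holds the CDS coordinate of the last base of every exon;
    the transcript's own first and last coding bases are not splice-adjacent
    and are never flagged.
    """
    internal_ends = [b for b in boundaries if b < cds_len]
    internal_starts = [b + 1 for b in internal_ends]
    if cds_pos in internal_ends:
        return ExonTerminalFlag.LAST_BASE
    if cds_pos in internal_starts:
        return ExonTerminalFlag.FIRST_BASE
    for b in internal_ends:
        if b - SPLICE_REGION_BASES < cds_pos < b:
            return ExonTerminalFlag.NEAR_TERMINAL
    for b in internal_starts:
        if b < cds_pos < b + SPLICE_REGION_BASES:
            return ExonTerminalFlag.NEAR_TERMINAL
    return ExonTerminalFlag.NONE


def _classify(codon_ref: str, codon_alt: str, protein_pos: int) -> tuple[SnvConsequence, str, str]:
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if protein_pos == 1:
        # any substitution in the initiator codon abolishes the start
        return SnvConsequence.START_LOST, aa_ref, aa_alt
    if aa_ref == "*":
        if aa_alt == "*":
            return SnvConsequence.SYNONYMOUS, aa_ref, aa_alt
        return SnvConsequence.STOP_LOST, aa_ref, aa_alt
    if aa_alt == "*":
        return SnvConsequence.NONSENSE, aa_ref, aa_alt
    if aa_alt == aa_ref:
        return SnvConsequence.SYNONYMOUS, aa_ref, aa_alt
    return SnvConsequence.MISSENSE, aa_ref, aa_alt


def enumerate_coding_snvs(t: TranscriptModel) -> list[CodingSnv]:
    """Enumerate all 3 x |CDS| single-base substitutions with consequences."""
    cds = t.cds_sequence
    boundaries = t.exon_boundary_cds_positions
    out: list[CodingSnv] = []
    for i, ref in enumerate(cds):
        cds_pos = i + 1
        protein_pos = math.ceil(cds_pos / 3)
        codon_start = (protein_pos - 1) * 3
        codon_ref = cds[codon_start : codon_start + 3]
        offset = i - codon_start
        flag = _terminal_flag(cds_pos, boundaries, len(cds))
        for alt in BASES:
            if alt == ref:
                continue
            codon_alt = codon_ref[:offset] + alt + codon_ref[offset + 1 :]
            consequence, aa_ref, aa_alt = _classify(codon_ref, codon_alt, protein_pos)
            out.append(
                CodingSnv(
                    cds_pos=cds_pos,
                    ref_base=ref,
                    alt_base=alt,
                    consequence=consequence,
                    protein_pos=protein_pos,
                    aa_ref=aa_ref,
                    aa_alt=aa_alt,
                    exon_terminal_flag=flag,
                )
            )
    return out


def annotate_domains(snvs: Iterable[CodingSnv], domains: DomainMap, protein_length: Optional[int] = None) -> list[CodingSnv]:
    """Label each variant with its containing domain or ``inter-domain``."""
    out = []
    for snv in snvs:
        if protein_length is not None and snv.protein_pos > protein_length + 1:
            raise ValueError(
                f"protein position {snv.protein_pos} beyond protein length {protein_length}"
            )
        snv.domain = domains.locate(snv.protein_pos) or "inter-domain"
        out.append(snv)
    return out


def domain_enrichment_test(
    observed_residues: Sequence[int],
    domain: str,
    domains: DomainMap,
    protein_length: int,
) -> tuple[float, float]:
    """One-sided Fisher exact test for enrichment of residues in a domain.

    The 2x2 table partitions the protein's residues into observed vs not and
    in-domain vs out; the one-sided (greater) p equals the hypergeometric
    tail P(X >= k) for k of n observed residues falling in the domain.
    Returns ``(p_value, odds_ratio)``.
    """
    dlen = domains.length(domain)
    if dlen <= 0:
        raise ValueError(f"domain {domain} has zero length")
    observed = list(observed_residues)
    for r in observed:
        if not 1 <= r <= protein_length:
            raise ValueError(f"residue {r} outside protein of length {protein_length}")
    if not observed:
        return 1.0, float("nan")
    name_interval = {n: (s, e) for n, s, e in domains.domains}
    s, e = name_interval[domain]
    k = sum(1 for r in observed if s <= r <= e)
    n = len(observed)
    table = [[k, n - k], [dlen - k, (protein_length - dlen) - (n - k)]]
    odds, p = fisher_exact(table, alternative="greater")
    return float(p), float(odds)


def windowed_score_profile(
    per_variant_scores: Sequence[tuple[int, float]],
    window: int,
    protein_length: Optional[int] = None,
) -> pd.Series:
    """Smoothed per-residue score profile by centered moving average.

    Scores at the same residue are averaged first; residues with no score
    contribute 0.  The window is truncated at the profile ends, so a constant
    per-residue score stays constant.  Returns a Series indexed by residue.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    if not per_variant_scores:
        return pd.Series(dtype=float)
    df = pd.DataFrame(per_variant_scores, columns=["protein_pos", "score"])
    per_res = df.groupby("protein_pos")["score"].mean()
    length = protein_length or int(per_res.index.max())
    dense = per_res.reindex(range(1, length + 1), fill_value=0.0)
    profile = dense.rolling(window=window, center=True, min_periods=1).mean()
    profile.index.name = "residue"
    return profile
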