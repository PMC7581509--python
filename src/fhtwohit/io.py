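"""Readers and writers for the plain-text formats the toolkit exchanges.

Variant tables travel as minimal VCF 4.2 (INFO DP/AF, one sample column with
GT:AD:DP) or as TSV; copy-number segments as a SEG-like TSV
(sample, chrom, start, end, log2, n_markers); transcripts as FASTA (CDS) plus
an exon TSV; structures as Cα-only PDB ATOM records; gene intervals as BED
(0-based half-open on disk, converted to 1-based inclusive in memory).
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

from .cnv import CnSegment, GeneInterval
from .saturation import TranscriptModel
from .structure import StructureModel
from .vaf import Consequence, VariantCall

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_seg",
    "read_seg",
    "read_genes_bed",
    "write_genes_bed",
    "write_transcript",
    "read_transcript",
    "write_pdb",
    "write_labels_tsv",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=fhtwohit
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(variants: Sequence[VariantCall], path: str, sample_id: Optional[str] = None) -> None:
    """Write one sample's variants as a minimal VCF 4.2 file."""
    ids = {v.sample_id for v in variants}
    if sample_id is None:
        if len(ids) > 1:
            raise ValueError(
                f"variants from multiple samples {sorted(ids)}; pass sample_id"
            )
        sample_id = next(iter(ids)) if ids else "TUMOR"
    rows = sorted(
        (v for v in variants if v.sample_id == sample_id or not ids),
        key=lambda v: (v.chrom, v.pos),
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = sorted({v.chrom for v in rows})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_id
            + "\n"
        )
        for v in rows:
            info = f"DP={v.total_reads};AF={v.vaf:.6g}"
            if v.gene:
                info += f";GENE={v.gene}"
            if v.consequence is not Consequence.OTHER:
                info += f";CSQ={v.consequence.value}"
            sample = f"0/1:{v.total_reads - v.alt_reads},{v.alt_reads}:{v.total_reads}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t"
                f"GT:AD:DP\t{sample}\n"
            )


def read_vcf(path: str, sample_id: Optional[str] = None) -> list[VariantCall]:
    """Read variant calls from a VCF, using AD when present, else DP + AF."""
    from pysam import VariantFile

    out: list[VariantCall] = []
    with VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        sid = sample_id or (samples[0] if samples else "TUMOR")
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            alt_reads = total = None
            if samples:
                fmt = rec.samples[samples[0]]
                ad = fmt.get("AD")
                if ad is not None and ad[0] is not None:
                    total = sum(x for x in ad if x is not None)
                    alt_reads = sum(x for x in ad[1:] if x is not None)
                elif fmt.get("DP") is not None:
                    total = fmt["DP"]
            if total is None:
                total = rec.info.get("DP", 0)
            if alt_reads is None:
                af = rec.info.get("AF", 0.0)
                if isinstance(af, tuple):
                    af = af[0]
                alt_reads = round(float(af) * total)
            gene = rec.info.get("GENE", "")
            csq = rec.info.get("CSQ", "other")
            out.append(
                VariantCall(
                    sample_id=sid,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    alt_reads=int(alt_reads),
                    total_reads=int(total),
                    gene=gene,
                    consequence=Consequence(csq),
                )
            )
    return out


_VARIANT_TSV_COLS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "alt_reads", "total_reads", "vaf", "gene", "hgvs_c", "consequence",
]


def write_variants_tsv(variants: Sequence[VariantCall] | pd.DataFrame, path: str) -> None:
    if isinstance(variants, pd.DataFrame):
        df = variants
    else:
        df = pd.DataFrame(
            [
                {
                    "sample_id": v.sample_id, "chrom": v.chrom, "pos": v.pos,
                    "ref": v.ref, "alt": v.alt, "alt_reads": v.alt_reads,
                    "total_reads": v.total_reads, "vaf": v.vaf, "gene": v.gene,
                    "hgvs_c": v.hgvs_c, "consequence": v.consequence.value,
                }
                for v in variants
            ],
            columns=_VARIANT_TSV_COLS,
        )
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantCall(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                alt_reads=int(row.alt_reads),
                total_reads=int(row.total_reads),
                gene="" if pd.isna(row.gene) else str(row.gene),
                hgvs_c=None if pd.isna(row.hgvs_c) else str(row.hgvs_c),
                consequence=Consequence(row.consequence),
            )
        )
    return out


def write_seg(segments: Sequence[CnSegment] | pd.DataFrame, path: str) -> None:
    """Write segments as the SEG-like TSV (sample, chrom, start, end, log2, n_markers)."""
    if isinstance(segments, pd.DataFrame):
        df = segments
    else:
        df = pd.DataFrame(
            [
                {
                    "sample": s.sample_id, "chrom": s.chrom, "start": s.start,
                    "end": s.end, "log2": s.log2_ratio, "n_markers": s.n_markers,
                }
                for s in segments
            ],
            columns=["sample", "chrom", "start", "end", "log2", "n_markers"],
        )
    df.to_csv(path, sep="\t", index=False)


def read_seg(path: str) -> list[CnSegment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        nm = getattr(row, "n_markers", None)
        out.append(
            CnSegment(
                sample_id=str(row.sample),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                log2_ratio=float(row.log2),
                n_markers=None if nm is None or pd.isna(nm) else int(nm),
            )
        )
    return out


def read_genes_bed(path: str) -> list[GeneInterval]:
    """Read gene intervals from BED; converts to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            out.append(GeneInterval(name, chrom, start + 1, end))
    return out


def write_genes_bed(genes: Sequence[GeneInterval], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


def write_transcript(t: TranscriptModel, fasta_path: str, exon_tsv_path: str) -> None:
    """Write the CDS as FASTA and the exon structure as a 1-based TSV."""
    SeqIO.write(
        [SeqRecord(Seq(t.cds_sequence), id=t.id, description="CDS")],
        fasta_path,
        "fasta",
    )
    pd.DataFrame(
        [
            {"transcript": t.id, "chrom": t.chrom, "exon": i + 1,
             "start": s, "end": e, "strand": t.strand}
            for i, (s, e) in enumerate(t.exons)
        ]
    ).to_csv(exon_tsv_path, sep="\t", index=False)


def read_transcript(fasta_path: str, exon_tsv_path: str) -> TranscriptModel:
    rec = next(SeqIO.parse(fasta_path, "fasta"))
    df = pd.read_csv(exon_tsv_path, sep="\t").sort_values("exon")
    strand = str(df["strand"].iloc[0])
    chrom = "" if pd.isna(df["chrom"].iloc[0]) else str(df["chrom"].iloc[0])
    exons = [(int(r.start), int(r.end)) for r in df.itertuples(index=False)]
    return TranscriptModel(
        id=rec.id, strand=strand, exons=exons, cds_sequence=str(rec.seq), chrom=chrom
    )


def write_pdb(s: StructureModel, path: str) -> None:
    """Write a Cα-only PDB (ATOM records) for a structure model."""
    one_to_three = {}
    with open(path, "w") as fh:
        for serial, ((chain, resnum), aa, (x, y, z)) in enumerate(
            zip(s.residue_ids, s.amino_acids, s.coords), start=1
        ):
            resname = one_to_three.get(aa)
            if resname is None:
                try:
                    resname = seq3(aa).upper()
                except Exception:
                    resname = "UNK"
                one_to_three[aa] = resname
            fh.write(
                f"ATOM  {serial:5d}  CA  {resname:>3s} {chain:1s}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_labels_tsv(labels: pd.DataFrame, path: str) -> None:
    labels.to_csv(path, sep="\t", index=False)
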