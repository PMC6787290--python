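"""Readers and writers for the standard formats the pipeline touches.

GTF and SAM store 1-based coordinates; everything is converted to the
internal 0-based half-open convention on the way in and back on the way
out. All writers emit deterministic, lexicographically sorted output.
"""

from __future__ import annotations

import io as _io
import tempfile
from collections import OrderedDict
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from .model import (
    AlignedSegment,
    ChimericAlignment,
    ExpressionMatrix,
    GeneModel,
    PeakSet,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "parse_annotation",
    "write_annotation",
    "parse_alignments",
    "read_peaks_bed",
    "read_fasta",
    "read_expression_tsv",
    "write_expression_tsv",
    "FormatError",
]


class FormatError(ValueError):
    """Raised on malformed input, naming the offending line."""


_NONCODING_BIOTYPES = {
    "lincRNA", "lncRNA", "antisense", "processed_transcript", "ncRNA",
    "miRNA", "snoRNA", "snRNA", "noncoding",
}


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_annotation(gtf_text: str) -> list[GeneModel]:
    """Parse GTF text (Ensembl dialect attributes) into gene models.

    Only ``exon`` features are structural; gene/transcript feature lines are
    used for biotype lookup when present. 1-based closed GTF coordinates are
    converted to 0-based half-open. Exon lists are sorted; transcripts are
    grouped under their gene_id.

    Raises
    ------
    FormatError
        If an exon line lacks a transcript_id attribute (the line number is
        named in the message).
    ValidationError
        If exons within one transcript overlap.
    """
    # transcript_id -> (gene_id, chrom, strand, [exons])
    tx: "OrderedDict[str, dict]" = OrderedDict()
    biotypes: dict[str, str] = {}
    for lineno, line in enumerate(gtf_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
        chrom, _source, feature, start, end, _score, strand, _frame, attr_f = fields
        attrs = _parse_gtf_attributes(attr_f)
        gene_id = attrs.get("gene_id")
        if feature in ("gene", "transcript") and gene_id:
            bt = attrs.get("gene_biotype") or attrs.get("gene_type")
            if bt:
                biotypes[gene_id] = bt
        if feature != "exon":
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            raise FormatError(f"line {lineno}: exon record missing transcript_id")
        rec = tx.setdefault(
            tid, {"gene_id": gene_id, "chrom": chrom, "strand": strand, "exons": []}
        )
        rec["exons"].append((int(start) - 1, int(end)))
        bt = attrs.get("gene_biotype") or attrs.get("gene_type")
        if bt and gene_id:
            biotypes[gene_id] = bt

    genes: "OrderedDict[str, GeneModel]" = OrderedDict()
    for tid, rec in tx.items():
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        gid = rec["gene_id"] or tid
        gene = genes.get(gid)
        if gene is None:
            raw_bt = biotypes.get(gid, "")
            if raw_bt == "protein_coding":
                bt = "protein_coding"
            elif raw_bt in _NONCODING_BIOTYPES:
                bt = "noncoding"
            else:
                bt = "other"
            gene = GeneModel(
                gene_id=gid, chrom=t.chrom, strand=t.strand, biotype=bt
            )
            genes[gid] = gene
        gene.transcripts.append(t)
    for g in genes.values():
        g.__post_init__()  # re-check chrom/strand consistency after filling
    return list(genes.values())


_BIOTYPE_OUT = {"protein_coding": "protein_coding", "noncoding": "lncRNA"}


def write_annotation(genes: list[GeneModel]) -> str:
    """Serialize gene models back to GTF (exon lines only), sorted."""
    lines = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
        bt = _BIOTYPE_OUT.get(g.biotype, "misc")
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            for s, e in t.exons:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{bt}";'
                )
                lines.append(
                    "\t".join(
                        [g.chrom, "isotrx", "exon", str(s + 1), str(e),
                         ".", t.strand, ".", attrs]
                    )
                )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Alignments

def _segments_from_sam(text: str, keep_mapq0: bool) -> dict[str, ChimericAlignment]:
    reads: "OrderedDict[str, ChimericAlignment]" = OrderedDict()
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as af:
            for rec in af:
                qname = rec.query_name
                if rec.is_unmapped:
                    qlen = rec.query_length or rec.infer_read_length() or 1
                    reads.setdefault(qname, ChimericAlignment(qname, qlen, []))
                    continue
                cig = rec.cigartuples or []
                # leading/trailing clips, counting hard clips toward read length
                lead = 0
                for op, n in cig:
                    if op in (4, 5):
                        lead += n
                    else:
                        break
                trail = 0
                for op, n in reversed(cig):
                    if op in (4, 5):
                        trail += n
                    else:
                        break
                aligned_q = sum(n for op, n in cig if op in (0, 1, 7, 8))
                qlen = lead + aligned_q + trail
                if rec.is_reverse:
                    qs, qe = trail, qlen - lead
                else:
                    qs, qe = lead, qlen - trail
                seg = AlignedSegment(
                    query_start=qs,
                    query_end=qe,
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    mapq=rec.mapping_quality,
                )
                if seg.mapq == 0 and not keep_mapq0:
                    continue
                aln = reads.get(qname)
                if aln is None:
                    reads[qname] = ChimericAlignment(qname, qlen, [seg])
                elif aln.query_length != qlen:
                    raise ValidationError(
                        f"{qname}: inconsistent query length across alignment "
                        f"lines ({aln.query_length} vs {qlen})"
                    )
                else:
                    aln.segments.append(seg)
    finally:
        Path(path).unlink(missing_ok=True)
    return reads


def _segments_from_paf(text: str, keep_mapq0: bool) -> dict[str, ChimericAlignment]:
    reads: "OrderedDict[str, ChimericAlignment]" = OrderedDict()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise FormatError(f"line {lineno}: PAF needs >=12 columns")
        qname, qlen = f[0], int(f[1])
        if f[5] == "*":
            reads.setdefault(qname, ChimericAlignment(qname, qlen, []))
            continue
        mapq = int(f[11])
        seg = AlignedSegment(
            query_start=int(f[2]),
            query_end=int(f[3]),
            chrom=f[5],
            strand=f[4],
            target_start=int(f[7]),
            target_end=int(f[8]),
            mapq=mapq,
        )
        if mapq == 0 and not keep_mapq0:
            continue
        aln = reads.get(qname)
        if aln is None:
            reads[qname] = ChimericAlignment(qname, qlen, [seg])
        elif aln.query_length != qlen:
            raise ValidationError(
                f"{qname}: inconsistent query length across PAF lines "
                f"({aln.query_length} vs {qlen})"
            )
        else:
            aln.segments.append(seg)
    return reads


def parse_alignments(text: str, dialect: str = "paf",
                     keep_mapq0: bool = True) -> list[ChimericAlignment]:
    """Parse SAM or PAF text, merging all lines of one query into one record.

    Query intervals are reconstructed from soft/hard clipping for SAM (clips
    flipped for reverse-strand records so intervals live on the original
    read) and taken from the given columns for PAF. Unmapped records yield a
    zero-segment (unaligned) record. ``keep_mapq0=False`` drops mapq-0
    segments.
    """
    if dialect == "sam":
        reads = _segments_from_sam(text, keep_mapq0)
    elif dialect == "paf":
        reads = _segments_from_paf(text, keep_mapq0)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    for aln in reads.values():
        aln.segments.sort(key=lambda s: (s.query_start, s.query_end))
    return list(reads.values())


# ---------------------------------------------------------------------------
# Peaks, sequences, matrices

def read_peaks_bed(text: str, name: str) -> PeakSet:
    """Read BED3+ intervals (already 0-based half-open) into a PeakSet."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise FormatError(f"line {lineno}: BED needs >=3 columns")
        per_chrom.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return PeakSet(name, per_chrom)


def read_fasta(source: str | Path) -> dict[str, str]:
    """Read FASTA (path or literal text) into an id -> sequence dict."""
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        handle = open(source)
    else:
        handle = _io.StringIO(str(source))
    with handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def read_expression_tsv(text: str) -> ExpressionMatrix:
    """Read a feature x sample TSV (header row = samples, first column = ids)."""
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float))


def write_expression_tsv(matrix: ExpressionMatrix) -> str:
    df = matrix.values.sort_index()
    return df.to_csv(sep="\t", lineterminator="\n")
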