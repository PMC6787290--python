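"""Novelty classification of long-read transcripts against an annotation.

Three deliverables of the long-read survey live here: per-transcript
novelty categories, cross-sample sharing counts of novel transcripts, and
distances between transcript start sites and promoter/epigenetic peak sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .model import (
    GeneModel,
    PeakSet,
    TranscriptModel,
    exonic_overlap_bp,
    intron_chain_key,
    tss_of,
)

__all__ = [
    "NoveltyCall",
    "TssDistanceRecord",
    "classify_transcripts",
    "sharing_counts",
    "tss_peak_distances",
]

KNOWN_ISOFORM = "known_isoform_known_gene"
NOVEL_ISOFORM = "novel_isoform_known_gene"
NOVEL_GENE = "isoform_novel_gene"
NOVEL_ISOFORM_NOVEL_GENE = "novel_isoform_novel_gene"

CATEGORIES = (KNOWN_ISOFORM, NOVEL_ISOFORM, NOVEL_GENE, NOVEL_ISOFORM_NOVEL_GENE)


@dataclass(frozen=True)
class NoveltyCall:
    transcript_id: str
    category: str
    matched_gene_id: str  # annotated gene id or novel locus label
    antisense: bool = False


@dataclass(frozen=True)
class TssDistanceRecord:
    transcript_id: str
    peak_set: str
    distance: float  # bp >= 0; math.inf when the chromosome has no peaks


def _exonic_overlap_same_strand(t: TranscriptModel, g: GeneModel) -> int:
    if t.chrom != g.chrom or t.strand != g.strand:
        return 0
    best = 0
    for gt in g.transcripts:
        best = max(best, exonic_overlap_bp(t.exons, gt.exons))
    return best


def _exonic_overlap_any_strand(t: TranscriptModel, g: GeneModel) -> int:
    if t.chrom != g.chrom:
        return 0
    best = 0
    for gt in g.transcripts:
        best = max(best, exonic_overlap_bp(t.exons, gt.exons))
    return best


def classify_transcripts(
    transcripts: Sequence[TranscriptModel],
    annotation: Sequence[GeneModel],
) -> list[NoveltyCall]:
    """Assign each query transcript a novelty category.

    Rules, applied in order:

    1. Intron chain identical to any annotated transcript ->
       ``known_isoform_known_gene``.
    2. Same-strand exonic overlap (>=1 bp) with an annotated gene ->
       ``novel_isoform_known_gene``; the gene with maximal overlap is
       reported.
    3. Remaining queries are clustered into novel loci by single-linkage
       same-strand exonic overlap. Per locus, the representative
       (longest exonic length, then lexicographic transcript_id) and any
       transcript sharing its intron chain -> ``isoform_novel_gene``;
       structurally distinct transcripts at the locus ->
       ``novel_isoform_novel_gene``.

    A query whose only exonic overlap with annotation is on the opposite
    strand goes to the novel-gene classes but is flagged ``antisense``.
    """
    known_keys: dict[tuple, str] = {}
    for g in annotation:
        for t in g.transcripts:
            known_keys.setdefault(intron_chain_key(t), g.gene_id)

    calls: dict[str, NoveltyCall] = {}
    unassigned: list[TranscriptModel] = []
    for t in transcripts:
        key = intron_chain_key(t)
        if key in known_keys:
            calls[t.transcript_id] = NoveltyCall(
                t.transcript_id, KNOWN_ISOFORM, known_keys[key]
            )
            continue
        best_gene, best_ov = None, 0
        for g in annotation:
            ov = _exonic_overlap_same_strand(t, g)
            if ov > best_ov or (ov == best_ov and ov > 0 and best_gene
                                and g.gene_id < best_gene):
                best_gene, best_ov = g.gene_id, ov
        if best_ov > 0:
            calls[t.transcript_id] = NoveltyCall(
                t.transcript_id, NOVEL_ISOFORM, best_gene
            )
        else:
            unassigned.append(t)

    # single-linkage clustering of unassigned transcripts into novel loci
    parent: dict[str, str] = {t.transcript_id: t.transcript_id for t in unassigned}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in combinations(unassigned, 2):
        if (a.chrom == b.chrom and a.strand == b.strand
                and exonic_overlap_bp(a.exons, b.exons) > 0):
            union(a.transcript_id, b.transcript_id)

    clusters: dict[str, list[TranscriptModel]] = {}
    for t in unassigned:
        clusters.setdefault(find(t.transcript_id), []).append(t)

    for members in clusters.values():
        # representative: longest exonic length, ties to the smaller id
        best_len = max(m.exonic_length for m in members)
        rep = min(
            (m for m in members if m.exonic_length == best_len),
            key=lambda t: t.transcript_id,
        )
        locus = f"novel_locus:{rep.chrom}:{min(m.start for m in members)}"
        rep_key = intron_chain_key(rep)
        for m in members:
            antisense = any(
                _exonic_overlap_any_strand(m, g) > 0 for g in annotation
            )
            cat = (NOVEL_GENE if intron_chain_key(m) == rep_key
                   else NOVEL_ISOFORM_NOVEL_GENE)
            calls[m.transcript_id] = NoveltyCall(
                m.transcript_id, cat, locus, antisense=antisense
            )

    return [calls[t.transcript_id] for t in transcripts]


def sharing_counts(
    sample_keys: Mapping[str, Iterable],
) -> dict[tuple[str, ...], int]:
    """Count novel-transcript keys by the exact sample subset holding them.

    Returns a mapping from each non-empty sample-name subset (sorted tuple)
    to the number of keys present in exactly that subset. Counts sum to the
    size of the union of all per-sample key sets.
    """
    if not sample_keys:
        raise ValueError("at least one sample required")
    sets = {s: set(k) for s, k in sample_keys.items()}
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[combo] = 0
    for key in set().union(*sets.values()):
        members = tuple(s for s in names if key in sets[s])
        counts[members] += 1
    return counts


def _nearest_peak_distance(pos: int, intervals: Sequence[tuple[int, int]]) -> int:
    best = None
    for s, e in intervals:
        if s <= pos < e:
            return 0
        d = s - pos if pos < s else pos - (e - 1)
        if best is None or d < best:
            best = d
    return best


def tss_peak_distances(
    transcripts: Sequence[TranscriptModel],
    peaks: PeakSet,
    summary_thresholds: Sequence[int] = (1, 10, 100, 1000, 10000),
) -> tuple[list[TssDistanceRecord], dict[int, float]]:
    """Distance of each transcript's TSS to the nearest peak interval.

    Distance is 0 when the TSS lies inside a peak, otherwise the unsigned
    gap to the nearest peak boundary on the same chromosome. Transcripts on
    peak-less chromosomes get ``inf`` and are excluded from the summary,
    which reports the fraction of transcripts within ``d`` bp for each
    threshold.
    """
    records = []
    for t in transcripts:
        pos = tss_of(t)
        ivs = peaks.intervals.get(t.chrom)
        if not ivs:
            d: float = math.inf
        else:
            d = float(_nearest_peak_distance(pos, ivs))
        records.append(TssDistanceRecord(t.transcript_id, peaks.name, d))
    finite = [r.distance for r in records if math.isfinite(r.distance)]
    summary = {
        thr: (sum(1 for d in finite if d <= thr) / len(finite)) if finite else 0.0
        for thr in summary_thresholds
    }
    return records, summary
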