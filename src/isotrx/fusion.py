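"""Fusion-transcript detection from chimeric long-read alignments.

A long read aligning in pieces to two or more well-separated genomic loci
is a fusion candidate. Four conjunctive criteria decide the call:

1. every locus maps at least 10% of the query transcript;
2. the combined alignment coverage of the query is at least 99%;
3. every pair of loci is on different chromosomes or more than 100 kb
   apart;
4. at least two short reads span the fusion junction.

Reads passing 1-4 are tier-1 fusions. A verification shortlist (tier-2)
additionally requires the flanking short-read counts a and b on either
side of the junction to be below twice the spanning count s (a/s < 2 and
b/s < 2), i.e. the fusion is expressed comparably to its flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .model import ChimericAlignment, GeneModel, exonic_overlap_bp

__all__ = [
    "FusionParams",
    "FusionCandidate",
    "JunctionSupport",
    "CRITERIA",
    "detect_candidates",
    "audit_reads",
    "count_junction_support",
    "apply_support_filters",
    "assign_parental_genes",
    "match_to_database",
]

CRITERIA = ("locus_fraction", "combined_coverage", "locus_distance", "support")


@dataclass(frozen=True)
class FusionParams:
    min_locus_query_fraction: float = 0.10
    min_combined_coverage: float = 0.99
    min_locus_distance: int = 100_000
    min_spanning_reads: int = 2
    max_flank_to_spanning_ratio: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.min_locus_query_fraction <= 1:
            raise ValueError("min_locus_query_fraction must be in (0, 1]")
        if not 0 < self.min_combined_coverage <= 1:
            raise ValueError("min_combined_coverage must be in (0, 1]")
        if self.min_locus_distance <= 0:
            raise ValueError("min_locus_distance must be positive")


@dataclass(frozen=True)
class JunctionSupport:
    s: int  # junction-spanning short-read count
    a: int  # flanking reads on the upstream parent
    b: int  # flanking reads on the downstream parent

    def __post_init__(self) -> None:
        if min(self.s, self.a, self.b) < 0:
            raise ValueError("support counts must be non-negative")


@dataclass
class FusionCandidate:
    query_id: str
    loci: list  # AlignedSegment, ordered by query interval
    criteria: dict[str, bool] = field(default_factory=dict)
    support: JunctionSupport | None = None
    gene_pair: tuple[str, str] | None = None

    @property
    def junction_query_positions(self) -> list[int]:
        """Query-coordinate breakpoints between consecutive loci."""
        return [
            (self.loci[i].query_end + self.loci[i + 1].query_start) // 2
            for i in range(len(self.loci) - 1)
        ]


def _union_covered(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _loci_separated(a, b, min_distance: int) -> bool:
    if a.chrom != b.chrom:
        return True
    gap = max(a.target_start, b.target_start) - min(a.target_end, b.target_end)
    return gap > min_distance


def evaluate_criteria(
    aln: ChimericAlignment, params: FusionParams
) -> dict[str, bool]:
    """Pass/fail of the three alignment-geometry criteria for one read.

    Criteria are conjunctive and evaluated independently, so a read's audit
    flags every criterion it fails, not just the first.
    """
    segs = aln.segments
    frac_ok = len(segs) >= 2 and all(
        seg.query_span / aln.query_length >= params.min_locus_query_fraction
        for seg in segs
    )
    covered = _union_covered([(s.query_start, s.query_end) for s in segs])
    cov_ok = covered / aln.query_length >= params.min_combined_coverage
    dist_ok = len(segs) >= 2 and all(
        _loci_separated(a, b, params.min_locus_distance)
        for a, b in combinations(segs, 2)
    )
    return {
        "locus_fraction": frac_ok,
        "combined_coverage": cov_ok,
        "locus_distance": dist_ok,
    }


def audit_reads(
    alignments: Sequence[ChimericAlignment], params: FusionParams
) -> dict[str, dict[str, bool]]:
    """Per-criterion audit of every chimeric read (>=2 segments)."""
    return {
        aln.query_id: evaluate_criteria(aln, params)
        for aln in alignments
        if aln.is_chimeric
    }


def detect_candidates(
    alignments: Sequence[ChimericAlignment], params: FusionParams | None = None
) -> list[FusionCandidate]:
    """Fusion candidates: chimeric reads passing the geometry criteria 1-3."""
    params = params or FusionParams()
    out = []
    for aln in alignments:
        if not aln.is_chimeric:
            continue
        crit = evaluate_criteria(aln, params)
        if all(crit.values()):
            loci = sorted(aln.segments, key=lambda s: (s.query_start, s.query_end))
            out.append(FusionCandidate(aln.query_id, loci, dict(crit)))
    return out


def count_junction_support(
    candidate: FusionCandidate,
    coverage_table: Mapping[str, tuple[int, int, int]] | None = None,
    short_reads: Sequence[tuple[int, int]] | None = None,
    overhang: int = 8,
    flank_window: int = 100,
) -> JunctionSupport:
    """Short-read support for a candidate's (first) fusion junction.

    Two input modes. A precomputed table mapping query_id -> (s, a, b) is
    passed through verbatim. Otherwise ``short_reads`` are read alignment
    intervals on the fusion-transcript coordinate system: a read spans the
    junction when it covers >= ``overhang`` aligned bases on both sides of
    the breakpoint (a read ending exactly at the junction does not count);
    a and b count reads overlapping the ``flank_window`` bp immediately
    interior to the junction on each parent.
    """
    if coverage_table is not None:
        if candidate.query_id not in coverage_table:
            raise KeyError(
                f"{candidate.query_id}: junction unresolved (no coverage row)"
            )
        s, a, b = coverage_table[candidate.query_id]
        return JunctionSupport(int(s), int(a), int(b))
    if short_reads is None:
        raise ValueError("supply either a coverage table or short reads")
    j = candidate.junction_query_positions[0]
    s = sum(1 for rs, re in short_reads if rs <= j - overhang and re >= j + overhang)
    a = sum(1 for rs, re in short_reads if rs < j and re > j - flank_window)
    b = sum(1 for rs, re in short_reads if rs < j + flank_window and re > j)
    return JunctionSupport(s, a, b)


def apply_support_filters(
    candidates: Sequence[FusionCandidate],
    params: FusionParams | None = None,
) -> tuple[list[FusionCandidate], list[FusionCandidate]]:
    """Split supported candidates into tier-1 fusions and a tier-2 shortlist.

    Tier-1: spanning-read count s >= min_spanning_reads (criterion 4).
    Tier-2: tier-1 fusions whose flank counts satisfy a/s < ratio and
    b/s < ratio; with s = 0 the ratios are undefined and the candidate
    fails tier-2 by definition.
    """
    params = params or FusionParams()
    tier1, tier2 = [], []
    for cand in candidates:
        if cand.support is None:
            continue
        sup = cand.support
        ok4 = sup.s >= params.min_spanning_reads
        cand.criteria["support"] = ok4
        if not ok4:
            continue
        tier1.append(cand)
        if sup.s > 0 and (
            sup.a / sup.s < params.max_flank_to_spanning_ratio
            and sup.b / sup.s < params.max_flank_to_spanning_ratio
        ):
            tier2.append(cand)
    return tier1, tier2


def assign_parental_genes(
    candidate: FusionCandidate, annotation: Sequence[GeneModel]
) -> tuple[str, ...]:
    """Assign each locus its parental gene by maximal same-strand exonic
    overlap; loci hitting no gene get a novel-locus label."""
    labels = []
    for seg in candidate.loci:
        best_gene, best_ov = None, 0
        for g in annotation:
            if g.chrom != seg.chrom or g.strand != seg.strand:
                continue
            ov = max(
                exonic_overlap_bp([(seg.target_start, seg.target_end)], t.exons)
                for t in g.transcripts
            )
            if ov > best_ov or (ov == best_ov and ov > 0
                                and best_gene is not None
                                and g.gene_id < best_gene):
                best_gene, best_ov = g.gene_id, ov
        if best_gene is None:
            labels.append(f"novel_locus:{seg.chrom}:{seg.target_start}")
        else:
            labels.append(best_gene)
    candidate.gene_pair = tuple(labels[:2])
    return tuple(labels)


def match_to_database(
    detected_pairs: Sequence[tuple[str, str]],
    db_records: Sequence[tuple[str, str]],
    symbol_map: Mapping[str, str] | None = None,
) -> list[dict]:
    """Match detected gene pairs against a known-fusion database.

    Database records hold gene symbols; ``symbol_map`` translates them to
    the stable gene ids used by the detector. Matching is on the unordered
    pair. Records with unmapped symbols are skipped and reported in the
    output rows with ``skipped=True``.
    """
    out = []
    mapped_db = set()
    for sym_a, sym_b in db_records:
        if symbol_map is not None:
            ga, gb = symbol_map.get(sym_a), symbol_map.get(sym_b)
            if ga is None or gb is None:
                out.append({
                    "db_pair": (sym_a, sym_b), "skipped": True,
                    "reason": "unmapped symbol",
                })
                continue
        else:
            ga, gb = sym_a, sym_b
        mapped_db.add(frozenset((ga, gb)))
    for pair in detected_pairs:
        key = frozenset(pair)
        out.append({
            "detected_pair": tuple(pair),
            "in_database": key in mapped_db,
            "skipped": False,
        })
    return out
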