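"""Alternative-splicing event enumeration and isoform-usage divergence.

Events follow the seven local types standard in transcriptome analysis
(SE, MXE, A5, A3, AF, AL, RI), derived pairwise from the transcript models
of one gene and deduplicated by defining coordinates.

The per-gene divergence score D compares the isoform set of each cancer
sample against the normal sample with a Jaccard distance and sums the
terms: D_j = sum_i (1 - |a_i n b| / |a_i u b|). A gene whose isoform
repertoire differs more between cancer and normal scores higher; with four
cancer samples D ranges over [0, 4].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .model import GeneModel, TranscriptModel, spans_overlap

__all__ = [
    "ASEvent",
    "DivergenceScore",
    "ProportionTestResult",
    "EVENT_TYPES",
    "enumerate_as_events",
    "event_type_proportions",
    "divergence_score",
    "rank_spliced_genes",
]

EVENT_TYPES = ("SE", "MXE", "A5", "A3", "AF", "AL", "RI")


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    event_type: str
    coordinates: tuple[int, ...]
    inclusion: frozenset[str] = frozenset()
    exclusion: frozenset[str] = frozenset()

    @property
    def event_id(self) -> str:
        coords = "-".join(map(str, self.coordinates))
        return f"{self.gene_id};{self.event_type};{coords}"


@dataclass
class DivergenceScore:
    gene_id: str
    terms: list[float]

    @property
    def d(self) -> float:
        return float(sum(self.terms))


@dataclass
class ProportionTestResult:
    table: np.ndarray  # samples x event types, raw counts
    chi2: float
    dof: int
    p_value: float
    percentages: "dict[str, dict[str, float]]" = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Event enumeration


def _pair_events(t1: TranscriptModel, t2: TranscriptModel,
                 gene_id: str, strand: str) -> list[ASEvent]:
    """All local events derivable from one ordered transcript pair."""
    events: list[ASEvent] = []
    in1, in2 = set(t1.introns), set(t2.introns)
    ex1, ex2 = list(t1.exons), list(t2.exons)
    id1, id2 = frozenset([t1.transcript_id]), frozenset([t2.transcript_id])

    # SE: internal exon of t1 flanked by introns whose outer boundaries form
    # one skipping intron of t2
    for k in range(1, len(ex1) - 1):
        xs, xe = ex1[k]
        left = t1.introns[k - 1]   # (prev_exon_end, xs)
        right = t1.introns[k]      # (xe, next_exon_start)
        skip = (left[0], right[1])
        if skip in in2:
            events.append(ASEvent(gene_id, "SE",
                                  (left[0], xs, xe, right[1]), id1, id2))

    # RI: an intron of t1 fully inside an exon of t2 whose bounds equal the
    # flanking exon boundaries of t1
    for k, (i_s, i_e) in enumerate(t1.introns):
        up_start = ex1[k][0]
        down_end = ex1[k + 1][1]
        if (up_start, down_end) in set(ex2):
            events.append(
                ASEvent(gene_id, "RI", (up_start, i_s, i_e, down_end), id2, id1)
            )

    # MXE: exons e1 (t1 only) and e2 (t2 only), disjoint, flanked by shared
    # upstream donor and downstream acceptor boundaries
    for k in range(1, len(ex1) - 1):
        e1 = ex1[k]
        c = t1.introns[k - 1][0]
        d = t1.introns[k][1]
        for m in range(1, len(ex2) - 1):
            e2 = ex2[m]
            if spans_overlap(e1, e2):
                continue
            if t2.introns[m - 1][0] == c and t2.introns[m][1] == d:
                lo, hi = sorted([e1, e2])
                events.append(
                    ASEvent(gene_id, "MXE", (c, *lo, *hi, d), id1, id2)
                )

    # Alternative splice sites / terminal exons: intron pairs sharing
    # exactly one boundary. The differing boundaries must sit on exons that
    # overlap each other (a splice-site shift); non-overlapping *terminal*
    # exons spliced to a shared boundary are AF/AL; anything else (e.g. the
    # intron pair induced by a skipped exon) is not a local event here.
    for ai, a in enumerate(t1.introns):
        for bi, b in enumerate(t2.introns):
            if a == b:
                continue
            if a[1] == b[1] and a[0] != b[0]:
                # shared right boundary; exons ending at the differing left
                # boundaries
                el1, el2 = ex1[ai], ex2[bi]
                if spans_overlap(el1, el2):
                    etype = "A5" if strand == "+" else "A3"
                    coords = (min(a[0], b[0]), max(a[0], b[0]), a[1])
                elif ai == 0 and bi == 0:
                    etype = "AF" if strand == "+" else "AL"
                    lo, hi = sorted([el1, el2])
                    coords = (*lo, *hi, a[1])
                else:
                    continue
                events.append(ASEvent(gene_id, etype, coords, id1, id2))
            elif a[0] == b[0] and a[1] != b[1]:
                er1, er2 = ex1[ai + 1], ex2[bi + 1]
                if spans_overlap(er1, er2):
                    etype = "A3" if strand == "+" else "A5"
                    coords = (a[0], min(a[1], b[1]), max(a[1], b[1]))
                elif ai == len(t1.introns) - 1 and bi == len(t2.introns) - 1:
                    etype = "AL" if strand == "+" else "AF"
                    lo, hi = sorted([er1, er2])
                    coords = (a[0], *lo, *hi)
                else:
                    continue
                events.append(ASEvent(gene_id, etype, coords, id1, id2))
    return events


def enumerate_as_events(gene: GeneModel) -> list[ASEvent]:
    """Enumerate all pairwise-derivable local splicing events of a gene.

    Events are deduplicated by (type, defining coordinates); inclusion and
    exclusion transcript sets are merged across the pairs that support the
    same event. A single-transcript gene yields no events.
    """
    if len(gene.transcripts) < 2:
        return []
    merged: dict[tuple[str, tuple[int, ...]], ASEvent] = {}
    for t1, t2 in combinations(gene.transcripts, 2):
        for a, b in ((t1, t2), (t2, t1)):
            for ev in _pair_events(a, b, gene.gene_id, gene.strand):
                key = (ev.event_type, ev.coordinates)
                prev = merged.get(key)
                if prev is None:
                    merged[key] = ev
                else:
                    merged[key] = ASEvent(
                        ev.gene_id, ev.event_type, ev.coordinates,
                        prev.inclusion | ev.inclusion,
                        prev.exclusion | ev.exclusion,
                    )
    return sorted(merged.values(), key=lambda e: (e.event_type, e.coordinates))


# ---------------------------------------------------------------------------
# Proportions and chi-square


def event_type_proportions(
    sample_events: Mapping[str, Sequence[ASEvent]],
) -> ProportionTestResult:
    """Per-sample event-type percentage table plus a chi-square test.

    The chi-square statistic is computed on the raw count contingency table
    (samples x event types), without continuity correction; percentages per
    sample sum to 100. Samples with zero events are excluded with a warning.
    """
    counts: dict[str, dict[str, int]] = {}
    for sample, events in sample_events.items():
        vec = {et: 0 for et in EVENT_TYPES}
        for ev in events:
            vec[ev.event_type] += 1
        if sum(vec.values()) == 0:
            warnings.warn(f"sample {sample!r} has no events; excluded")
            continue
        counts[sample] = vec
    if len(counts) < 2:
        raise ValueError("need >=2 samples with >=1 event each")
    samples = sorted(counts)
    # drop all-zero event-type columns: they contribute no information and
    # break the chi-square expected-count denominator
    used_types = [et for et in EVENT_TYPES
                  if any(counts[s][et] for s in samples)]
    table = np.array([[counts[s][et] for et in used_types] for s in samples])
    if table.shape[1] < 2:
        chi2, p, dof = 0.0, 1.0, 0
    else:
        chi2, p, dof, _ = chi2_contingency(table, correction=False)
    percentages = {
        s: {
            et: 100.0 * counts[s][et] / sum(counts[s].values())
            for et in EVENT_TYPES
        }
        for s in samples
    }
    return ProportionTestResult(table, float(chi2), int(dof), float(p),
                                percentages)


# ---------------------------------------------------------------------------
# Divergence score D


def divergence_score(
    normal: Mapping[str, set],
    cancers: Sequence[Mapping[str, set]],
) -> list[DivergenceScore]:
    """Per-gene isoform-usage divergence of cancer samples vs the normal.

    ``normal`` and each element of ``cancers`` map gene_id to the set of
    isoform identity keys observed in that sample. For each gene present in
    any sample, D = sum over cancer samples of (1 - |a n b| / |a u b|)
    where a is the cancer isoform set and b the normal set. A comparison in
    which both sets are empty contributes 0 (no divergence when the gene is
    absent from both).
    """
    if not cancers:
        raise ValueError("at least one cancer sample required")
    genes: set[str] = set(normal)
    for c in cancers:
        genes.update(c)
    scores = []
    for gid in sorted(genes):
        b = normal.get(gid, set())
        terms = []
        for c in cancers:
            a = c.get(gid, set())
            union = a | b
            if not union:
                terms.append(0.0)
            else:
                terms.append(1.0 - len(a & b) / len(union))
        scores.append(DivergenceScore(gid, terms))
    return scores


def rank_spliced_genes(
    scores: Sequence[DivergenceScore],
    top_n: int | None = None,
    top_fraction: float | None = None,
) -> list[str]:
    """Gene ids ordered by descending D, ties broken lexicographically."""
    if not scores:
        raise ValueError("scores must be non-empty")
    if top_n is None:
        if top_fraction is None:
            top_n = len(scores)
        else:
            top_n = int(round(top_fraction * len(scores)))
    if top_n > len(scores):
        warnings.warn(
            f"requested top {top_n} of {len(scores)} genes; returning all"
        )
        top_n = len(scores)
    ordered = sorted(scores, key=lambda s: (-s.d, s.gene_id))
    return [s.gene_id for s in ordered[:top_n]]
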