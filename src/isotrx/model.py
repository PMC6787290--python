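"""Core domain types for long-read transcriptome analysis.

All genomic coordinates are 0-based half-open; conversion from 1-based
formats (GTF, SAM) happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "AlignedSegment",
    "ChimericAlignment",
    "PeakSet",
    "ExpressionMatrix",
    "intron_chain_key",
    "tss_of",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its structural invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript on a genome.

    Parameters
    ----------
    transcript_id : str
    gene_id : str or None
        Parent gene if known.
    chrom : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        0-based half-open genomic intervals, sorted ascending,
        non-overlapping, separated by >=1 bp introns.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for start, end in exons:
            if start >= end:
                raise ValidationError(
                    f"{self.transcript_id}: empty or inverted exon ({start}, {end})"
                )
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0 + 1:
                raise ValidationError(
                    f"{self.transcript_id}: exons ({s0},{e0}) and ({s1},{e1}) "
                    "overlap or abut without an intron"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing chrom and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "other"  # protein_coding | noncoding | other

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"{self.gene_id}: transcript {t.transcript_id} on "
                    f"{t.chrom}{t.strand}, gene on {self.chrom}{self.strand}"
                )

    @property
    def span(self) -> tuple[int, int]:
        """(min exon start, max exon end) over all member transcripts."""
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned piece of a read: query interval <-> genomic interval."""

    query_start: int
    query_end: int
    chrom: str
    strand: str
    target_start: int
    target_end: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.query_start < self.query_end:
            raise ValidationError(
                f"segment query interval ({self.query_start}, {self.query_end}) empty"
            )
        if not self.target_start < self.target_end:
            raise ValidationError(
                f"segment target interval ({self.target_start}, {self.target_end}) empty"
            )

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class ChimericAlignment:
    """All aligned segments of one long-read query.

    A read mapping in pieces to two or more well-separated loci is the raw
    signal of a fusion transcript; a read with zero segments is unaligned.
    """

    query_id: str
    query_length: int
    segments: list[AlignedSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.query_length <= 0:
            raise ValidationError(f"{self.query_id}: query_length must be positive")
        for seg in self.segments:
            if seg.query_start < 0 or seg.query_end > self.query_length:
                raise ValidationError(
                    f"{self.query_id}: segment query interval "
                    f"({seg.query_start}, {seg.query_end}) outside read of "
                    f"length {self.query_length}"
                )

    @property
    def is_aligned(self) -> bool:
        return bool(self.segments)

    @property
    def is_chimeric(self) -> bool:
        return len(self.segments) >= 2


class PeakSet:
    """Named per-chromosome interval sets (CAGE tags, histone-mark peaks)."""

    def __init__(self, name: str, intervals: dict[str, Iterable[tuple[int, int]]]):
        self.name = name
        self.intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted((int(s), int(e)) for s, e in ivs)
            for s, e in ivs:
                if s >= e:
                    raise ValidationError(f"{name}/{chrom}: empty interval ({s},{e})")
            self.intervals[chrom] = ivs

    def __repr__(self) -> str:  # pragma: no cover
        n = sum(len(v) for v in self.intervals.values())
        return f"PeakSet({self.name!r}, {n} intervals)"


class ExpressionMatrix:
    """Feature x sample matrix of non-negative expression values.

    A thin wrapper over a pandas DataFrame that enforces rectangularity and
    non-negativity and offers row lookup by feature id.
    """

    def __init__(self, values: pd.DataFrame):
        if (values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.values = values

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.values.index


IsoformKey = tuple


def intron_chain_key(t: TranscriptModel) -> IsoformKey:
    """Structural identity key of a transcript.

    Multi-exon transcripts are identified by their ordered intron chain
    (chrom, strand, intron boundary list); terminal-exon end variation is
    ignored, which is the standard way to equate isoforms across samples.
    Mono-exonic transcripts carry their exact exon bounds instead.
    """
    if len(t.exons) == 1:
        s, e = t.exons[0]
        return (t.chrom, t.strand, "mono", s, e)
    return (t.chrom, t.strand, t.introns)


def tss_of(t: TranscriptModel) -> int:
    """Transcription start site: the 5'-most transcribed base (0-based).

    First genomic position of the transcript structure on the plus strand;
    the last base of the last exon on the minus strand.
    """
    if t.strand == "+":
        return t.exons[0][0]
    return t.exons[-1][1] - 1


def spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two half-open intervals; 0 if they overlap or abut."""
    if spans_overlap(a, b):
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


def exonic_overlap_bp(exons_a: Sequence[tuple[int, int]],
                      exons_b: Sequence[tuple[int, int]]) -> int:
    """Total overlapping bp between two exon lists (both sorted)."""
    total = 0
    i = j = 0
    a = sorted(exons_a)
    b = sorted(exons_b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total
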