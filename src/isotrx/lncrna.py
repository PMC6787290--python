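"""lncRNA identification, cancer-specific lincRNA set logic, target genes.

The candidate lncRNA set is the consensus of four coding-potential
predictors (CNCI, PLEK, CPC, Pfam-scan): a transcript flagged coding by
any predictor is removed. lincRNAs are the intergenic subset — no genomic
overlap with a protein-coding gene span on either strand. Cancer-specific
lincRNAs are those seen in cancer samples but absent from the normal
sample and from a reference lincRNA catalog. Target genes of a lincRNA
combine co-expression (Pearson r above threshold at a p-value cutoff)
with co-location (gene span within a genomic window of the lincRNA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .model import ExpressionMatrix, GeneModel, TranscriptModel, span_gap

__all__ = [
    "PREDICTORS",
    "TargetParams",
    "consensus_noncoding_filter",
    "classify_lincRNA",
    "cancer_specific_lincRNAs",
    "predict_targets",
    "find_premirna",
]

PREDICTORS = ("CNCI", "PLEK", "CPC", "PfamScan")


class MissingCallError(KeyError):
    """A candidate transcript has no row (or an incomplete row) of
    coding-potential calls."""


@dataclass(frozen=True)
class TargetParams:
    """Thresholds for co-expression/co-location target calling."""

    r_threshold: float = 0.95
    p_threshold: float = 0.001
    window: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")


def consensus_noncoding_filter(
    candidates: Iterable[str],
    calls: Mapping[str, Mapping[str, str]],
) -> set[str]:
    """Keep only transcripts all four predictors call noncoding.

    ``calls`` maps transcript_id -> {predictor: "coding"|"noncoding"}; every
    candidate must have all four predictors present.
    """
    kept = set()
    for tid in candidates:
        row = calls.get(tid)
        if row is None:
            raise MissingCallError(f"no coding-potential calls for {tid!r}")
        missing = [p for p in PREDICTORS if p not in row]
        if missing:
            raise MissingCallError(
                f"{tid!r}: missing predictor calls {missing}"
            )
        if all(row[p] == "noncoding" for p in PREDICTORS):
            kept.add(tid)
    return kept


def classify_lincRNA(
    lnc: TranscriptModel, annotation: Sequence[GeneModel]
) -> bool:
    """True iff the lncRNA is intergenic: its span overlaps no
    protein-coding gene span on either strand."""
    span = (lnc.start, lnc.end)
    for g in annotation:
        if g.biotype != "protein_coding" or g.chrom != lnc.chrom:
            continue
        if span_gap(span, g.span) == 0:
            return False
    return True


def cancer_specific_lincRNAs(
    cancer_sets: Sequence[set[str]],
    normal_set: set[str],
    reference_catalog: set[str],
    mode: str = "union",
) -> set[str]:
    """lincRNAs present in cancer samples but absent from the normal
    sample and the reference catalog.

    ``mode="union"`` (default) takes lincRNAs detected in any cancer
    sample; ``mode="intersection"`` requires detection in all of them.
    """
    if not cancer_sets:
        raise ValueError("at least one cancer set required")
    if mode == "union":
        pool: set[str] = set().union(*cancer_sets)
    elif mode == "intersection":
        pool = set.intersection(*map(set, cancer_sets))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pool - (set(normal_set) | set(reference_catalog))


def _feature_span(f: TranscriptModel | GeneModel) -> tuple[str, tuple[int, int]]:
    if isinstance(f, GeneModel):
        return f.chrom, f.span
    return f.chrom, (f.start, f.end)


def predict_targets(
    lincRNAs: Sequence[TranscriptModel],
    coding_genes: Sequence[GeneModel],
    expr: ExpressionMatrix,
    params: TargetParams | None = None,
) -> list[dict]:
    """Co-expression/co-location target genes of each lincRNA.

    A (lincRNA, gene) pair is reported iff Pearson r > ``r_threshold`` with
    two-sided p < ``p_threshold`` (the t-transform of r with n-2 degrees of
    freedom) and the gap between the two genomic spans is below ``window``
    (overlapping spans count as distance 0). Pairs with a zero-variance
    expression vector are skipped with a warning (r undefined).
    """
    params = params or TargetParams()
    n = len(expr.samples)
    if n < 3:
        raise ValueError("need >=3 samples for a correlation p-value")
    out = []
    for lnc in lincRNAs:
        if lnc.transcript_id not in expr:
            raise KeyError(f"{lnc.transcript_id} absent from expression matrix")
        x = expr.row(lnc.transcript_id)
        lnc_chrom, lnc_span = _feature_span(lnc)
        for gene in coding_genes:
            if gene.gene_id not in expr:
                raise KeyError(f"{gene.gene_id} absent from expression matrix")
            g_chrom, g_span = _feature_span(gene)
            if g_chrom != lnc_chrom:
                continue
            gap = span_gap(lnc_span, g_span)
            if gap >= params.window:
                continue
            y = expr.row(gene.gene_id)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero-variance expression for pair "
                    f"({lnc.transcript_id}, {gene.gene_id}); skipped"
                )
                continue
            r, p = stats.pearsonr(x, y)
            if r > params.r_threshold and p < params.p_threshold:
                out.append({
                    "lincRNA": lnc.transcript_id,
                    "gene": gene.gene_id,
                    "r": float(r),
                    "p": float(p),
                    "distance": int(gap),
                })
    return sorted(out, key=lambda d: (d["lincRNA"], d["gene"]))


def _hairpin_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -2.5
    return aligner


def _best_local_hit(aligner, hairpin: str, target: str):
    if not aligner.score(hairpin, target):
        return None
    aln = aligner.align(hairpin, target)[0]
    matches = 0
    aligned_cols = 0
    q_aligned = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        q_aligned += qe - qs
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            aligned_cols += 1
            if hairpin[qi] == target[ti]:
                matches += 1
    if aligned_cols == 0:
        return None
    blocks_q = aln.aligned[0]
    span = blocks_q[-1][1] - blocks_q[0][0]
    return {
        "identity": matches / span if span else 0.0,
        "coverage": span / len(hairpin),
        "score": float(aln.score),
    }


def find_premirna(
    hairpins: Mapping[str, str],
    lincRNA_seqs: Mapping[str, str],
    min_identity: float = 0.90,
    min_hairpin_coverage: float = 0.90,
) -> list[dict]:
    """Search miRNA hairpins inside lincRNA sequences by local alignment.

    Each hairpin is aligned (match +1, mismatch -2, gaps -2.5) against each
    lincRNA and its reverse complement. A hit requires identity >=
    ``min_identity`` over >= ``min_hairpin_coverage`` of the hairpin length.
    U is normalized to T; empty sequences are skipped with a warning.
    """
    aligner = _hairpin_aligner()
    hits = []
    for hp_id, hp_seq in sorted(hairpins.items()):
        hp = hp_seq.upper().replace("U", "T")
        if not hp:
            warnings.warn(f"empty hairpin sequence {hp_id!r}; skipped")
            continue
        for lnc_id, lnc_seq in sorted(lincRNA_seqs.items()):
            lnc = lnc_seq.upper().replace("U", "T")
            if not lnc:
                warnings.warn(f"empty lincRNA sequence {lnc_id!r}; skipped")
                continue
            for strand, target in (
                ("+", lnc),
                ("-", str(Seq(lnc).reverse_complement())),
            ):
                res = _best_local_hit(aligner, hp, target)
                if (res and res["identity"] >= min_identity
                        and res["coverage"] >= min_hairpin_coverage):
                    hits.append({
                        "hairpin": hp_id, "lincRNA": lnc_id,
                        "strand": strand, **res,
                    })
                    break  # one hit per (hairpin, lincRNA)
    return hits
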