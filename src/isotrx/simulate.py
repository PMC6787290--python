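"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study design this pipeline targets: five cell
lines (one normal-like, four cancer), long reads aligned to a reference
annotation, a short-read junction-coverage table, an expression matrix,
per-sample lncRNA presence catalogs and a reference lincRNA catalog.
Everything is a pure function of the configuration (the seed is part of
it): identical inputs give byte-identical outputs.

Planted truth is emitted alongside every dataset so that the pipeline's
recovery can be checked exactly: fusion reads that satisfy all four
detection criteria or violate exactly one of them, cancer-specific
lincRNAs, correlated lincRNA-gene target pairs with decoys violating
exactly one of the two target rules, and one local splicing event of each
requested type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .model import (
    AlignedSegment,
    ChimericAlignment,
    ExpressionMatrix,
    GeneModel,
    TranscriptModel,
    span_gap,
)

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_reference",
    "simulate_fusion_alignments",
    "simulate_expression_with_targets",
    "simulate_presence_catalogs",
    "simulate_qc_metadata",
    "write_paf",
    "write_junction_table",
]

AS_TYPES = ("SE", "MXE", "A5", "A3", "AF", "AL", "RI")

FAILURE_CLASSES = (
    "fails_coverage",   # violates criterion 1 (per-locus query fraction)
    "fails_combined",   # violates criterion 2 (combined coverage)
    "fails_distance",   # violates criterion 3 (locus separation)
    "fails_support",    # violates criterion 4 (spanning short reads)
)


@dataclass
class SimulationConfig:
    """Study-condition knobs for all generators. ``seed`` is mandatory."""

    seed: int
    n_genes: int = 100                    # coding genes on the main chroms
    n_as_genes_per_type: int = 2          # genes planted with each AS event
    exons_per_transcript: tuple[int, int] = (3, 5)
    n_samples: int = 5                    # 1 normal + 4 cancer cell lines
    n_expression_samples: int = 12        # columns of the expression matrix
    n_chroms: int = 2
    chrom_length: int = 40_000_000
    intergenic_gap: int = 150_000         # keeps neighbours fusion-separable
    n_lincRNAs: int = 15
    n_target_pairs: int = 6               # planted correlated close pairs
    n_decoy_lowr: int = 3                 # close but uncorrelated
    n_decoy_far: int = 3                  # correlated but beyond the window
    target_window: int = 100_000
    target_r_threshold: float = 0.95
    expression_noise_sigma: float = 0.25  # log-normal multiplicative noise
    n_true_fusions: int = 20
    n_per_failure_class: int = 5
    n_non_fusion: int = 160
    fusion_read_length: int = 3000
    spanning_depth_mean: float = 8.0      # Poisson mean for s of true fusions
    flank_depth_mean: float = 6.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "n_lincRNAs", "n_true_fusions",
                     "n_per_failure_class", "n_non_fusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sample_names(self) -> list[str]:
        return ["normal"] + [f"cancer{i}" for i in range(1, self.n_samples)]


@dataclass
class SyntheticTruth:
    """Planted labels emitted with each synthetic dataset."""

    seed: int
    fusion_status: dict[str, str] = field(default_factory=dict)
    specific_lincRNAs: set[str] = field(default_factory=set)
    target_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_events: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["specific_lincRNAs"] = sorted(self.specific_lincRNAs)
        d["target_pairs"] = sorted(list(p) for p in self.target_pairs)
        return json.dumps(d, indent=2, sort_keys=True)


class CapacityError(ValueError):
    """The requested features do not fit on the configured chromosomes."""


# ---------------------------------------------------------------------------
# Reference annotation


def _event_transcript_pair(start: int) -> dict[str, list[list[tuple[int, int]]]]:
    """Exon structures (relative to ``start``) realizing exactly one local
    splicing event of each type between the two transcripts."""
    def sh(exons):
        return [(start + s, start + e) for s, e in exons]

    base4 = [(0, 200), (400, 600), (800, 1000), (1200, 1400)]
    base3 = [(0, 200), (400, 600), (800, 1000)]
    return {
        "SE": [sh(base4), sh([(0, 200), (800, 1000), (1200, 1400)])],
        "RI": [sh(base4), sh([(0, 200), (400, 1000), (1200, 1400)])],
        "A5": [sh(base4), sh([(0, 200), (400, 650), (800, 1000), (1200, 1400)])],
        "A3": [sh(base4), sh([(0, 200), (400, 600), (850, 1000), (1200, 1400)])],
        "MXE": [sh([(0, 200), (400, 600), (1200, 1400)]),
                sh([(0, 200), (700, 900), (1200, 1400)])],
        "AF": [sh(base3), sh([(250, 350), (400, 600), (800, 1000)])],
        "AL": [sh(base3), sh([(0, 200), (400, 600), (1100, 1300)])],
    }


def _random_exons(rng: np.random.Generator, start: int,
                  n_exons: int) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(100, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(200, 1200))
    return exons


def simulate_reference(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int], SyntheticTruth]:
    """Build a synthetic annotation with planted splicing events.

    Coding genes are laid out without overlap along the main chromosomes,
    separated by ``intergenic_gap``. The first ``n_as_genes_per_type``
    genes of each splicing-event type carry two isoforms differing by
    exactly that event; remaining genes are single-isoform. lincRNA loci
    live on a dedicated chromosome, each followed (except "isolated" ones)
    by a partner coding gene at a controlled gap so the co-location half
    of target calling has planted positives and decoys.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth(seed=cfg.seed)
    genes: list[GeneModel] = []
    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}

    # --- coding genes on main chromosomes
    planted: list[str] = []
    for etype in AS_TYPES:
        planted.extend([etype] * cfg.n_as_genes_per_type)
    if len(planted) > cfg.n_genes:
        raise CapacityError(
            f"{len(planted)} event genes requested but only {cfg.n_genes} genes"
        )
    chrom_idx, cursor = 0, 100_000
    for i in range(cfg.n_genes):
        gid = f"G{i + 1:04d}"
        chrom = f"chr{chrom_idx + 1}"
        strand = "+" if rng.random() < 0.7 else "-"
        if i < len(planted):
            etype = planted[i]
            strand = "+"
            pair = _event_transcript_pair(cursor)[etype]
            transcripts = [
                TranscriptModel(f"{gid}.{k + 1}", chrom, strand,
                                tuple(ex), gene_id=gid)
                for k, ex in enumerate(pair)
            ]
            truth.planted_events.append((gid, etype))
        else:
            n_ex = int(rng.integers(*cfg.exons_per_transcript, endpoint=True))
            exons = _random_exons(rng, cursor, n_ex)
            transcripts = [
                TranscriptModel(f"{gid}.1", chrom, strand,
                                tuple(exons), gene_id=gid)
            ]
        g = GeneModel(gid, chrom, strand, transcripts, biotype="protein_coding")
        genes.append(g)
        cursor = g.span[1] + cfg.intergenic_gap
        if cursor > cfg.chrom_length - 2_000_000:
            chrom_idx += 1
            cursor = 100_000
            if chrom_idx >= cfg.n_chroms:
                raise CapacityError(
                    "chromosomes too short for the requested gene count"
                )

    # --- lincRNA loci with partner coding genes on a dedicated chromosome
    if cfg.n_lincRNAs:
        chrom = "chrL"
        chrom_lengths[chrom] = max(
            5_000_000, (cfg.n_lincRNAs + 1) * 600_000
        )
        close_gap, far_gap, cluster_gap = 40_000, cfg.target_window + 50_000, 500_000
        n_paired_close = cfg.n_target_pairs + cfg.n_decoy_lowr
        cursor = 50_000
        for i in range(cfg.n_lincRNAs):
            lid = f"LINC{i + 1:03d}"
            lnc_exons = _random_exons(rng, cursor, 2)
            lnc = GeneModel(
                lid, chrom, "+",
                [TranscriptModel(f"{lid}.1", chrom, "+",
                                 tuple(lnc_exons), gene_id=lid)],
                biotype="noncoding",
            )
            genes.append(lnc)
            end = lnc.span[1]
            if i < n_paired_close:
                gap = close_gap
            elif i < n_paired_close + cfg.n_decoy_far:
                gap = far_gap
            else:
                gap = None  # isolated lincRNA, no partner
            if gap is not None:
                tg_id = f"TG{i + 1:03d}"
                tg_exons = _random_exons(rng, end + gap, 3)
                tg = GeneModel(
                    tg_id, chrom, "+",
                    [TranscriptModel(f"{tg_id}.1", chrom, "+",
                                     tuple(tg_exons), gene_id=tg_id)],
                    biotype="protein_coding",
                )
                genes.append(tg)
                end = tg.span[1]
            cursor = end + cluster_gap
        if cursor > chrom_lengths[chrom]:
            chrom_lengths[chrom] = cursor + 100_000
    return genes, chrom_lengths, truth


# ---------------------------------------------------------------------------
# Fusion alignments


def _segment_on_gene(gene: GeneModel, qs: int, qe: int,
                     offset: int = 0) -> AlignedSegment:
    start = gene.span[0] + offset
    return AlignedSegment(
        query_start=qs, query_end=qe, chrom=gene.chrom, strand=gene.strand,
        target_start=start, target_end=start + (qe - qs),
    )


def simulate_fusion_alignments(
    annotation: Sequence[GeneModel], cfg: SimulationConfig
) -> tuple[list[ChimericAlignment], dict[str, tuple[int, int, int]], SyntheticTruth]:
    """Chimeric long-read alignments with per-read planted fusion labels.

    Each failure class violates exactly its one named criterion and
    satisfies the other three; true fusions satisfy all four. The junction
    table rows (s, a, b) cover every chimeric read so criterion 4 can be
    audited independently of criteria 1-3.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = SyntheticTruth(seed=cfg.seed)
    coding = [g for g in annotation
              if g.biotype == "protein_coding" and not g.gene_id.startswith("TG")]
    n_pairs_needed = cfg.n_true_fusions + 3 * cfg.n_per_failure_class
    pairs = []
    for i in range(0, len(coding) - 1, 2):
        a, b = coding[i], coding[i + 1]
        if a.chrom != b.chrom or span_gap(a.span, b.span) > 110_000:
            pairs.append((a, b))
    if len(pairs) < n_pairs_needed + cfg.n_per_failure_class:
        raise CapacityError(
            f"need {n_pairs_needed + cfg.n_per_failure_class} separable gene "
            f"pairs, found {len(pairs)}"
        )
    alignments: list[ChimericAlignment] = []
    junctions: dict[str, tuple[int, int, int]] = {}
    L = cfg.fusion_read_length
    half = L // 2
    pair_iter = iter(pairs)

    def good_support() -> tuple[int, int, int]:
        s = 2 + int(rng.poisson(cfg.spanning_depth_mean))
        a = int(min(rng.poisson(cfg.flank_depth_mean), 2 * s - 1))
        b = int(min(rng.poisson(cfg.flank_depth_mean), 2 * s - 1))
        return s, a, b

    for k in range(cfg.n_true_fusions):
        qid = f"read_true_{k + 1:03d}"
        ga, gb = next(pair_iter)
        segs = [_segment_on_gene(ga, 0, half),
                _segment_on_gene(gb, half, L)]
        alignments.append(ChimericAlignment(qid, L, segs))
        junctions[qid] = good_support()
        truth.fusion_status[qid] = "true_fusion"

    for k in range(cfg.n_per_failure_class):
        qid = f"read_cov_{k + 1:03d}"
        ga, gb = next(pair_iter)
        cut = int(0.05 * L)  # one locus maps only 5% of the query
        segs = [_segment_on_gene(ga, 0, cut),
                _segment_on_gene(gb, cut, L)]
        alignments.append(ChimericAlignment(qid, L, segs))
        junctions[qid] = good_support()
        truth.fusion_status[qid] = "fails_coverage"

    for k in range(cfg.n_per_failure_class):
        qid = f"read_comb_{k + 1:03d}"
        ga, gb = next(pair_iter)
        gap_q = int(0.05 * L)  # 5% of the query aligns nowhere
        segs = [_segment_on_gene(ga, 0, half),
                _segment_on_gene(gb, half + gap_q, L)]
        alignments.append(ChimericAlignment(qid, L, segs))
        junctions[qid] = good_support()
        truth.fusion_status[qid] = "fails_combined"

    for k in range(cfg.n_per_failure_class):
        qid = f"read_dist_{k + 1:03d}"
        ga = pairs[k][0]  # loci inside one intergenic neighbourhood, 50 kb apart
        segs = [
            _segment_on_gene(ga, 0, half),
            _segment_on_gene(ga, half, L, offset=50_000),
        ]
        alignments.append(ChimericAlignment(qid, L, segs))
        junctions[qid] = good_support()
        truth.fusion_status[qid] = "fails_distance"

    for k in range(cfg.n_per_failure_class):
        qid = f"read_supp_{k + 1:03d}"
        ga, gb = next(pair_iter)
        segs = [_segment_on_gene(ga, 0, half),
                _segment_on_gene(gb, half, L)]
        alignments.append(ChimericAlignment(qid, L, segs))
        junctions[qid] = (int(rng.integers(0, 2)), int(rng.poisson(3)),
                          int(rng.poisson(3)))
        truth.fusion_status[qid] = "fails_support"

    for k in range(cfg.n_non_fusion):
        qid = f"read_lin_{k + 1:04d}"
        g = coding[k % len(coding)]
        alignments.append(
            ChimericAlignment(qid, L, [_segment_on_gene(g, 0, L - 5)])
        )
        truth.fusion_status[qid] = "non_fusion"

    return alignments, junctions, truth


# ---------------------------------------------------------------------------
# Expression with planted targets


def simulate_expression_with_targets(
    annotation: Sequence[GeneModel], cfg: SimulationConfig
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with planted correlated lincRNA-gene target pairs.

    Partner pairs are read off the annotation geometry: a lincRNA with a
    coding gene whose span sits within ``target_window`` is a "close"
    pair, a partner beyond the window is a "far" pair. The first
    ``n_target_pairs`` close pairs (sorted by id) become planted targets:
    their expression shares a latent profile with bounded jitter,
    rejection-sampled until the realized Pearson r exceeds the detection
    threshold. Remaining close pairs get independent profiles
    (rejection-sampled to r below 0.8): decoys violating the correlation
    rule. Far pairs get correlated profiles: decoys violating the distance
    rule. Only planted close pairs enter the truth table.
    """
    if cfg.n_expression_samples < 3:
        raise ValueError("need >=3 samples: correlation degenerate below that")
    rng = np.random.default_rng(cfg.seed + 2)
    truth = SyntheticTruth(seed=cfg.seed)
    n = cfg.n_expression_samples
    lincs = sorted(
        (g for g in annotation if g.biotype == "noncoding"),
        key=lambda g: g.gene_id,
    )
    coding = [g for g in annotation if g.biotype == "protein_coding"]

    close_pairs, far_pairs = [], []
    for lnc in lincs:
        for g in coding:
            if g.chrom != lnc.chrom:
                continue
            gap = span_gap(lnc.span, g.span)
            if gap < cfg.target_window:
                close_pairs.append((lnc, g))
            elif gap < 3 * cfg.target_window:
                far_pairs.append((lnc, g))

    def base_profile() -> np.ndarray:
        return np.exp(rng.normal(np.log(50.0), 1.0, size=n))

    def noisy(vec: np.ndarray, sigma: float) -> np.ndarray:
        return vec * np.exp(rng.normal(0.0, sigma, size=n))

    def correlated_pair() -> tuple[np.ndarray, np.ndarray]:
        for _ in range(1000):
            latent = base_profile()
            x = noisy(latent, cfg.expression_noise_sigma)
            y = noisy(latent, cfg.expression_noise_sigma)
            r = np.corrcoef(x, y)[0, 1]
            if r > cfg.target_r_threshold:
                return x, y
        raise RuntimeError("rejection sampling failed for a correlated pair")

    def uncorrelated_pair() -> tuple[np.ndarray, np.ndarray]:
        for _ in range(1000):
            x, y = base_profile(), base_profile()
            if abs(np.corrcoef(x, y)[0, 1]) < 0.8:
                return x, y
        raise RuntimeError("rejection sampling failed for an uncorrelated pair")

    rows: dict[str, np.ndarray] = {}
    for idx, (lnc, g) in enumerate(close_pairs):
        tid = lnc.transcripts[0].transcript_id
        if idx < cfg.n_target_pairs:
            x, y = correlated_pair()
            truth.target_pairs.add((tid, g.gene_id))
        else:
            x, y = uncorrelated_pair()
        rows[tid] = x
        rows[g.gene_id] = y
    for lnc, g in far_pairs:
        tid = lnc.transcripts[0].transcript_id
        x, y = correlated_pair()
        rows.setdefault(tid, x)
        rows.setdefault(g.gene_id, y)
    for lnc in lincs:
        rows.setdefault(lnc.transcripts[0].transcript_id, base_profile())
    for g in coding:
        rows.setdefault(g.gene_id, base_profile())

    samples = [f"S{i + 1:02d}" for i in range(n)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return ExpressionMatrix(df.sort_index()), truth


# ---------------------------------------------------------------------------
# Presence catalogs


_PRESENCE_CLASSES = (
    "cancer_only",          # -> cancer-specific (the truth set)
    "cancer_and_normal",
    "cancer_and_reference",
    "normal_only",
    "everywhere",
)


def simulate_presence_catalogs(
    annotation: Sequence[GeneModel], cfg: SimulationConfig
) -> tuple[dict[str, set[str]], set[str], SyntheticTruth]:
    """Per-sample lincRNA presence sets plus a reference catalog.

    lincRNA ids cycle through planting classes; the truth set holds
    exactly those planted in at least one cancer sample but neither in the
    normal sample nor in the reference catalog.
    """
    if cfg.n_samples < 2:
        raise ValueError("need >=2 samples, one designated normal")
    rng = np.random.default_rng(cfg.seed + 3)
    truth = SyntheticTruth(seed=cfg.seed)
    samples = cfg.sample_names
    presence: dict[str, set[str]] = {s: set() for s in samples}
    reference: set[str] = set()
    lincs = sorted(
        g.gene_id for g in annotation if g.biotype == "noncoding"
    )
    cancer_samples = samples[1:]
    for i, lid in enumerate(lincs):
        cls = _PRESENCE_CLASSES[i % len(_PRESENCE_CLASSES)]
        n_cancer = int(rng.integers(1, len(cancer_samples) + 1))
        chosen = list(rng.choice(cancer_samples, size=n_cancer, replace=False))
        if cls == "cancer_only":
            for s in chosen:
                presence[s].add(lid)
            truth.specific_lincRNAs.add(lid)
        elif cls == "cancer_and_normal":
            for s in chosen:
                presence[s].add(lid)
            presence["normal"].add(lid)
        elif cls == "cancer_and_reference":
            for s in chosen:
                presence[s].add(lid)
            reference.add(lid)
        elif cls == "normal_only":
            presence["normal"].add(lid)
        else:  # everywhere
            for s in samples:
                presence[s].add(lid)
            reference.add(lid)
    return presence, reference, truth


# ---------------------------------------------------------------------------
# QC metadata


def simulate_qc_metadata(cfg: SimulationConfig) -> list[dict]:
    """Per-sample read QC counts shaped like a long-read run summary."""
    rng = np.random.default_rng(cfg.seed + 4)
    rows = []
    for s in cfg.sample_names:
        ccs = int(rng.integers(300_000, 650_000))
        frac = rng.uniform(0.75, 0.88)
        flnc = int(ccs * frac)
        rows.append({
            "sample": s,
            "ccs_count": ccs,
            "with_5p_primer": int(ccs * rng.uniform(0.88, 0.93)),
            "with_3p_primer": int(ccs * rng.uniform(0.9, 0.95)),
            "with_polya": int(ccs * rng.uniform(0.88, 0.93)),
            "flnc_count": flnc,
            "mean_flnc_length": float(rng.integers(2200, 3100)),
        })
    return rows


# ---------------------------------------------------------------------------
# Text fixture writers


def write_paf(alignments: Sequence[ChimericAlignment],
              chrom_lengths: dict[str, int] | None = None) -> str:
    """Serialize alignments as PAF lines (one per segment; unmapped reads
    emit a placeholder line with '*' as target)."""
    lines = []
    for aln in alignments:
        if not aln.segments:
            lines.append("\t".join([
                aln.query_id, str(aln.query_length), "0", "0", "+",
                "*", "0", "0", "0", "0", "0", "0",
            ]))
            continue
        for seg in aln.segments:
            tlen = (chrom_lengths or {}).get(seg.chrom, seg.target_end + 1)
            span = seg.query_end - seg.query_start
            lines.append("\t".join([
                aln.query_id, str(aln.query_length),
                str(seg.query_start), str(seg.query_end), seg.strand,
                seg.chrom, str(tlen),
                str(seg.target_start), str(seg.target_end),
                str(span), str(span), str(seg.mapq),
            ]))
    return "\n".join(lines) + ("\n" if lines else "")


def write_junction_table(junctions: dict[str, tuple[int, int, int]]) -> str:
    lines = ["candidate\ts\ta\tb"]
    for qid in sorted(junctions):
        s, a, b = junctions[qid]
        lines.append(f"{qid}\t{s}\t{a}\t{b}")
    return "\n".join(lines) + "\n"
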