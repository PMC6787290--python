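"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: membership tests and exhaustive
scans instead of the index-based logic in the package, so that agreement
between the two routes is meaningful.
"""

from __future__ import annotations

from itertools import combinations


def brute_pair_events(t1, t2, strand: str) -> set[tuple[str, tuple]]:
    """All local events between two transcripts, by set membership."""
    out: set[tuple[str, tuple]] = set()
    ex1, ex2 = set(t1.exons), set(t2.exons)
    in1, in2 = set(t1.introns), set(t2.introns)

    # SE: exon (xs, xe) of t1 with flanking introns (p, xs), (xe, q) in t1
    # and the skipping intron (p, q) in t2
    for xs, xe in ex1:
        for p, ps in in1:
            if ps != xs:
                continue
            for qs, q in in1:
                if qs != xe:
                    continue
                if (p, q) in in2:
                    out.add(("SE", (p, xs, xe, q)))

    # RI: intron (s, e) of t1 whose flanking exons (a, s), (e, b) exist in
    # t1 while t2 has the merged exon (a, b)
    for s, e in in1:
        for a, a_end in ex1:
            if a_end != s:
                continue
            for b_start, b in ex1:
                if b_start != e:
                    continue
                if (a, b) in ex2:
                    out.add(("RI", (a, s, e, b)))

    # MXE: t1 exon u and t2 exon v, disjoint, both flanked by a shared
    # upstream intron start c and downstream intron end d
    for u in ex1:
        for v in ex2:
            if u == v or not (u[1] <= v[0] or v[1] <= u[0]):
                continue
            for c, cs in in1:
                if cs != u[0]:
                    continue
                for ds, d in in1:
                    if ds != u[1]:
                        continue
                    if (c, v[0]) in in2 and (v[1], d) in in2:
                        lo, hi = sorted([u, v])
                        out.add(("MXE", (c, *lo, *hi, d)))

    # splice-site shifts and terminal exon swaps
    introns1 = list(t1.introns)
    introns2 = list(t2.introns)
    for a in introns1:
        for b in introns2:
            if a == b:
                continue
            if a[1] == b[1] and a[0] != b[0]:
                el1 = next(e for e in t1.exons if e[1] == a[0])
                el2 = next(e for e in t2.exons if e[1] == b[0])
                if el1[0] < el2[1] and el2[0] < el1[1]:
                    etype = "A5" if strand == "+" else "A3"
                    out.add((etype, (min(a[0], b[0]), max(a[0], b[0]), a[1])))
                elif a == introns1[0] and b == introns2[0]:
                    etype = "AF" if strand == "+" else "AL"
                    lo, hi = sorted([el1, el2])
                    out.add((etype, (*lo, *hi, a[1])))
            elif a[0] == b[0] and a[1] != b[1]:
                er1 = next(e for e in t1.exons if e[0] == a[1])
                er2 = next(e for e in t2.exons if e[0] == b[1])
                if er1[0] < er2[1] and er2[0] < er1[1]:
                    etype = "A3" if strand == "+" else "A5"
                    out.add((etype, (a[0], min(a[1], b[1]), max(a[1], b[1]))))
                elif a == introns1[-1] and b == introns2[-1]:
                    etype = "AL" if strand == "+" else "AF"
                    lo, hi = sorted([er1, er2])
                    out.add((etype, (a[0], *lo, *hi)))
    return out


def brute_gene_events(gene) -> set[tuple[str, tuple]]:
    out: set[tuple[str, tuple]] = set()
    for t1, t2 in combinations(gene.transcripts, 2):
        out |= brute_pair_events(t1, t2, gene.strand)
        out |= brute_pair_events(t2, t1, gene.strand)
    return out


def brute_tss_distance(pos: int, intervals) -> float:
    """O(m) scan over every interval boundary."""
    best = float("inf")
    for s, e in intervals:
        if s <= pos < e:
            return 0.0
        best = min(best, abs(pos - s), abs(pos - (e - 1)))
    return best


def brute_sharing(sample_sets: dict) -> dict:
    names = sorted(sample_sets)
    counts: dict[tuple, int] = {}
    universe = set()
    for s in sample_sets.values():
        universe |= set(s)
    for key in universe:
        combo = tuple(n for n in names if key in sample_sets[n])
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def brute_fusion_pass(aln, params) -> bool:
    """Evaluate all three geometry criteria on one read, from scratch."""
    segs = aln.segments
    if len(segs) < 2:
        return False
    if any((s.query_end - s.query_start) / aln.query_length
           < params.min_locus_query_fraction for s in segs):
        return False
    covered = set()
    for s in segs:
        covered.update(range(s.query_start, s.query_end))
    if len(covered) / aln.query_length < params.min_combined_coverage:
        return False
    for s1, s2 in combinations(segs, 2):
        if s1.chrom != s2.chrom:
            continue
        gap = max(s1.target_start, s2.target_start) - min(
            s1.target_end, s2.target_end
        )
        if gap <= params.min_locus_distance:
            return False
    return True


def brute_divergence(normal: set, cancer_sets) -> float:
    d = 0.0
    for a in cancer_sets:
        union = set(a) | set(normal)
        if union:
            d += 1 - len(set(a) & set(normal)) / len(union)
    return d


def local_align_identity(query: str, target: str,
                         match=1.0, mismatch=-2.0, gap=-2.5):
    """Smith-Waterman with linear gap cost; returns (identity, coverage)
    of the best local alignment, measured on the query span."""
    n, m = len(query), len(target)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + (
                match if query[i - 1] == target[j - 1] else mismatch
            )
            s = max(0.0, diag, score[i - 1][j] + gap, score[i][j - 1] + gap)
            score[i][j] = s
            if s > best:
                best, bi, bj = s, i, j
    if best == 0:
        return 0.0, 0.0
    # traceback
    i, j = bi, bj
    matches = 0
    q_lo = i
    while i > 0 and j > 0 and score[i][j] > 0:
        s = score[i][j]
        diag = score[i - 1][j - 1] + (
            match if query[i - 1] == target[j - 1] else mismatch
        )
        if abs(s - diag) < 1e-9:
            if query[i - 1] == target[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif abs(s - (score[i - 1][j] + gap)) < 1e-9:
            i -= 1
        else:
            j -= 1
        q_lo = i
    span = bi - q_lo
    if span == 0:
        return 0.0, 0.0
    return matches / span, span / len(query)
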