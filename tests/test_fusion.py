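from itertools import product

import pytest

from isotrx import fusion
from isotrx.model import AlignedSegment, ChimericAlignment, GeneModel, TranscriptModel

from oracles import brute_fusion_pass


def seg(qs, qe, chrom, ts, te, strand="+"):
    return AlignedSegment(qs, qe, chrom, strand, ts, te)


def read(qid, qlen, segments):
    return ChimericAlignment(qid, qlen, segments)


@pytest.fixture()
def hand_candidate():
    # qlen 3000: locus A covers 50%, locus B 49.7%; union 99.7%; ~199 kb apart
    return read("r", 3000, [
        seg(0, 1500, "chr1", 1_000_000, 1_001_500),
        seg(1500, 2990, "chr1", 1_200_000, 1_201_490),
    ])


class TestGeometryCriteria:
    def test_hand_evaluated_read_passes_all_three(self, hand_candidate):
        crit = fusion.evaluate_criteria(hand_candidate, fusion.FusionParams())
        assert crit == {"locus_fraction": True, "combined_coverage": True,
                        "locus_distance": True}
        assert len(fusion.detect_candidates([hand_candidate])) == 1

    def test_loci_fifty_kb_apart_fail_distance_only(self):
        r = read("r", 3000, [
            seg(0, 1500, "chr1", 1_000_000, 1_001_500),
            seg(1500, 2990, "chr1", 1_051_500, 1_052_990),
        ])
        crit = fusion.evaluate_criteria(r, fusion.FusionParams())
        assert crit["locus_distance"] is False
        assert crit["locus_fraction"] and crit["combined_coverage"]

    def test_five_percent_locus_fails_fraction(self):
        r = read("r", 3000, [
            seg(0, 150, "chr1", 1_000_000, 1_000_150),
            seg(150, 3000, "chr2", 1_000_000, 1_002_850),
        ])
        crit = fusion.evaluate_criteria(r, fusion.FusionParams())
        assert crit["locus_fraction"] is False
        assert crit["combined_coverage"] and crit["locus_distance"]

    def test_overlapping_query_intervals_not_double_counted(self):
        # two 60% segments overlapping on the query: union is 90%, not 120%
        r = read("r", 1000, [
            seg(0, 600, "chr1", 0, 600),
            seg(300, 900, "chr2", 0, 600),
        ])
        crit = fusion.evaluate_criteria(r, fusion.FusionParams())
        assert crit["combined_coverage"] is False

    def test_different_chromosomes_always_pass_distance(self):
        r = read("r", 1000, [
            seg(0, 500, "chr1", 100, 600),
            seg(500, 1000, "chr2", 100, 600),
        ])
        assert fusion.evaluate_criteria(r, fusion.FusionParams())["locus_distance"]

    def test_three_locus_read_needs_every_pair_separated(self):
        base = [
            seg(0, 400, "chr1", 0, 400),
            seg(400, 700, "chr2", 0, 300),
            seg(700, 1000, "chr2", 50_000, 50_300),  # 49.7 kb from locus 2
        ]
        r = read("r", 1000, base)
        assert not fusion.evaluate_criteria(r, fusion.FusionParams())["locus_distance"]

    def test_matches_brute_force_on_synthetic_reads(self, fusion_data):
        alignments, _, _ = fusion_data
        params = fusion.FusionParams()
        got = {c.query_id for c in fusion.detect_candidates(alignments, params)}
        expected = {a.query_id for a in alignments if brute_fusion_pass(a, params)}
        assert got == expected


class TestJunctionSupport:
    def test_table_passthrough(self, hand_candidate):
        cand = fusion.detect_candidates([hand_candidate])[0]
        sup = fusion.count_junction_support(cand, {"r": (10, 15, 12)})
        assert (sup.s, sup.a, sup.b) == (10, 15, 12)

    def test_simulated_reads_straddling_junction(self, hand_candidate):
        cand = fusion.detect_candidates([hand_candidate])[0]
        j = cand.junction_query_positions[0]  # 1500
        reads = [(j - 50, j + 50), (j - 8, j + 8), (j - 100, j + 9)]
        sup = fusion.count_junction_support(cand, short_reads=reads)
        assert sup.s == 3

    def test_read_ending_exactly_at_junction_does_not_span(self, hand_candidate):
        cand = fusion.detect_candidates([hand_candidate])[0]
        j = cand.junction_query_positions[0]
        sup = fusion.count_junction_support(
            cand, short_reads=[(j - 100, j), (j, j + 100)]
        )
        assert sup.s == 0
        assert sup.a == 1 and sup.b == 1  # both still flank

    def test_unresolved_junction_raises(self, hand_candidate):
        cand = fusion.detect_candidates([hand_candidate])[0]
        with pytest.raises(KeyError, match="unresolved"):
            fusion.count_junction_support(cand, {"other": (1, 1, 1)})


class TestSupportFilters:
    def make(self, s, a, b):
        cand = fusion.FusionCandidate("q", [])
        cand.support = fusion.JunctionSupport(s, a, b)
        return cand

    def test_comparable_expression_reaches_tier2(self):
        t1, t2 = fusion.apply_support_filters([self.make(10, 15, 12)])
        assert len(t1) == 1 and len(t2) == 1  # 1.5 < 2 and 1.2 < 2

    def test_single_spanning_read_fails_tier1(self):
        t1, t2 = fusion.apply_support_filters([self.make(1, 0, 0)])
        assert t1 == [] and t2 == []

    def test_flank_dominated_fusion_stays_tier1_only(self):
        t1, t2 = fusion.apply_support_filters([self.make(5, 20, 5)])
        assert len(t1) == 1 and t2 == []  # a/s = 4 >= 2

    def test_tier2_subset_of_tier1(self):
        cands = [self.make(s, a, b)
                 for s, a, b in [(3, 1, 1), (2, 10, 1), (0, 0, 0), (7, 2, 2)]]
        t1, t2 = fusion.apply_support_filters(cands)
        assert set(map(id, t2)) <= set(map(id, t1))


class TestParentalGenes:
    annotation = [
        GeneModel("G1", "chr1", "+",
                  [TranscriptModel("G1.1", "chr1", "+", ((1000, 2000),))],
                  biotype="protein_coding"),
        GeneModel("G2", "chr2", "+",
                  [TranscriptModel("G2.1", "chr2", "+", ((5000, 6000),))],
                  biotype="protein_coding"),
        GeneModel("G3", "chr1", "+",
                  [TranscriptModel("G3.1", "chr1", "+", ((2100, 2600),))],
                  biotype="protein_coding"),
    ]

    def make_cand(self, loci):
        return fusion.FusionCandidate("q", loci)

    def test_both_loci_inside_genes(self):
        cand = self.make_cand([
            seg(0, 500, "chr1", 1200, 1700),
            seg(500, 1000, "chr2", 5100, 5600),
        ])
        assert fusion.assign_parental_genes(cand, self.annotation) == ("G1", "G2")

    def test_locus_without_gene_gets_novel_label(self):
        cand = self.make_cand([
            seg(0, 500, "chr1", 5_000_000, 5_000_500),
            seg(500, 1000, "chr2", 5100, 5600),
        ])
        pair = fusion.assign_parental_genes(cand, self.annotation)
        assert pair == ("novel_locus:chr1:5000000", "G2")

    def test_maximal_exonic_overlap_wins(self):
        # 400 bp overlap with G3 vs 100 bp with G1
        cand = self.make_cand([
            seg(0, 500, "chr1", 1900, 2500),
            seg(500, 1000, "chr2", 5100, 5600),
        ])
        assert fusion.assign_parental_genes(cand, self.annotation)[0] == "G3"


class TestDatabaseMatch:
    def test_unordered_pair_match_after_symbol_mapping(self):
        rows = fusion.match_to_database(
            [("ENSG_A", "ENSG_B")],
            [("B_sym", "A_sym")],
            {"A_sym": "ENSG_A", "B_sym": "ENSG_B"},
        )
        assert rows[-1]["in_database"] is True

    def test_nonmatching_pair(self):
        rows = fusion.match_to_database(
            [("ENSG_A", "ENSG_C")], [("A", "B")],
            {"A": "ENSG_A", "B": "ENSG_B"},
        )
        assert rows[-1]["in_database"] is False

    def test_empty_database_and_unmapped_symbols(self):
        assert fusion.match_to_database([("x", "y")], [], {})[-1][
            "in_database"] is False
        rows = fusion.match_to_database(
            [("ENSG_A", "ENSG_B")], [("A", "UNKNOWN")], {"A": "ENSG_A"}
        )
        assert rows[0]["skipped"] is True
        assert rows[-1]["in_database"] is False


class TestPlantedRecovery:
    def test_tier1_equals_planted_truth_with_exact_flags(self, fusion_data):
        alignments, junctions, truth = fusion_data
        params = fusion.FusionParams()
        candidates = fusion.detect_candidates(alignments, params)
        for cand in candidates:
            cand.support = fusion.count_junction_support(cand, junctions)
        tier1, _ = fusion.apply_support_filters(candidates, params)
        expected = {q for q, s in truth.fusion_status.items()
                    if s == "true_fusion"}
        got = {c.query_id for c in tier1}
        assert got == expected  # precision = recall = 1.0

        audit = fusion.audit_reads(alignments, params)
        failing_criterion = {
            "fails_coverage": "locus_fraction",
            "fails_combined": "combined_coverage",
            "fails_distance": "locus_distance",
        }
        for qid, status in truth.fusion_status.items():
            if status in failing_criterion:
                flags = audit[qid]
                failed = [c for c, ok in flags.items() if not ok]
                assert failed == [failing_criterion[status]], (qid, status)
            elif status == "fails_support":
                assert all(audit[qid].values())
                s, _, _ = junctions[qid]
                assert s < params.min_spanning_reads

    def test_candidate_count_monotone_over_threshold_grid(self, fusion_data):
        alignments, _, _ = fusion_data
        fracs = [0.05, 0.10, 0.20]
        covs = [0.90, 0.99, 0.995]
        dists = [50_000, 100_000, 200_000]
        counts = {}
        for f, c, d in product(fracs, covs, dists):
            params = fusion.FusionParams(
                min_locus_query_fraction=f, min_combined_coverage=c,
                min_locus_distance=d,
            )
            counts[(f, c, d)] = len(fusion.detect_candidates(alignments, params))
        for (f, c, d), n in counts.items():
            for f2 in fracs:
                if f2 > f:
                    assert counts[(f2, c, d)] <= n
            for c2 in covs:
                if c2 > c:
                    assert counts[(f, c2, d)] <= n
            for d2 in dists:
                if d2 > d:
                    assert counts[(f, c, d2)] <= n
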