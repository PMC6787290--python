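import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isotrx import lncrna
from isotrx.model import ExpressionMatrix, GeneModel, TranscriptModel

from oracles import local_align_identity


def tx(tid, exons, chrom="chr1", strand="+"):
    return TranscriptModel(tid, chrom, strand, tuple(exons))


def coding_gene(gid, exons, chrom="chr1"):
    return GeneModel(gid, chrom, "+",
                     [tx(f"{gid}.1", exons, chrom=chrom)],
                     biotype="protein_coding")


CALLS = {
    "t_nc": {"CNCI": "noncoding", "PLEK": "noncoding",
             "CPC": "noncoding", "PfamScan": "noncoding"},
    "t_cpc": {"CNCI": "noncoding", "PLEK": "noncoding",
              "CPC": "coding", "PfamScan": "noncoding"},
}


class TestConsensusFilter:
    def test_all_four_noncoding_is_kept(self):
        assert lncrna.consensus_noncoding_filter(["t_nc"], CALLS) == {"t_nc"}

    def test_any_coding_call_removes(self):
        assert lncrna.consensus_noncoding_filter(["t_cpc"], CALLS) == set()

    def test_empty_candidates(self):
        assert lncrna.consensus_noncoding_filter([], CALLS) == set()

    def test_missing_candidate_or_predictor_raises(self):
        with pytest.raises(lncrna.MissingCallError, match="t_gone"):
            lncrna.consensus_noncoding_filter(["t_gone"], CALLS)
        partial = {"t": {"CNCI": "noncoding"}}
        with pytest.raises(lncrna.MissingCallError):
            lncrna.consensus_noncoding_filter(["t"], partial)

    def test_kept_and_removed_partition_candidates(self):
        cands = list(CALLS)
        kept = lncrna.consensus_noncoding_filter(cands, CALLS)
        removed = set(cands) - kept
        assert kept | removed == set(cands)
        assert kept & removed == set()


class TestLincRNAClassification:
    annotation = [
        coding_gene("C1", [(1000, 2000), (5000, 6000)]),
        GeneModel("N1", "chr1", "+",
                  [tx("N1.1", [(20_000, 21_000)])], biotype="noncoding"),
    ]

    def test_between_genes_is_intergenic(self):
        assert lncrna.classify_lincRNA(tx("l", [(10_000, 11_000)]),
                                       self.annotation)

    def test_inside_coding_intron_is_not_intergenic(self):
        # span overlap with the coding gene's span counts even in an intron
        assert not lncrna.classify_lincRNA(tx("l", [(3000, 4000)]),
                                           self.annotation)

    def test_overlap_with_noncoding_gene_still_intergenic(self):
        assert lncrna.classify_lincRNA(tx("l", [(20_100, 20_500)]),
                                       self.annotation)


class TestCancerSpecificSets:
    def test_union_mode_keeps_partial_cancer_presence(self):
        cancer = [{"a", "b"}, {"b"}, set(), set()]
        got = lncrna.cancer_specific_lincRNAs(cancer, set(), set())
        assert got == {"a", "b"}

    def test_reference_catalog_membership_excludes(self):
        cancer = [{"a", "b"}] * 4
        got = lncrna.cancer_specific_lincRNAs(cancer, set(), {"b"})
        assert got == {"a"}

    def test_normal_presence_excludes(self):
        got = lncrna.cancer_specific_lincRNAs([{"a"}], {"a"}, set())
        assert got == set()

    def test_empty_sets(self):
        assert lncrna.cancer_specific_lincRNAs([set()], set(), set()) == set()

    def test_intersection_mode(self):
        cancer = [{"a", "b"}, {"b"}]
        got = lncrna.cancer_specific_lincRNAs(cancer, set(), set(),
                                              mode="intersection")
        assert got == {"b"}

    def test_monotone_nonincreasing_in_reference_catalog(self):
        cancer = [{"a", "b", "c"}, {"c", "d"}]
        prev = lncrna.cancer_specific_lincRNAs(cancer, set(), set())
        for ref in [{"a"}, {"a", "c"}, {"a", "c", "d"}]:
            cur = lncrna.cancer_specific_lincRNAs(cancer, set(), ref)
            assert cur <= prev
            prev = cur


def expr_matrix(rows):
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


class TestTargetPrediction:
    def setup_method(self):
        self.lnc = tx("L1", [(0, 1000)])
        self.near = coding_gene("GN", [(51_000, 52_000)])    # 50 kb gap
        self.far = coding_gene("GF", [(151_000, 152_000)])   # 150 kb gap

    def test_identical_vectors_reported_with_r_one(self):
        v = np.arange(1, 13, dtype=float)
        expr = expr_matrix({"L1": v, "GN": v})
        (hit,) = lncrna.predict_targets([self.lnc], [self.near], expr)
        assert hit["r"] == pytest.approx(1.0)
        assert hit["distance"] == 50_000

    def test_high_r_but_outside_window_not_reported(self):
        v = np.arange(1, 13, dtype=float)
        expr = expr_matrix({"L1": v, "GF": v * 2})
        assert lncrna.predict_targets([self.lnc], [self.far], expr) == []

    def test_hand_computed_half_correlation_not_reported(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])  # r = 0.8 by hand
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.8)
        expr = expr_matrix({"L1": x, "GN": y})
        assert lncrna.predict_targets([self.lnc], [self.near], expr) == []

    def test_zero_variance_vector_skipped_with_warning(self):
        expr = expr_matrix({"L1": np.ones(12), "GN": np.arange(12.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            assert lncrna.predict_targets([self.lnc], [self.near], expr) == []

    def test_fewer_than_three_samples_rejected(self):
        expr = expr_matrix({"L1": np.array([1.0, 2.0]),
                            "GN": np.array([1.0, 2.0])})
        with pytest.raises(ValueError):
            lncrna.predict_targets([self.lnc], [self.near], expr)

    def test_planted_pairs_recovered_decoys_rejected(self, annotation,
                                                     expression_data):
        expr, truth = expression_data
        lnc_tx = [g.transcripts[0] for g in annotation
                  if g.biotype == "noncoding"]
        coding = [g for g in annotation if g.biotype == "protein_coding"]
        hits = lncrna.predict_targets(lnc_tx, coding, expr)
        assert {(h["lincRNA"], h["gene"]) for h in hits} == truth.target_pairs

    def test_pearson_p_matches_permutation_estimate(self):
        rng = np.random.default_rng(42)
        n = 12
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        r, p = stats.pearsonr(x, y)
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            if abs(rp) >= abs(r):
                hits += 1
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < 3 * max(se, 1e-4)


class TestPremirnaSearch:
    def test_exact_substring_hits_with_identity_one(self):
        rng = np.random.default_rng(0)
        lnc = "".join(rng.choice(list("ACGT"), size=500))
        hairpin = lnc[100:170]
        hits = lncrna.find_premirna({"h": hairpin}, {"l": lnc})
        assert len(hits) == 1
        assert hits[0]["identity"] == pytest.approx(1.0)
        assert hits[0]["strand"] == "+"

    def test_reverse_complement_match_hits(self):
        from Bio.Seq import Seq
        rng = np.random.default_rng(1)
        lnc = "".join(rng.choice(list("ACGT"), size=400))
        hairpin = str(Seq(lnc[50:120]).reverse_complement())
        hits = lncrna.find_premirna({"h": hairpin}, {"l": lnc})
        assert len(hits) == 1
        assert hits[0]["strand"] == "-"

    def test_random_unrelated_hairpin_no_hit_confirmed_by_dp_oracle(self):
        rng = np.random.default_rng(2)
        lnc = "".join(rng.choice(list("ACGT"), size=1000))
        hairpin = "".join(rng.choice(list("ACGT"), size=70))
        assert lncrna.find_premirna({"h": hairpin}, {"l": lnc}) == []
        ident, cov = local_align_identity(hairpin, lnc)
        assert ident < 0.9 or cov < 0.9

    def test_uracil_normalized(self):
        lnc = "ACGTACGTACGTACGTACGTACGT" * 4
        hairpin = lnc[:40].replace("T", "U")
        hits = lncrna.find_premirna({"h": hairpin}, {"l": lnc})
        assert hits and hits[0]["identity"] == pytest.approx(1.0)
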