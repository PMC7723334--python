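"""Cis classification, local alignment, promoter windows, PWM scanning."""

import numpy as np
import pandas as pd
import pytest

from cernet.io import PWM, ExpressionMatrix, GenomicFeature, revcomp
from cernet.regulation import (
    build_tf_network,
    classify_cis_relation,
    extract_promoter_window,
    find_cis_pairs,
    local_align,
    predict_trans_targets,
    scan_pwm,
    tf_degrees,
)

from oracles import pwm_score_naive, sw_score_dp


def F(id, start, end, strand, biotype="mRNA", introns=()):
    return GenomicFeature(id, "chrS", start, end, strand, biotype, tuple(introns))


class TestCisClassification:
    def test_intronic_containment(self):
        gene = F("g", 50, 1000, "+", introns=((80, 900),))
        assert classify_cis_relation(F("l", 100, 500, "+", "lncRNA"), gene) == "intronic"
        # either strand counts as intronic
        assert classify_cis_relation(F("l", 100, 500, "-", "lncRNA"), gene) == "intronic"

    def test_sense_overlap(self):
        assert classify_cis_relation(
            F("l", 100, 500, "+", "lncRNA"), F("g", 300, 900, "+")
        ) == "sense"

    def test_antisense_overlap(self):
        assert classify_cis_relation(
            F("l", 100, 500, "-", "lncRNA"), F("g", 300, 900, "+")
        ) == "antisense"

    def test_divergent_worked_example(self):
        """lncRNA [2000,3000)- (TSS 2999) vs gene [3400,5000)+ (TSS 3400):
        head-to-head with TSS gap 401 <= 1000."""
        lnc = F("l", 2000, 3000, "-", "lncRNA")
        gene = F("g", 3400, 5000, "+")
        assert lnc.tss == 2999 and gene.tss == 3400
        assert classify_cis_relation(lnc, gene) == "divergent"

    def test_head_to_head_required_for_divergent(self):
        # opposite strands but transcribed toward each other -> neighbor
        lnc = F("l", 2000, 3000, "+", "lncRNA")
        gene = F("g", 3400, 5000, "-")
        assert classify_cis_relation(lnc, gene) == "neighbor"

    def test_tss_gap_exceeding_limit_degrades_to_neighbor(self):
        lnc = F("l", 1000, 2000, "-", "lncRNA")  # TSS 1999
        gene = F("g", 4000, 5000, "+")  # TSS 4000, gap 2001
        assert classify_cis_relation(lnc, gene) == "neighbor"

    def test_window_gate(self):
        lnc = F("l", 0, 1000, "+", "lncRNA")
        assert classify_cis_relation(lnc, F("g", 16_000, 17_000, "+")) is None
        assert classify_cis_relation(lnc, F("g", 10_900, 12_000, "+")) == "neighbor"

    def test_different_chromosome_none(self):
        lnc = GenomicFeature("l", "chr2", 0, 100, "+", "lncRNA")
        assert classify_cis_relation(lnc, F("g", 0, 100, "+")) is None

    def test_intronic_precedence_over_sense(self):
        gene = F("g", 0, 2000, "+", introns=((100, 1900),))
        lnc = F("l", 200, 800, "+", "lncRNA")
        assert classify_cis_relation(lnc, gene) == "intronic"

    def test_total_on_window_pairs(self, rng):
        """Every same-chromosome pair within the window maps to exactly
        one category under the precedence order."""
        cats = set()
        for _ in range(300):
            s1 = int(rng.integers(0, 5000))
            s2 = int(rng.integers(0, 5000))
            lnc = F("l", s1, s1 + int(rng.integers(100, 2000)), "+-"[rng.integers(2)], "lncRNA")
            gene = F("g", s2, s2 + int(rng.integers(100, 3000)), "+-"[rng.integers(2)])
            got = classify_cis_relation(lnc, gene)
            assert got is not None  # gap always < window at these scales
            cats.add(got)
        assert cats <= {"sense", "antisense", "intronic", "divergent", "neighbor"}


class TestLocalAlign:
    def test_identical_sequences(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        aln = local_align(seq, seq)
        assert aln.score == 30
        assert aln.identity == 1.0
        assert (aln.a_start, aln.a_end) == (0, 30)

    def test_disjoint_alphabets_empty(self):
        aln = local_align("AAAA", "CCCC")
        assert aln.score == 0
        assert aln.length == 0

    def test_embedded_match(self):
        aln = local_align("GGGG" + "ACGTACGTAC" + "GGGG", "TTT" + "ACGTACGTAC" + "TTT")
        assert aln.score == 10
        assert aln.a_start == 4
        assert aln.b_start == 3

    def test_matches_dp_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            a = "".join(rng.choice(bases, rng.integers(5, 50)))
            b = "".join(rng.choice(bases, rng.integers(5, 50)))
            assert local_align(a, b).score == sw_score_dp(a, b)

    def test_rejects_empty_and_bad_alphabet(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")
        with pytest.raises(ValueError):
            local_align("ACGT", "ACXT")


class TestPromoterWindow:
    CHROM = None

    @classmethod
    def chrom(cls):
        if cls.CHROM is None:
            rng = np.random.default_rng(99)
            cls.CHROM = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 9000)])
        return {"chrS": cls.CHROM}

    def test_plus_strand_arithmetic(self):
        w = extract_promoter_window(F("x", 5000, 6000, "+", "lncRNA"), self.chrom())
        assert (w.genomic_start, w.genomic_end) == (3000, 5500)
        assert w.sequence == self.chrom()["chrS"][3000:5500]
        assert not w.clipped

    def test_minus_strand_arithmetic(self):
        # TSS at 5000 requires end 5001 on the minus strand
        w = extract_promoter_window(F("x", 4000, 5001, "-", "lncRNA"), self.chrom())
        assert (w.genomic_start, w.genomic_end) == (4500, 7000)
        assert w.sequence == revcomp(self.chrom()["chrS"][4500:7000])

    def test_clip_at_chromosome_start(self):
        w = extract_promoter_window(F("x", 100, 400, "+", "lncRNA"), self.chrom())
        assert (w.genomic_start, w.genomic_end) == (0, 600)
        assert w.clipped

    def test_missing_chromosome(self):
        with pytest.raises(KeyError):
            extract_promoter_window(F("x", 100, 400, "+", "lncRNA"), {"chr9": "ACGT"})


class TestScanPWM:
    def _pwm(self, consensus):
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts = np.full((4, len(consensus)), 2.0)
        for j, b in enumerate(consensus):
            counts[idx[b], j] = 90.0
        return PWM("M", counts)

    def test_consensus_scores_maximum(self):
        pwm = self._pwm("ACGTACGTA")
        hits = scan_pwm("TTTT" + "ACGTACGTA" + "TTTT", pwm, threshold=1.0)
        fwd = hits[hits["strand"] == "+"]
        assert list(fwd["offset"]) == [4]
        assert fwd["score"].iloc[0] == pytest.approx(pwm.max_score)

    def test_reverse_strand_hit_maps_to_forward_offset(self):
        pwm = self._pwm("ACCGTTGCA")
        seq = "GGGG" + revcomp("ACCGTTGCA") + "GGGG"
        hits = scan_pwm(seq, pwm, threshold=1.0)
        rev = hits[hits["strand"] == "-"]
        assert list(rev["offset"]) == [4]

    def test_no_hits_without_consensus_at_full_threshold(self):
        pwm = self._pwm("AAAAAAAA")
        assert scan_pwm("CGCGCGCGCGCGCGCG", pwm, threshold=1.0).empty

    def test_scores_match_naive_summation(self, rng):
        pwm = self._pwm("GATTACA")
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        hits = scan_pwm(seq, pwm, threshold=0.0)
        fwd = hits[hits["strand"] == "+"].set_index("offset")["score"]
        assert len(fwd) > 0
        for offset, score in fwd.items():
            assert score == pytest.approx(
                pwm_score_naive(seq, pwm.probs, offset), abs=1e-9
            )
        # offsets absent from the hit list must score below the cutoff
        for offset in range(200 - 7):
            if offset not in fwd.index:
                assert pwm_score_naive(seq, pwm.probs, offset) < 0.0

    def test_window_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_pwm("ACG", self._pwm("ACGTACG"))


class TestCisPairs:
    def _expr(self, data, species, ids):
        samples = [f"s{i}" for i in range(data.shape[1])]
        return ExpressionMatrix(
            species, pd.DataFrame(data, index=ids, columns=samples),
            {s: "c" for s in samples},
        )

    def test_distance_and_chromosome_gates(self, rng):
        shared = rng.normal(size=9)
        lnc_e = self._expr(shared[None, :] + 0.001 * rng.normal(size=(1, 9)), "lncRNA", ["L"])
        gene_e = self._expr(shared[None, :] + 0.001 * rng.normal(size=(1, 9)), "mRNA", ["G"])
        near = [F("G", 2000, 3000, "+")]
        far = [F("G", 20_000, 21_000, "+")]
        other_chrom = [GenomicFeature("G", "chr2", 2000, 3000, "+", "mRNA")]
        lnc = [F("L", 0, 1000, "+", "lncRNA")]
        assert len(find_cis_pairs(lnc, near, lnc_e, gene_e)) == 1
        assert find_cis_pairs(lnc, far, lnc_e, gene_e).empty
        assert find_cis_pairs(lnc, other_chrom, lnc_e, gene_e).empty

    def test_correlation_gate(self, rng):
        lnc_e = self._expr(rng.normal(size=(1, 9)), "lncRNA", ["L"])
        gene_e = self._expr(rng.normal(size=(1, 9)), "mRNA", ["G"])
        lnc = [F("L", 0, 1000, "+", "lncRNA")]
        gene = [F("G", 2000, 3000, "+")]
        assert find_cis_pairs(lnc, gene, lnc_e, gene_e, min_r=0.99).empty

    def test_planted_pairs_recovered_with_category(self, default_bundle):
        bundle, truth = default_bundle
        lncs = [f for f in bundle.features if f.biotype == "lncRNA"]
        genes = [f for f in bundle.features if f.biotype == "mRNA"]
        found = find_cis_pairs(
            lncs, genes, bundle.expression["lncRNA"], bundle.expression["mRNA"]
        )
        got = set(zip(found["lncrna_id"], found["gene_id"], found["category"]))
        assert truth.planted_cis <= got

    def test_window_shrink_monotone(self, default_bundle):
        bundle, _ = default_bundle
        lncs = [f for f in bundle.features if f.biotype == "lncRNA"][:30]
        genes = [f for f in bundle.features if f.biotype == "mRNA"]
        wide = find_cis_pairs(lncs, genes, bundle.expression["lncRNA"],
                              bundle.expression["mRNA"], window=10_000)
        narrow = find_cis_pairs(lncs, genes, bundle.expression["lncRNA"],
                                bundle.expression["mRNA"], window=1_000)
        assert set(zip(narrow["lncrna_id"], narrow["gene_id"])) <= set(
            zip(wide["lncrna_id"], wide["gene_id"])
        )


class TestTransTargets:
    def test_exact_substring_hit(self):
        utr = "TTGACCGTAGGCTAAGCTTGACGATCGATCGGATC" * 2
        lnc = "CCCCCCCC" + utr[5:40] + "GGGGGGGG"
        edges = pd.DataFrame(
            [("L", "lncRNA", "M", "mRNA", 0.999, 1e-6, "positive")],
            columns=["node_a", "species_a", "node_b", "species_b", "r", "p", "sign"],
        )
        hits = predict_trans_targets({"L": lnc}, {"M": utr}, edges, min_len=20)
        assert len(hits) == 1
        assert hits.loc[0, "identity"] >= 0.9
        assert hits.loc[0, "length"] >= 30

    def test_non_coexpressed_pair_not_evaluated(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGT"
        edges = pd.DataFrame(
            columns=["node_a", "species_a", "node_b", "species_b", "r", "p", "sign"])
        hits = predict_trans_targets({"L": seq}, {"M": seq}, edges)
        assert hits.empty

    def test_random_pairs_yield_no_hits(self, rng):
        bases = np.array(list("ACGT"))
        rows = []
        lnc_seqs, utr_seqs = {}, {}
        for i in range(20):
            lnc_seqs[f"L{i}"] = "".join(rng.choice(bases, 200))
            utr_seqs[f"M{i}"] = "".join(rng.choice(bases, 200))
            rows.append((f"L{i}", "lncRNA", f"M{i}", "mRNA", 0.999, 1e-6, "positive"))
        edges = pd.DataFrame(
            rows, columns=["node_a", "species_a", "node_b", "species_b", "r", "p", "sign"])
        hits = predict_trans_targets(lnc_seqs, utr_seqs, edges)
        assert hits.empty

    def test_missing_sequence_rejected(self):
        edges = pd.DataFrame(
            [("L", "lncRNA", "M", "mRNA", 0.999, 1e-6, "positive")],
            columns=["node_a", "species_a", "node_b", "species_b", "r", "p", "sign"],
        )
        with pytest.raises(KeyError):
            predict_trans_targets({}, {"M": "ACGT"}, edges)


class TestTFNetwork:
    def test_planted_motifs_recovered(self, default_bundle):
        bundle, truth = default_bundle
        lncs = [f for f in bundle.features if f.biotype == "lncRNA"]
        edges = build_tf_network(lncs, bundle.pwms, bundle.chromosomes)
        got = set(zip(edges["lncrna_id"], edges["motif_id"]))
        planted = {(l, m) for l, m, _off in truth.planted_motifs}
        assert planted <= got

    def test_degree_equals_recount(self, default_bundle):
        bundle, _ = default_bundle
        lncs = [f for f in bundle.features if f.biotype == "lncRNA"][:40]
        edges = build_tf_network(lncs, bundle.pwms, bundle.chromosomes)
        deg = tf_degrees(edges)
        for motif_id, d in deg.items():
            assert d == edges[edges["motif_id"] == motif_id]["lncrna_id"].nunique()

    def test_threshold_raise_monotone(self, default_bundle):
        bundle, _ = default_bundle
        lncs = [f for f in bundle.features if f.biotype == "lncRNA"][:40]
        loose = build_tf_network(lncs, bundle.pwms, bundle.chromosomes, threshold=0.7)
        tight = build_tf_network(lncs, bundle.pwms, bundle.chromosomes, threshold=0.95)
        assert set(zip(tight["lncrna_id"], tight["motif_id"])) <= set(
            zip(loose["lncrna_id"], loose["motif_id"])
        )
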