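"""Local alignment, E-value statistics, k-mer candidates, bootstrap
enrichment and precision evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coexcis import (
    AlignParams,
    KnownElementList,
    KmerCandidateSet,
    PlantedMotifTruth,
    PromoterSet,
    bootstrap_enrichment,
    count_occurrences,
    direct_kmer_candidates,
    enrichment_screen,
    homopolymer_filter,
    karlin_altschul_evalue,
    karlin_altschul_lambda,
    precision_eval,
    seed_extend_align,
    shared_kmer_candidates,
    synth_promoters,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestKarlinAltschul:
    def test_lambda_closed_form(self):
        # (1/4)e^l + (3/4)e^(-2l) = 1; with u = e^l, u^3 - 4u^2 + 3 = 0,
        # whose relevant root is u = (3 + sqrt(21))/2
        expected = np.log((3 + np.sqrt(21)) / 2)
        assert karlin_altschul_lambda(1, -2) == pytest.approx(expected, abs=1e-9)

    def test_lambda_satisfies_defining_equation(self):
        lam = karlin_altschul_lambda(1, -2)
        assert 0.25 * np.exp(lam) + 0.75 * np.exp(-2 * lam) == pytest.approx(1.0)

    def test_doubling_db_length_doubles_evalue(self):
        e1 = karlin_altschul_evalue(20, 1000, 10000)
        e2 = karlin_altschul_evalue(20, 1000, 20000)
        assert e2 == pytest.approx(2 * e1)

    def test_evalue_monotone_decreasing_in_score(self):
        evs = [karlin_altschul_evalue(s, 1000, 10000) for s in (5, 10, 20, 40, 80)]
        assert evs == sorted(evs, reverse=True)
        assert evs[-1] < 1e-30

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError, match="expected score"):
            karlin_altschul_lambda(3, -1)


class TestSeedExtendAlign:
    def test_identical_record_full_span_hit(self, rng):
        seq = random_seq(rng, 50)
        db = PromoterSet({"target": seq, "other": random_seq(rng, 50)})
        hits = seed_extend_align("query", seq, db)
        top = hits[0]
        assert top.subject_id == "target"
        assert top.identity == pytest.approx(1.0)
        assert top.query_span == (0, 50)

    def test_no_common_word_no_hits(self):
        db = PromoterSet({"a": "ACACACACACACAC"})
        hits = seed_extend_align("q", "GTGTGTGTGTGTGT", db, AlignParams(word_size=7))
        assert hits == []

    def test_eighty_percent_identity_passes_filter(self):
        # 40 nt, mismatch at every 5th position: identity 32/40 = 0.8
        rng = np.random.default_rng(80)
        a = list(random_seq(rng, 40))
        b = a.copy()
        for p in range(4, 40, 5):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        db = PromoterSet({"s": "".join(b)})
        hits = seed_extend_align("q", "".join(a), db, AlignParams(word_size=4))
        best = max(hits, key=lambda h: h.score)
        assert best.identity >= 0.75
        assert best.length >= 30

    def test_self_hit_excluded(self, rng):
        seq = random_seq(rng, 60)
        db = PromoterSet({"g1": seq})
        assert seed_extend_align("g1", seq, db) == []


class TestHomopolymerFilter:
    def test_run_of_four_kept(self):
        assert homopolymer_filter("AAAAGT")

    def test_run_of_five_rejected(self):
        assert not homopolymer_filter("AAAAAG")

    def test_mixed_kept(self):
        assert homopolymer_filter("ACGTAC")

    def test_bad_input(self):
        with pytest.raises(ValueError):
            homopolymer_filter("ACG")
        with pytest.raises(ValueError):
            homopolymer_filter("ACGTAN")

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=6))
    def test_matches_regex_oracle(self, kmer):
        import re

        expected = not re.search(r"(.)\1{4,}", kmer)
        assert homopolymer_filter(kmer) == expected


class TestCountOccurrences:
    def test_overlapping(self):
        assert count_occurrences("AAAAAA", "AAAAAAA") == 2

    def test_absent(self):
        assert count_occurrences("GTCGTC", "AAAAAAAA") == 0

    def test_both_strands(self):
        # revcomp of GTCGTC is GACGAC
        seq = "TTGTCGTCTTGACGACTT"
        assert count_occurrences("GTCGTC", seq) == 1
        assert count_occurrences("GTCGTC", seq, both_strands=True) == 2

    def test_palindrome_not_double_counted(self):
        assert count_occurrences("GAATTC", "GGAATTCG", both_strands=True) == 1


class TestSharedKmerCandidates:
    def _promoters_with_block(self, rng, block):
        a = random_seq(rng, 400) + block + random_seq(rng, 400)
        b = random_seq(rng, 300) + block + random_seq(rng, 500)
        return PromoterSet({"p1": a, "p2": b})

    def test_shared_block_kmers_all_present(self, rng):
        block = "GATTCGATCCAGTTACGTGA"  # 20 nt, no homopolymer runs
        ps = self._promoters_with_block(rng, block)
        cands = shared_kmer_candidates(ps)
        for i in range(15):
            assert block[i : i + 6] in cands.kmers

    def test_unrelated_promoters_give_nothing(self, rng):
        ps = PromoterSet({"p1": random_seq(rng, 500), "p2": random_seq(rng, 500)})
        assert len(shared_kmer_candidates(ps)) == 0

    def test_homopolymer_windows_excluded(self, rng):
        block = "AAAAAAGTCGATTCCAGTGA"  # leading 6-A run
        ps = self._promoters_with_block(rng, block)
        cands = shared_kmer_candidates(ps)
        assert "AAAAAA" not in cands.kmers
        assert "AAAAAG" not in cands.kmers
        assert all(homopolymer_filter(k) for k in cands.kmers)

    def test_order_invariance(self, rng):
        block = "GATTCGATCCAGTTACGTGA"
        a = random_seq(rng, 400) + block + random_seq(rng, 400)
        b = random_seq(rng, 300) + block + random_seq(rng, 500)
        k1 = shared_kmer_candidates(PromoterSet({"p1": a, "p2": b}))
        k2 = shared_kmer_candidates(PromoterSet({"p2": b, "p1": a}))
        assert k1.kmers == k2.kmers

    def test_candidate_set_validation(self):
        with pytest.raises(ValueError, match="homopolymer"):
            KmerCandidateSet({"AAAAAG"})


class TestBootstrapEnrichment:
    def test_null_fold_ratio_calibrated(self):
        truth = PlantedMotifTruth("GATCGA", cluster_rate=0.0, background_rate=0.25)
        cluster, background = synth_promoters(50, 100, 1000, truth, seed=81)
        rec = bootstrap_enrichment("GATCGA", cluster, background, n_boot=1000, seed=82)
        assert 0.67 <= rec.fold_ratio <= 1.5

    def test_planted_three_fold_detected(self):
        # background occurrence ~ 0.5 planted + 0.24 chance; cluster gets
        # 2 * (0.5 + 0.24) extra so the expected ratio is 3
        truth = PlantedMotifTruth("TCATGG", cluster_rate=1.49, background_rate=0.5)
        cluster, background = synth_promoters(50, 100, 1000, truth, seed=83)
        rec = bootstrap_enrichment("TCATGG", cluster, background, n_boot=1000, seed=84)
        assert rec.fold_ratio == pytest.approx(3.0, rel=0.3)
        assert rec.p_value < 0.01

    def test_reproducible_given_seed(self):
        truth = PlantedMotifTruth("GTCGTC", cluster_rate=1.0, background_rate=0.5)
        cluster, background = synth_promoters(20, 40, 500, truth, seed=85)
        a = bootstrap_enrichment("GTCGTC", cluster, background, n_boot=200, seed=86)
        b = bootstrap_enrichment("GTCGTC", cluster, background, n_boot=200, seed=86)
        assert a == b

    def test_background_smaller_than_cluster_rejected(self):
        truth = PlantedMotifTruth("GTCGTC", cluster_rate=0.0)
        cluster, background = synth_promoters(10, 5, 200, truth, seed=87)
        with pytest.raises(ValueError, match="background"):
            bootstrap_enrichment("GTCGTC", cluster, background, seed=88)


class TestEnrichmentScreen:
    def test_planted_motif_top_at_tier_three(self):
        truth = PlantedMotifTruth("TCATGG", cluster_rate=4.0, background_rate=1.0)
        cluster, background = synth_promoters(30, 120, 1000, truth, seed=89)
        records = enrichment_screen(
            cluster.gene_ids, cluster, background,
            n_boot=1000, seed=90, candidate_mode="direct",
        )
        assert records, "no candidates found"
        top = records[0]
        # the winner is the motif itself or a 6-mer overlapping its copies
        assert top.kmer == "TCATGG" or top.kmer in "TCATGGTCATGG"
        motif_rec = next(r for r in records if r.kmer == "TCATGG")
        assert 3 in motif_rec.tiers

    def test_tier_flags_nested(self):
        truth = PlantedMotifTruth("TCATGG", cluster_rate=4.0, background_rate=1.0)
        cluster, background = synth_promoters(20, 60, 800, truth, seed=91)
        records = enrichment_screen(
            cluster.gene_ids, cluster, background,
            n_boot=300, seed=92, candidate_mode="direct",
        )
        for r in records:
            if 4 in r.tiers:
                assert 3 in r.tiers and 2 in r.tiers
            if 3 in r.tiers:
                assert 2 in r.tiers

    def test_no_planting_rarely_reaches_tier_three(self):
        hits = 0
        for seed in range(93, 103):
            truth = PlantedMotifTruth("GATCGA", cluster_rate=0.0, background_rate=1.0)
            cluster, background = synth_promoters(30, 120, 1000, truth, seed=seed)
            records = enrichment_screen(
                cluster.gene_ids, cluster, background,
                n_boot=300, seed=seed + 1000, candidate_mode="direct",
            )
            if any(3 in r.tiers for r in records):
                hits += 1
        assert hits <= 1  # tier >= 3 in at most 1 of 10 null runs

    def test_small_module_rejected(self):
        truth = PlantedMotifTruth("GTCGTC", cluster_rate=1.0)
        cluster, background = synth_promoters(5, 10, 200, truth, seed=104)
        with pytest.raises(ValueError, match="2 genes"):
            enrichment_screen(cluster.gene_ids[:1], cluster, background, seed=105)


class TestPrecisionEval:
    def test_perfect_precision(self):
        known = KnownElementList(["TCATGG", "CATGGA"])
        ntp, nfp, precision = precision_eval(["TCATGG", "CATGGA"], known)
        assert (ntp, nfp, precision) == (2, 0, 1.0)

    def test_half_precision(self):
        known = KnownElementList(["TCATGG", "CATGGA"])
        found = ["TCATGG", "CATGGA", "GGGCCC", "ATATAT"]
        assert precision_eval(found, known) == (2, 2, 0.5)

    def test_substring_of_known_element_is_tp(self):
        known = KnownElementList(["CTTACCTTTCATGGATTA"])  # long known element
        ntp, nfp, _ = precision_eval(["TCATGG"], known)
        assert (ntp, nfp) == (1, 0)

    def test_reverse_complement_match_is_tp(self):
        known = KnownElementList(["GACGAC"])  # revcomp of GTCGTC
        ntp, _, _ = precision_eval(["GTCGTC"], known)
        assert ntp == 1

    def test_forward_only_rule(self):
        known = KnownElementList(["GACGAC"])
        ntp, _, _ = precision_eval(["GTCGTC"], known, match_rule="substring_forward")
        assert ntp == 0

    def test_empty_found_set_undefined_precision(self):
        known = KnownElementList(["TCATGG"])
        assert precision_eval([], known) == (0, 0, None)
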