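"""Target prediction: expectation scoring, dual-scheme scanning,
intersection, and the site-openness proxy."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xylomir._seq import revcomp
from xylomir.synth import synth_transcriptome
from xylomir.targets import (expectation_score, intersect_predictions,
                             penalty_score_B, scan_transcript_A,
                             scan_transcriptome, transcript_gene, upe_proxy)

from oracles import expectation_min_oracle

MIRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


class TestExpectationScore:
    def test_perfect(self):
        assert expectation_score("|" * 21) == 0.0

    def test_wobble_outside_seed(self):
        p = list("|" * 21)
        p[14] = "o"
        assert expectation_score("".join(p)) == 0.5

    def test_mismatch_in_seed_doubles(self):
        p = list("|" * 21)
        p[4] = "."
        assert expectation_score("".join(p)) == 2.0

    def test_gap_in_seed(self):
        p = list("|" * 21)
        p.insert(2, "-")  # gap column before miRNA position 3
        assert expectation_score("".join(p)) == 4.0

    def test_unknown_symbol_errors(self):
        with pytest.raises(ValueError):
            expectation_score("||x||")

    @given(st.integers(0, 3000))
    def test_adding_mismatch_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        pairing = list(rng.choice(list("|o."), 21, p=[0.7, 0.15, 0.15]))
        base = expectation_score("".join(pairing))
        i = int(rng.integers(0, 21))
        worse = pairing.copy()
        worse[i] = "." if worse[i] != "." else worse[i]
        assert expectation_score("".join(worse)) >= base


class TestSchemeA:
    def test_exact_site_recovered(self):
        t = "A" * 50 + revcomp(MIRNA) + "C" * 50
        hits = scan_transcript_A(MIRNA, t)
        assert len(hits) == 1
        h = hits[0]
        assert (h.site_start, h.site_end) == (51, 71)
        assert h.expectation == 0.0
        assert h.pairing == "|" * 21
        assert h.inhibition == "Cleavage"

    def test_planted_mismatch_at_20(self):
        site = list(revcomp(MIRNA))
        site[1] = MIRNA[19]  # the base pairing miRNA position 20
        t = "G" * 40 + "".join(site) + "T" * 40
        hits = scan_transcript_A(MIRNA, t)
        assert hits and hits[0].expectation == 1.0
        assert (hits[0].site_start, hits[0].site_end) == (41, 61)

    def test_mismatch_at_10_means_translation(self):
        site = list(revcomp(MIRNA))
        site[11] = MIRNA[9]  # disrupt pairing at miRNA position 10
        t = "G" * 30 + "".join(site) + "T" * 30
        hits = scan_transcript_A(MIRNA, t, cutoff=10.0)
        assert hits and hits[0].inhibition == "Translation"

    def test_dp_matches_bruteforce_quick(self, rng):
        for _ in range(30):
            m = int(rng.integers(18, 23))
            mirna = "".join(rng.choice(list("ACGT"), m))
            window = "".join(rng.choice(list("ACGT"), m + int(rng.integers(2, 6))))
            hits = scan_transcript_A(mirna, window, cutoff=1e9)
            got = min(h.expectation for h in hits)
            assert got == pytest.approx(expectation_min_oracle(mirna, window))

    def test_pairing_recomputes_expectation(self, rng):
        for _ in range(20):
            t = "".join(rng.choice(list("ACGT"), 120))
            for h in scan_transcript_A(MIRNA, t, cutoff=1e9):
                assert expectation_score(h.pairing) == pytest.approx(h.expectation)
                assert h.site_end - h.site_start + 1 == len(MIRNA) + h.n_gaps


class TestSchemeB:
    def test_perfect_site(self):
        t = "A" * 30 + revcomp(MIRNA) + "C" * 30
        hits = penalty_score_B(MIRNA, t)
        assert hits and hits[0].penalty_b == 0.0

    def test_wobble_weights(self):
        # G:U at position 20 (outside 2-17): 0.5; at position 4: 1.0
        for pos, expected in [(20, 0.5), (4, 1.0)]:
            mirna = list(MIRNA)
            mirna[pos - 1] = "G"
            mirna = "".join(mirna)
            site = list(revcomp(mirna))
            site[len(mirna) - pos] = "T"  # G:U instead of G:C
            t = "A" * 30 + "".join(site) + "C" * 30
            hits = penalty_score_B(mirna, t)
            assert hits and hits[0].penalty_b == pytest.approx(expected)

    def test_two_core_mismatches_excluded(self):
        site = list(revcomp(MIRNA))
        site[len(MIRNA) - 5] = MIRNA[4]
        site[len(MIRNA) - 9] = MIRNA[8]
        t = "A" * 30 + "".join(site) + "C" * 30
        assert penalty_score_B(MIRNA, t, cutoff=2.5) == []
        hits = penalty_score_B(MIRNA, t, cutoff=4.0)
        assert hits and hits[0].penalty_b == pytest.approx(4.0)


class TestIntersection:
    def test_planted_recovered_decoys_rejected(self):
        """Consensus keeps strong planted sites and rejects decoy sites
        carrying several seed-region mismatches."""
        mirnas = [("mirA", MIRNA)]
        good = [[], [(15, "gu")]]
        decoy = [[(4, "mismatch"), (6, "mismatch"), (8, "mismatch")]]  # exp 6.0
        tx_good, t_good = synth_transcriptome(mirnas, 10, 5, good, seed=2)
        tx_dec, t_dec = synth_transcriptome(mirnas, 10, 5, decoy, seed=3)
        assert all(t.expected_expectation <= 2 for t in t_good)
        assert all(t.expected_expectation >= 6 for t in t_dec)
        transcripts = {**tx_good, **{f"D{k}": v for k, v in tx_dec.items()}}
        hits_a, hits_b = scan_transcriptome({"mirA": MIRNA}, transcripts)
        consensus = intersect_predictions(hits_a, hits_b)
        pairs = {(c.mirna, c.transcript_id) for c in consensus}
        assert pairs == {("mirA", t.transcript_id) for t in t_good}
        coords = {(c.transcript_id, c.site_start, c.site_end) for c in consensus}
        assert coords == {(t.transcript_id, t.site_start, t.site_end) for t in t_good}

    def test_pair_in_one_scheme_only_excluded(self):
        t = "A" * 30 + revcomp(MIRNA) + "C" * 30
        hits_a = scan_transcript_A(MIRNA, t, mirna_id="m", transcript_id="tx")
        assert intersect_predictions(hits_a, []) == []

    def test_full_overlap_carries_both_scores(self):
        t = "A" * 30 + revcomp(MIRNA) + "C" * 30
        hits_a = scan_transcript_A(MIRNA, t, mirna_id="m", transcript_id="tx")
        hits_b = penalty_score_B(MIRNA, t, mirna_id="m", transcript_id="tx")
        cons = intersect_predictions(hits_a, hits_b)
        assert len(cons) == 1
        assert cons[0].expectation == 0.0 and cons[0].penalty_b == 0.0

    def test_cutoff_coherence(self, rng):
        t = "".join(rng.choice(list("ACGT"), 300))
        t = t[:100] + revcomp(MIRNA) + t[100:]
        hits_a = scan_transcript_A(MIRNA, t, mirna_id="m", transcript_id="tx")
        hits_b = penalty_score_B(MIRNA, t, mirna_id="m", transcript_id="tx")
        assert all(h.expectation <= 5.0 for h in hits_a)
        assert all(h.penalty_b <= 2.5 for h in hits_b)
        cons = intersect_predictions(hits_a, hits_b)
        keys_a = {(c.mirna, c.transcript_id) for c in cons}
        assert keys_a <= {(h.mirna, h.transcript_id) for h in hits_a}
        assert keys_a <= {(h.mirna, h.transcript_id) for h in hits_b}

    def test_gene_rollup_suffix_rule(self):
        assert transcript_gene("ZM2G064954_T01") == "ZM2G064954"
        assert transcript_gene("scaffold123") is None
        assert transcript_gene("x_T02", {"x_T02": "geneY"}) == "geneY"


class TestUpeProxy:
    def test_unstructured_context_is_zero(self):
        t = "A" * 200
        assert upe_proxy(t, (100, 120)) == 0.0

    def test_strong_stem_costs_energy(self):
        stem5 = "GCGGCCGCGGCCGCGGCC"
        hairpin = stem5 + "AAAA" + revcomp(stem5)
        t = "A" * 60 + hairpin + "A" * 60
        site = (61 + 2, 61 + 14)  # inside the 5' stem arm
        assert upe_proxy(t, site) > 0

    def test_nonnegative_sweep(self, rng):
        t = "".join(rng.choice(list("ACGT"), 2000))
        for _ in range(100):
            s = int(rng.integers(1, len(t) - 22))
            val = upe_proxy(t, (s, s + 20))
            assert val is not None and val >= 0

    def test_short_window_returns_none(self):
        assert upe_proxy("ACGTACGTAC", (1, 5), flank=0) is None
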