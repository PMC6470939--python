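"""Synthetic-data generators: construction contracts, determinism, and
truth re-derivability from the emitted artifacts."""

import warnings

import numpy as np
import pytest

from xylomir._seq import revcomp
from xylomir.readproc import DEFAULT_ADAPTER
from xylomir.synth import (CapacityError, assign_de_truth, bundled_contaminants,
                           simulate_null_tag_counts, simulate_study,
                           synth_degradome, synth_genome, synth_libraries,
                           synth_transcriptome, write_study)

from oracles import genome_scan_oracle


class TestGenome:
    def test_construction_contract(self):
        genome, truth = synth_genome(1, 100_000, 10, seed=1)
        assert len(truth.planted_mirnas) == 10
        assert sum(len(s) for s in genome.values()) == 100_000
        loci = sorted((pm.precursor_locus.start, pm.precursor_locus.end)
                      for pm in truth.planted_mirnas)
        for (s1, e1), (s2, e2) in zip(loci, loci[1:]):
            assert e1 < s2  # non-overlapping

    def test_determinism(self):
        g1, t1 = synth_genome(1, 50_000, 5, seed=1)
        g2, t2 = synth_genome(1, 50_000, 5, seed=1)
        assert g1 == g2
        assert [(p.name, p.mature_seq, p.locus.start) for p in t1.planted_mirnas] == \
               [(p.name, p.mature_seq, p.locus.start) for p in t2.planted_mirnas]
        g3, _ = synth_genome(1, 50_000, 5, seed=2)
        assert g1 != g3

    def test_matures_found_only_at_truth_locus(self):
        genome, truth = synth_genome(2, 60_000, 8, seed=3)
        for pm in truth.planted_mirnas:
            hits = genome_scan_oracle(pm.mature_seq, genome)
            assert hits == [(pm.locus.chrom, pm.locus.start)]
            chrom = genome[pm.locus.chrom]
            assert chrom[pm.locus.start - 1 : pm.locus.end] == pm.mature_seq

    def test_mature_inside_one_arm(self):
        genome, truth = synth_genome(1, 60_000, 6, seed=4)
        for pm in truth.planted_mirnas:
            assert 20 <= len(pm.mature_seq) <= 22
            assert pm.precursor_locus.start <= pm.locus.start
            assert pm.locus.end <= pm.precursor_locus.end

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            synth_genome(1, 1_000, 50, seed=1)


class TestLibraries:
    def _truth(self, seed=0):
        genome, truth = synth_genome(1, 40_000, 6, seed=seed)
        assign_de_truth(truth, seed=seed)
        return genome, truth

    def test_determinism(self):
        genome, truth = self._truth()
        l1 = synth_libraries(truth, genome, depth=15_000, seed=9)
        l2 = synth_libraries(truth, genome, depth=15_000, seed=9)
        assert l1 == l2

    def test_fold_change_in_poisson_limit(self):
        genome, truth = synth_genome(1, 40_000, 2, seed=5)
        names = [pm.name for pm in truth.planted_mirnas]
        truth.de_truth = {names[0]: (10_000.0, 4.0), names[1]: (10_000.0, 1.0)}
        libs = synth_libraries(truth, genome, depth=100_000, dispersion=0.0,
                               seed=1, isomir_rates=(0.0, 0.0))
        mat = truth.planted_mirnas[0].mature_seq + DEFAULT_ADAPTER
        c1 = sum(r == mat for r in libs["C1"])
        cd1 = sum(r == mat for r in libs["Cd1"])
        assert cd1 / c1 == pytest.approx(4.0, rel=0.15)

    def test_background_band_and_adapter(self):
        genome, truth = self._truth(seed=2)
        # Poisson limit so library composition concentrates on its mean
        libs = synth_libraries(truth, genome, depth=20_000, seed=3, dispersion=0.0)
        reads = libs["C0"]
        assert len(reads) == 20_000
        assert all(r.endswith(DEFAULT_ADAPTER) for r in reads[:500])
        matures = {pm.mature_seq for pm in truth.planted_mirnas}
        n_mirna = sum(any(r.startswith(m) for m in matures) for r in reads)
        assert 0.7 <= n_mirna / len(reads) <= 0.9  # ~20% background planted

    def test_depth_warning_for_rare_mirnas(self):
        genome, truth = synth_genome(1, 40_000, 2, seed=6)
        names = [pm.name for pm in truth.planted_mirnas]
        truth.de_truth = {names[0]: (10.0, 1.0), names[1]: (5000.0, 1.0)}
        with pytest.warns(UserWarning, match="too small"):
            synth_libraries(truth, genome, depth=10_000, seed=1)

    def test_depth_precondition(self):
        genome, truth = self._truth()
        with pytest.raises(ValueError):
            synth_libraries(truth, genome, depth=500, seed=1)


class TestNullModel:
    def test_null_counts_have_unit_fold_change(self):
        counts, totals = simulate_null_tag_counts(500, seed=8)
        ratios = [c["Cd1"] / max(c["C1"], 1) for c in counts.values() if c["C1"] > 20]
        assert np.median(ratios) == pytest.approx(1.0, abs=0.1)
        assert totals == {"C1": 1_000_000, "Cd1": 1_000_000}


MIRNA = "TGGAGCTCCCTTCATTCCAAT"


class TestTranscriptome:
    def test_perfect_site_scores_zero(self):
        tx, targets = synth_transcriptome([("m", MIRNA)], 5, 2, [[]], seed=1)
        for t in targets:
            assert t.expected_expectation == 0.0
            seq = tx[t.transcript_id][t.site_start - 1 : t.site_end]
            assert seq == revcomp(MIRNA)

    def test_wobble_and_seed_mismatch_scores(self):
        mirna = MIRNA[:14] + "G" + MIRNA[15:]  # guarantee G at position 15
        _tx, t_gu = synth_transcriptome([("m", mirna)], 3, 1, [[(15, "gu")]], seed=2)
        assert t_gu[0].expected_expectation == 0.5
        _tx, t_mm = synth_transcriptome([("m", mirna)], 3, 1, [[(5, "mismatch")]], seed=2)
        assert t_mm[0].expected_expectation == 2.0

    def test_bulge_edit_lengthens_site(self):
        _tx, targets = synth_transcriptome([("m", MIRNA)], 3, 1, [[(15, "bulge1")]],
                                           seed=3)
        t = targets[0]
        assert t.site_end - t.site_start + 1 == len(MIRNA) + 1
        assert t.pairing.count("-") == 1

    def test_edit_position_out_of_range(self):
        with pytest.raises(ValueError):
            synth_transcriptome([("m", MIRNA)], 3, 1, [[(40, "mismatch")]], seed=1)

    def test_sites_do_not_overlap(self):
        tx, targets = synth_transcriptome([("m", MIRNA), ("n", revcomp(MIRNA))],
                                          4, 6, [[]], seed=5)
        by_tx = {}
        for t in targets:
            by_tx.setdefault(t.transcript_id, []).append((t.site_start, t.site_end))
        for spans in by_tx.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestDegradome:
    def test_full_peak_is_unique_maximum(self):
        tx, targets = synth_transcriptome([("m", MIRNA)], 4, 2, [[]], seed=6)
        deg = synth_degradome(targets, tx, peak_fraction=1.0, depth=10_000, seed=1)
        for lib in deg.values():
            for t in targets:
                profile = lib[t.transcript_id]
                peak = max(profile.values())
                assert profile[t.true_cleavage_pos] == peak

    def test_zero_peak_rarely_peaks_at_site(self):
        tx, targets = synth_transcriptome([("m", MIRNA)], 4, 2, [[]], seed=7)
        hits = 0
        reps = 200
        for rep in range(reps):
            deg = synth_degradome(targets, tx, peak_fraction=0.0, n_libraries=1,
                                  depth=5_000, seed=rep)
            profile = deg["D1"][targets[0].transcript_id]
            peak = max(profile.values())
            hits += profile.get(targets[0].true_cleavage_pos, 0) == peak
        assert hits < reps * 0.1

    def test_invalid_peak_fraction(self):
        with pytest.raises(ValueError):
            synth_degradome([], {}, peak_fraction=1.5)


class TestStudyArtifacts:
    def test_written_study_is_byte_identical(self, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = simulate_study(seed=21, depth=12_000, chrom_length=30_000,
                                n_transcripts=20, sites_per_mirna=2,
                                degradome_depth=3_000)
            s2 = simulate_study(seed=21, depth=12_000, chrom_length=30_000,
                                n_transcripts=20, sites_per_mirna=2,
                                degradome_depth=3_000)
        p1 = write_study(s1, tmp_path / "a")
        p2 = write_study(s2, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_contaminants_are_fixed(self):
        c1 = bundled_contaminants()
        assert len(c1) >= 5
        assert c1 == bundled_contaminants()
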