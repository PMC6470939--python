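"""Read processing: adapter trimming, tag collapsing/filtering, variant
matching and naming, genome mapping."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from xylomir._seq import revcomp
from xylomir.readproc import (DEFAULT_ADAPTER, MatchPolicy, ReferenceMature,
                              apply_variant, collapse_and_filter,
                              is_low_complexity, map_to_genome, match_tag,
                              process_libraries, trim_adapter)

from oracles import genome_scan_oracle

INSERT24 = "ACGTACGTCCGGATTACGCTAGCA"


def naive_trim(read, adapter, min_overlap, rate):
    """Enumeration oracle: leftmost i where read[i:] matches the adapter
    prefix to the read end (or the full adapter internally)."""
    for i in range(0, len(read)):
        overlap = min(len(adapter), len(read) - i)
        if overlap < min_overlap:
            break
        if overlap < len(adapter) and i + overlap != len(read):
            continue
        mism = sum(1 for x, y in zip(read[i : i + overlap], adapter) if x != y)
        if mism <= int(rate * overlap):
            return None if i < 15 else read[:i]
    return None


class TestTrimming:
    def test_exact_adapter(self):
        assert trim_adapter(INSERT24 + DEFAULT_ADAPTER) == INSERT24

    def test_adapter_dimer(self):
        assert trim_adapter(DEFAULT_ADAPTER) is None

    def test_partial_adapter_at_end(self):
        read = INSERT24 + DEFAULT_ADAPTER[:6]
        assert trim_adapter(read, min_overlap=5) == INSERT24

    def test_no_adapter(self):
        assert trim_adapter("ACGT" * 9) is None

    def test_empty_read_errors(self):
        with pytest.raises(ValueError):
            trim_adapter("")

    @given(st.integers(0, 5000))
    def test_matches_enumeration_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 45))
        read = "".join(rng.choice(list("ACGT"), n))
        if rng.random() < 0.7:  # usually embed some adapter
            cut = int(rng.integers(0, n))
            read = read[:cut] + DEFAULT_ADAPTER[: n - cut]
        assert trim_adapter(read, min_overlap=6, max_mismatch_rate=0.1) == \
            naive_trim(read, DEFAULT_ADAPTER, 6, 0.1)


class TestCollapseAndFilter:
    def test_identical_reads_merge(self):
        tags, _ = collapse_and_filter({"C1": [INSERT24] * 3})
        assert len(tags) == 1
        assert tags[0].raw_counts == {"C1": 3}

    def test_contaminant_substring_removed(self):
        contam = "G" + INSERT24 + "TTACG"
        tags, ledger = collapse_and_filter({"C1": [INSERT24]}, [contam])
        assert tags == []
        assert ledger["C1"]["contaminant"] == 1

    def test_contaminant_matched_on_either_strand(self):
        contam = "G" + revcomp(INSERT24) + "TT"
        tags, _ = collapse_and_filter({"C1": [INSERT24]}, [contam])
        assert tags == []

    def test_low_complexity_rules(self):
        assert is_low_complexity("A" * 22)
        assert is_low_complexity("ACACACACACACACACACAC")
        assert is_low_complexity("AAAAAAAAAAAAAAAAAAGC")  # 18/20 mono
        assert not is_low_complexity(INSERT24)

    def test_read_conservation_ledger(self, rng):
        reads = []
        for _ in range(1000):
            n = int(rng.integers(10, 35))
            reads.append("".join(rng.choice(list("ACGT"), n)) + DEFAULT_ADAPTER)
        contam = ["".join(rng.choice(list("ACGT"), 100))]
        tags, ledger = process_libraries({"C0": reads}, contaminant_refs=contam)
        led = ledger["C0"]
        assert led["reads_in"] == 1000
        parts = (led["kept"] + led["no_adapter"] + led["too_short"]
                 + led["contaminant"] + led["low_complexity"] + led["out_of_range"])
        assert parts == 1000
        assert sum(t.raw_counts.get("C0", 0) for t in tags) == led["kept"]


MATURE21 = "TGGAGCTCCCTTCATTCCAAT"


def _ref(prec_left="GATC", prec_right="CTGA", rid="zma-miR159a-3p"):
    prec = prec_left + MATURE21 + prec_right
    return ReferenceMature(id=rid, mature=MATURE21, precursor=prec,
                           mature_start=len(prec_left) + 1)


class TestVariantMatching:
    def test_exact_match_unsuffixed(self):
        vm = match_tag(MATURE21, [_ref(rid="zma-miR390a-5p")])
        assert vm is not None and vm.variant_name == "zma-miR390a-5p"
        assert vm.is_exact

    def test_three_prime_trim_names_r_minus_1(self):
        vm = match_tag(MATURE21[:-1], [_ref()])
        assert vm.variant_name == "zma-miR159a-3p_R-1"

    def test_substitution_names_1ss(self):
        ref = _ref(rid="zma-miR160f-5p")
        tag = MATURE21[:20] + ("A" if MATURE21[20] != "A" else "C")
        vm = match_tag(tag, [ref])
        assert vm.variant_name == f"zma-miR160f-5p_1ss21{MATURE21[20]}{tag[20]}"

    def test_templated_extension_names_l_plus_1(self):
        ref = _ref(rid="zma-miR827-5p")
        tag = ref.precursor[ref.mature_start - 2] + MATURE21
        vm = match_tag(tag, [ref])
        assert vm.variant_name == "zma-miR827-5p_L+1"

    def test_untemplated_extension_rejected(self):
        ref = _ref()
        flank = ref.precursor[ref.mature_start - 2]
        bad = next(b for b in "ACGT" if b != flank)
        assert match_tag(bad + MATURE21, [ref]) is None

    def test_priority_breaks_ties(self):
        own = _ref(rid="zma-miRX")
        other = ReferenceMature(id="osa-miRX", mature=MATURE21, priority=1)
        vm = match_tag(MATURE21, [other, own])
        assert vm.reference_id == "zma-miRX"

    @given(st.integers(0, 2000))
    def test_name_reconstructs_tag(self, seed):
        """Applying the recorded shifts/substitutions to the reference
        reproduces the tag exactly (variant naming is lossless)."""
        import numpy as np

        rng = np.random.default_rng(seed)
        ref = _ref()
        l = int(rng.integers(-2, 3))
        r = int(rng.integers(-2, 3))
        tag = apply_variant(ref, type("M", (), {
            "l_shift": l, "r_shift": r, "substitutions": []})())
        if rng.random() < 0.5 and len(tag) > 4:
            pos = int(rng.integers(1, len(tag) + 1))
            obs = rng.choice([b for b in "ACGT" if b != tag[pos - 1]])
            tag = tag[: pos - 1] + obs + tag[pos:]
        vm = match_tag(tag, [ref])
        if vm is not None:
            assert apply_variant(ref, vm) == tag


class TestGenomeMapping:
    def test_planted_matches_bruteforce(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        tag = genome["chr1"][1200:1221]
        loci = map_to_genome(tag, genome)
        fwd = [(l.chrom, l.start) for l in loci if l.strand == "+"]
        assert fwd == genome_scan_oracle(tag, genome)

    def test_absent_tag(self, rng):
        genome = {"chr1": "AC" * 500}
        assert map_to_genome("TTTTGGGGTTTTGGGGTTTT", genome) == []

    def test_duplicate_loci_sorted(self):
        tag = "GATTACAGATTACAGATTAC"
        genome = {"chr1": "A" * 100 + tag + "C" * 100 + tag + "G" * 50}
        loci = map_to_genome(tag, genome)
        assert [(l.start, l.strand) for l in loci] == [(101, "+"), (221, "+")]

    def test_reverse_strand_hit(self):
        tag = "GATTACACCGGTTAAGCTAG"
        genome = {"chr1": "T" * 40 + revcomp(tag) + "A" * 40}
        loci = map_to_genome(tag, genome)
        assert len(loci) == 1 and loci[0].strand == "-"
        assert loci[0].start == 41 and loci[0].end == 60

    def test_ambiguous_base_errors(self):
        with pytest.raises(ValueError):
            map_to_genome("ACGTNACGTACGTACGTACG", {"chr1": "ACGT" * 100})
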