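"""Tag classification: priority order, partition property, naming, and
the confidence/significance filters."""

import pytest

from xylomir.annotate import (AnnotatePolicy, MiRNARecord, base_name,
                              classify_tags, high_confidence_filter,
                              select_significant)
from xylomir.fold import PrecursorEvaluation
from xylomir.readproc import ReferenceMature, UniqueTag
from xylomir.synth import assign_de_truth, synth_genome


def _tag(seq, counts=None):
    t = UniqueTag(sequence=seq, raw_counts=counts or {"C1": 5})
    t.norm_counts = {k: float(v) for k, v in t.raw_counts.items()}
    return t


def _refs_from_truth(genome, truth, n=None):
    refs = []
    for pm in truth.planted_mirnas[:n]:
        chrom = genome[pm.precursor_locus.chrom]
        prec = chrom[pm.precursor_locus.start - 1 : pm.precursor_locus.end]
        refs.append(ReferenceMature(pm.name, pm.mature_seq, prec,
                                    pm.locus.start - pm.precursor_locus.start + 1))
    return refs


@pytest.fixture(scope="module")
def planted():
    genome, truth = synth_genome(1, 60_000, 6, seed=13)
    assign_de_truth(truth, seed=13)
    return genome, truth


class TestClassification:
    def test_known_beats_every_other_class(self, planted):
        genome, truth = planted
        refs = _refs_from_truth(genome, truth)
        monocot = [ReferenceMature(f"osa-{r.id}", r.mature, r.precursor,
                                   r.mature_start, priority=1) for r in refs]
        tags = [_tag(truth.planted_mirnas[0].mature_seq)]
        records, drops = classify_tags(tags, refs, refs, monocot, genome)
        assert not drops
        assert records[0].mclass == "known"
        assert records[0].name == truth.planted_mirnas[0].name

    def test_novel_pc_naming_and_serial_order(self, planted):
        genome, truth = planted
        tags = [_tag(pm.mature_seq, {"C0": 3, "C1": 4}) for pm in truth.planted_mirnas]
        records, drops = classify_tags(tags, [], [], [], genome)
        assert not drops
        assert all(r.mclass == "novel_pc" for r in records)
        # PC-{arm}-{serial}_{total raw count}, serials in genome order
        starts = []
        for r in records:
            arm, serial, total = r.name.split("-")[1], r.name.split("-")[2].split("_")[0], \
                r.name.split("_")[1]
            assert arm in ("5p", "3p") and total == "7"
            starts.append((int(serial), r.locus.start))
        assert starts == sorted(starts)
        assert [s for s, _ in starts] == list(range(1, len(records) + 1))

    def test_novel_arm_from_opposite_arm(self, planted):
        genome, truth = planted
        refs = _refs_from_truth(genome, truth, n=1)
        ref = refs[0]
        # a 21-mer from the arm opposite the annotated mature
        mat_mid = ref.mature_start + len(ref.mature) / 2
        if mat_mid < len(ref.precursor) / 2:
            opp = ref.precursor[len(ref.precursor) - 25 : len(ref.precursor) - 4]
            want_arm = "p3"
        else:
            opp = ref.precursor[4:25]
            want_arm = "p5"
        records, drops = classify_tags([_tag(opp)], refs, refs, [], genome)
        assert records and records[0].mclass == "novel_arm"
        assert records[0].name == f"{ref.id}-{want_arm}"

    def test_homolog_requires_precursor_in_genome(self, planted):
        genome, truth = planted
        refs = _refs_from_truth(genome, truth, n=2)
        # monocot reference whose precursor IS in the genome
        mono_in = ReferenceMature("bdi-mir1", refs[0].mature, refs[0].precursor,
                                  refs[0].mature_start, priority=1)
        # and one whose precursor is foreign
        foreign = "ACGT" * 40
        mono_out = ReferenceMature("bdi-mir2", refs[1].mature, foreign, 10, priority=1)
        records, _ = classify_tags([_tag(refs[0].mature)], [], [], [mono_in], genome)
        assert records and records[0].mclass == "homolog"
        assert records[0].name == "bdi-mir1"
        records2, drops2 = classify_tags([_tag(refs[1].mature)], [], [], [mono_out],
                                         genome)
        # falls through to novel_pc via its genuine genomic hairpin
        assert records2 and records2[0].mclass == "novel_pc"

    def test_partition_property(self, planted):
        genome, truth = planted
        refs = _refs_from_truth(genome, truth, n=3)
        tags = [_tag(pm.mature_seq) for pm in truth.planted_mirnas]
        tags += [_tag("ACGTGTCAGTACGATCGTAC"), _tag("A" * 21), _tag("ACGT" * 6)]
        records, drops = classify_tags(tags, refs, refs, [], genome)
        assert len(records) + len(drops) == len(tags)
        assert drops["A" * 21] in ("unmapped", "fails_hairpin")

    def test_length_precondition_enforced(self, planted):
        genome, _truth = planted
        records, drops = classify_tags([_tag("ACGTACGTACGTACGTACG")], [], [], [],
                                       genome)  # 19 nt
        assert not records and list(drops.values()) == ["length"]

    def test_missing_genome_is_configuration_error(self):
        with pytest.raises(ValueError):
            classify_tags([_tag("ACGTGTCAGTACGATCGTACG")], [], [], [], None)


def _record(name, norm, mfei=1.0, passes=True, with_eval=True):
    tag = UniqueTag(sequence="ACGTGTCAGTACGATCGTACG",
                    raw_counts={k: int(round(v)) for k, v in norm.items()})
    tag.norm_counts = dict(norm)
    ev = None
    if with_eval:
        ev = PrecursorEvaluation(mfe=-40, amfe=40, gc_percent=50, mfei=mfei,
                                 mature_on_one_arm=True, duplex_mismatches=1,
                                 max_asym_bulge=0, passes=passes)
    return MiRNARecord(name=name, mclass="novel_pc" if with_eval else "known",
                       tag=tag, evaluation=ev)


class TestHighConfidenceFilter:
    def test_reported_rows_pass(self):
        # rows drawn from the high-confidence compendium
        kept = high_confidence_filter([
            _record("cme-MIR156j-p3", {"c0": 27, "C1": 22, "Cd1": 52}, mfei=0.90),
            _record("PC-3p-65413_10", {"c0": 4, "C1": 10, "Cd1": 1}, mfei=1.00),
        ])
        assert len(kept) == 2  # the >=10 threshold is inclusive

    def test_below_threshold_dropped(self):
        kept = high_confidence_filter([
            _record("x", {"c0": 4, "C1": 9, "Cd1": 1}, mfei=1.0)])
        assert kept == []

    def test_mfei_binding(self):
        kept = high_confidence_filter([
            _record("x", {"c0": 40, "C1": 40, "Cd1": 40}, mfei=0.80, passes=False)])
        assert kept == []

    def test_two_library_rule(self):
        kept = high_confidence_filter([
            _record("x", {"C1": 50})])
        assert kept == []

    def test_missing_norm_counts_error(self):
        rec = _record("x", {"C1": 50, "C0": 1})
        rec.tag.norm_counts = {}
        with pytest.raises(ValueError):
            high_confidence_filter([rec])


class TestSignificance:
    def test_min_pairwise_rule(self):
        r1 = _record("a", {"C1": 5, "Cd1": 5})
        r1.p_values = {"C0_vs_C1": 0.20, "C1_vs_Cd1": 0.01}
        r2 = _record("b", {"C1": 5, "Cd1": 5})
        r2.p_values = {"C0_vs_C1": 0.40, "C1_vs_Cd1": 0.30, "C0_vs_Cd1": 0.06}
        assert select_significant([r1, r2]) == [r1]
        assert select_significant([r1, r2], alpha=1.0) == [r1, r2]

    def test_requires_de_first(self):
        with pytest.raises(ValueError):
            select_significant([_record("a", {"C1": 5, "C0": 3})])


class TestBaseName:
    @pytest.mark.parametrize("name,expected", [
        ("zma-miR159a-3p_R-1", "zma-miR159a-3p"),
        ("zma-miR827-5p_L+1", "zma-miR827-5p"),
        ("zma-miR160f-5p_1ss21GA", "zma-miR160f-5p"),
        ("zma-miR169f-5p_R-1_1ss1TG", "zma-miR169f-5p"),
        ("PC-3p-33282_23", "PC-3p-33282_23"),
        ("zma-miR390a-5p", "zma-miR390a-5p"),
    ])
    def test_variant_suffix_stripping(self, name, expected):
        assert base_name(name) == expected
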