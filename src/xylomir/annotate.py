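"""Classification of 20-22-nt unique tags into miRNA classes.

Priority order (first match wins):

1. variant match to an own-species mature  -> ``known``
2. exact hit on the arm of an own precursor opposite its annotated
   mature -> ``novel_arm`` (named PRECURSOR-p5/p3 by the arm the tag is on)
3. variant match to an other-monocot mature or precursor arm, with the
   source precursor locatable in the own genome -> ``homolog``
4. genome-mapped tag whose flanking window folds into a passing hairpin
   -> ``novel_pc`` (named PC-{5p|3p}-{serial}_{total raw count}; serials
   are assigned in genome-position order, so runs are reproducible)

Unclassified tags are dropped with a reason; every input tag receives
exactly one class or one drop reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .fold import FoldThresholds, PrecursorEvaluation, evaluate_precursor
from .readproc import (GenomeLocus, MatchPolicy, ReferenceMature, UniqueTag,
                       VariantMatch, map_to_genome, match_tag)
from ._seq import revcomp

__all__ = [
    "MiRNARecord",
    "AnnotatePolicy",
    "classify_tags",
    "high_confidence_filter",
    "select_significant",
    "base_name",
]


@dataclass
class AnnotatePolicy:
    length_range: tuple[int, int] = (20, 22)
    match: MatchPolicy = field(default_factory=MatchPolicy)
    flank: int = 120
    fold_thresholds: FoldThresholds = field(default_factory=FoldThresholds)
    max_eval_loci: int = 4
    anchor_k: int = 10


@dataclass
class MiRNARecord:
    name: str
    mclass: str  # "known" | "novel_arm" | "homolog" | "novel_pc"
    tag: UniqueTag
    locus: Optional[GenomeLocus] = None
    evaluation: Optional[PrecursorEvaluation] = None
    p_values: dict[str, float] = field(default_factory=dict)
    variant: Optional[VariantMatch] = None


def base_name(name: str) -> str:
    """Strip isomiR variant suffixes (_L+-n, _R+-n, _kss...) from a name."""
    return re.sub(r"(_L[+-]\d+)?(_R[+-]\d+)?(_\d+ss[ACGTU\d]+)?$", "", name)


class _AnchorIndex:
    """k-mer prefilter so variant matching only runs on plausible refs."""

    def __init__(self, refs: Sequence[ReferenceMature], k: int):
        self.refs = refs
        self.k = k
        self.index: dict[str, set[int]] = {}
        for i, ref in enumerate(refs):
            context = ref.precursor if ref.precursor else ref.mature
            for j in range(len(context) - k + 1):
                self.index.setdefault(context[j : j + k], set()).add(i)

    def candidates(self, tag: str) -> list[ReferenceMature]:
        hits: set[int] = set()
        for j in range(len(tag) - self.k + 1):
            hits |= self.index.get(tag[j : j + self.k], set())
        return [self.refs[i] for i in sorted(hits)]


def _opposite_arm_hit(tag_seq: str, ref: ReferenceMature) -> Optional[str]:
    """If the tag sits on the precursor arm opposite the annotated mature,
    return '5p' or '3p' (the tag's arm); else None."""
    prec = ref.precursor
    if prec is None or ref.mature_start is None:
        return None
    pos = prec.find(tag_seq)
    if pos == -1:
        return None
    mid = len(prec) / 2
    tag_mid = pos + len(tag_seq) / 2
    mat_mid = ref.mature_start - 1 + len(ref.mature) / 2
    if (tag_mid < mid) == (mat_mid < mid):
        return None
    return "5p" if tag_mid < mid else "3p"


def _precursor_in_genome(prec: str, genome: Mapping[str, str]) -> bool:
    for seq in genome.values():
        if prec in seq or revcomp(prec) in seq:
            return True
    return False


def classify_tags(
    tags: Sequence[UniqueTag],
    own_matures: Sequence[ReferenceMature],
    own_precursors: Sequence[ReferenceMature] = (),
    monocot_refs: Sequence[ReferenceMature] = (),
    genome: Optional[Mapping[str, str]] = None,
    policy: Optional[AnnotatePolicy] = None,
) -> tuple[list[MiRNARecord], dict[str, str]]:
    """Classify tags; returns (records, drop reasons by tag sequence).

    ``own_precursors`` are own-species hairpins (with annotated mature
    coordinates) used for the opposite-arm ``novel_arm`` class; they may
    repeat the entries of ``own_matures``.
    """
    policy = policy or AnnotatePolicy()
    lo, hi = policy.length_range
    own_idx = _AnchorIndex(own_matures, policy.anchor_k) if own_matures else None
    mono_idx = _AnchorIndex(monocot_refs, policy.anchor_k) if monocot_refs else None
    records: list[MiRNARecord] = []
    pc_records: list[MiRNARecord] = []
    drops: dict[str, str] = {}
    names_taken: set[str] = set()

    def unique_name(name: str) -> str:
        if name not in names_taken:
            names_taken.add(name)
            return name
        i = 2
        while f"{name}.{i}" in names_taken:
            i += 1
        names_taken.add(f"{name}.{i}")
        return f"{name}.{i}"

    for tag in sorted(tags, key=lambda t: t.sequence):
        seq = tag.sequence
        if not (lo <= len(seq) <= hi):
            drops[seq] = "length"
            continue
        # (1) known: variant match to an own-species mature
        if own_idx is not None:
            cands = own_idx.candidates(seq)
            vm = match_tag(seq, cands, policy.match) if cands else None
            if vm is not None:
                locus = None
                if genome is not None:
                    loci = map_to_genome(seq, genome)
                    locus = loci[0] if loci else None
                records.append(MiRNARecord(unique_name(vm.variant_name), "known",
                                           tag, locus=locus, variant=vm))
                continue
        # (2) novel_arm: opposite arm of an own precursor
        hit = None
        for ref in own_precursors:
            arm = _opposite_arm_hit(seq, ref)
            if arm is not None:
                hit = (ref, arm)
                break
        if hit is not None:
            ref, arm = hit
            records.append(MiRNARecord(unique_name(f"{ref.id}-p{arm[0]}"), "novel_arm",
                                       tag))
            continue
        # (3) homolog: other-monocot mature/precursor, precursor in own genome
        if mono_idx is not None and genome is not None:
            cands = mono_idx.candidates(seq)
            vm = match_tag(seq, cands, policy.match) if cands else None
            named = None
            if vm is not None:
                ref = next(r for r in monocot_refs if r.id == vm.reference_id)
                if ref.precursor and _precursor_in_genome(ref.precursor, genome):
                    named = vm.variant_name
            if named is None:
                for ref in monocot_refs:
                    if ref.precursor and seq in ref.precursor and \
                            _precursor_in_genome(ref.precursor, genome):
                        pos = ref.precursor.find(seq)
                        arm = "5" if pos + len(seq) / 2 < len(ref.precursor) / 2 else "3"
                        named = f"{ref.id}-p{arm}"
                        vm = None
                        break
            if named is not None:
                loci = map_to_genome(seq, genome)
                records.append(MiRNARecord(unique_name(named), "homolog", tag,
                                           locus=loci[0] if loci else None, variant=vm))
                continue
        # (4) novel_pc: genome locus folding into a passing hairpin
        if genome is None:
            raise ValueError("genome required to evaluate novel miRNA candidates")
        loci = map_to_genome(seq, genome)
        if not loci:
            drops[seq] = "unmapped"
            continue
        chosen = None
        for locus in loci[: policy.max_eval_loci]:
            ev = evaluate_precursor(genome, locus, seq, flank=policy.flank,
                                    thresholds=policy.fold_thresholds)
            if ev.passes:
                chosen = (locus, ev)
                break
        if chosen is None:
            drops[seq] = "fails_hairpin"
            continue
        locus, ev = chosen
        pc_records.append(MiRNARecord("", "novel_pc", tag, locus=locus, evaluation=ev))

    # deterministic PC serials: genome-position order
    pc_records.sort(key=lambda r: (r.locus.chrom, r.locus.start, r.locus.strand))
    for serial, rec in enumerate(pc_records, start=1):
        arm = rec.evaluation.mature_arm or "5p"
        rec.name = unique_name(f"PC-{arm}-{serial}_{rec.tag.total_raw}")
        records.append(rec)
    return records, drops


def _libs_with_reads(tag: UniqueTag) -> int:
    return sum(1 for c in tag.raw_counts.values() if c >= 1)


def high_confidence_filter(
    records: Sequence[MiRNARecord],
    min_reads: float = 10,
    min_mfei: float = 0.85,
    min_libraries: int = 2,
) -> list[MiRNARecord]:
    """Keep records with a normalized count >= ``min_reads`` in at least
    one library, a passing precursor with MFEI >= ``min_mfei`` (records
    annotated by reference identity carry no evaluation and skip the
    structural part), and reads in >= ``min_libraries`` libraries.

    The read threshold is inclusive (>= 10), which is what makes a
    high-confidence table containing rows whose best library has exactly
    10 normalized reads self-consistent.
    """
    out = []
    for rec in records:
        if not rec.tag.norm_counts:
            raise ValueError("normalized counts missing; normalize before filtering")
        if max(rec.tag.norm_counts.values()) < min_reads:
            continue
        if rec.evaluation is not None:
            if not rec.evaluation.passes or rec.evaluation.mfei < min_mfei:
                continue
            rec.evaluation.n_supporting_libraries = _libs_with_reads(rec.tag)
        if _libs_with_reads(rec.tag) < min_libraries:
            continue
        out.append(rec)
    return out


def select_significant(records: Sequence[MiRNARecord], alpha: float = 0.05) -> list[MiRNARecord]:
    """Keep records significant (min pairwise p <= alpha) in at least one
    library comparison.  Differential expression must have populated
    ``p_values`` first."""
    for rec in records:
        if not rec.p_values:
            raise ValueError(
                f"record {rec.name!r} has no p-values; run differential expression first")
    return [rec for rec in records if min(rec.p_values.values()) <= alpha]
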