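"""Raw sRNA reads -> length-filtered, contaminant-free unique tags, plus
variant-aware matching of tags to reference matures and the genome.

Processing ledger (per library, exact partition of input reads):
``reads_in == kept + no_adapter + too_short + contaminant + low_complexity
+ out_of_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ._seq import check_alphabet, normalize, revcomp

__all__ = [
    "UniqueTag",
    "VariantMatch",
    "GenomeLocus",
    "ReferenceMature",
    "MatchPolicy",
    "trim_adapter",
    "collapse_and_filter",
    "match_tag",
    "map_to_genome",
    "process_libraries",
    "is_low_complexity",
    "DEFAULT_ADAPTER",
]

# 3' adapter of a widely used small-RNA library kit; configurable everywhere.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MIN_INSERT = 15


@dataclass
class GenomeLocus:
    chrom: str
    strand: str  # "+" | "-"
    start: int   # 1-based
    end: int     # inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("locus start > end")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    def overlaps(self, other: "GenomeLocus") -> bool:
        return (self.chrom == other.chrom
                and not (self.end < other.start or self.start > other.end))


@dataclass
class UniqueTag:
    sequence: str
    raw_counts: dict[str, int]
    norm_counts: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_raw(self) -> int:
        return sum(self.raw_counts.values())


@dataclass
class VariantMatch:
    reference_id: str
    l_shift: int   # 5' end: + extended, - trimmed
    r_shift: int   # 3' end: + extended, - trimmed
    substitutions: list[tuple[int, str, str]]  # (tag position 1-based, ref base, obs base)

    @property
    def variant_name(self) -> str:
        name = self.reference_id
        if self.l_shift:
            name += f"_L{self.l_shift:+d}"
        if self.r_shift:
            name += f"_R{self.r_shift:+d}"
        if self.substitutions:
            name += f"_{len(self.substitutions)}ss" + "".join(
                f"{pos}{ref}{obs}" for pos, ref, obs in self.substitutions
            )
        return name

    @property
    def is_exact(self) -> bool:
        return not (self.l_shift or self.r_shift or self.substitutions)


@dataclass
class ReferenceMature:
    """A reference mature miRNA, optionally with its precursor context.

    ``priority`` orders reference classes at match ties (0 = own species
    known, 1 = other monocot, ...).
    """

    id: str
    mature: str
    precursor: Optional[str] = None
    mature_start: Optional[int] = None  # 1-based start of the mature in the precursor
    priority: int = 0

    def flank_base(self, offset: int) -> Optional[str]:
        """Precursor base at mature-relative 0-based ``offset`` (may be
        negative / beyond the mature); None if unknown."""
        if self.precursor is None or self.mature_start is None:
            return None
        idx = self.mature_start - 1 + offset
        if 0 <= idx < len(self.precursor):
            return self.precursor[idx]
        return None


@dataclass
class MatchPolicy:
    max_shift: int = 2
    max_subs: int = 1


def trim_adapter(read: str, adapter: str = DEFAULT_ADAPTER, min_overlap: int = 6,
                 max_mismatch_rate: float = 0.1) -> Optional[str]:
    """Remove the leftmost 3' adapter occurrence from a read.

    An occurrence is either the full adapter anywhere in the read, or an
    adapter prefix of >= ``min_overlap`` nt reaching the read's 3' end;
    up to ``max_mismatch_rate`` x overlap mismatches are tolerated.
    Returns the insert, or None when no adapter is found or the insert is
    shorter than 15 nt (adapter dimer / junk).
    """
    if not read:
        raise ValueError("empty read")
    if min_overlap < 5 or len(adapter) < min_overlap:
        raise ValueError("require adapter length >= min_overlap >= 5")
    read = normalize(read)
    adapter = normalize(adapter)
    la = len(adapter)
    # fast path: exact full occurrence
    exact = read.find(adapter)
    best = exact if exact >= 0 else None
    # any earlier mismatched full occurrence, or to-the-end prefix match
    limit = best if best is not None else len(read) - min_overlap
    for i in range(0, limit + 1 if best is None else best):
        overlap = min(la, len(read) - i)
        if overlap < min_overlap:
            break
        if overlap < la and i + overlap != len(read):
            continue  # partial adapter allowed only at the read end
        allowed = int(max_mismatch_rate * overlap)
        mism = 0
        seg = read[i : i + overlap]
        for x, y in zip(seg, adapter):
            if x != y:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            best = i
            break
    if best is None:
        return None
    if best < MIN_INSERT:
        return None
    return read[:best]


def is_low_complexity(seq: str, threshold: float = 0.8) -> bool:
    """True when a mono- or di-nucleotide repeat covers >= ``threshold``
    of the tag (best single base, or best 2-periodic pattern)."""
    n = len(seq)
    if n == 0:
        return True
    mono = max(seq.count(b) for b in "ACGT") / n
    if mono >= threshold:
        return True
    even, odd = seq[::2], seq[1::2]
    be = max("ACGT", key=even.count)
    bo = max("ACGT", key=odd.count)
    di = (even.count(be) + odd.count(bo)) / n
    return di >= threshold


def collapse_and_filter(
    reads_per_library: Mapping[str, Iterable[str]],
    contaminant_refs: Sequence[str] = (),
    length_range: tuple[int, int] = (18, 30),
) -> tuple[list[UniqueTag], dict[str, dict[str, int]]]:
    """Collapse trimmed reads into unique tags and drop contaminant,
    low-complexity and out-of-range tags.

    Returns (tags sorted by sequence, per-library ledger of read fates).
    Contaminant matching is exact substring against either strand of any
    contaminant reference.
    """
    counts: dict[str, dict[str, int]] = {}
    ledger = {lib: {"kept": 0, "contaminant": 0, "low_complexity": 0, "out_of_range": 0}
              for lib in reads_per_library}
    for lib, reads in reads_per_library.items():
        per = counts.setdefault(lib, {})
        for seq in reads:
            per[seq] = per.get(seq, 0) + 1
    all_seqs = sorted(set().union(*[set(c) for c in counts.values()]) if counts else set())
    joined = "\n".join(normalize(c) for c in contaminant_refs)
    lo, hi = length_range
    tags: list[UniqueTag] = []
    for seq in all_seqs:
        per_lib = {lib: counts[lib].get(seq, 0) for lib in counts if counts[lib].get(seq, 0)}
        if not (lo <= len(seq) <= hi):
            fate = "out_of_range"
        elif joined and (seq in joined or revcomp(seq) in joined):
            fate = "contaminant"
        elif is_low_complexity(seq):
            fate = "low_complexity"
        else:
            fate = "kept"
        for lib, c in per_lib.items():
            ledger[lib][fate] += c
        if fate == "kept":
            tags.append(UniqueTag(sequence=seq, raw_counts=per_lib))
    return tags, ledger


def process_libraries(
    raw_reads: Mapping[str, Iterable[str]],
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    contaminant_refs: Sequence[str] = (),
    length_range: tuple[int, int] = (18, 30),
) -> tuple[list[UniqueTag], dict[str, dict[str, int]]]:
    """Full read processing: trim, collapse, filter; exact read ledger.

    Trimming is memoized on the raw read sequence, so deeply duplicated
    libraries trim in O(unique reads).
    """
    trimmed: dict[str, dict[str, int]] = {}
    ledger: dict[str, dict[str, int]] = {}
    # memoized trim fate: insert sequence, or the discard reason
    cache: dict[str, str | None] = {}
    adapter_anchor = normalize(adapter)[:min_overlap]
    for lib, reads in raw_reads.items():
        kept: dict[str, int] = {}
        led = {"reads_in": 0, "no_adapter": 0, "too_short": 0}
        for read in reads:
            led["reads_in"] += 1
            if read in cache:
                ins = cache[read]
            else:
                try:
                    ins = trim_adapter(read, adapter, min_overlap, max_mismatch_rate)
                except ValueError:
                    ins = None
                if ins is None and adapter_anchor in normalize(read):
                    ins = "!too_short"
                cache[read] = ins
            if ins is None:
                led["no_adapter"] += 1
            elif ins == "!too_short":
                led["too_short"] += 1
            else:
                kept[ins] = kept.get(ins, 0) + 1
        trimmed[lib] = kept
        ledger[lib] = led
    # expand via counts without materializing read lists
    expanded = {lib: _CountExpander(kept) for lib, kept in trimmed.items()}  # type: ignore[arg-type]
    tags, filt = collapse_and_filter(expanded, contaminant_refs, length_range)
    for lib in ledger:
        ledger[lib].update(filt.get(lib, {}))
        led = ledger[lib]
        led_sum = (led["kept"] + led["no_adapter"] + led["too_short"]
                   + led["contaminant"] + led["low_complexity"] + led["out_of_range"])
        assert led_sum == led["reads_in"], "read ledger does not balance"
    return tags, ledger


class _CountExpander:
    """Iterates (sequence repeated count times) without building a list."""

    def __init__(self, counts: Mapping[str, int]):
        self.counts = counts

    def __iter__(self):
        for seq, c in self.counts.items():
            for _ in range(c):
                yield seq


def match_tag(
    tag_seq: str,
    references: Sequence[ReferenceMature],
    policy: Optional[MatchPolicy] = None,
) -> Optional[VariantMatch]:
    """Best variant-aware match of a tag to a reference mature set.

    End shifts up to ``max_shift`` nt per side (5' extensions/trims = L,
    3' = R; extensions must be templated by the reference's precursor
    context) and up to ``max_subs`` internal substitutions.  The match
    minimizing (substitutions, |l_shift| + |r_shift|) wins; ties break by
    reference priority class, then lexicographic id.  An exact match
    yields ``variant_name == reference_id``.
    """
    policy = policy or MatchPolicy()
    tag_seq = normalize(tag_seq)
    best: Optional[tuple[tuple, VariantMatch]] = None
    for ref in references:
        mat = ref.mature
        lm, lt = len(mat), len(tag_seq)
        for l_shift in range(-policy.max_shift, policy.max_shift + 1):
            r_shift = lt - lm - l_shift
            if abs(r_shift) > policy.max_shift:
                continue
            subs: list[tuple[int, str, str]] = []
            ok = True
            for k in range(lt):
                ref_off = k - l_shift  # 0-based position on the mature
                if 0 <= ref_off < lm:
                    if tag_seq[k] != mat[ref_off]:
                        subs.append((k + 1, mat[ref_off], tag_seq[k]))
                        if len(subs) > policy.max_subs:
                            ok = False
                            break
                else:
                    base = ref.flank_base(ref_off)
                    if base is None or base != tag_seq[k]:
                        ok = False  # untemplated extension
                        break
            if not ok:
                continue
            vm = VariantMatch(ref.id, l_shift, r_shift, subs)
            key = (len(subs), abs(l_shift) + abs(r_shift), ref.priority, ref.id)
            if best is None or key < best[0]:
                best = (key, vm)
    return best[1] if best else None


def apply_variant(ref: ReferenceMature, match: VariantMatch) -> str:
    """Reconstruct the tag sequence from a reference and a variant record
    (inverse of :func:`match_tag`; used as a consistency check)."""
    lm = len(ref.mature)
    lt = lm + match.l_shift + match.r_shift
    out = []
    for k in range(lt):
        ref_off = k - match.l_shift
        if 0 <= ref_off < lm:
            out.append(ref.mature[ref_off])
        else:
            base = ref.flank_base(ref_off)
            if base is None:
                raise ValueError("extension without precursor context")
            out.append(base)
    for pos, _ref_base, obs in match.substitutions:
        out[pos - 1] = obs
    return "".join(out)


def map_to_genome(tag_seq: str, genome: Mapping[str, str], max_loci: int = 20) -> list[GenomeLocus]:
    """All exact-match loci of a tag on both genome strands, sorted by
    (chrom, start, strand), truncated to ``max_loci``."""
    check_alphabet(tag_seq, "tag")
    loci: list[GenomeLocus] = []
    rc = revcomp(tag_seq)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for query, strand in ((tag_seq, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                loci.append(GenomeLocus(chrom, strand, start + 1, start + len(query)))
                start = seq.find(query, start + 1)
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return loci[:max_loci]
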