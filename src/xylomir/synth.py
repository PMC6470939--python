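"""Synthetic study generator: genomes with planted miRNA hairpins, three
sRNA libraries (two controls and one Cd-treated) with planted fold
changes, transcriptomes with planted complementary target sites, and
degradome tag libraries peaked at the canonical cleavage position.

Everything is reproducible from integer seeds, and every truth record is
re-derivable from the emitted files (sequence search, count aggregation).
The generator emulates the statistical structure the downstream analysis
assumes; see docs/methods.md for what it deliberately does not model
(sequencing errors, multi-copy miRNA families, quality scores).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from ._seq import revcomp, write_fasta, write_fastq
from .readproc import DEFAULT_ADAPTER, GenomeLocus, ReferenceMature
from .targets import expectation_score

__all__ = [
    "PlantedMiRNA",
    "PlantedTarget",
    "TruthSet",
    "CapacityError",
    "synth_genome",
    "assign_de_truth",
    "synth_libraries",
    "synth_transcriptome",
    "synth_degradome",
    "simulate_null_tag_counts",
    "bundled_contaminants",
    "SimulatedStudy",
    "simulate_study",
    "write_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
# bases that pair (WC or wobble) with a given base
_PAIRS_WITH = {"A": {"T"}, "T": {"A", "G"}, "G": {"C", "T"}, "C": {"G"}}


class CapacityError(ValueError):
    """Requested hairpins cannot be placed without overlap."""


@dataclass
class PlantedMiRNA:
    name: str
    mature_seq: str
    arm: str                      # "5p" | "3p"
    locus: GenomeLocus            # of the mature sequence
    precursor_locus: GenomeLocus  # of the whole hairpin


@dataclass
class PlantedTarget:
    mirna: str
    transcript_id: str
    site_start: int   # 1-based inclusive
    site_end: int
    n_mismatch: int
    n_gu: int
    true_cleavage_pos: int
    pairing: str = ""
    expected_expectation: float = 0.0


@dataclass
class TruthSet:
    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    de_truth: dict[str, tuple[float, float]] = field(default_factory=dict)  # name -> (baseline RPM, fold change)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    rng_seed: int = 0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _seq_with_gc(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random sequence with an exact GC base count (shuffled composition)."""
    n_gc = int(round(gc * n))
    g = int(rng.integers(0, n_gc + 1))
    a = int(rng.integers(0, n - n_gc + 1))
    chars = ["G"] * g + ["C"] * (n_gc - g) + ["A"] * a + ["T"] * (n - n_gc - a)
    idx = rng.permutation(n)
    return "".join(chars[i] for i in idx)


def synth_genome(
    n_chromosomes: int = 1,
    chrom_length: int = 100_000,
    n_hairpins: int = 10,
    seed: int = 0,
    arm_len_range: tuple[int, int] = (55, 90),
    loop_range: tuple[int, int] = (6, 12),
    mispair_range: tuple[int, int] = (0, 3),
    gc_range: tuple[float, float] = (0.40, 0.65),
    mature_len_range: tuple[int, int] = (20, 22),
) -> tuple[dict[str, str], TruthSet]:
    """Random chromosomes with ``n_hairpins`` planted, non-overlapping
    miRNA hairpin loci (arm + 6-12 nt loop + near-reverse-complement arm).

    Each planted mature 20-22-mer lies fully within one arm and occurs in
    the genome only at its truth locus (background regions containing a
    spurious copy are re-drawn).
    """
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if n_hairpins < 1:
        raise ValueError("need at least one hairpin")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chroms = {c: np.frombuffer(_random_seq(rng, chrom_length).encode(), dtype=np.uint8).copy()
              for c in chrom_names}
    truth = TruthSet(rng_seed=seed)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    min_gap = 50
    for h in range(n_hairpins):
        arm_len = int(rng.integers(arm_len_range[0], arm_len_range[1] + 1))
        loop_len = int(rng.integers(loop_range[0], loop_range[1] + 1))
        n_mispair = int(rng.integers(mispair_range[0], mispair_range[1] + 1))
        mature_len = int(rng.integers(mature_len_range[0], mature_len_range[1] + 1))
        gc = float(rng.uniform(*gc_range))
        arm5 = _seq_with_gc(rng, arm_len, gc)
        arm3 = list(revcomp(arm5))
        arm = "5p" if rng.random() < 0.5 else "3p"
        off = int(rng.integers(0, arm_len - mature_len + 1))
        # the mature/star duplex region in 3' arm coordinates; planted
        # mispairs stay clear of it (and >= 5 nt apart) so the optimal
        # fold keeps the duplex criteria of the downstream evaluation
        if arm == "3p":
            dup_lo, dup_hi = off, off + mature_len - 1
        else:
            dup_lo, dup_hi = arm_len - mature_len - off, arm_len - 1 - off
        allowed = [p for p in range(arm_len) if p < dup_lo - 3 or p > dup_hi + 3]
        chosen: list[int] = []
        for p in (int(x) for x in rng.permutation(allowed)):
            if len(chosen) >= n_mispair:
                break
            if all(abs(p - q) >= 5 for q in chosen):
                chosen.append(p)
        for p in sorted(chosen):
            partner = arm5[arm_len - 1 - p]
            banned = _PAIRS_WITH[partner] | {arm3[p]}
            choices = [b for b in "ACGT" if b not in banned]
            arm3[p] = choices[int(rng.integers(len(choices)))]
        arm3 = "".join(arm3)
        hairpin = arm5 + _random_seq(rng, loop_len) + arm3
        mature = (arm5 if arm == "5p" else arm3)[off : off + mature_len]
        # place without overlap
        for _attempt in range(500):
            chrom = chrom_names[int(rng.integers(n_chromosomes))]
            start = int(rng.integers(0, chrom_length - len(hairpin)))
            end = start + len(hairpin)
            if all(end + min_gap <= s or start >= e + min_gap for s, e in placed[chrom]):
                break
        else:
            raise CapacityError(f"could not place hairpin {h + 1} without overlap")
        placed[chrom].append((start, end))
        chroms[chrom][start:end] = np.frombuffer(hairpin.encode(), dtype=np.uint8)
        arm_off = off if arm == "5p" else arm_len + loop_len + off
        m_start = start + arm_off + 1  # 1-based
        truth.planted_mirnas.append(PlantedMiRNA(
            name=f"syn-miR{h + 1:03d}-{arm}",
            mature_seq=mature,
            arm=arm,
            locus=GenomeLocus(chrom, "+", m_start, m_start + mature_len - 1),
            precursor_locus=GenomeLocus(chrom, "+", start + 1, end),
        ))
    genome = {c: arr.tobytes().decode() for c, arr in chroms.items()}
    genome = _scrub_collisions(genome, truth, placed, rng)
    return genome, truth


def _scrub_collisions(genome: dict[str, str], truth: TruthSet,
                      placed: dict[str, list[tuple[int, int]]],
                      rng: np.random.Generator) -> dict[str, str]:
    """Re-draw background regions that happen to contain a planted mature
    (either strand), so each mature's truth locus is unique."""
    queries = []
    for pm in truth.planted_mirnas:
        queries.append((pm.mature_seq, pm))
        queries.append((revcomp(pm.mature_seq), pm))
    for _round in range(50):
        dirty = False
        for chrom, seq in genome.items():
            hp = placed[chrom]
            for query, _pm in queries:
                start = seq.find(query)
                while start != -1:
                    inside_hairpin = any(s <= start and start + len(query) <= e for s, e in hp)
                    if not inside_hairpin:
                        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                        arr[start : start + len(query)] = _BASES[rng.integers(0, 4, len(query))]
                        seq = arr.tobytes().decode()
                        genome[chrom] = seq
                        dirty = True
                    start = seq.find(query, start + 1)
        if not dirty:
            return genome
    raise RuntimeError("could not scrub background collisions")


def assign_de_truth(
    truth: TruthSet,
    seed: int = 0,
    background_fraction: float = 0.2,
    fold_changes: Optional[Sequence[float]] = None,
) -> TruthSet:
    """Assign per-miRNA baseline abundances (reads per million) and Cd
    fold changes.

    The planted miRNAs take ``1 - background_fraction`` of a library.
    Cd-responsive miRNAs are planted at moderate fixed baselines
    (hundreds to a few thousand RPM): two strong inductions (8x), two
    strong repressions (1/8) and one mild induction (2x); the flat
    (fold-change 1) miRNAs share the remaining library mass with
    log-uniform weights.  Keeping the responsive miRNAs a small fraction
    of the library mirrors the regime the study design assumes -
    normalization against the library total is only fold-change-faithful
    when the changing tags do not themselves dominate the total.
    """
    rng = np.random.default_rng(seed)
    names = [pm.name for pm in truth.planted_mirnas]
    planted_mass = (1.0 - background_fraction) * 1e6
    if fold_changes is None:
        fold_changes = [8.0, 0.125, 8.0, 0.125, 2.0] + [1.0] * max(0, len(names) - 5)
    fold_changes = list(fold_changes) + [1.0] * max(0, len(names) - len(fold_changes))
    de_baselines = iter([2000.0, 1500.0, 800.0, 400.0, 1000.0, 600.0, 300.0, 150.0])
    baselines = np.zeros(len(names))
    flat_idx = [i for i, fc in enumerate(fold_changes[: len(names)]) if fc == 1.0]
    for i, fc in enumerate(fold_changes[: len(names)]):
        if fc != 1.0:
            baselines[i] = next(de_baselines, 500.0)
    remaining = planted_mass - baselines.sum()
    if remaining <= 0 or (not flat_idx and remaining > 0):
        raise ValueError("background_fraction leaves no mass for flat miRNAs")
    w = 10 ** rng.uniform(0.0, 1.5, len(flat_idx))
    for i, wi in zip(flat_idx, w):
        baselines[i] = wi / w.sum() * remaining
    for name, b, fc in zip(names, baselines, fold_changes):
        if fc <= 0:
            raise ValueError("fold_change_cd must be > 0")
        truth.de_truth[name] = (float(b), float(fc))
    return truth


@lru_cache(maxsize=1)
def bundled_contaminants() -> tuple[tuple[str, str], ...]:
    """A small fixed set of synthetic rRNA/tRNA-like contaminant
    references (stand-ins for the common structural-RNA families that
    read processing removes)."""
    rng = np.random.default_rng(774422)
    out = []
    for i, (kind, length) in enumerate(
        [("rRNA", 160), ("rRNA", 140), ("rRNA", 120), ("tRNA", 90),
         ("tRNA", 85), ("snRNA", 110), ("snoRNA", 100), ("repeat", 150)]
    ):
        out.append((f"synthetic-{kind}-{i + 1}", _random_seq(rng, length)))
    return tuple(out)


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1e-12:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def synth_libraries(
    truth: TruthSet,
    genome: Mapping[str, str],
    depth: int = 1_000_000,
    dispersion: float = 0.1,
    seed: int = 0,
    adapter: str = DEFAULT_ADAPTER,
    background_fraction: float = 0.2,
    contaminant_share: float = 0.5,
    isomir_rates: tuple[float, float] = (0.05, 0.05),  # (R+1, R-1), genome-templated
    lib_ids: Sequence[str] = ("C0", "C1", "Cd1"),
    cd_lib: str = "Cd1",
    contaminants: Optional[Sequence[tuple[str, str]]] = None,
) -> dict[str, list[str]]:
    """Three read libraries with planted miRNA abundances.

    Per-library miRNA counts are negative binomial with mean
    ``baseline x depth / 1e6`` (times ``fold_change_cd`` in the Cd
    library) and the stated dispersion (0 = Poisson limit).  The rest of
    the library is background: random 18-30-mers and fragments of the
    contaminant references, all 20-24-nt dominated.  Reads carry the 3'
    adapter; a configurable fraction of miRNA reads are 3' end-variant
    (R+1 templated / R-1) isomiRs.
    """
    if depth < 10_000:
        raise ValueError("depth must be >= 10000")
    if not truth.de_truth:
        raise ValueError("truth has no de_truth; call assign_de_truth first")
    rng = np.random.default_rng(seed)
    contaminants = contaminants if contaminants is not None else bundled_contaminants()
    cont_seqs = [s for _n, s in contaminants]
    rate_p, rate_m = isomir_rates
    lengths = np.arange(18, 31)
    len_w = np.array([1, 1, 3, 6, 6, 5, 5, 2, 1, 1, 1, 1, 1], dtype=float)
    len_w /= len_w.sum()
    low_means = [name for name, (b, _fc) in truth.de_truth.items()
                 if b * depth / 1e6 < 1.0]
    if low_means:
        warnings.warn(
            f"depth {depth} too small to represent planted miRNAs at mean >= 1: "
            + ", ".join(low_means),
            stacklevel=2,
        )
    by_name = {pm.name: pm for pm in truth.planted_mirnas}
    out: dict[str, list[str]] = {}
    for lib in lib_ids:
        reads: list[str] = []
        for pm in truth.planted_mirnas:
            baseline, fc = truth.de_truth[pm.name]
            mean = baseline * depth / 1e6 * (fc if lib == cd_lib else 1.0)
            count = _draw_counts(rng, mean, dispersion)
            if count == 0:
                continue
            n_plus, n_minus = 0, 0
            if rate_p + rate_m > 0:
                n_can, n_plus, n_minus = rng.multinomial(
                    count, [1 - rate_p - rate_m, rate_p, rate_m])
            else:
                n_can = count
            mature = pm.mature_seq
            reads.extend([mature + adapter] * int(n_can))
            if n_plus:
                chrom = genome[pm.locus.chrom]
                if pm.locus.strand == "+" and pm.locus.end < len(chrom):
                    ext = mature + chrom[pm.locus.end]
                elif pm.locus.strand == "-" and pm.locus.start > 1:
                    ext = mature + _COMP[chrom[pm.locus.start - 2]]
                else:
                    ext = mature
                reads.extend([ext + adapter] * int(n_plus))
            if n_minus:
                reads.extend([mature[:-1] + adapter] * int(n_minus))
        n_bg = max(0, depth - len(reads))
        n_cont = int(round(n_bg * contaminant_share))
        n_rand = n_bg - n_cont
        if n_cont:
            ref_idx = rng.integers(0, len(cont_seqs), n_cont)
            frag_len = rng.choice(lengths, n_cont, p=len_w)
            for ri, fl in zip(ref_idx, frag_len):
                ref = cont_seqs[int(ri)]
                fl = min(int(fl), len(ref))
                start = int(rng.integers(0, len(ref) - fl + 1))
                reads.append(ref[start : start + fl] + adapter)
        if n_rand:
            rand_len = rng.choice(lengths, n_rand, p=len_w)
            total = int(rand_len.sum())
            buf = _BASES[rng.integers(0, 4, total)].tobytes().decode()
            pos = 0
            for fl in rand_len:
                fl = int(fl)
                reads.append(buf[pos : pos + fl] + adapter)
                pos += fl
        order = rng.permutation(len(reads))
        out[lib] = [reads[i] for i in order]
    return out


def simulate_null_tag_counts(
    n_tags: int,
    depth: int = 1_000_000,
    dispersion: float = 0.0,
    seed: int = 0,
    baseline_range: tuple[float, float] = (20.0, 2000.0),
    lib_ids: tuple[str, str] = ("C1", "Cd1"),
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Per-tag counts in two libraries under the null (fold change 1 for
    every tag); used to calibrate the differential-expression stage.

    Baselines (RPM) are log-uniform over ``baseline_range``; counts are
    drawn from the generator's count model.  Returns (counts, totals)
    ready for :func:`xylomir.de.pairwise_de`.
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(baseline_range[0]), np.log10(baseline_range[1])
    baselines = 10 ** rng.uniform(lo, hi, n_tags)
    counts: dict[str, dict[str, int]] = {}
    for i, b in enumerate(baselines):
        mean = b * depth / 1e6
        counts[f"tag{i:05d}"] = {
            lib: _draw_counts(rng, mean, dispersion) for lib in lib_ids
        }
    totals = {lib: depth for lib in lib_ids}
    return counts, totals


_EDIT_KINDS = ("mismatch", "gu", "bulge1", "bulge2")

DEFAULT_MISMATCH_PLAN: list[list[tuple[int, str]]] = [
    [],                   # perfect complement
    [(15, "gu")],         # wobble outside the seed
    [(20, "mismatch")],   # mismatch near the miRNA 3' end
    [],
    [(18, "mismatch")],
]


def _build_site(mirna: str, edits: Sequence[tuple[int, str]],
                rng: np.random.Generator) -> tuple[str, str]:
    """Return (site sequence 5'->3' on the transcript, pairing string)."""
    m = len(mirna)
    cols: list[tuple[str, str]] = []  # (transcript base in miRNA order, symbol)
    edit_map: dict[int, list[str]] = {}
    for pos, kind in edits:
        if not (1 <= pos <= m):
            raise ValueError(f"edit position {pos} outside miRNA length {m}")
        if kind not in _EDIT_KINDS:
            raise ValueError(f"unknown edit kind {kind!r}")
        edit_map.setdefault(pos, []).append(kind)
    for pos in range(1, m + 1):
        base = mirna[pos - 1]
        for kind in edit_map.get(pos, []):
            if kind.startswith("bulge"):
                if pos in (10, 11):
                    raise ValueError("bulge opposite miRNA positions 10-11 not allowed")
                for _ in range(int(kind[-1])):
                    cols.append((_BASES[rng.integers(0, 4)].tobytes().decode(), "-"))
        kinds = [k for k in edit_map.get(pos, []) if not k.startswith("bulge")]
        if not kinds:
            cols.append((_COMP[base], "|"))
        elif kinds[0] == "mismatch":
            cols.append((base, "."))  # self-pairing is never WC nor wobble
        else:  # gu
            if base == "G":
                cols.append(("T", "o"))
            elif base == "T":
                cols.append(("G", "o"))
            else:
                raise ValueError(f"G:U edit at position {pos}: miRNA base {base} is not G/U")
    site = "".join(b for b, _s in cols)[::-1]  # transcript runs antiparallel
    pairing = "".join(s for _b, s in cols)
    return site, pairing


def _adapt_edits(mirna: str, edits: Sequence[tuple[int, str]]) -> list[tuple[int, str]]:
    """Relocate G:U edits to the nearest miRNA position whose base can
    actually wobble (G or U), so one edit plan applies to any miRNA; the
    truth records the realized pairing and score."""
    out: list[tuple[int, str]] = []
    used = {p for p, _k in edits}
    m = len(mirna)
    for pos, kind in edits:
        if kind != "gu" or mirna[pos - 1] in "GT":
            out.append((pos, kind))
            continue
        moved = None
        for delta in range(1, m):
            for cand in (pos + delta, pos - delta):
                if 1 <= cand <= m and cand not in used and mirna[cand - 1] in "GT":
                    moved = cand
                    break
            if moved:
                break
        if moved is None:
            # no wobble-capable base at all: degrade to a mismatch edit
            out.append((pos, "mismatch"))
            continue
        used.add(moved)
        out.append((moved, "gu"))
    return out


def synth_transcriptome(
    mirnas: Sequence[tuple[str, str]],
    n_transcripts: int = 60,
    sites_per_mirna: int = 5,
    mismatch_plan: Optional[Sequence[Sequence[tuple[int, str]]]] = None,
    seed: int = 0,
    length_range: tuple[int, int] = (400, 900),
) -> tuple[dict[str, str], list[PlantedTarget]]:
    """Random transcripts with planted miRNA-complementary sites.

    Each site is the reverse complement of its miRNA with the plan's
    edits applied (Watson-Crick mismatch, G:U wobble, or a 1-2 nt
    transcript-side bulge) at the stated miRNA positions; plans cycle
    over sites.  Truth records the pairing string and the expectation
    score the target-prediction stage should assign.
    """
    if length_range[0] < 200:
        raise ValueError("transcripts must be >= 200 nt")
    rng = np.random.default_rng(seed)
    plan = list(mismatch_plan) if mismatch_plan is not None else DEFAULT_MISMATCH_PLAN
    tx_ids = [f"synT{i + 1:04d}_T01" for i in range(n_transcripts)]
    tx_seqs = {tid: np.frombuffer(
        _random_seq(rng, int(rng.integers(length_range[0], length_range[1] + 1))).encode(),
        dtype=np.uint8).copy() for tid in tx_ids}
    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in tx_ids}
    targets: list[PlantedTarget] = []
    gi = 0
    margin = 30
    for name, mseq in mirnas:
        for _k in range(sites_per_mirna):
            edits = plan[gi % len(plan)] if plan else []
            edits = _adapt_edits(mseq, edits)
            site, pairing = _build_site(mseq, edits, rng)
            tid = tx_ids[gi % n_transcripts]
            arr = tx_seqs[tid]
            L = len(arr)
            for _attempt in range(200):
                start = int(rng.integers(margin, L - len(site) - margin))
                end = start + len(site) - 1
                if all(end + 5 < s or start > e + 5 for s, e in occupied[tid]):
                    break
            else:
                raise CapacityError(f"could not place site {gi} in {tid}")
            occupied[tid].append((start, end))
            arr[start : start + len(site)] = np.frombuffer(site.encode(), dtype=np.uint8)
            site_start, site_end = start + 1, end + 1  # 1-based
            # walk the pairing from the site 3' end to find the position
            # pairing miRNA position 10
            t, pos, cleave = site_end, 0, None
            for ch in pairing:
                if ch != "-":
                    pos += 1
                    if pos == 10:
                        cleave = t
                        break
                t -= 1
            assert cleave is not None
            targets.append(PlantedTarget(
                mirna=name, transcript_id=tid,
                site_start=site_start, site_end=site_end,
                n_mismatch=pairing.count("."), n_gu=pairing.count("o"),
                true_cleavage_pos=cleave, pairing=pairing,
                expected_expectation=expectation_score(pairing),
            ))
            gi += 1
    transcripts = {tid: arr.tobytes().decode() for tid, arr in tx_seqs.items()}
    return transcripts, targets


def synth_degradome(
    planted_targets: Sequence[PlantedTarget],
    transcripts: Mapping[str, str],
    peak_fraction: float = 0.8,
    n_libraries: int = 3,
    depth: int = 30_000,
    seed: int = 0,
) -> dict[str, dict[str, dict[int, int]]]:
    """Degradome 5'-end tag-count profiles per library.

    For each targeted transcript, ``peak_fraction`` of its tags fall
    exactly at the planted cleavage position(s); the rest are uniform
    over the transcript.  ``peak_fraction == 0`` gives pure uniform
    profiles (the no-signal control)."""
    if not (0.0 <= peak_fraction <= 1.0):
        raise ValueError("peak_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_tx: dict[str, list[PlantedTarget]] = {}
    for t in planted_targets:
        by_tx.setdefault(t.transcript_id, []).append(t)
    if not by_tx:
        return {f"D{i + 1}": {} for i in range(n_libraries)}
    n_per_tx = max(1, depth // len(by_tx))
    out: dict[str, dict[str, dict[int, int]]] = {}
    for li in range(n_libraries):
        lib: dict[str, dict[int, int]] = {}
        for tid, sites in by_tx.items():
            L = len(transcripts[tid])
            n_peak_total = int(round(peak_fraction * n_per_tx))
            profile: dict[int, int] = {}
            share = [n_peak_total // len(sites)] * len(sites)
            share[0] += n_peak_total - sum(share)
            for s, site in zip(share, sites):
                if s:
                    profile[site.true_cleavage_pos] = profile.get(site.true_cleavage_pos, 0) + s
            n_noise = n_per_tx - n_peak_total
            if n_noise:
                positions = rng.integers(1, L + 1, n_noise)
                vals, cnts = np.unique(positions, return_counts=True)
                for p, c in zip(vals, cnts):
                    profile[int(p)] = profile.get(int(p), 0) + int(c)
            lib[tid] = profile
        out[f"D{li + 1}"] = lib
    return out


@dataclass
class SimulatedStudy:
    seed: int
    genome: dict[str, str]
    truth: TruthSet
    libraries: dict[str, list[str]]
    transcripts: dict[str, str]
    degradome: dict[str, dict[str, dict[int, int]]]
    known_refs: list[ReferenceMature]
    contaminants: tuple[tuple[str, str], ...]
    config: dict = field(default_factory=dict)


def simulate_study(
    seed: int = 0,
    n_chromosomes: int = 1,
    chrom_length: int = 100_000,
    n_hairpins: int = 10,
    depth: int = 1_000_000,
    dispersion: float = 0.1,
    n_transcripts: int = 60,
    sites_per_mirna: int = 5,
    degradome_depth: int = 30_000,
    degradome_libraries: int = 3,
    peak_fraction: float = 0.8,
    known_fraction: float = 0.5,
    background_fraction: float = 0.2,
    mismatch_plan: Optional[Sequence[Sequence[tuple[int, str]]]] = None,
) -> SimulatedStudy:
    """Generate one complete synthetic study (genome, three sRNA
    libraries, transcriptome with planted targets, degradome libraries)
    with all ground truth, reproducibly from one seed."""
    rng = np.random.default_rng(seed)
    s_genome, s_de, s_libs, s_tx, s_deg = (int(x) for x in rng.integers(0, 2**31 - 1, 5))
    genome, truth = synth_genome(n_chromosomes, chrom_length, n_hairpins, seed=s_genome)
    assign_de_truth(truth, seed=s_de, background_fraction=background_fraction)
    libraries = synth_libraries(truth, genome, depth=depth, dispersion=dispersion,
                                seed=s_libs, background_fraction=background_fraction)
    mirnas = [(pm.name, pm.mature_seq) for pm in truth.planted_mirnas]
    transcripts, targets = synth_transcriptome(
        mirnas, n_transcripts=n_transcripts, sites_per_mirna=sites_per_mirna,
        mismatch_plan=mismatch_plan, seed=s_tx)
    truth.planted_targets = targets
    degradome = synth_degradome(targets, transcripts, peak_fraction=peak_fraction,
                                n_libraries=degradome_libraries, depth=degradome_depth,
                                seed=s_deg)
    n_known = int(round(known_fraction * len(truth.planted_mirnas)))
    refs = []
    for pm in truth.planted_mirnas[:n_known]:
        chrom = genome[pm.precursor_locus.chrom]
        prec = chrom[pm.precursor_locus.start - 1 : pm.precursor_locus.end]
        refs.append(ReferenceMature(
            id=pm.name, mature=pm.mature_seq, precursor=prec,
            mature_start=pm.locus.start - pm.precursor_locus.start + 1, priority=0))
    config = dict(seed=seed, n_chromosomes=n_chromosomes, chrom_length=chrom_length,
                  n_hairpins=n_hairpins, depth=depth, dispersion=dispersion,
                  n_transcripts=n_transcripts, sites_per_mirna=sites_per_mirna,
                  degradome_depth=degradome_depth, degradome_libraries=degradome_libraries,
                  peak_fraction=peak_fraction, known_fraction=known_fraction,
                  background_fraction=background_fraction)
    return SimulatedStudy(seed=seed, genome=genome, truth=truth, libraries=libraries,
                          transcripts=transcripts, degradome=degradome, known_refs=refs,
                          contaminants=bundled_contaminants(), config=config)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated study to disk: FASTA genome/transcriptome/
    references/contaminants, FASTQ reads, GFF3 hairpin loci, degradome
    count TSV, truth TSVs and a JSON manifest.  Byte-identical for equal
    inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_fasta(p("genome.fa"), sorted(study.genome.items()))
    write_fasta(p("transcripts.fa"), sorted(study.transcripts.items()))
    write_fasta(p("contaminants.fa"), study.contaminants)
    write_fasta(p("refs_mature.fa"), [(r.id, r.mature) for r in study.known_refs])
    write_fasta(p("refs_hairpin.fa"), [(r.id, r.precursor) for r in study.known_refs])
    for lib, reads in study.libraries.items():
        write_fastq(p(f"reads_{lib}.fastq"), reads, prefix=lib)
    with open(p("hairpins.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for pm in study.truth.planted_mirnas:
            loc = pm.precursor_locus
            fh.write(f"{loc.chrom}\txylomir_sim\tmiRNA_primary_transcript\t{loc.start}\t"
                     f"{loc.end}\t.\t{loc.strand}\t.\tID={pm.name}-precursor\n")
            m = pm.locus
            fh.write(f"{m.chrom}\txylomir_sim\tmiRNA\t{m.start}\t{m.end}\t.\t"
                     f"{m.strand}\t.\tID={pm.name}\n")
    with open(p("degradome_counts.tsv"), "w") as fh:
        fh.write("transcript_id\tposition\tcount\tlibrary_id\n")
        for lib in sorted(study.degradome):
            for tid in sorted(study.degradome[lib]):
                for pos in sorted(study.degradome[lib][tid]):
                    fh.write(f"{tid}\t{pos}\t{study.degradome[lib][tid][pos]}\t{lib}\n")
    with open(p("truth_mirnas.tsv"), "w") as fh:
        fh.write("name\tmature_seq\tarm\tchrom\tstrand\tstart\tend\tbaseline_rpm\tfold_change_cd\n")
        for pm in study.truth.planted_mirnas:
            b, fc = study.truth.de_truth.get(pm.name, (float("nan"), float("nan")))
            fh.write(f"{pm.name}\t{pm.mature_seq}\t{pm.arm}\t{pm.locus.chrom}\t"
                     f"{pm.locus.strand}\t{pm.locus.start}\t{pm.locus.end}\t{b:.4f}\t{fc}\n")
    with open(p("truth_targets.tsv"), "w") as fh:
        fh.write("mirna\ttranscript_id\tsite_start\tsite_end\tn_mismatch\tn_gu\t"
                 "true_cleavage_pos\tpairing\texpected_expectation\n")
        for t in study.truth.planted_targets:
            fh.write(f"{t.mirna}\t{t.transcript_id}\t{t.site_start}\t{t.site_end}\t"
                     f"{t.n_mismatch}\t{t.n_gu}\t{t.true_cleavage_pos}\t{t.pairing}\t"
                     f"{t.expected_expectation}\n")
    with open(p("manifest.json"), "w") as fh:
        json.dump({"generator": "xylomir.synth", "config": study.config}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
    return paths
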