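"""Single stem-loop folding under the simplified energy model SLF-1, and
plant pre-miRNA evaluation (MFE, AMFE, MFEI, duplex criteria).

SLF-1 scores a structure made of one helix (with bulges/internal loops)
closed by one terminal loop:

* pair energies: GC/CG -3.0, AT/TA -2.0 (A:U), GT/TG -1.0 (G:U wobble)
* +3.0 for closing the terminal loop (>= 3 unpaired nt, i.e. j-i >= 4)
* +0.5 per unpaired nucleotide interior to the stem
* nucleotides outside the outermost pair are free

The minimum-energy stem-loop over all placements is found by dynamic
programming (equivalent to optimally aligning the 5' prefix against the
reverse-complemented 3' suffix over all split points).  Energies are kept
in integer half-units so ties are exact; ties are broken toward more
pairs, then toward the lexicographically smallest pair list.

The folding backend is pluggable: any callable with the signature of
:func:`fold_best_hairpin` (e.g. a thermodynamic folder) can be passed to
:func:`evaluate_precursor`; everything shipped here uses SLF-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from ._seq import check_alphabet, gc_percent, revcomp

__all__ = [
    "HairpinStructure",
    "PrecursorEvaluation",
    "FoldThresholds",
    "fold_best_hairpin",
    "compute_mfei",
    "evaluate_precursor",
    "dot_bracket",
]

# energies in half-units (1 unit == 0.5 kcal/mol of the model scale)
_PAIR_E2 = np.zeros((5, 5), dtype=np.int64)
_PAIRABLE = np.zeros((5, 5), dtype=bool)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
for _a, _b, _e in [("A", "T", -4), ("T", "A", -4), ("G", "C", -6), ("C", "G", -6),
                   ("G", "T", -2), ("T", "G", -2)]:
    _PAIR_E2[_CODE[_a], _CODE[_b]] = _e
    _PAIRABLE[_CODE[_a], _CODE[_b]] = True

_LOOP_E2 = 6        # +3.0 terminal loop closure
_BULGE_E2 = 1       # +0.5 per interior unpaired nt
_MIN_LOOP = 3       # terminal loop >= 3 nt  <=>  j - i >= 4 for every pair

# value encoding: enc = e2 * 1024 - n_pairs  (minimize energy, then maximize pairs)
_NP_MOD = 1024
_INF = np.int64(1) << 40

MIN_FOLD_LEN = 15
MAX_FOLD_LEN = 400


@dataclass
class HairpinStructure:
    """One stem-loop: non-crossing pair list (1-based, i<j) plus model energy."""

    sequence: str
    pairs: list[tuple[int, int]]
    mfe: float
    loop_span: Optional[tuple[int, int]]  # (first, last) unpaired nt of the terminal loop

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _encode_seq(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


def _decode(enc: int) -> tuple[int, int]:
    """Return (e2, n_pairs) from an encoded value."""
    npairs = int((-enc) % _NP_MOD)
    e2 = int((enc + npairs) // _NP_MOD)
    return e2, npairs


def _fill_tables(codes: np.ndarray, blocked: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """DP tables over all regions.

    A[i, j]: best encoded value of a stem whose outermost pair is exactly (i, j).
    B[i, j]: best encoded value of the interior of a stem whose enclosing pair
             is (i-1, j+1): either the terminal loop, or an inner stem with the
             skipped flanking nucleotides charged as bulge.
    """
    n = len(codes)
    A = np.full((n, n), _INF, dtype=np.int64)
    B = np.full((n, n), _INF, dtype=np.int64)
    close_enc = np.int64(_LOOP_E2 * _NP_MOD)
    skip = np.int64(_BULGE_E2 * _NP_MOD)
    for s in range(2, n):
        i = np.arange(0, n - s)
        j = i + s
        if s >= _MIN_LOOP + 1:
            pe2 = _PAIR_E2[codes[i], codes[j]]
            ok = _PAIRABLE[codes[i], codes[j]]
            if blocked is not None:
                ok = ok & ~blocked[i] & ~blocked[j]
            a_diag = np.where(ok, pe2 * _NP_MOD - 1 + B[i + 1, j - 1], _INF)
            A[i, j] = a_diag
        else:
            a_diag = np.full(n - s, _INF, dtype=np.int64)
        b_diag = np.minimum(a_diag, close_enc)
        b_diag = np.minimum(b_diag, B[i + 1, j] + skip)
        b_diag = np.minimum(b_diag, B[i, j - 1] + skip)
        B[i, j] = b_diag
    return A, B


def _traceback(codes: np.ndarray, A: np.ndarray, opt: int) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Recover the optimal pair list (0-based), lexicographically smallest."""
    n = len(codes)
    outer = None
    for i in range(n):
        row = A[i]
        hits = np.nonzero(row == opt)[0]
        if hits.size:
            outer = (i, int(hits[0]))
            break
    if outer is None:  # pragma: no cover - internal consistency
        raise RuntimeError("traceback failed to locate the optimal outer pair")
    pairs = [outer]
    i, j = outer
    v = opt - (int(_PAIR_E2[codes[i], codes[j]]) * _NP_MOD - 1)
    a, b = i + 1, j - 1
    while True:
        if b - a + 1 >= _MIN_LOOP and v == _LOOP_E2 * _NP_MOD:
            return pairs, (a, b)
        found = False
        for k in range(a, b - _MIN_LOOP):
            lo = k + _MIN_LOOP + 1
            cand = A[k, lo : b + 1] + (np.int64(k - a) + (b - np.arange(lo, b + 1))) * _NP_MOD
            hits = np.nonzero(cand == v)[0]
            if hits.size:
                l = lo + int(hits[0])
                pairs.append((k, l))
                v = int(A[k, l]) - (int(_PAIR_E2[codes[k], codes[l]]) * _NP_MOD - 1)
                a, b = k + 1, l - 1
                found = True
                break
        if not found:  # pragma: no cover - internal consistency
            raise RuntimeError("traceback failed inside the stem")


def fold_best_hairpin(seq: str, blocked: Optional[Sequence[int]] = None) -> HairpinStructure:
    """Fold *seq* into its minimum-energy single stem-loop under SLF-1.

    Parameters
    ----------
    seq:
        DNA-alphabet sequence, 15-400 nt.
    blocked:
        Optional 1-based positions forced to stay unpaired (used e.g. to
        estimate the energy needed to open a target site).

    Returns the empty structure (``mfe == 0``) when no stem-loop has
    negative energy.
    """
    if not (MIN_FOLD_LEN <= len(seq) <= MAX_FOLD_LEN):
        raise ValueError(f"sequence length {len(seq)} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    check_alphabet(seq)
    codes = _encode_seq(seq)
    mask = None
    if blocked:
        mask = np.zeros(len(seq), dtype=bool)
        for p in blocked:
            if not 1 <= p <= len(seq):
                raise ValueError(f"blocked position {p} outside sequence")
            mask[p - 1] = True
    A, _B = _fill_tables(codes, mask)
    opt = int(A.min())
    e2, _npairs = _decode(opt) if opt < _INF else (0, 0)
    if opt >= _INF or e2 >= 0:
        return HairpinStructure(sequence=seq, pairs=[], mfe=0.0, loop_span=None)
    pairs0, loop0 = _traceback(codes, A, opt)
    pairs = [(i + 1, j + 1) for i, j in pairs0]
    return HairpinStructure(
        sequence=seq,
        pairs=pairs,
        mfe=e2 / 2.0,
        loop_span=(loop0[0] + 1, loop0[1] + 1),
    )


def dot_bracket(structure: HairpinStructure) -> str:
    out = ["."] * len(structure.sequence)
    for i, j in structure.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def compute_mfei(structure: HairpinStructure) -> tuple[float, float, float]:
    """Return (AMFE, GC%, MFEI) for a folded window.

    AMFE = -MFE / length x 100; MFEI = AMFE / GC%.  GC% is computed on the
    full window, on a 0-100 scale.
    """
    gcp = gc_percent(structure.sequence)
    if gcp == 0:
        raise ValueError("degenerate sequence: GC content is zero, MFEI undefined")
    amfe = -structure.mfe / len(structure.sequence) * 100.0
    return amfe, gcp, amfe / gcp


@dataclass
class FoldThresholds:
    """Criteria a candidate precursor window must satisfy."""

    max_mfe: float = -18.0
    min_mfei: float = 0.85
    max_duplex_unpaired: int = 4   # mature positions unpaired/mismatched vs the star arm
    max_asym_bulge: int = 2        # nt of asymmetry within the mature/star duplex


@dataclass
class PrecursorEvaluation:
    mfe: float
    amfe: float
    gc_percent: float
    mfei: float
    mature_on_one_arm: bool
    duplex_mismatches: int
    max_asym_bulge: int
    passes: bool
    n_supporting_libraries: int = 0
    mature_arm: Optional[str] = None           # "5p" | "3p"
    window: Optional[tuple[int, int]] = None   # genomic 1-based inclusive
    structure: Optional[HairpinStructure] = field(default=None, repr=False)


_WOBBLE_RC = {("G", "A"), ("T", "C")}  # wobble pairs in reverse-complement space


def _best_duplex(
    mature_start: int,
    mature_end: int,
    wseq: str,
    max_side_gaps: int = 2,
    min_loop_gap: int = 3,
) -> Optional[tuple[int, int, int, int, str]]:
    """Best mature/star duplex alignment within a precursor window.

    Aligns the mature (window positions ``mature_start..mature_end``,
    1-based) antiparallel against every candidate star segment elsewhere
    in the window, allowing up to ``max_side_gaps`` bulged nucleotides on
    each strand.  Following the usual plant miRNA duplex convention,
    every mismatched mature position and every bulged nucleotide (either
    strand) counts toward the unpaired tally; G:U wobbles count as
    paired.  The star segment must not overlap the mature and must leave
    >= ``min_loop_gap`` nt for a loop.

    Returns (n_unpaired, max_bulge, star_start, star_end, arm) for the
    best (fewest unpaired, then fewest bulges) alignment, or None.
    """
    m = mature_end - mature_start + 1
    mature = wseq[mature_start - 1 : mature_end]
    n = len(wseq)
    wrc = revcomp(wseq)
    G = max_side_gaps
    pad = wrc + "N" * (2 * G + 2)
    nS = n - m + 1 + G
    if nS <= 0:
        return None
    big = np.int64(1) << 30
    # cost = unpaired * 64 + gaps; states keyed by (gm, gw)
    codes = np.frombuffer(pad.encode(), dtype=np.uint8)
    mism = {}
    for base in "ACGT":
        row = np.ones(256, dtype=np.int64) * 64
        row[ord(base)] = 0
        for x, y in _WOBBLE_RC:
            if x == base:
                row[ord(y)] = 0
        row[ord("N")] = big
        mism[base] = row
    D = {(gm, gw): np.full(nS, big, dtype=np.int64) for gm in range(G + 1)
         for gw in range(G + 1)}
    D[(0, 0)][:] = 0
    s_idx = np.arange(nS)
    for i in range(1, m + 1):
        newD = {}
        for gm in range(G + 1):
            for gw in range(G + 1):
                off = (i - 1) - gm + gw
                col = mism[mature[i - 1]][codes[s_idx + off]]
                val = D[(gm, gw)] + col
                if gm >= 1:  # mature base bulged (unpaired, no star base)
                    val = np.minimum(val, D[(gm - 1, gw)] + 65)
                newD[(gm, gw)] = val
        for gm in range(G + 1):  # star-side bulge between mature positions
            for gw in range(1, G + 1):
                newD[(gm, gw)] = np.minimum(newD[(gm, gw)], newD[(gm, gw - 1)] + 65)
        D = newD
    best = None
    for (gm, gw), vals in D.items():
        star_len = m - gm + gw
        for s in np.nonzero(vals < big)[0]:
            s = int(s)
            b = n - s           # star 3' end in window coordinates
            a = b - star_len + 1
            if a < 1 or b > n:
                continue
            if not (b < mature_start - min_loop_gap or a > mature_end + min_loop_gap):
                continue
            cost = int(vals[s])
            unpaired, gaps = cost // 64, cost % 64
            key = (unpaired, gaps, a)
            if best is None or key < best[0]:
                arm = "3p" if a < mature_start else "5p"
                best = (key, (unpaired, max(gm, gw), a, b, arm))
    return best[1] if best else None


def _evaluate_window(
    wseq: str,
    mature_start: int,
    mature_end: int,
    thresholds: FoldThresholds,
    folder: Callable[[str], HairpinStructure],
) -> PrecursorEvaluation:
    structure = folder(wseq)
    if structure.pairs:
        amfe, gcp, mfei = compute_mfei(structure)
    else:
        amfe, gcp, mfei = 0.0, gc_percent(wseq), 0.0
    duplex = _best_duplex(mature_start, mature_end, wseq)
    if duplex is None:
        duplex_mm, max_asym, arm = mature_end - mature_start + 1, 0, None
        duplex_ok = False
    else:
        duplex_mm, max_asym, _a, _b, arm = duplex
        duplex_ok = duplex_mm <= thresholds.max_duplex_unpaired
    passes = (
        duplex_ok
        and max_asym <= thresholds.max_asym_bulge
        and structure.mfe <= thresholds.max_mfe
        and mfei >= thresholds.min_mfei
    )
    return PrecursorEvaluation(
        mfe=structure.mfe, amfe=amfe, gc_percent=gcp, mfei=mfei,
        mature_on_one_arm=duplex_ok, duplex_mismatches=duplex_mm,
        max_asym_bulge=max_asym, passes=passes, mature_arm=arm, structure=structure,
    )


def evaluate_precursor(
    genome: Mapping[str, str],
    tag_locus,
    tag_seq: str,
    flank: int = 120,
    thresholds: Optional[FoldThresholds] = None,
    folder: Callable[[str], HairpinStructure] = fold_best_hairpin,
) -> PrecursorEvaluation:
    """Fold candidate precursor windows around a genome-mapped tag.

    Three windows are tried (the tag centred; the tag at the window 5' end
    with 2 x *flank* downstream; the tag at the 3' end with 2 x *flank*
    upstream), since a mature miRNA may come from either hairpin arm.  The
    best passing window is kept (lowest model MFE); if none passes, the
    window with the highest MFEI is reported with its failing flags.

    Energy statistics (MFE, AMFE, MFEI) come from the window's global
    fold; the duplex criteria (mature positions unpaired against the star
    arm, bulge asymmetry, arm assignment) are judged on the best direct
    mature/star duplex alignment within the window, which is robust to
    the global fold absorbing the mature into long bulged flank stems.
    """
    thresholds = thresholds or FoldThresholds()
    chrom = genome[tag_locus.chrom]
    L = len(chrom)
    s, e = tag_locus.start, tag_locus.end
    windows = [(s - flank, e + flank), (s, e + 2 * flank), (s - 2 * flank, e)]
    seen: set[tuple[int, int]] = set()
    evals: list[PrecursorEvaluation] = []
    for ws, we in windows:
        ws, we = max(1, ws), min(L, we)
        if (ws, we) in seen or we - ws + 1 < MIN_FOLD_LEN:
            continue
        seen.add((ws, we))
        wseq = chrom[ws - 1 : we]
        if tag_locus.strand == "-":
            wseq = revcomp(wseq)
            m0 = we - e + 1
        else:
            m0 = s - ws + 1
        m1 = m0 + len(tag_seq) - 1
        if wseq[m0 - 1 : m1] != tag_seq:
            raise ValueError("tag sequence does not match the genome at its locus")
        ev = _evaluate_window(wseq, m0, m1, thresholds, folder)
        ev.window = (ws, we)
        evals.append(ev)
    if not evals:
        raise ValueError("no foldable window around locus")
    passing = [ev for ev in evals if ev.passes]
    if passing:
        return min(passing, key=lambda ev: ev.mfe)
    return max(evals, key=lambda ev: ev.mfei)
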