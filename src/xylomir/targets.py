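"""miRNA target-site scanning on a transcriptome under two complementarity
penalty schemes, plus their intersection and a site-openness energy proxy.

Both schemes score the antiparallel duplex between a miRNA (5'->3') and a
transcript window (the miRNA 5' end pairs the window 3' end):

* scheme A ("expectation"): mismatch 1.0, G:U wobble 0.5, gap 2.0, doubled
  over the seed region (miRNA positions 2-13); up to ``max_gaps``
  transcript-side insertions (extra target nucleotides), never opposite
  miRNA positions 10-11; sites reported at expectation <= cutoff (5.0).
* scheme B ("penalty"): gapless; mismatch 1.0, G:U 0.5, doubled over
  miRNA positions 2-17; sites reported at penalty <= cutoff (2.5).

Pairing strings use one character per alignment column, miRNA 5'->3':
``|`` Watson-Crick pair, ``o`` G:U wobble, ``.`` mismatch, ``-`` an extra
(unpaired) target nucleotide.  A ``-`` column is charged the gap weight at
the next miRNA position and does not advance the miRNA position counter,
so the expectation is exactly recomputable from the pairing string alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._seq import check_alphabet, revcomp
from .fold import MIN_FOLD_LEN, fold_best_hairpin

__all__ = [
    "TargetAlignment",
    "ConsensusTarget",
    "expectation_score",
    "scan_transcript_A",
    "penalty_score_B",
    "intersect_predictions",
    "upe_proxy",
    "scan_transcriptome",
    "transcript_gene",
]

_SEED_A = (2, 13)
_CORE_B = (2, 17)
_NO_GAP_POSITIONS = (10, 11)

_CODE_TBL = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _CODE_TBL[ord(_c)] = _i


def _codes(seq: str) -> np.ndarray:
    return _CODE_TBL[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _symbol(mirna_base: str, rc_base: str) -> str:
    """Pairing symbol given the miRNA base and the reverse-complemented
    target base (so a Watson-Crick pair is letter equality)."""
    if mirna_base == rc_base:
        return "|"
    if (mirna_base, rc_base) in (("G", "A"), ("T", "C")):
        return "o"
    return "."


@dataclass
class TargetAlignment:
    mirna: str                 # miRNA identifier
    transcript_id: str
    site_start: int            # 1-based inclusive on the transcript, 5'->3'
    site_end: int
    pairing: str               # per alignment column, miRNA 5'->3'
    expectation: float
    penalty_b: Optional[float] = None
    inhibition: str = "Cleavage"   # "Cleavage" | "Translation"
    upe_proxy: Optional[float] = None
    mirna_seq: str = ""

    @property
    def n_gaps(self) -> int:
        return self.pairing.count("-")


def expectation_score(
    pairing: str,
    seed_range: tuple[int, int] = _SEED_A,
    seed_factor: float = 2.0,
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Scheme-A expectation of a pairing string (lower = better match)."""
    w = {"mismatch": 1.0, "gu": 0.5, "gap": 2.0}
    if weights:
        w.update(weights)
    total = 0.0
    pos = 1
    for ch in pairing:
        if ch == "-":
            use_pos = pos  # the next miRNA position; the counter does not advance
            step = w["gap"]
        elif ch == ".":
            use_pos, step = pos, w["mismatch"]
            pos += 1
        elif ch == "o":
            use_pos, step = pos, w["gu"]
            pos += 1
        elif ch == "|":
            use_pos, step = pos, 0.0
            pos += 1
        else:
            raise ValueError(f"unknown pairing symbol {ch!r}")
        if seed_range[0] <= use_pos <= seed_range[1]:
            step *= seed_factor
        total += step
    return total


def _weight_rows(mirna: str, seed_range: tuple[int, int], half_units: bool,
                 mismatch: int, gu: int) -> np.ndarray:
    """Per-miRNA-position cost of each rc-target base code (0..4).

    Costs are in integer half-units; code 4 (N / out of transcript) is a
    large sentinel so sites never run off the transcript end.
    """
    m = len(mirna)
    big = 1 << 30
    W = np.zeros((m, 5), dtype=np.int64)
    for i, base in enumerate(mirna, start=1):
        factor = 2 if seed_range[0] <= i <= seed_range[1] else 1
        for code, rc_base in enumerate("ACGT"):
            sym = _symbol(base, rc_base)
            cost = 0 if sym == "|" else (gu if sym == "o" else mismatch)
            W[i - 1, code] = cost * factor
        W[i - 1, 4] = big
    return W


def scan_transcript_A(
    mirna: str,
    transcript: str,
    cutoff: float = 5.0,
    max_gaps: int = 2,
    mirna_id: str = "",
    transcript_id: str = "",
) -> list[TargetAlignment]:
    """Scheme-A scan: minimum-expectation gapped alignment at every window.

    All non-overlapping sites with expectation <= cutoff are returned,
    best first (ties toward smaller site_start).
    """
    check_alphabet(mirna, "miRNA")
    check_alphabet(transcript, "transcript")
    m, L = len(mirna), len(transcript)
    if L < m:
        raise ValueError("transcript shorter than miRNA")
    rc = revcomp(transcript)
    rc_codes = np.concatenate([_codes(rc), np.full(max_gaps, 4, dtype=np.int64)])
    W = _weight_rows(mirna, _SEED_A, True, mismatch=2, gu=1)
    gapw = np.array(
        [4 * (2 if _SEED_A[0] <= p <= _SEED_A[1] else 1) for p in range(0, m + 2)],
        dtype=np.int64,
    )  # indexed by the gap column's miRNA position
    nS = L - m + 1
    big = np.int64(1) << 40
    D = [np.full(nS, big, dtype=np.int64) for _ in range(max_gaps + 1)]
    D[0][:] = 0
    for i in range(1, m + 1):
        newD = []
        for g in range(max_gaps + 1):
            off = i - 1 + g
            newD.append(D[g] + W[i - 1][rc_codes[off : off + nS]])
        # transcript insertion after consuming i miRNA bases: next position i+1
        if i < m and (i + 1) not in _NO_GAP_POSITIONS:
            for g in range(1, max_gaps + 1):
                off = i + g - 1
                cand = newD[g - 1] + gapw[i + 1]
                newD[g] = np.minimum(newD[g], cand)
        D = newD
    stacked = np.stack(D)                       # (g, s)
    best_g = np.argmin(stacked, axis=0)
    best = stacked[best_g, np.arange(nS)]
    cut2 = int(round(cutoff * 2))
    hits = np.nonzero(best <= cut2)[0]
    # best-first, ties toward smaller site_start (site_start falls with s)
    candidates = sorted(
        ((int(best[s]), -int(s), int(s), int(best_g[s])) for s in hits)
    )
    taken: list[tuple[int, int]] = []
    out: list[TargetAlignment] = []
    for score2, _negs, s, g in candidates:
        site_end = L - s
        site_start = L - s - (m + g) + 1
        if any(not (site_end < a or site_start > b) for a, b in taken):
            continue
        taken.append((site_start, site_end))
        pairing = _traceback_A(mirna, rc, s, g, int(score2), W, gapw, max_gaps)
        out.append(_make_alignment(mirna, pairing, site_start, site_end,
                                   score2 / 2.0, mirna_id, transcript_id))
    return out


def _traceback_A(mirna: str, rc: str, s: int, g_final: int, score2: int,
                 W: np.ndarray, gapw: np.ndarray, max_gaps: int) -> str:
    """Scalar re-run of the window DP to recover the column string."""
    m = len(mirna)
    big = 1 << 40
    D = [[big] * (max_gaps + 1) for _ in range(m + 1)]
    D[0][0] = 0
    for i in range(1, m + 1):
        for g in range(max_gaps + 1):
            off = s + i - 1 + g
            c = _CODE_TBL[ord(rc[off])] if off < len(rc) else 4
            if D[i - 1][g] < big:
                D[i][g] = D[i - 1][g] + int(W[i - 1][c])
        if i < m and (i + 1) not in _NO_GAP_POSITIONS:
            for g in range(1, max_gaps + 1):
                cand = D[i][g - 1] + int(gapw[i + 1])
                if cand < D[i][g]:
                    D[i][g] = cand
    # walk back from (m, g_final)
    cols: list[str] = []
    i, g = m, g_final
    while i > 0 or g > 0:
        if i > 0 and g >= 0:
            off = s + i - 1 + g
            c = _CODE_TBL[ord(rc[off])] if off < len(rc) else 4
            came_diag = D[i - 1][g] < big and D[i][g] == D[i - 1][g] + int(W[i - 1][c])
        else:
            came_diag = False
        came_gap = (
            g > 0 and i < m and (i + 1) not in _NO_GAP_POSITIONS
            and D[i][g] == D[i][g - 1] + int(gapw[i + 1])
        )
        if came_gap and not came_diag:
            cols.append("-")
            g -= 1
        elif came_diag:
            off = s + i - 1 + g
            cols.append(_symbol(mirna[i - 1], rc[off]))
            i -= 1
        elif came_gap:
            cols.append("-")
            g -= 1
        else:  # pragma: no cover - internal consistency
            raise RuntimeError("scheme-A traceback failed")
    return "".join(reversed(cols))


def _make_alignment(mirna: str, pairing: str, site_start: int, site_end: int,
                    expectation: float, mirna_id: str, transcript_id: str,
                    penalty_b: Optional[float] = None) -> TargetAlignment:
    # inhibition: cleavage needs miRNA positions 9-11 perfectly paired
    pos = 0
    core = {}
    for ch in pairing:
        if ch != "-":
            pos += 1
            if 9 <= pos <= 11:
                core[pos] = ch
    cleavage = all(core.get(p) == "|" for p in (9, 10, 11))
    return TargetAlignment(
        mirna=mirna_id or mirna,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_end,
        pairing=pairing,
        expectation=expectation,
        penalty_b=penalty_b,
        inhibition="Cleavage" if cleavage else "Translation",
        mirna_seq=mirna,
    )


def penalty_score_B(
    mirna: str,
    transcript: str,
    cutoff: float = 2.5,
    mirna_id: str = "",
    transcript_id: str = "",
) -> list[TargetAlignment]:
    """Scheme-B scan: gapless penalty (mismatch 1, G:U 0.5, doubled over
    miRNA positions 2-17); every window with penalty <= cutoff is reported."""
    check_alphabet(mirna, "miRNA")
    check_alphabet(transcript, "transcript")
    m, L = len(mirna), len(transcript)
    if L < m:
        raise ValueError("transcript shorter than miRNA")
    rc = revcomp(transcript)
    rc_codes = _codes(rc)
    W = _weight_rows(mirna, _CORE_B, True, mismatch=2, gu=1)
    nS = L - m + 1
    acc = np.zeros(nS, dtype=np.int64)
    for i in range(m):
        acc += W[i][rc_codes[i : i + nS]]
    cut2 = int(round(cutoff * 2))
    out = []
    for s in np.nonzero(acc <= cut2)[0]:
        s = int(s)
        pairing = "".join(_symbol(mirna[i], rc[s + i]) for i in range(m))
        site_end = L - s
        site_start = site_end - m + 1
        aln = _make_alignment(mirna, pairing, site_start, site_end,
                              expectation_score(pairing), mirna_id, transcript_id,
                              penalty_b=float(acc[s]) / 2.0)
        out.append(aln)
    out.sort(key=lambda a: (a.penalty_b, a.site_start))
    return out


@dataclass
class ConsensusTarget:
    mirna: str
    transcript_id: str
    gene: Optional[str]
    site_start: int
    site_end: int
    expectation: float
    penalty_b: float
    inhibition: str
    pairing: str
    mirna_seq: str = ""


_GENE_SUFFIX = re.compile(r"_T\d+$")


def transcript_gene(transcript_id: str, gene_map: Optional[Mapping[str, str]] = None) -> Optional[str]:
    if gene_map is not None:
        return gene_map.get(transcript_id)
    if _GENE_SUFFIX.search(transcript_id):
        return _GENE_SUFFIX.sub("", transcript_id)
    return None


def _overlap_frac(a: TargetAlignment, b: TargetAlignment) -> float:
    inter = min(a.site_end, b.site_end) - max(a.site_start, b.site_start) + 1
    if inter <= 0:
        return 0.0
    shorter = min(a.site_end - a.site_start, b.site_end - b.site_start) + 1
    return inter / shorter


def intersect_predictions(
    hits_a: Iterable[TargetAlignment],
    hits_b: Iterable[TargetAlignment],
    gene_map: Optional[Mapping[str, str]] = None,
    min_overlap: float = 0.5,
) -> list[ConsensusTarget]:
    """Keep (miRNA, transcript) pairs found by both schemes with >= 50%
    site overlap; the consensus record carries both scores (scheme A's
    site coordinates are used)."""
    by_pair_b: dict[tuple[str, str], list[TargetAlignment]] = {}
    for h in hits_b:
        by_pair_b.setdefault((h.mirna, h.transcript_id), []).append(h)
    out: list[ConsensusTarget] = []
    seen: set[tuple[str, str, int]] = set()
    for ha in hits_a:
        partners = by_pair_b.get((ha.mirna, ha.transcript_id), [])
        best = None
        for hb in partners:
            if _overlap_frac(ha, hb) >= min_overlap:
                if best is None or hb.penalty_b < best.penalty_b:
                    best = hb
        if best is None:
            continue
        key = (ha.mirna, ha.transcript_id, ha.site_start)
        if key in seen:
            continue
        seen.add(key)
        out.append(ConsensusTarget(
            mirna=ha.mirna,
            transcript_id=ha.transcript_id,
            gene=transcript_gene(ha.transcript_id, gene_map),
            site_start=ha.site_start,
            site_end=ha.site_end,
            expectation=ha.expectation,
            penalty_b=best.penalty_b,
            inhibition=ha.inhibition,
            pairing=ha.pairing,
            mirna_seq=ha.mirna_seq,
        ))
    out.sort(key=lambda c: (c.mirna, c.transcript_id, c.site_start))
    return out


def upe_proxy(transcript: str, site: tuple[int, int], flank: int = 17) -> Optional[float]:
    """Model-energy cost of forcing the site single-stranded.

    Folds the site +/- *flank* window twice (free, and with the site
    blocked from pairing) and returns the non-negative energy difference.
    Returns None when the window is shorter than the foldable minimum.
    """
    start, end = site
    if not (1 <= start <= end <= len(transcript)):
        raise ValueError("site outside transcript")
    ws = max(1, start - flank)
    we = min(len(transcript), end + flank)
    if we - ws + 1 < MIN_FOLD_LEN:
        return None
    window = transcript[ws - 1 : we]
    blocked = list(range(start - ws + 1, end - ws + 2))
    free = fold_best_hairpin(window).mfe
    opened = fold_best_hairpin(window, blocked=blocked).mfe
    return max(0.0, opened - free)


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff_a: float = 5.0,
    max_gaps: int = 2,
    cutoff_b: float = 2.5,
) -> tuple[list[TargetAlignment], list[TargetAlignment]]:
    """Run both schemes for every miRNA against every transcript."""
    hits_a: list[TargetAlignment] = []
    hits_b: list[TargetAlignment] = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            if len(tseq) < len(mseq):
                continue
            hits_a.extend(scan_transcript_A(mseq, tseq, cutoff_a, max_gaps, mid, tid))
            hits_b.extend(penalty_score_B(mseq, tseq, cutoff_b, mid, tid))
    return hits_a, hits_b
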