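"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition by direct
enumeration or direct recursion, sharing no code with the implementation
paths they check.
"""

from __future__ import annotations

from math import comb

import numpy as np

PAIR_ENERGY = {("A", "T"): -2.0, ("T", "A"): -2.0, ("G", "C"): -3.0,
               ("C", "G"): -3.0, ("G", "T"): -1.0, ("T", "G"): -1.0}


def fold_mfe_oracle(seq: str) -> float:
    """Minimum single stem-loop energy by direct recursion over the
    definition: H(i,j) = E(i,j) + min(loop, min over inner pairs of
    H(k,l) + 0.5 per skipped nucleotide); O(n^4), vectorized inner min."""
    n = len(seq)
    INF = 1e18
    H = np.full((n, n), INF)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            e = PAIR_ENERGY.get((seq[i], seq[j]))
            if e is None:
                continue
            best = 3.0 if j - i - 1 >= 3 else INF
            sub = H[i + 1 : j, i + 1 : j]
            if sub.size:
                row_w = 0.5 * np.arange(sub.shape[0])[:, None]
                col_w = 0.5 * (np.arange(sub.shape[1])[::-1])[None, :]
                best = min(best, float((sub + row_w + col_w).min()))
            H[i, j] = e + best
    m = float(H.min())
    return min(0.0, m if m < INF else 0.0)


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _col_weight(mirna_base: str, target_base: str) -> float:
    """Scheme-A column weight (before seed doubling) of pairing a miRNA
    base against an actual transcript base."""
    if target_base == _COMP[mirna_base]:
        return 0.0
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return 0.5
    return 1.0


def expectation_min_oracle(mirna: str, window: str, max_gaps: int = 2) -> float:
    """Minimum scheme-A expectation over every placement and every
    gapped alignment (transcript insertions only, none opposite miRNA
    positions 10-11), by exhaustive enumeration of insertion patterns."""
    m = len(mirna)
    L = len(window)
    best = float("inf")
    # enumerate multisets of insertion next-positions (2..m, not 10/11)
    allowed = [p for p in range(2, m + 1) if p not in (10, 11)]
    patterns: list[tuple[int, ...]] = [()]
    if max_gaps >= 1:
        patterns += [(p,) for p in allowed]
    if max_gaps >= 2:
        patterns += [(p, q) for p in allowed for q in allowed if p <= q]
    for pattern in patterns:
        g = len(pattern)
        site_len = m + g
        if site_len > L:
            continue
        for start in range(0, L - site_len + 1):
            site = window[start : start + site_len]
            # walk columns: miRNA pos 1 pairs the site's last base
            t_idx = site_len - 1
            score = 0.0
            for pos in range(1, m + 1):
                for _ in range(pattern.count(pos)):
                    score += 2.0 * (2.0 if 2 <= pos <= 13 else 1.0)
                    t_idx -= 1
                w = _col_weight(mirna[pos - 1], site[t_idx])
                if 2 <= pos <= 13:
                    w *= 2.0
                score += w
                t_idx -= 1
            best = min(best, score)
    return best


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration over all tables
    with the observed margins (sum of probabilities <= observed)."""
    n1, n2, c1 = a + b, c + d, a + c
    if n1 + n2 == 0 or n1 == 0 or n2 == 0 or c1 == 0 or c1 == n1 + n2:
        return 1.0
    lo, hi = max(0, c1 - n2), min(n1, c1)
    nums = {x: comb(n1, x) * comb(n2, c1 - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    total = sum(v for v in nums.values() if v <= obs)
    return total / comb(n1 + n2, c1)


def genome_scan_oracle(query: str, genome: dict[str, str]) -> list[tuple[str, int]]:
    """All (chrom, 1-based start) occurrences of query on the forward
    strand, by naive position-by-position comparison."""
    out = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        for i in range(len(seq) - len(query) + 1):
            if seq[i : i + len(query)] == query:
                out.append((chrom, i + 1))
    return out
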