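"""Per-tag differential expression between single sRNA libraries.

With one library per condition there are no replicates, so expression
differences are tested on the raw-count 2x2 table

    [[count_a, total_a - count_a],
     [count_b, total_b - count_b]]

with Fisher's exact test, or the Pearson chi-squared test when all
expected counts are >= 5.  Fold changes are computed on library-size
normalized counts (reads per `scale`, default per million).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "DEResult",
    "DEThresholds",
    "normalize_counts",
    "fisher_exact_2x2",
    "chisq_2x2",
    "pairwise_de",
    "classify_regulation",
    "log2_fold_change",
]


@dataclass
class DEThresholds:
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    pseudocount: float = 0.5       # applied only when one side is zero
    min_expected_for_chisq: float = 5.0
    method: str = "auto"           # "auto" | "fisher" | "chisq"


@dataclass
class DEResult:
    name: str
    comparison: tuple[str, str]
    norm_a: float
    norm_b: float
    log2fc: float
    p_value: float
    method: str
    status: str  # "up" | "down" | "none"


def normalize_counts(raw: Mapping[str, float] | float, lib_totals: Mapping[str, float] | float,
                     scale: float = 1e6):
    """Scale raw counts to reads-per-*scale* of the library total.

    Accepts either a scalar (raw, total) pair or per-library mappings with
    matching keys.
    """
    if isinstance(raw, (int, float)):
        if lib_totals <= 0:
            raise ValueError("library total must be positive")
        return raw * scale / lib_totals
    out = {}
    for lib, count in raw.items():
        total = lib_totals[lib]
        if total <= 0:
            raise ValueError(f"library total for {lib!r} must be positive")
        out[lib] = count * scale / total
    return out


def _hypergeom_logpmf_support(n1: int, n2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-pmf of table cell a over its support, for fixed margins."""
    lo = max(0, c1 - n2)
    hi = min(n1, c1)
    a = np.arange(lo, hi + 1)
    lg = (
        gammaln(n1 + 1) - gammaln(a + 1) - gammaln(n1 - a + 1)
        + gammaln(n2 + 1) - gammaln(c1 - a + 1) - gammaln(n2 - (c1 - a) + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(c1 + 1) - gammaln(n1 + n2 - c1 + 1))
    )
    return a, lg


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one.  Computed
    in log space; the all-zero table returns 1.0 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2, c1 = a + b, c + d, a + c
    if n1 + n2 == 0:
        return 1.0
    if n1 == 0 or n2 == 0 or c1 == 0 or c1 == n1 + n2:
        return 1.0  # a margin is zero: only one table possible
    support, lg = _hypergeom_logpmf_support(n1, n2, c1)
    obs = lg[np.searchsorted(support, a)]
    # relative tolerance guards against log-space rounding at ties
    p = float(np.exp(lg[lg <= obs + 1e-7]).sum())
    return min(1.0, p)


def chisq_2x2(a: float, b: float, c: float, d: float, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test (1 df) for [[a, b], [c, d]].

    Returns (statistic, p).  No continuity correction by default; set
    ``yates=True`` for the corrected statistic.  Raises if any expected
    count is zero.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty table")
    exp = np.outer(rows, cols) / n
    if np.any(exp == 0):
        raise ValueError("expected count of zero; chi-squared undefined")
    diff = np.abs(obs - exp)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / exp).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def log2_fold_change(norm_a: float, norm_b: float, pseudocount: float = 0.5) -> float:
    """log2(b/a) on normalized counts; pseudocount only when a side is zero."""
    if norm_a < 0 or norm_b < 0:
        raise ValueError("negative normalized count")
    xa = norm_a if norm_a > 0 else pseudocount
    xb = norm_b if norm_b > 0 else pseudocount
    return math.log2(xb / xa)


def pairwise_de(
    counts: Mapping[str, Mapping[str, int]],
    lib_a: str,
    lib_b: str,
    lib_totals: Mapping[str, int],
    thresholds: Optional[DEThresholds] = None,
    scale: float = 1e6,
) -> list[DEResult]:
    """Test every tag for differential expression between *lib_a* and *lib_b*.

    ``counts`` maps tag name -> per-library raw counts.  The test runs on
    raw counts against library totals; the fold change on normalized
    counts.  Method selection (``auto``): chi-squared when all four
    expected counts are >= 5, Fisher otherwise.
    """
    th = thresholds or DEThresholds()
    for lib in (lib_a, lib_b):
        if lib not in lib_totals:
            raise KeyError(f"unknown library id {lib!r}")
    ta, tb = lib_totals[lib_a], lib_totals[lib_b]
    results = []
    for name, per_lib in counts.items():
        ca = int(per_lib.get(lib_a, 0))
        cb = int(per_lib.get(lib_b, 0))
        table = (ca, ta - ca, cb, tb - cb)
        if th.method == "fisher":
            method = "fisher"
        elif th.method == "chisq":
            method = "chisq"
        else:
            n = ta + tb
            rows = (ta, tb)
            cols = (ca + cb, n - ca - cb)
            exp_min = min(r * c / n for r in rows for c in cols)
            method = "chisq" if exp_min >= th.min_expected_for_chisq else "fisher"
        if method == "chisq":
            _stat, p = chisq_2x2(*table)
        else:
            p = fisher_exact_2x2(*table)
        na = normalize_counts(ca, ta, scale)
        nb = normalize_counts(cb, tb, scale)
        lfc = log2_fold_change(na, nb, th.pseudocount)
        if p <= th.alpha and lfc >= th.min_abs_log2fc:
            status = "up"
        elif p <= th.alpha and lfc <= -th.min_abs_log2fc:
            status = "down"
        else:
            status = "none"
        results.append(DEResult(name, (lib_a, lib_b), na, nb, lfc, p, method, status))
    return results


def _base_name(name: str) -> str:
    """Collapse locus-duplicated records to one miRNA name."""
    return name


def classify_regulation(results: Iterable[DEResult]) -> tuple[list[str], list[str]]:
    """Partition one comparison's results into (up, down) miRNA name lists.

    A miRNA reported at several genomic loci counts once.
    """
    up: list[str] = []
    down: list[str] = []
    seen_up: set[str] = set()
    seen_down: set[str] = set()
    for r in results:
        key = _base_name(r.name)
        if r.status == "up" and key not in seen_up:
            seen_up.add(key)
            up.append(key)
        elif r.status == "down" and key not in seen_down:
            seen_down.add(key)
            down.append(key)
    return up, down
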