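"""Degradome (PARE) cleavage-evidence scoring for predicted target sites.

A miRNA-guided cleavage leaves the 3' fragment's uncapped 5' end at the
transcript position pairing miRNA position 10.  Degradome libraries are
per-position 5'-end tag counts; each predicted site is assigned the
standard five-tier T-plot category in each library:

* 0 - the site count is the unique transcript maximum
* 1 - equal to the maximum, but the maximum is shared
* 2 - below the maximum but above the median of occupied positions
* 3 - at or below that median
* 4 - a single tag (raw count 1)
* none - no tag at the site

``deg_count`` is the number of libraries supporting the site at category
<= ``category_max`` (default 2), mirroring the "Deg" dataset-support
statistic of degradome-backed target tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Optional

from .targets import TargetAlignment

__all__ = [
    "DegradomeSupport",
    "expected_cleavage_pos",
    "site_category",
    "support_count",
]

# degradome libraries: library_id -> transcript_id -> {position: count}
DegradomeLibraries = Mapping[str, Mapping[str, Mapping[int, int]]]


@dataclass
class DegradomeSupport:
    mirna: str
    transcript_id: str
    cleavage_pos: int
    per_library: dict[str, tuple[int, Optional[int]]] = field(default_factory=dict)
    deg_count: int = 0

    @property
    def confirmed(self) -> bool:
        return self.deg_count >= 1


def expected_cleavage_pos(site: TargetAlignment) -> int:
    """Transcript position pairing miRNA position 10, by walking the
    pairing columns from ``site_end`` (miRNA position 1) toward 5'.

    Gap columns opposite positions 10-11 make the cleavage position
    undefined and raise.
    """
    t = site.site_end
    pos = 0
    for ch in site.pairing:
        if ch == "-":
            # gap column's miRNA position is the next consumed position
            if pos + 1 in (10, 11):
                raise ValueError("gap opposite miRNA positions 10-11: cleavage undefined")
            t -= 1
            continue
        pos += 1
        if pos == 10:
            return t
        t -= 1
    raise ValueError("miRNA shorter than 10 positions: no cleavage position")


def site_category(tag_counts: Mapping[int, int], pos: int) -> Optional[int]:
    """Five-tier T-plot category of *pos* in one transcript+library count
    profile; None when no tag starts at *pos*."""
    if not tag_counts:
        raise ValueError("empty degradome profile")
    count = tag_counts.get(pos, 0)
    if count == 0:
        return None
    if count == 1:
        return 4
    occupied = [c for c in tag_counts.values() if c > 0]
    peak = max(occupied)
    if count == peak:
        return 0 if sum(1 for c in occupied if c == peak) == 1 else 1
    return 2 if count > median(occupied) else 3


def support_count(
    site: TargetAlignment,
    libraries: DegradomeLibraries,
    category_max: int = 2,
    pos_tolerance: int = 1,
) -> DegradomeSupport:
    """Count how many degradome libraries support a predicted site.

    Each library is queried at the expected cleavage position +/-
    ``pos_tolerance`` (the best category at any queried position wins);
    a library supports the site when that category is <= ``category_max``.
    A library without the transcript contributes None.
    """
    pos = expected_cleavage_pos(site)
    support = DegradomeSupport(mirna=site.mirna, transcript_id=site.transcript_id,
                               cleavage_pos=pos)
    for lib_id, profiles in libraries.items():
        profile = profiles.get(site.transcript_id)
        if not profile:
            support.per_library[lib_id] = (0, None)
            continue
        best_cat: Optional[int] = None
        best_count = 0
        for p in range(pos - pos_tolerance, pos + pos_tolerance + 1):
            cat = site_category(profile, p)
            if cat is not None and (best_cat is None or cat < best_cat):
                best_cat, best_count = cat, profile.get(p, 0)
        support.per_library[lib_id] = (best_count, best_cat)
        if best_cat is not None and best_cat <= category_max:
            support.deg_count += 1
    return support
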