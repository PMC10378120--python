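"""QTN cluster calling: the 0.5 Mb sliding-window hotspot rule.

A QTN cluster is a region where at least three same-trait QTNs fall inside a
0.5 Mb sliding window.  Windows are anchored at QTN positions: for each QTN
at position ``p`` the full-width window ``[p, p + window)`` qualifies iff it
contains ≥ ``min_count`` same-trait QTNs.  Overlapping qualifying windows are
merged, and each merged extent becomes one cluster whose members are all the
same-trait QTNs inside it.  Because every qualifying window has full width,
no cluster can be narrower than the window — reproducing the reported 0.5 Mb
floor on cluster widths.

A continuous-sliding variant (window start ranging over every base) is
available for sensitivity checks; it generically produces wider extents
because windows reaching backwards past the first member also qualify.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from typing import Literal, Sequence

from .core import (
    ConfigError,
    GenomicInterval,
    QtnCluster,
    QtnRecord,
    chrom_sort_key,
    merge_overlapping,
)

__all__ = ["qualifying_windows", "call_qtn_clusters"]

WINDOW_BP_DEFAULT = 500_000


def _check_params(window_bp: int, min_count: int) -> None:
    if window_bp <= 0:
        raise ConfigError(f"window_bp must be positive, got {window_bp}")
    if min_count < 1:
        raise ConfigError(f"min_count must be ≥1, got {min_count}")


def qualifying_windows(
    qtns: Sequence[QtnRecord],
    window_bp: int = WINDOW_BP_DEFAULT,
    min_count: int = 3,
) -> list[GenomicInterval]:
    """Anchored windows holding ≥ min_count QTNs, for one (trait, chrom) group.

    For each QTN position ``p`` the window ``[p, p + window_bp)`` is emitted
    iff it contains at least ``min_count`` positions (``p ≤ q < p + window``).
    QTNs at identical positions count separately (they are distinct pieces of
    association evidence); deduplication by position is the caller's flag.
    """
    _check_params(window_bp, min_count)
    keys = {(q.trait, q.chrom) for q in qtns}
    if len(keys) > 1:
        raise ValueError(f"QTNs span several (trait, chrom) groups: {sorted(keys)}")
    positions = sorted(q.pos_bp for q in qtns)
    out = []
    for p in sorted(set(positions)):
        n_inside = bisect_left(positions, p + window_bp) - bisect_left(positions, p)
        if n_inside >= min_count:
            out.append(GenomicInterval(qtns[0].chrom, p, p + window_bp))
    return out


def _continuous_extents(
    positions: list[int], chrom: str, window_bp: int, min_count: int
) -> list[GenomicInterval]:
    """Union of [w, w+window) over every integer window start w whose window
    holds ≥ min_count positions (the continuous-sliding variant)."""
    extents = []
    n = len(positions)
    for i in range(n - min_count + 1):
        j = i + min_count - 1
        if positions[j] - positions[i] < window_bp:
            # qualifying starts w ∈ [positions[j] - window + 1, positions[i]]
            w_lo = max(0, positions[j] - window_bp + 1)
            extents.append(GenomicInterval(chrom, w_lo, positions[i] + window_bp))
    return merge_overlapping(extents)


def call_qtn_clusters(
    qtns: Sequence[QtnRecord],
    window_bp: int = WINDOW_BP_DEFAULT,
    min_count: int = 3,
    dedup_pos: bool = False,
    window_mode: Literal["anchored", "continuous"] = "anchored",
) -> list[QtnCluster]:
    """Call QTN clusters per (trait, chromosome).

    ``dedup_pos`` collapses QTNs at identical (study-independent) positions
    to one before counting.  Output clusters are pairwise disjoint within a
    (trait, chromosome) group and sorted by chromosome then start.
    """
    _check_params(window_bp, min_count)
    groups: dict[tuple[str, str], list[QtnRecord]] = defaultdict(list)
    for q in qtns:
        groups[(q.trait, q.chrom)].append(q)

    results = []
    for (trait, chrom), group in sorted(groups.items()):
        counted = group
        if dedup_pos:
            seen: set[int] = set()
            counted = [
                q for q in group if not (q.pos_bp in seen or seen.add(q.pos_bp))
            ]
        if window_mode == "anchored":
            extents = merge_overlapping(
                qualifying_windows(counted, window_bp, min_count)
            )
        elif window_mode == "continuous":
            extents = _continuous_extents(
                sorted(q.pos_bp for q in counted), chrom, window_bp, min_count
            )
        else:
            raise ConfigError(f"unknown window_mode {window_mode!r}")
        for extent in extents:
            members = [q for q in group if extent.contains_point(q.pos_bp)]
            results.append((trait, extent, members))

    results.sort(key=lambda r: (chrom_sort_key(r[1].chrom), r[1].start_bp, r[0]))
    clusters = []
    for i, (trait, extent, members) in enumerate(results, start=1):
        clusters.append(
            QtnCluster(
                cluster_id=f"QTNC{i:03d}",
                trait=trait,
                chrom=extent.chrom,
                interval=extent,
                member_ids=frozenset(q.record_id for q in members),
            )
        )
    return clusters
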