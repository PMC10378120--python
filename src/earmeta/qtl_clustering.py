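"""QTL cluster calling: distinct-study support with a span-dependent threshold.

A QTL cluster is a region where overlapping same-trait QTL intervals are
contributed by at least three distinct studies; because very long intervals
chain easily, a cluster whose span exceeds 30 Mb must be supported by at
least five distinct studies instead.  Grouping is by connected components of
the interval-overlap graph, computed per (trait, chromosome) with a sweep
over sorted starts.

Two region conventions are offered:

* ``union`` (default) — the cluster interval is the union span of its
  component, matching reported cluster extents up to tens of Mb;
* ``coverage`` — maximal runs inside a component where the number of
  distinct studies covering a point reaches the support threshold, a
  tighter, hotspot-style alternative for sensitivity checks.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Literal, Sequence

from .core import (
    MB,
    ConfigError,
    GenomicInterval,
    QtlCluster,
    QtlRecord,
    chrom_sort_key,
    merge_overlapping,
    union_span,
)

__all__ = ["qtl_components", "call_qtl_clusters"]


def qtl_components(records: Sequence[QtlRecord]) -> list[list[QtlRecord]]:
    """Connected components of the interval-overlap graph.

    All records must be normalized and share one (trait, chromosome); every
    record lands in exactly one component.  Sweep over sorted starts: a
    record starts a new component iff its start is at or beyond the running
    maximum end (half-open ⇒ abutment does not connect).
    """
    for r in records:
        if r.interval is None:
            raise ValueError(f"unnormalized record {r.record_id}")
    keys = {(r.trait, r.interval.chrom) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span several (trait, chrom) groups: {sorted(keys)}")
    ordered = sorted(records, key=lambda r: (r.interval.start_bp, r.interval.end_bp, r.record_id))
    components: list[list[QtlRecord]] = []
    current: list[QtlRecord] = []
    max_end = -1
    for rec in ordered:
        if current and rec.interval.start_bp >= max_end:
            components.append(current)
            current = []
        current.append(rec)
        max_end = max(max_end, rec.interval.end_bp)
    if current:
        components.append(current)
    return components


def _study_coverage_runs(
    members: Sequence[QtlRecord], min_studies: int
) -> list[GenomicInterval]:
    """Maximal runs where ≥ min_studies distinct studies cover each point."""
    per_study: dict[str, list[GenomicInterval]] = defaultdict(list)
    for r in members:
        per_study[r.study_id].append(r.interval)
    events: list[tuple[int, int]] = []
    for ivs in per_study.values():
        for iv in merge_overlapping(ivs):  # one study counts once per point
            events.append((iv.start_bp, +1))
            events.append((iv.end_bp, -1))
    events.sort()
    chrom = members[0].interval.chrom
    runs: list[GenomicInterval] = []
    depth, run_start = 0, None
    for pos, delta in events:
        depth += delta
        if depth >= min_studies and run_start is None:
            run_start = pos
        elif depth < min_studies and run_start is not None:
            runs.append(GenomicInterval(chrom, run_start, pos))
            run_start = None
    return merge_overlapping(runs)


def call_qtl_clusters(
    records: Sequence[QtlRecord],
    min_studies: int = 3,
    span_threshold_bp: int = 30 * MB,
    min_studies_large: int = 5,
    region_mode: Literal["union", "coverage"] = "union",
) -> list[QtlCluster]:
    """Call QTL clusters from normalized records.

    Records are grouped by (trait, chromosome); each overlap component whose
    members come from ≥ ``min_studies`` distinct studies is emitted as a
    cluster, unless its span exceeds ``span_threshold_bp`` with fewer than
    ``min_studies_large`` studies, in which case the whole component is
    discarded (no recursive splitting).  Output is sorted by chromosome then
    start, with deterministic ids.
    """
    if min_studies < 1 or min_studies_large < min_studies or span_threshold_bp <= 0:
        raise ConfigError("invalid clustering thresholds")
    groups: dict[tuple[str, str], list[QtlRecord]] = defaultdict(list)
    for r in records:
        if r.interval is None:
            raise ValueError(f"unnormalized record {r.record_id}")
        groups[(r.trait, r.interval.chrom)].append(r)

    candidates: list[tuple[str, GenomicInterval, list[QtlRecord], frozenset[str]]] = []
    for (trait, chrom), group in groups.items():
        for comp in qtl_components(group):
            studies = frozenset(r.study_id for r in comp)
            if len(studies) < min_studies:
                continue
            if region_mode == "union":
                regions = [union_span([r.interval for r in comp])]
            elif region_mode == "coverage":
                regions = _study_coverage_runs(comp, min_studies)
            else:
                raise ConfigError(f"unknown region_mode {region_mode!r}")
            for region in regions:
                members = [
                    r
                    for r in comp
                    if max(r.interval.start_bp, region.start_bp)
                    < min(r.interval.end_bp, region.end_bp)
                ]
                sup = frozenset(r.study_id for r in members)
                if len(sup) < min_studies:
                    continue
                if region.length_bp > span_threshold_bp and len(sup) < min_studies_large:
                    continue
                candidates.append((trait, region, members, sup))

    candidates.sort(
        key=lambda c: (chrom_sort_key(c[1].chrom), c[1].start_bp, c[1].end_bp, c[0])
    )
    clusters = []
    for i, (trait, region, members, studies) in enumerate(candidates, start=1):
        clusters.append(
            QtlCluster(
                cluster_id=f"QTLC{i:03d}",
                trait=trait,
                chrom=region.chrom,
                interval=region,
                member_ids=frozenset(r.record_id for r in members),
                supporting_studies=studies,
            )
        )
    return clusters
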