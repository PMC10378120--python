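"""Common-interval detection across called clusters.

Two classes of common interval (CI) are distinguished:

* **Class1** — a trait-matched overlap between one QTL cluster and one QTN
  cluster on the same chromosome: the locus is seen by both linkage mapping
  and GWAS, evidence that it is environmentally stable.  Counting is
  pair-level: a QTL cluster overlapping two QTN clusters yields two CIs.
* **Class2** — a pleiotropic locus: a maximal set of mutually overlapping
  cluster intervals (QTL and/or QTN, pooled) covering at least two distinct
  traits.  By the Helly property of intervals, pairwise overlap guarantees a
  non-empty common intersection, which is reported as the CI region.

Maximal sets are the maximal cliques of the interval-overlap graph, found by
stabbing at right endpoints; nested (subset) sets are pruned.  A chaining
variant (connected components instead of cliques) is available for
sensitivity analysis.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Literal, Sequence, Union

from .core import (
    Class1CI,
    Class2CI,
    DataResource,
    GeneModel,
    GenomicInterval,
    QtlCluster,
    QtnCluster,
    chrom_sort_key,
    intersection,
    overlaps,
    union_span,
)

__all__ = [
    "find_class1",
    "find_class2",
    "classify_resource",
    "overlay_known_genes",
]

Cluster = Union[QtlCluster, QtnCluster]


def find_class1(
    qtl_clusters: Sequence[QtlCluster], qtn_clusters: Sequence[QtnCluster]
) -> list[Class1CI]:
    """All (QTL cluster, QTN cluster) pairs with equal trait and chromosome
    whose intervals overlap; the CI region is their intersection."""
    by_key: dict[tuple[str, str], list[QtnCluster]] = defaultdict(list)
    for qc in qtn_clusters:
        by_key[(qc.trait, qc.chrom)].append(qc)
    pairs = []
    for lc in qtl_clusters:
        for qc in by_key.get((lc.trait, lc.chrom), ()):
            region = (
                intersection([lc.interval, qc.interval])
                if overlaps(lc.interval, qc.interval)
                else None
            )
            if region is not None:
                pairs.append((lc, qc, region))
    pairs.sort(
        key=lambda p: (chrom_sort_key(p[2].chrom), p[2].start_bp, p[0].cluster_id, p[1].cluster_id)
    )
    return [
        Class1CI(
            ci_id=f"C1_{i:03d}",
            trait=lc.trait,
            chrom=lc.chrom,
            qtl_cluster_id=lc.cluster_id,
            qtn_cluster_id=qc.cluster_id,
            qtl_interval=lc.interval,
            qtn_interval=qc.interval,
            overlap_region=region,
        )
        for i, (lc, qc, region) in enumerate(pairs, start=1)
    ]


def _resource_of(cluster: Cluster) -> str:
    return "QTL" if isinstance(cluster, QtlCluster) else "QTN"


def _maximal_cliques(items: Sequence[Cluster]) -> list[frozenset[int]]:
    """Maximal cliques of the interval-overlap graph on one chromosome.

    For interval graphs every maximal clique is the stabbing set of some
    point just left of a right endpoint; collect those and prune subsets.
    """
    cliques: set[frozenset[int]] = set()
    for c in items:
        p = c.interval.end_bp - 1  # last covered base of c
        stab = frozenset(
            i
            for i, other in enumerate(items)
            if other.interval.start_bp <= p < other.interval.end_bp
        )
        cliques.add(stab)
    return _prune_subsets(cliques)


def _prune_subsets(sets: set[frozenset[int]]) -> list[frozenset[int]]:
    kept = []
    for s in sorted(sets, key=len, reverse=True):
        if not any(s < k for k in kept):
            kept.append(s)
    return kept


def _chain_components(items: Sequence[Cluster]) -> list[frozenset[int]]:
    """Connected components of the overlap graph (the chaining variant)."""
    order = sorted(range(len(items)), key=lambda i: items[i].interval.start_bp)
    comps: list[list[int]] = []
    max_end = -1
    for i in order:
        iv = items[i].interval
        if comps and iv.start_bp < max_end:
            comps[-1].append(i)
        else:
            comps.append([i])
            max_end = iv.end_bp
        max_end = max(max_end, iv.end_bp)
    return [frozenset(c) for c in comps]


def find_class2(
    clusters: Sequence[Cluster],
    class2_mode: Literal["clique", "chain"] = "clique",
) -> list[Class2CI]:
    """Pleiotropic common intervals from the pooled QTL + QTN clusters.

    Per chromosome, enumerate maximal sets of mutually overlapping cluster
    intervals, keep those covering ≥2 distinct traits, prune member sets that
    are subsets of other kept sets, and report each set's common intersection
    as the CI region.  In ``chain`` mode, components of the overlap graph
    replace cliques; a chained component need not share a common point, in
    which case the spanning interval is reported instead (flagged only by its
    width — see the methods note).
    """
    by_chrom: dict[str, list[Cluster]] = defaultdict(list)
    for c in clusters:
        by_chrom[c.chrom].append(c)

    found: list[tuple[GenomicInterval, list[Cluster]]] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        items = by_chrom[chrom]
        if class2_mode == "clique":
            member_sets = _maximal_cliques(items)
        elif class2_mode == "chain":
            member_sets = _chain_components(items)
        else:
            raise ValueError(f"unknown class2_mode {class2_mode!r}")
        kept: set[frozenset[int]] = set()
        for s in member_sets:
            traits = {items[i].trait for i in s}
            if len(traits) >= 2:
                kept.add(s)
        for s in _prune_subsets(kept):
            members = [items[i] for i in sorted(s)]
            region = intersection([m.interval for m in members])
            if region is None:
                if class2_mode == "clique":
                    raise AssertionError(
                        "pairwise-overlapping intervals must share a point"
                    )
                region = union_span([m.interval for m in members])
            found.append((region, members))

    found.sort(key=lambda f: (chrom_sort_key(f[0].chrom), f[0].start_bp))
    out = []
    for i, (region, members) in enumerate(found, start=1):
        out.append(
            Class2CI(
                ci_id=f"C2_{i:03d}",
                chrom=region.chrom,
                region=region,
                member_cluster_ids=frozenset(m.cluster_id for m in members),
                traits=frozenset(m.trait for m in members),
                member_resources=frozenset(_resource_of(m) for m in members),
            )
        )
    return out


def classify_resource(ci: Class2CI) -> DataResource:
    """QTL_CLUSTER / QTN_CLUSTER / BOTH by the provenance of the members."""
    res = ci.member_resources
    if res == {"QTL", "QTN"}:
        return DataResource.BOTH
    if res == {"QTL"}:
        return DataResource.QTL_CLUSTER
    if res == {"QTN"}:
        return DataResource.QTN_CLUSTER
    raise ValueError(f"{ci.ci_id}: unknown member resources {set(res)}")


def overlay_known_genes(
    cis: Sequence[Union[Class1CI, Class2CI]], genes: Sequence[GeneModel]
) -> list[Union[Class1CI, Class2CI]]:
    """Annotate common intervals with the known genes they contain.

    A gene marks a CI when its span overlaps the CI's common region (the
    QTL∩QTN overlap for Class1, the member intersection for Class2) — the
    reading under which a CI "possesses" a gene.  Returns new CI objects;
    inputs are untouched.
    """
    from dataclasses import replace

    out = []
    for ci in cis:
        region = ci.overlap_region if isinstance(ci, Class1CI) else ci.region
        hits = tuple(
            g.gene_id for g in genes if overlaps(g.interval, region)
        )
        out.append(replace(ci, known_genes=hits))
    return out
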