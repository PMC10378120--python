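"""Candidate-gene assignment inside QTL/QTN clusters.

A gene is assigned as a most-possible candidate for a cluster when it
(a) overlaps the cluster interval (any-overlap, consistent with the rest of
the pipeline), (b) is expressed in the female inflorescence meristem (the
tissue whose proliferation determines ear size — the expression universe is
an input ID list, no quantification is performed here), and (c) its
annotation matches the pathway vocabulary, either via pre-computed
``pathway_tags`` or a direct keyword hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import pandas as pd

from .core import GeneModel, GenomicInterval, QtlCluster, QtnCluster, overlaps
from .vocab import PathwayVocabulary

__all__ = [
    "CandidateAssignment",
    "genes_in_interval",
    "assign_candidates",
    "summarize_candidates",
]

Cluster = Union[QtlCluster, QtnCluster]


@dataclass(frozen=True)
class CandidateAssignment:
    """One (cluster, gene) candidate call with its matching evidence."""

    cluster_id: str
    gene_id: str
    matched_pathways: frozenset[str]
    keyword_hits: tuple[str, ...]
    expressed: bool = True


def genes_in_interval(
    genes: Sequence[GeneModel], interval: GenomicInterval
) -> list[GeneModel]:
    """Genes whose span overlaps the query interval (any-overlap rule)."""
    return [g for g in genes if overlaps(g.interval, interval)]


def assign_candidates(
    clusters: Sequence[Cluster],
    genes: Sequence[GeneModel],
    vocab: PathwayVocabulary,
) -> list[CandidateAssignment]:
    """Assign pathway-matched, IM-expressed genes to the clusters they overlap.

    Deterministic given (clusters, genes, vocab); assignments are ordered by
    cluster then gene id.
    """
    out: list[CandidateAssignment] = []
    for cluster in clusters:
        for gene in genes_in_interval(genes, cluster.interval):
            if not gene.im_expressed:
                continue
            hits = vocab.match(gene.annotation)
            pathways = set(gene.pathway_tags) | set(hits)
            if not pathways:
                continue
            keywords = tuple(sorted({w for ws in hits.values() for w in ws}))
            out.append(
                CandidateAssignment(
                    cluster_id=cluster.cluster_id,
                    gene_id=gene.gene_id,
                    matched_pathways=frozenset(pathways),
                    keyword_hits=keywords,
                )
            )
    out.sort(key=lambda a: (a.cluster_id, a.gene_id))
    return out


def summarize_candidates(
    assignments: Sequence[CandidateAssignment],
    clusters: Sequence[Cluster],
) -> dict:
    """Summary counts: clusters with ≥1 candidate per resource, and per-pathway
    gene / host-cluster tallies."""
    by_cluster: dict[str, set[str]] = {}
    for a in assignments:
        by_cluster.setdefault(a.cluster_id, set()).add(a.gene_id)
    qtl_ids = {c.cluster_id for c in clusters if isinstance(c, QtlCluster)}
    qtn_ids = {c.cluster_id for c in clusters if isinstance(c, QtnCluster)}
    pathway_genes: dict[str, set[str]] = {}
    pathway_hosts: dict[str, set[str]] = {}
    for a in assignments:
        for p in a.matched_pathways:
            pathway_genes.setdefault(p, set()).add(a.gene_id)
            pathway_hosts.setdefault(p, set()).add(a.cluster_id)
    return {
        "n_qtl_clusters_with_candidate": len(set(by_cluster) & qtl_ids),
        "n_qtn_clusters_with_candidate": len(set(by_cluster) & qtn_ids),
        "per_pathway": {
            p: {
                "n_genes": len(pathway_genes[p]),
                "n_host_clusters": len(pathway_hosts[p]),
            }
            for p in sorted(pathway_genes)
        },
    }


def assignments_to_frame(assignments: Sequence[CandidateAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": a.cluster_id,
                "gene_id": a.gene_id,
                "pathways": ",".join(sorted(a.matched_pathways)),
                "keywords": ",".join(a.keyword_hits),
            }
            for a in assignments
        ],
        columns=["cluster_id", "gene_id", "pathways", "keywords"],
    )
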