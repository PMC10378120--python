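"""Summary statistics and human-readable reporting for pipeline outputs.

The summary mirrors the tallies a meta-analysis reports: per-trait and
per-chromosome locus counts, cluster counts with a width histogram at the
1 Mb and 10 Mb thresholds, common-interval counts by class, and the Class2
breakdowns by data resource, trait arity and known-gene overlap.  The pretty
text rendering is generated from the same rows as the TSV, so every printed
number equals the corresponding TSV cell by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .common_intervals import classify_resource
from .core import (
    MB,
    Class1CI,
    Class2CI,
    DataResource,
    QtlCluster,
    QtlRecord,
    QtnCluster,
    QtnRecord,
    chrom_sort_key,
)

__all__ = ["SummaryReport", "summarize"]

WIDTH_THRESHOLDS_BP = (1 * MB, 10 * MB)


@dataclass
class SummaryReport:
    """Flat (section, key, value) rows; rendered to TSV or pretty text."""

    rows: list[tuple[str, str, int]] = field(default_factory=list)

    def add(self, section: str, key: str, value: int) -> None:
        self.rows.append((section, key, int(value)))

    def value(self, section: str, key: str) -> int:
        for s, k, v in self.rows:
            if s == section and k == key:
                return v
        raise KeyError((section, key))

    def section(self, section: str) -> dict[str, int]:
        return {k: v for s, k, v in self.rows if s == section}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["section", "key", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def pretty(self) -> str:
        lines = []
        current = None
        for section, key, value in self.rows:
            if section != current:
                lines.append(f"[{section}]")
                current = section
            lines.append(f"  {key}: {value}")
        return "\n".join(lines) + "\n"


def plot_width_histogram(clusters: Sequence, path, bin_mb: float = 1.0) -> None:
    """Write a simple cluster-width histogram (widths in Mb) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    widths = [c.interval.length_mb for c in clusters]
    fig, ax = plt.subplots(figsize=(6, 4))
    upper = max(widths, default=1.0)
    n_bins = max(1, int(upper / bin_mb) + 1)
    ax.hist(widths, bins=n_bins, color="#4878a8", edgecolor="black")
    for t in WIDTH_THRESHOLDS_BP:
        ax.axvline(t / MB, color="red", linestyle="--", linewidth=0.8)
    ax.set_xlabel("cluster width (Mb)")
    ax.set_ylabel("clusters")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _count_widths(clusters: Sequence) -> dict[str, int]:
    widths = [c.interval.length_bp for c in clusters]
    out = {"total": len(widths)}
    for t in WIDTH_THRESHOLDS_BP:
        out[f"shorter_than_{t // MB}Mb"] = sum(w < t for w in widths)
    return out


def summarize(
    qtl_records: Sequence[QtlRecord] = (),
    qtn_records: Sequence[QtnRecord] = (),
    qtl_clusters: Sequence[QtlCluster] = (),
    qtn_clusters: Sequence[QtnCluster] = (),
    class1: Sequence[Class1CI] = (),
    class2: Sequence[Class2CI] = (),
) -> SummaryReport:
    """Deterministic aggregation of every pipeline stage's outputs."""
    rep = SummaryReport()

    for name, records in (("qtl_records", qtl_records), ("qtn_records", qtn_records)):
        by_trait = Counter(r.trait for r in records)
        for trait in sorted(by_trait):
            rep.add(f"{name}_by_trait", trait, by_trait[trait])
        chrom_of = (
            lambda r: r.interval.chrom if isinstance(r, QtlRecord) and r.interval else r.chrom
        )
        by_chrom = Counter(
            chrom_of(r) for r in records if isinstance(r, QtnRecord) or r.interval
        )
        for chrom in sorted(by_chrom, key=chrom_sort_key):
            rep.add(f"{name}_by_chrom", chrom, by_chrom[chrom])
        rep.add(f"{name}_by_trait", "total", len(records))

    for name, clusters in (
        ("qtl_clusters", qtl_clusters),
        ("qtn_clusters", qtn_clusters),
    ):
        by_trait = Counter(c.trait for c in clusters)
        for trait in sorted(by_trait):
            rep.add(f"{name}_by_trait", trait, by_trait[trait])
        by_chrom = Counter(c.chrom for c in clusters)
        for chrom in sorted(by_chrom, key=chrom_sort_key):
            rep.add(f"{name}_by_chrom", chrom, by_chrom[chrom])
        for key, v in _count_widths(clusters).items():
            rep.add(f"{name}_widths", key, v)

    rep.add("common_intervals", "class1", len(class1))
    rep.add("common_intervals", "class2", len(class2))
    rep.add(
        "common_intervals",
        "class1_with_known_gene",
        sum(bool(ci.known_genes) for ci in class1),
    )

    if class2:
        res = Counter(classify_resource(ci) for ci in class2)
        rep.add("class2_resource", "both", res.get(DataResource.BOTH, 0))
        rep.add("class2_resource", "qtl_only", res.get(DataResource.QTL_CLUSTER, 0))
        rep.add("class2_resource", "qtn_only", res.get(DataResource.QTN_CLUSTER, 0))
        rep.add(
            "class2_resource",
            "single",
            res.get(DataResource.QTL_CLUSTER, 0) + res.get(DataResource.QTN_CLUSTER, 0),
        )
        arity = Counter(len(ci.traits) for ci in class2)
        for k in sorted(arity):
            rep.add("class2_trait_arity", f"{k}_traits", arity[k])
        rep.add(
            "class2_genes",
            "with_known_gene",
            sum(bool(ci.known_genes) for ci in class2),
        )
    return rep
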