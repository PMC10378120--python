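"""Domain types and exact interval algebra for the ear-trait meta-analysis.

All genomic coordinates are integer base pairs on a half-open, 0-based
interval ``[start_bp, end_bp)`` — the BED convention.  Published tables print
positions in megabases to two decimals; those are converted with
``round(Mb * 1e6)`` so that the 2-decimal Mb → bp → Mb round trip is exact.

Chromosomes are opaque string labels ("1".."10" for maize); the natural
numeric order is used only when sorting output for reports.  Strand is
carried on gene models but ignored by all interval logic: mapped loci are
strandless.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "IntervalError",
    "FormatError",
    "ConfigError",
    "GenomicInterval",
    "TraitRegistry",
    "DEFAULT_TRAITS",
    "default_trait_registry",
    "QtlRecord",
    "QtnRecord",
    "QtlCluster",
    "QtnCluster",
    "DataResource",
    "Class1CI",
    "Class2CI",
    "GeneModel",
    "mb_to_bp",
    "bp_to_mb",
    "overlaps",
    "intersection",
    "union_span",
    "merge_overlapping",
    "chrom_sort_key",
]


class IntervalError(ValueError):
    """A malformed interval or an illegal cross-chromosome operation."""


class FormatError(ValueError):
    """A structural problem in an input file (missing columns, bad rows)."""


class ConfigError(ValueError):
    """An invalid parameter or configuration value."""


MB = 1_000_000


def mb_to_bp(mb: float) -> int:
    """Convert a printed megabase coordinate to integer base pairs."""
    return int(round(mb * MB))


def bp_to_mb(bp: int) -> float:
    return bp / MB


def chrom_sort_key(chrom: str):
    """Sort key putting numeric chromosome labels in natural order."""
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start_bp, end_bp)`` on a named chromosome."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 0:
            raise IntervalError(f"negative start: {self.start_bp}")
        if self.start_bp >= self.end_bp:
            raise IntervalError(
                f"empty or inverted interval [{self.start_bp}, {self.end_bp})"
            )

    @classmethod
    def from_mb(cls, chrom: str, start_mb: float, end_mb: float) -> "GenomicInterval":
        return cls(str(chrom), mb_to_bp(start_mb), mb_to_bp(end_mb))

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / MB

    def contains_point(self, pos_bp: int) -> bool:
        return self.start_bp <= pos_bp < self.end_bp

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.start_bp
            and other.end_bp <= self.end_bp
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base pair.

    Abutting intervals (``a.end_bp == b.start_bp``) do not overlap under the
    half-open convention.  Intervals on different chromosomes never overlap.
    """
    if a.chrom != b.chrom:
        return False
    return max(a.start_bp, b.start_bp) < min(a.end_bp, b.end_bp)


def _require_same_chrom(intervals: Sequence[GenomicInterval]) -> str:
    if not intervals:
        raise IntervalError("empty interval list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise IntervalError(f"mixed chromosomes: {sorted(chroms)}")
    return intervals[0].chrom


def intersection(intervals: Sequence[GenomicInterval]) -> Optional[GenomicInterval]:
    """Common intersection of same-chromosome intervals, or None if empty."""
    chrom = _require_same_chrom(intervals)
    start = max(iv.start_bp for iv in intervals)
    end = min(iv.end_bp for iv in intervals)
    if start < end:
        return GenomicInterval(chrom, start, end)
    return None


def union_span(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Smallest interval containing every member (gaps included)."""
    chrom = _require_same_chrom(intervals)
    return GenomicInterval(
        chrom,
        min(iv.start_bp for iv in intervals),
        max(iv.end_bp for iv in intervals),
    )


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted list of disjoint intervals covering the same points.

    Abutting intervals are not merged (they cover disjoint point sets but the
    result is still minimal and disjoint); overlapping ones are.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start_bp, iv.end_bp))
    if not ivs:
        return []
    _require_same_chrom(ivs)
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start_bp < last.end_bp:  # strict: abutment does not merge coverage gaps
            if iv.end_bp > last.end_bp:
                merged[-1] = GenomicInterval(last.chrom, last.start_bp, iv.end_bp)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

#: The eight ear-trait codes analysed throughout: kernel row number, ear
#: length, ear diameter, kernel number per row, ear weight, cob diameter,
#: kernel weight per ear, cob weight.
DEFAULT_TRAITS: tuple[str, ...] = ("KRN", "EL", "ED", "KNPR", "EW", "CD", "KWPE", "CW")


class TraitRegistry:
    """Extensible registry of trait codes.

    Unknown codes encountered in input tables are registered on the fly (with
    a warning at the I/O layer) so heterogeneous curated tables pass through.
    """

    def __init__(self, codes: Iterable[str] = DEFAULT_TRAITS):
        self._codes: set[str] = set()
        for c in codes:
            self.register(c)

    def register(self, code: str) -> str:
        code = code.strip().upper()
        if not code:
            raise ConfigError("empty trait code")
        self._codes.add(code)
        return code

    def is_known(self, code: str) -> bool:
        return code.strip().upper() in self._codes

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self._codes)


def default_trait_registry() -> TraitRegistry:
    return TraitRegistry()


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QtlRecord:
    """One published QTL: an interval (once normalized) with provenance."""

    record_id: str
    study_id: str
    trait: str
    chrom: Optional[str] = None
    interval: Optional[GenomicInterval] = None
    left_marker: Optional[str] = None
    right_marker: Optional[str] = None
    source: str = ""

    @property
    def is_normalized(self) -> bool:
        return self.interval is not None

    def with_interval(self, interval: GenomicInterval) -> "QtlRecord":
        return replace(self, chrom=interval.chrom, interval=interval)


@dataclass(frozen=True)
class QtnRecord:
    """One published trait-associated SNP (QTN): a point with provenance."""

    record_id: str
    study_id: str
    trait: str
    chrom: str
    pos_bp: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.pos_bp < 0:
            raise IntervalError(f"negative QTN position: {self.pos_bp}")


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QtlCluster:
    """A QTL support region: overlapping same-trait QTLs from ≥3 studies.

    ``interval`` is the union span of the member intervals.  Regions longer
    than 30 Mb require support from ≥5 distinct studies.
    """

    cluster_id: str
    trait: str
    chrom: str
    interval: GenomicInterval
    member_ids: frozenset[str] = frozenset()
    supporting_studies: frozenset[str] = frozenset()

    @property
    def n_studies(self) -> int:
        return len(self.supporting_studies)

    def validate(
        self,
        members: Optional[Sequence[QtlRecord]] = None,
        min_studies: int = 3,
        span_threshold_bp: int = 30 * MB,
        min_studies_large: int = 5,
    ) -> None:
        """Machine-check the cluster invariants; raises on violation."""
        if self.n_studies < min_studies:
            raise ValueError(f"{self.cluster_id}: only {self.n_studies} studies")
        if self.interval.length_bp > span_threshold_bp and self.n_studies < min_studies_large:
            raise ValueError(
                f"{self.cluster_id}: span {self.interval.length_mb:.2f} Mb "
                f"needs ≥{min_studies_large} studies, has {self.n_studies}"
            )
        if members is not None:
            for m in members:
                if m.record_id in self.member_ids:
                    assert m.interval is not None
                    if not self.interval.contains(m.interval):
                        raise ValueError(
                            f"{self.cluster_id}: member {m.record_id} outside span"
                        )


@dataclass(frozen=True)
class QtnCluster:
    """A QTN hotspot: ≥3 same-trait QTNs inside a 0.5 Mb sliding window.

    ``interval`` is the union of qualifying anchored windows, so its width is
    never below the window width.
    """

    cluster_id: str
    trait: str
    chrom: str
    interval: GenomicInterval
    member_ids: frozenset[str] = frozenset()

    @property
    def qtn_count(self) -> int:
        return len(self.member_ids)

    def validate(
        self,
        members: Optional[Sequence[QtnRecord]] = None,
        window_bp: int = 500_000,
        min_count: int = 3,
    ) -> None:
        if self.qtn_count < min_count:
            raise ValueError(f"{self.cluster_id}: only {self.qtn_count} QTNs")
        if self.interval.length_bp < window_bp:
            raise ValueError(
                f"{self.cluster_id}: width {self.interval.length_bp} < window {window_bp}"
            )
        if members is not None:
            for m in members:
                if m.record_id in self.member_ids and not self.interval.contains_point(
                    m.pos_bp
                ):
                    raise ValueError(
                        f"{self.cluster_id}: member {m.record_id} outside interval"
                    )


# ---------------------------------------------------------------------------
# Common intervals
# ---------------------------------------------------------------------------


class DataResource(enum.Enum):
    """Provenance of the clusters backing a pleiotropic common interval."""

    QTL_CLUSTER = "QTL cluster"
    QTN_CLUSTER = "QTN cluster"
    BOTH = "QTN cluster/QTL cluster"


@dataclass(frozen=True)
class Class1CI:
    """Trait-matched common interval: a QTL cluster × QTN cluster overlap.

    Evidence that the locus is detected by both linkage mapping and GWAS and
    hence environmentally stable.  Counting is pair-level: one QTL cluster
    overlapping two QTN clusters yields two common intervals.
    """

    ci_id: str
    trait: str
    chrom: str
    qtl_cluster_id: str
    qtn_cluster_id: str
    qtl_interval: GenomicInterval
    qtn_interval: GenomicInterval
    overlap_region: GenomicInterval
    known_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class Class2CI:
    """Pleiotropic common interval: mutually overlapping clusters of ≥2 traits.

    ``region`` is the common intersection of all member cluster intervals;
    ``member_resources`` records whether members came from QTL clusters, QTN
    clusters, or both.
    """

    ci_id: str
    chrom: str
    region: GenomicInterval
    member_cluster_ids: frozenset[str]
    traits: frozenset[str]
    member_resources: frozenset[str]  # subset of {"QTL", "QTN"}
    known_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.traits) < 2:
            raise ValueError(f"{self.ci_id}: pleiotropic CI needs ≥2 traits")


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene span with annotation, IM-expression flag and pathway tags."""

    gene_id: str
    chrom: str
    interval: GenomicInterval
    strand: str = "."
    annotation: str = ""
    pathway_tags: frozenset[str] = frozenset()
    im_expressed: bool = False
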