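"""Coordinate normalization onto the single working assembly.

Published QTLs are delimited by flanking markers and published QTNs sit on
assorted assembly versions.  Here both are resolved onto one coordinate
system (e.g. B73 RefGen_v5.0) through offline lookup tables: a
:class:`MarkerMap` giving each marker name a single position, and a
:class:`PositionLookup` mapping source-assembly positions to target
positions.  Sequence-similarity search and remote remap services are out of
scope; the tables are their deterministic, reproducible stand-in.

Unresolvable records are never dropped silently: batch resolvers return them
in a rejects list with a reason, and resolved + rejected always equals the
input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import FormatError, GenomicInterval, QtlRecord, QtnRecord

__all__ = [
    "MarkerMap",
    "PositionLookup",
    "UnresolvedError",
    "resolve_qtl",
    "lift_qtn",
    "resolve_qtls",
    "lift_qtns",
    "NormalizationResult",
]


class UnresolvedError(ValueError):
    """A record that cannot be placed on the target assembly."""


@dataclass(frozen=True)
class MarkerMap:
    """Marker name → (chrom, pos_bp) on the target assembly.

    Each marker has exactly one position; multi-mapping marker sequences are
    an explicit simplification (first exact name match wins at load time).
    """

    positions: dict[str, tuple[str, int]]
    provenance: str = ""

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "MarkerMap":
        """Load a 3-column TSV: marker, chrom, pos_bp (header required)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        for col in ("marker", "chrom", "pos_bp"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        positions: dict[str, tuple[str, int]] = {}
        for _, row in df.iterrows():
            name = row["marker"].strip()
            if name in positions:
                continue  # first exact name match wins
            positions[name] = (row["chrom"].strip(), int(float(row["pos_bp"])))
        return cls(positions, provenance or str(path))

    def lookup(self, marker: str) -> Optional[tuple[str, int]]:
        return self.positions.get(marker)


@dataclass(frozen=True)
class PositionLookup:
    """(chrom, source_pos_bp) → target_pos_bp with optional identity fallback.

    With ``identity_fallback`` set, positions absent from the table pass
    through unchanged — the behaviour wanted when most input is already on
    the target assembly.
    """

    table: dict[tuple[str, int], int] = field(default_factory=dict)
    identity_fallback: bool = False

    @classmethod
    def identity(cls) -> "PositionLookup":
        return cls({}, identity_fallback=True)

    @classmethod
    def from_tsv(cls, path, identity_fallback: bool = False) -> "PositionLookup":
        """Load a 3-column TSV: chrom, source_pos, target_pos."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        for col in ("chrom", "source_pos", "target_pos"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        table = {
            (row["chrom"].strip(), int(float(row["source_pos"]))): int(
                float(row["target_pos"])
            )
            for _, row in df.iterrows()
        }
        return cls(table, identity_fallback)

    def lift(self, chrom: str, pos_bp: int) -> int:
        key = (chrom, pos_bp)
        if key in self.table:
            return self.table[key]
        if self.identity_fallback:
            return pos_bp
        raise UnresolvedError(f"no lookup entry for {chrom}:{pos_bp}")

    def inverse(self) -> "PositionLookup":
        """Swap source and target positions (for round-trip checks)."""
        inv = {(c, t): s for (c, s), t in self.table.items()}
        return PositionLookup(inv, self.identity_fallback)


def resolve_qtl(record: QtlRecord, markers: MarkerMap) -> QtlRecord:
    """Place a marker-delimited QTL on the target assembly.

    Records already carrying an interval pass through unchanged.  Marker
    order is not trusted: the interval is [min pos, max pos).  Coincident
    markers yield the minimal 1 bp interval [p, p+1) so the record stays
    usable downstream.  Raises :class:`UnresolvedError` when a marker is
    missing or the pair maps to different chromosomes.
    """
    if record.interval is not None:
        return record
    if not (record.left_marker and record.right_marker):
        raise UnresolvedError("record has neither interval nor a marker pair")
    left = markers.lookup(record.left_marker)
    right = markers.lookup(record.right_marker)
    missing = [
        m
        for m, hit in ((record.left_marker, left), (record.right_marker, right))
        if hit is None
    ]
    if missing:
        raise UnresolvedError(f"marker(s) not in map: {missing}")
    (lc, lp), (rc, rp) = left, right
    if lc != rc:
        raise UnresolvedError("trans-marker pair")
    start, end = min(lp, rp), max(lp, rp)
    if start == end:
        end = start + 1  # coincident markers → degenerate 1 bp interval
    return record.with_interval(GenomicInterval(lc, start, end))


def lift_qtn(record: QtnRecord, lookup: PositionLookup) -> QtnRecord:
    """Lift a QTN position onto the target assembly."""
    from dataclasses import replace

    return replace(record, pos_bp=lookup.lift(record.chrom, record.pos_bp))


@dataclass
class NormalizationResult:
    """Resolved records plus the rejects report (record, reason)."""

    resolved: list
    rejects: list[tuple[object, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.resolved) + len(self.rejects)


def resolve_qtls(records: Sequence[QtlRecord], markers: MarkerMap) -> NormalizationResult:
    out = NormalizationResult([])
    for rec in records:
        try:
            out.resolved.append(resolve_qtl(rec, markers))
        except UnresolvedError as exc:
            out.rejects.append((rec, str(exc)))
    return out


def lift_qtns(records: Sequence[QtnRecord], lookup: PositionLookup) -> NormalizationResult:
    out = NormalizationResult([])
    for rec in records:
        try:
            out.resolved.append(lift_qtn(rec, lookup))
        except UnresolvedError as exc:
            out.rejects.append((rec, str(exc)))
    return out


def write_rejects_report(result: NormalizationResult, path) -> None:
    """Write the rejects report as TSV (record_id, study_id, trait, reason)."""
    rows = [
        {
            "record_id": rec.record_id,
            "study_id": rec.study_id,
            "trait": rec.trait,
            "reason": reason,
        }
        for rec, reason in result.rejects
    ]
    pd.DataFrame(rows, columns=["record_id", "study_id", "trait", "reason"]).to_csv(
        path, sep="\t", index=False
    )
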