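"""Readers and writers for the pipeline's tabular and genomic formats.

Curated QTL/QTN tables arrive as TSV with heterogeneous column naming, so
each reader takes an explicit *dialect* mapping logical fields to column
names.  Readers are total: every input row becomes either a record or a
reported row-level error — nothing is dropped silently, and the counts always
add up.

Also houses the packaged fixtures transcribing the published summary tables
of common intervals (19 trait-matched Class1 rows, 40 pleiotropic Class2
rows), plus synthetic point genes standing in for the printed known-gene
cells (the source prints gene names, not coordinates; each synthetic gene is
placed at the midpoint of its host common interval).
"""

from __future__ import annotations

import hashlib
import io as _stdio
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import (
    Class2CI,
    DataResource,
    FormatError,
    GeneModel,
    GenomicInterval,
    QtlCluster,
    QtlRecord,
    QtnCluster,
    QtnRecord,
    TraitRegistry,
    chrom_sort_key,
    default_trait_registry,
    mb_to_bp,
)
from .vocab import PathwayVocabulary

logger = logging.getLogger("earmeta.io")

__all__ = [
    "QtlTableDialect",
    "QtnTableDialect",
    "RowError",
    "ReadResult",
    "read_qtl_tsv",
    "read_qtn_tsv",
    "write_qtl_tsv",
    "write_qtn_tsv",
    "read_gff3_genes",
    "write_gff3_genes",
    "write_bed",
    "FixtureSet",
    "load_fixtures",
]


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QtlTableDialect:
    """Column names for a curated QTL table.

    Per row, either the flanking-marker pair or the Mb coordinate pair must be
    present; marker-only rows are left unresolved for the normalization stage.
    """

    study_id: str = "study_id"
    trait: str = "trait"
    chrom: str = "chrom"
    left_marker: str = "left_marker"
    right_marker: str = "right_marker"
    start_mb: str = "start_mb"
    end_mb: str = "end_mb"
    record_id: Optional[str] = "record_id"
    source: Optional[str] = None

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.study_id, self.trait)


@dataclass(frozen=True)
class QtnTableDialect:
    """Column names for a curated QTN table; position in bp or Mb."""

    study_id: str = "study_id"
    trait: str = "trait"
    chrom: str = "chrom"
    pos: str = "pos_bp"
    pos_unit: str = "bp"  # "bp" or "mb"
    record_id: Optional[str] = "record_id"
    source: Optional[str] = None

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.study_id, self.trait, self.chrom, self.pos)


@dataclass(frozen=True)
class RowError:
    """One rejected input row: its 1-based data row number and the reason."""

    row: int
    message: str


@dataclass
class ReadResult:
    """Records plus per-row errors; ``len(records) + len(errors)`` = rows read."""

    records: list
    errors: list[RowError] = field(default_factory=list)
    n_rows: int = 0

    def raise_on_errors(self) -> "ReadResult":
        if self.errors:
            first = self.errors[0]
            raise FormatError(
                f"{len(self.errors)} bad row(s); first: row {first.row}: {first.message}"
            )
        return self


def _check_header(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c and c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _normalize_trait(raw: str, registry: TraitRegistry) -> str:
    code = raw.strip().upper()
    if not registry.is_known(code):
        logger.warning("unknown trait code %r kept and registered", code)
    return registry.register(code)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")


def read_qtl_tsv(
    path,
    dialect: QtlTableDialect = QtlTableDialect(),
    registry: Optional[TraitRegistry] = None,
) -> ReadResult:
    """Read a curated QTL table.

    Rows carrying a Mb coordinate pair get their interval immediately
    (inverted pairs are swapped with a logged warning — flanking-marker order
    in source tables is unreliable); marker-only rows come back unresolved.
    Duplicate rows are retained: distinct-study counting happens at the
    study_id level downstream.
    """
    registry = registry or default_trait_registry()
    df = _read_tsv(path)
    _check_header(df, dialect.mandatory, path)
    d = dialect
    records: list[QtlRecord] = []
    errors: list[RowError] = []

    def cell(row, col) -> str:
        return str(row[col]).strip() if col and col in df.columns else ""

    for i, (_, row) in enumerate(df.iterrows(), start=1):
        study, trait_raw = cell(row, d.study_id), cell(row, d.trait)
        if not study or not trait_raw:
            errors.append(RowError(i, "missing study_id or trait"))
            continue
        trait = _normalize_trait(trait_raw, registry)
        chrom = cell(row, d.chrom) or None
        rid = cell(row, d.record_id) or f"QTL{i:05d}"
        source = cell(row, d.source)
        s_mb, e_mb = cell(row, d.start_mb), cell(row, d.end_mb)
        lm, rm = cell(row, d.left_marker) or None, cell(row, d.right_marker) or None
        interval = None
        if s_mb and e_mb:
            if not chrom:
                errors.append(RowError(i, "coordinate row without chromosome"))
                continue
            try:
                start_bp, end_bp = mb_to_bp(float(s_mb)), mb_to_bp(float(e_mb))
            except ValueError:
                errors.append(RowError(i, f"non-numeric Mb pair ({s_mb!r}, {e_mb!r})"))
                continue
            if start_bp > end_bp:
                logger.warning(
                    "row %d: inverted interval %s > %s swapped", i, s_mb, e_mb
                )
                start_bp, end_bp = end_bp, start_bp
            if start_bp == end_bp:
                end_bp = start_bp + 1  # degenerate printed point, keep usable
            interval = GenomicInterval(chrom, start_bp, end_bp)
        elif not (lm and rm):
            errors.append(RowError(i, "neither Mb pair nor marker pair present"))
            continue
        records.append(
            QtlRecord(
                record_id=rid,
                study_id=study,
                trait=trait,
                chrom=chrom,
                interval=interval,
                left_marker=lm,
                right_marker=rm,
                source=source,
            )
        )
    return ReadResult(records, errors, n_rows=len(df))


def read_qtn_tsv(
    path,
    dialect: QtnTableDialect = QtnTableDialect(),
    registry: Optional[TraitRegistry] = None,
) -> ReadResult:
    """Read a curated QTN table (one genomic position per row).

    Duplicate (study, trait, chrom, pos) rows are both kept and the
    duplication is reported via the logger; deduplication is an explicit
    pipeline flag, not a reader default.
    """
    registry = registry or default_trait_registry()
    df = _read_tsv(path)
    _check_header(df, dialect.mandatory, path)
    d = dialect
    records: list[QtnRecord] = []
    errors: list[RowError] = []
    seen: set[tuple] = set()

    for i, (_, row) in enumerate(df.iterrows(), start=1):
        study = str(row[d.study_id]).strip()
        trait_raw = str(row[d.trait]).strip()
        chrom = str(row[d.chrom]).strip()
        raw_pos = str(row[d.pos]).strip()
        if not (study and trait_raw and chrom and raw_pos):
            errors.append(RowError(i, "missing mandatory field"))
            continue
        try:
            pos_bp = (
                mb_to_bp(float(raw_pos)) if d.pos_unit == "mb" else int(float(raw_pos))
            )
        except ValueError:
            errors.append(RowError(i, f"non-numeric position {raw_pos!r}"))
            continue
        if pos_bp < 0:
            errors.append(RowError(i, f"negative position {pos_bp}"))
            continue
        trait = _normalize_trait(trait_raw, registry)
        key = (study, trait, chrom, pos_bp)
        if key in seen:
            logger.warning("row %d duplicates (study,trait,chrom,pos)=%s; kept", i, key)
        seen.add(key)
        rid = ""
        if d.record_id and d.record_id in df.columns:
            rid = str(row[d.record_id]).strip()
        records.append(
            QtnRecord(
                record_id=rid or f"QTN{i:05d}",
                study_id=study,
                trait=trait,
                chrom=chrom,
                pos_bp=pos_bp,
                source=str(row[d.source]).strip() if d.source in df.columns else "",
            )
        )
    return ReadResult(records, errors, n_rows=len(df))


def write_qtl_tsv(records: Sequence[QtlRecord], path) -> None:
    """Write QTL records in the default dialect (Mb to 6 decimals, lossless)."""
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "study_id": r.study_id,
                "trait": r.trait,
                "chrom": r.chrom or "",
                "start_mb": f"{r.interval.start_bp / 1e6:.6f}" if r.interval else "",
                "end_mb": f"{r.interval.end_bp / 1e6:.6f}" if r.interval else "",
                "left_marker": r.left_marker or "",
                "right_marker": r.right_marker or "",
                "source": r.source,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_qtn_tsv(records: Sequence[QtnRecord], path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "study_id": r.study_id,
            "trait": r.trait,
            "chrom": r.chrom,
            "pos_bp": r.pos_bp,
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3_genes(
    path,
    im_expressed_ids: Optional[set[str]] = None,
    vocab: Optional[PathwayVocabulary] = None,
) -> list[GeneModel]:
    """Read gene features from a GFF3 file into :class:`GeneModel` objects.

    Annotation text is taken from the Name/description/Note/product
    attributes.  ``im_expressed`` is set by membership in the provided
    inflorescence-meristem-expressed gene-ID list; ``pathway_tags`` by
    vocabulary keyword match against the annotation text.
    """
    import gffutils

    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise FormatError(f"{path}: unparseable GFF3 line {lineno}")
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    im_expressed_ids = im_expressed_ids or set()
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.id
        parts = []
        for key in ("Name", "description", "Note", "product"):
            parts.extend(feat.attributes.get(key, []))
        annotation = " ".join(parts)
        tags = frozenset(vocab.match(annotation)) if vocab else frozenset()
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                # GFF3 is 1-based inclusive; convert to 0-based half-open
                interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end),
                strand=feat.strand or ".",
                annotation=annotation,
                pathway_tags=tags,
                im_expressed=gene_id in im_expressed_ids,
            )
        )
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 gene features (1-based inclusive spans)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(
            genes, key=lambda g: (chrom_sort_key(g.chrom), g.interval.start_bp)
        ):
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";description={g.annotation}"
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "earmeta",
                        "gene",
                        str(g.interval.start_bp + 1),
                        str(g.interval.end_bp),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _item_name(item) -> str:
    for attr in ("cluster_id", "ci_id", "gene_id", "name"):
        if hasattr(item, attr):
            return str(getattr(item, attr))
    raise TypeError(f"cannot derive a BED name for {item!r}")


def _item_interval(item) -> GenomicInterval:
    if isinstance(item, GenomicInterval):
        return item
    iv = getattr(item, "interval", None) or getattr(item, "region", None) or getattr(
        item, "overlap_region", None
    )
    if iv is None:
        raise TypeError(f"no interval on {item!r}")
    return iv


def write_bed(items: Sequence, path) -> None:
    """Write clusters / common intervals / genes as BED4 (0-based half-open).

    An empty item list produces an empty file.  Lines are sorted by
    chromosome (natural order) then start, so output is deterministic.
    """
    lines = []
    for item in items:
        iv = _item_interval(item)
        lines.append((chrom_sort_key(iv.chrom), iv.start_bp, iv.end_bp, _item_name(item), iv.chrom))
    lines.sort()
    with open(path, "w", encoding="utf-8") as fh:
        for _key, start, end, name, chrom in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Cluster and CI tables
# ---------------------------------------------------------------------------


def write_qtl_clusters_tsv(clusters: Sequence[QtlCluster], path, header: str = "") -> None:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "trait": c.trait,
            "chrom": c.chrom,
            "start_bp": c.interval.start_bp,
            "end_bp": c.interval.end_bp,
            "n_studies": c.n_studies,
            "supporting_studies": ",".join(sorted(c.supporting_studies)),
            "member_ids": ",".join(sorted(c.member_ids)),
        }
        for c in clusters
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "trait",
            "chrom",
            "start_bp",
            "end_bp",
            "n_studies",
            "supporting_studies",
            "member_ids",
        ],
    )
    _to_tsv_with_header(df, path, header)


def write_qtn_clusters_tsv(clusters: Sequence[QtnCluster], path, header: str = "") -> None:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "trait": c.trait,
            "chrom": c.chrom,
            "start_bp": c.interval.start_bp,
            "end_bp": c.interval.end_bp,
            "qtn_count": c.qtn_count,
            "member_ids": ",".join(sorted(c.member_ids)),
        }
        for c in clusters
    ]
    df = pd.DataFrame(
        rows,
        columns=["cluster_id", "trait", "chrom", "start_bp", "end_bp", "qtn_count", "member_ids"],
    )
    _to_tsv_with_header(df, path, header)


def _split_ids(cell: str) -> frozenset[str]:
    return frozenset(x for x in str(cell).split(",") if x)


def read_qtl_clusters_tsv(path) -> list[QtlCluster]:
    df = _read_tsv(path)
    return [
        QtlCluster(
            cluster_id=r["cluster_id"],
            trait=r["trait"],
            chrom=r["chrom"],
            interval=GenomicInterval(r["chrom"], int(r["start_bp"]), int(r["end_bp"])),
            member_ids=_split_ids(r.get("member_ids", "")),
            supporting_studies=_split_ids(r.get("supporting_studies", "")),
        )
        for _, r in df.iterrows()
    ]


def read_qtn_clusters_tsv(path) -> list[QtnCluster]:
    df = _read_tsv(path)
    return [
        QtnCluster(
            cluster_id=r["cluster_id"],
            trait=r["trait"],
            chrom=r["chrom"],
            interval=GenomicInterval(r["chrom"], int(r["start_bp"]), int(r["end_bp"])),
            member_ids=_split_ids(r.get("member_ids", "")),
        )
        for _, r in df.iterrows()
    ]


def _to_tsv_with_header(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.strip().splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures: the published common-interval tables
# ---------------------------------------------------------------------------

_FIXTURE_SHA256 = {
    "class1_common_intervals.tsv": "01b0afe57a67912f41b12e7468905dd388fd5fed5b0c3dc49ca83d1911dcd053",
    "class2_common_intervals.tsv": "4473657e34bc9600d0d91a99c0a5d7537373286b047b344aeb12a95a0a637d05",
}


@dataclass(frozen=True)
class Class1FixtureRow:
    number: int
    chrom: str
    qtl_interval: GenomicInterval
    qtn_interval: GenomicInterval
    known_genes: tuple[str, ...]


@dataclass(frozen=True)
class Class2FixtureRow:
    number: int
    chrom: str
    region: GenomicInterval
    data_resource: DataResource
    traits: frozenset[str]
    known_genes: tuple[str, ...]


@dataclass(frozen=True)
class FixtureSet:
    """The transcribed common-interval tables: 19 Class1 + 40 Class2 rows."""

    table1_rows: tuple[Class1FixtureRow, ...]
    table2_rows: tuple[Class2FixtureRow, ...]

    # -- materialization helpers ------------------------------------------

    def table1_qtl_clusters(self) -> list[QtlCluster]:
        """Distinct QTL-cluster intervals of the Class1 table (trait KRN).

        Member/study provenance is not printed, so these carry empty member
        sets; they exist to drive interval-level common-interval detection.
        """
        out, seen = [], set()
        for row in self.table1_rows:
            key = (row.chrom, row.qtl_interval)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                QtlCluster(
                    cluster_id=f"T1_QTL_{len(out) + 1:02d}",
                    trait="KRN",
                    chrom=row.chrom,
                    interval=row.qtl_interval,
                )
            )
        return out

    def table1_qtn_clusters(self) -> list[QtnCluster]:
        out = []
        for row in self.table1_rows:
            out.append(
                QtnCluster(
                    cluster_id=f"T1_QTN_{row.number:02d}",
                    trait="KRN",
                    chrom=row.chrom,
                    interval=row.qtn_interval,
                )
            )
        return out

    def table1_known_gene_models(self) -> list[GeneModel]:
        """Synthetic point genes for the printed known-gene cells.

        The source prints gene names only, so each non-empty cell becomes one
        synthetic 1 kb gene placed at the midpoint of that row's common
        interval (the QTL∩QTN overlap region); where a cell lists two genes
        appearing in two sibling rows, one gene is placed per row.
        """
        genes = []
        used: set[str] = set()
        for row in self.table1_rows:
            if not row.known_genes:
                continue
            name = next(
                (g for g in row.known_genes if g not in used), row.known_genes[0]
            )
            used.add(name)
            from .core import intersection

            region = intersection([row.qtl_interval, row.qtn_interval])
            assert region is not None
            mid = (region.start_bp + region.end_bp) // 2
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=row.chrom,
                    interval=GenomicInterval(row.chrom, mid, mid + 1000),
                    annotation=", ".join(row.known_genes) + " (synthetic placement)",
                )
            )
        return genes

    def table2_cis(self) -> list[Class2CI]:
        """The Class2 rows as common-interval objects with resource provenance."""
        out = []
        for row in self.table2_rows:
            resources_ = {
                DataResource.QTL_CLUSTER: frozenset({"QTL"}),
                DataResource.QTN_CLUSTER: frozenset({"QTN"}),
                DataResource.BOTH: frozenset({"QTL", "QTN"}),
            }[row.data_resource]
            members = frozenset(
                f"T2_{row.number:02d}_{res}{i}"
                for i, res in enumerate(sorted(resources_))
            )
            out.append(
                Class2CI(
                    ci_id=f"T2_CI_{row.number:02d}",
                    chrom=row.chrom,
                    region=row.region,
                    member_cluster_ids=members,
                    traits=row.traits,
                    member_resources=resources_,
                    known_genes=row.known_genes,
                )
            )
        return out

    def table2_known_gene_models(self) -> list[GeneModel]:
        """Synthetic point genes for the Class2 known-gene cells (BA2, ACO2)."""
        genes = []
        for row in self.table2_rows:
            for name in row.known_genes:
                mid = (row.region.start_bp + row.region.end_bp) // 2
                genes.append(
                    GeneModel(
                        gene_id=name,
                        chrom=row.chrom,
                        interval=GenomicInterval(row.chrom, mid, mid + 1000),
                        annotation=f"{name} (synthetic placement)",
                    )
                )
        return genes


def _fixture_text(name: str) -> str:
    ref = resources.files("earmeta").joinpath(f"data/{name}")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FormatError(f"packaged fixture {name} checksum mismatch ({digest})")
    return raw.decode("utf-8")


def _split_genes(cell: str) -> tuple[str, ...]:
    return tuple(g.strip() for g in cell.split(",") if g.strip()) if cell else ()


def load_fixtures() -> FixtureSet:
    """Load the packaged common-interval tables (checksum-verified)."""
    t1 = pd.read_csv(
        _stdio.StringIO(_fixture_text("class1_common_intervals.tsv")),
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
    )
    rows1 = tuple(
        Class1FixtureRow(
            number=int(r["number"]),
            chrom=r["chrom"],
            qtl_interval=GenomicInterval.from_mb(
                r["chrom"], float(r["qtl_start_mb"]), float(r["qtl_end_mb"])
            ),
            qtn_interval=GenomicInterval.from_mb(
                r["chrom"], float(r["qtn_start_mb"]), float(r["qtn_end_mb"])
            ),
            known_genes=_split_genes(r.get("known_genes", "")),
        )
        for _, r in t1.iterrows()
    )
    t2 = pd.read_csv(
        _stdio.StringIO(_fixture_text("class2_common_intervals.tsv")),
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
    )
    resource_of = {d.value: d for d in DataResource}
    rows2 = tuple(
        Class2FixtureRow(
            number=int(r["number"]),
            chrom=r["chrom"],
            region=GenomicInterval.from_mb(
                r["chrom"], float(r["start_mb"]), float(r["end_mb"])
            ),
            data_resource=resource_of[r["data_resource"]],
            traits=frozenset(t.strip() for t in r["traits"].split(",")),
            known_genes=_split_genes(r.get("known_genes", "")),
        )
        for _, r in t2.iterrows()
    )
    fs = FixtureSet(rows1, rows2)
    if len(fs.table1_rows) != 19 or len(fs.table2_rows) != 40:
        raise FormatError(
            f"fixture row counts {len(fs.table1_rows)}/{len(fs.table2_rows)}, expected 19/40"
        )
    return fs
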