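"""End-to-end pipeline driver.

Executes normalize → cluster-qtl → cluster-qtn → common-intervals →
candidates → summarize from a single YAML-configurable description, writing
TSV + BED + report artifacts into an output directory.  Outputs are
deterministic: identical inputs and configuration reproduce byte-identical
files (content files carry parameter headers but no timestamps), and the
effective configuration is echoed into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .candidate_genes import assign_candidates, assignments_to_frame, summarize_candidates
from .common_intervals import find_class1, find_class2, overlay_known_genes
from .core import MB, FormatError
from .io import (
    QtlTableDialect,
    QtnTableDialect,
    read_gff3_genes,
    read_qtl_tsv,
    read_qtn_tsv,
    write_bed,
    write_qtl_clusters_tsv,
    write_qtl_tsv,
    write_qtn_clusters_tsv,
    write_qtn_tsv,
    _to_tsv_with_header,
)
from .normalization import (
    MarkerMap,
    PositionLookup,
    lift_qtns,
    resolve_qtls,
    write_rejects_report,
)
from .qtl_clustering import call_qtl_clusters
from .qtn_clustering import call_qtn_clusters
from .report import summarize
from .vocab import PathwayVocabulary, default_vocabulary

logger = logging.getLogger("earmeta.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the failing stage's name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and stage parameters; flags mirror the CLI options."""

    out_dir: str
    qtl: Optional[str] = None
    qtn: Optional[str] = None
    markers: Optional[str] = None
    position_lookup: Optional[str] = None
    identity_fallback: bool = True
    genes: Optional[str] = None
    expressed: Optional[str] = None
    vocab: Optional[str] = None

    min_studies: int = 3
    span_threshold_mb: float = 30.0
    min_studies_large: int = 5
    region_mode: str = "union"
    window_mb: float = 0.5
    min_qtn_count: int = 3
    dedup_pos: bool = False
    window_mode: str = "anchored"
    class2_mode: str = "clique"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def effective_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def _require_file(path: Optional[str], what: str, stage: str) -> Path:
    if not path:
        raise PipelineError(stage, FileNotFoundError(f"no {what} input configured"))
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, FileNotFoundError(f"{what} file not found: {p}"))
    return p


def _header(cfg: PipelineConfig, stage: str, **params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"earmeta {__version__} stage={stage} {kv}".strip()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Stage errors abort with the failing stage named; outputs written by
    earlier stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.yaml").write_text(cfg.effective_yaml(), encoding="utf-8")

    # --- normalize --------------------------------------------------------
    stage = "normalize"
    try:
        qtl_path = _require_file(cfg.qtl, "QTL table", stage)
        qtn_path = _require_file(cfg.qtn, "QTN table", stage)
        qtl_read = read_qtl_tsv(qtl_path, QtlTableDialect())
        qtn_read = read_qtn_tsv(qtn_path, QtnTableDialect())
        logger.info(
            "[%s] read %d QTL rows (%d bad), %d QTN rows (%d bad)",
            stage, len(qtl_read.records), len(qtl_read.errors),
            len(qtn_read.records), len(qtn_read.errors),
        )
        markers = (
            MarkerMap.from_tsv(_require_file(cfg.markers, "marker map", stage))
            if cfg.markers
            else MarkerMap({})
        )
        lookup = (
            PositionLookup.from_tsv(
                _require_file(cfg.position_lookup, "position lookup", stage),
                identity_fallback=cfg.identity_fallback,
            )
            if cfg.position_lookup
            else (PositionLookup.identity() if cfg.identity_fallback else PositionLookup())
        )
        qtl_norm = resolve_qtls(qtl_read.records, markers)
        qtn_norm = lift_qtns(qtn_read.records, lookup)
        write_qtl_tsv(qtl_norm.resolved, out / "normalized_qtl.tsv")
        write_qtn_tsv(qtn_norm.resolved, out / "normalized_qtn.tsv")
        write_rejects_report(qtl_norm, out / "qtl_rejects.tsv")
        write_rejects_report(qtn_norm, out / "qtn_rejects.tsv")
        logger.info(
            "[%s] resolved %d/%d QTLs, %d/%d QTNs",
            stage, len(qtl_norm.resolved), qtl_norm.n_input,
            len(qtn_norm.resolved), qtn_norm.n_input,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - named-stage reporting
        raise PipelineError(stage, exc) from exc

    # --- cluster-qtl ------------------------------------------------------
    stage = "cluster-qtl"
    try:
        qtl_clusters = call_qtl_clusters(
            qtl_norm.resolved,
            min_studies=cfg.min_studies,
            span_threshold_bp=int(cfg.span_threshold_mb * MB),
            min_studies_large=cfg.min_studies_large,
            region_mode=cfg.region_mode,
        )
        write_qtl_clusters_tsv(
            qtl_clusters,
            out / "qtl_clusters.tsv",
            header=_header(cfg, stage, min_studies=cfg.min_studies,
                           span_threshold_mb=cfg.span_threshold_mb,
                           min_studies_large=cfg.min_studies_large,
                           region_mode=cfg.region_mode),
        )
        write_bed(qtl_clusters, out / "qtl_clusters.bed")
        logger.info("[%s] %d QTL clusters", stage, len(qtl_clusters))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- cluster-qtn ------------------------------------------------------
    stage = "cluster-qtn"
    try:
        qtn_clusters = call_qtn_clusters(
            qtn_norm.resolved,
            window_bp=int(cfg.window_mb * MB),
            min_count=cfg.min_qtn_count,
            dedup_pos=cfg.dedup_pos,
            window_mode=cfg.window_mode,
        )
        write_qtn_clusters_tsv(
            qtn_clusters,
            out / "qtn_clusters.tsv",
            header=_header(cfg, stage, window_mb=cfg.window_mb,
                           min_count=cfg.min_qtn_count, dedup_pos=cfg.dedup_pos,
                           window_mode=cfg.window_mode),
        )
        write_bed(qtn_clusters, out / "qtn_clusters.bed")
        logger.info("[%s] %d QTN clusters", stage, len(qtn_clusters))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- common intervals -------------------------------------------------
    stage = "ci"
    try:
        genes = []
        vocab = None
        if cfg.genes:
            expressed = set()
            if cfg.expressed:
                expressed = {
                    line.strip()
                    for line in Path(
                        _require_file(cfg.expressed, "expressed-ID list", stage)
                    ).read_text(encoding="utf-8").splitlines()
                    if line.strip()
                }
            vocab = (
                PathwayVocabulary.from_yaml(_require_file(cfg.vocab, "vocabulary", stage))
                if cfg.vocab
                else default_vocabulary()
            )
            genes = read_gff3_genes(
                _require_file(cfg.genes, "gene GFF3", stage), expressed, vocab
            )
        class1 = find_class1(qtl_clusters, qtn_clusters)
        class2 = find_class2(
            list(qtl_clusters) + list(qtn_clusters), class2_mode=cfg.class2_mode
        )
        if genes:
            class1 = overlay_known_genes(class1, genes)
            class2 = overlay_known_genes(class2, genes)
        _write_class1(class1, out / "class1_ci.tsv", _header(cfg, stage))
        _write_class2(class2, out / "class2_ci.tsv", _header(cfg, stage, mode=cfg.class2_mode))
        write_bed(class1, out / "class1_ci.bed")
        write_bed(class2, out / "class2_ci.bed")
        logger.info("[%s] %d Class1, %d Class2", stage, len(class1), len(class2))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- candidates -------------------------------------------------------
    stage = "candidates"
    assignments = []
    try:
        if genes and vocab is not None:
            assignments = assign_candidates(
                list(qtl_clusters) + list(qtn_clusters), genes, vocab
            )
            _to_tsv_with_header(
                assignments_to_frame(assignments),
                out / "candidates.tsv",
                _header(cfg, stage),
            )
            cand_summary = summarize_candidates(
                assignments, list(qtl_clusters) + list(qtn_clusters)
            )
            (out / "candidates_summary.yaml").write_text(
                yaml.safe_dump(cand_summary, sort_keys=True), encoding="utf-8"
            )
            logger.info("[%s] %d assignments", stage, len(assignments))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- summarize --------------------------------------------------------
    stage = "report"
    try:
        rep = summarize(
            qtl_records=qtl_norm.resolved,
            qtn_records=qtn_norm.resolved,
            qtl_clusters=qtl_clusters,
            qtn_clusters=qtn_clusters,
            class1=class1,
            class2=class2,
        )
        rep.to_tsv(out / "summary.tsv")
        (out / "summary.txt").write_text(rep.pretty(), encoding="utf-8")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    return out


def _write_class1(cis, path, header: str) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "ci_id": ci.ci_id,
                "trait": ci.trait,
                "chrom": ci.chrom,
                "start_bp": ci.overlap_region.start_bp,
                "end_bp": ci.overlap_region.end_bp,
                "qtl_cluster_id": ci.qtl_cluster_id,
                "qtn_cluster_id": ci.qtn_cluster_id,
                "known_genes": ",".join(ci.known_genes),
            }
            for ci in cis
        ],
        columns=["ci_id", "trait", "chrom", "start_bp", "end_bp",
                 "qtl_cluster_id", "qtn_cluster_id", "known_genes"],
    )
    _to_tsv_with_header(df, path, header)


def _write_class2(cis, path, header: str) -> None:
    import pandas as pd

    from .common_intervals import classify_resource

    df = pd.DataFrame(
        [
            {
                "ci_id": ci.ci_id,
                "chrom": ci.chrom,
                "start_bp": ci.region.start_bp,
                "end_bp": ci.region.end_bp,
                "data_resource": classify_resource(ci).value,
                "traits": ",".join(sorted(ci.traits)),
                "members": ",".join(sorted(ci.member_cluster_ids)),
                "known_genes": ",".join(ci.known_genes),
            }
            for ci in cis
        ],
        columns=["ci_id", "chrom", "start_bp", "end_bp", "data_resource",
                 "traits", "members", "known_genes"],
    )
    _to_tsv_with_header(df, path, header)
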