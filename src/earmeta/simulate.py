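"""Synthetic QTL studies, QTN panels and gene annotations with planted truth.

The generator emulates the statistical structure the meta-analysis assumes:

* several independent studies contribute same-trait QTL intervals that all
  contain a planted site's center (co-location at true loci), on top of
  scattered background intervals whose combined distinct-study support never
  reaches the clustering threshold at any point;
* GWAS panels contain planted hotspots of ≥3 same-trait QTNs within less
  than one window width, plus sparse background positions whose chance of
  forming a spurious ≥3-in-a-window triple is analytically bounded below
  0.01 per (trait, chromosome) and additionally excluded by rejection
  sampling;
* gene annotations contain pathway-keyword genes planted inside truth
  intervals (IM-expressed) among neutral background genes.

Everything is deterministic under (config, seed): each generator draws from
its own seeded substream, and an infeasible background regime raises after
bounded retries instead of silently degrading the guarantees.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    MB,
    ConfigError,
    GeneModel,
    GenomicInterval,
    QtlRecord,
    QtnRecord,
    merge_overlapping,
    union_span,
)
from .vocab import PathwayVocabulary, default_vocabulary

__all__ = [
    "PlantedQtlSite",
    "PlantedQtnHotspot",
    "PlantedGene",
    "SimulationConfig",
    "TruthRow",
    "TruthTable",
    "simulate_qtl_studies",
    "simulate_qtn_panel",
    "simulate_genes",
    "simulate_all",
    "SimBundle",
]

_MAX_RETRIES = 50


@dataclass(frozen=True)
class PlantedQtlSite:
    """A true QTL locus: every supporting study's interval contains center_bp."""

    chrom: str
    center_bp: int
    trait: str
    n_supporting_studies: int = 3
    span_spread_bp: int = 3 * MB  # maximum half-span of a member interval

    @property
    def site_id(self) -> str:
        return f"QTL_SITE_{self.chrom}_{self.center_bp}"


@dataclass(frozen=True)
class PlantedQtnHotspot:
    """A true GWAS hotspot: n_qtns positions within spread_bp of center_bp."""

    chrom: str
    center_bp: int
    trait: str
    n_qtns: int = 3
    spread_bp: int = 300_000  # must stay below the calling window width

    @property
    def site_id(self) -> str:
        return f"QTN_HOT_{self.chrom}_{self.center_bp}"


@dataclass(frozen=True)
class PlantedGene:
    """A pathway-annotated, IM-expressed gene planted inside a truth site."""

    site_id: str
    pathway: str


def _default_qtl_sites() -> tuple[PlantedQtlSite, ...]:
    return (
        PlantedQtlSite("1", 50 * MB, "KRN", 4, 3 * MB),
        PlantedQtlSite("2", 120 * MB, "EL", 3, 2 * MB),
        PlantedQtlSite("3", 200 * MB, "KRN", 5, 5 * MB),
        PlantedQtlSite("5", 60 * MB, "ED", 3, 1 * MB),
        PlantedQtlSite("7", 30 * MB, "KNPR", 4, 2 * MB),
        PlantedQtlSite("9", 150 * MB, "KRN", 6, 8 * MB),
    )


def _default_qtn_hotspots() -> tuple[PlantedQtnHotspot, ...]:
    return (
        PlantedQtnHotspot("1", 40 * MB, "KRN", 4, 300_000),
        PlantedQtnHotspot("2", 10 * MB, "CD", 3, 200_000),
        PlantedQtnHotspot("4", 180 * MB, "KRN", 5, 400_000),
        PlantedQtnHotspot("5", 220 * MB, "ED", 3, 250_000),
        PlantedQtnHotspot("8", 90 * MB, "EL", 3, 300_000),
        PlantedQtnHotspot("10", 140 * MB, "KRN", 4, 350_000),
    )


def _default_planted_genes() -> tuple[PlantedGene, ...]:
    return (
        PlantedGene("QTL_SITE_1_50000000", "auxin"),
        PlantedGene("QTL_SITE_3_200000000", "WD40"),
        PlantedGene("QTN_HOT_1_40000000", "ethylene"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator (all sizes in base pairs)."""

    n_chromosomes: int = 10
    chrom_length_bp: int = 250 * MB
    n_studies: int = 8
    traits: tuple[str, ...] = ("KRN", "EL", "ED", "KNPR", "EW", "CD", "KWPE", "CW")
    planted_qtl_sites: tuple[PlantedQtlSite, ...] = field(
        default_factory=_default_qtl_sites
    )
    background_qtl_per_study_per_trait: int = 1
    planted_qtn_hotspots: tuple[PlantedQtnHotspot, ...] = field(
        default_factory=_default_qtn_hotspots
    )
    background_qtn_per_trait_per_chrom: float = 3.0
    window_bp: int = 500_000
    min_studies: int = 3
    min_qtn_count: int = 3
    n_genes: int = 150
    planted_pathway_genes: tuple[PlantedGene, ...] = field(
        default_factory=_default_planted_genes
    )
    seed: int = 1

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(str(i + 1) for i in range(self.n_chromosomes))

    def validate(self) -> None:
        for h in self.planted_qtn_hotspots:
            if h.spread_bp > self.window_bp:
                raise ConfigError(
                    f"hotspot {h.site_id}: spread {h.spread_bp} exceeds window "
                    f"{self.window_bp}; it would not qualify by construction"
                )
        for s in self.planted_qtl_sites:
            if s.n_supporting_studies > self.n_studies:
                raise ConfigError(
                    f"site {s.site_id} needs {s.n_supporting_studies} studies, "
                    f"pool has {self.n_studies}"
                )
        # Analytic bound on spurious background triples: with n uniform
        # positions on length L, E[#anchored windows holding ≥3] ≤
        # n·C(n-1,2)·(w/L)², required < 0.01 per (trait, chromosome).
        n = self.background_qtn_per_trait_per_chrom
        if n >= 3:
            bound = n * math.comb(int(math.ceil(n)) - 1 + 2, 2) * (
                self.window_bp / self.chrom_length_bp
            ) ** 2
            if bound >= 0.01:
                raise ConfigError(
                    f"background QTN density too high: spurious-triple bound "
                    f"{bound:.3g} ≥ 0.01"
                )


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthRow:
    site_id: str
    site_type: str  # "qtl_site" | "qtn_hotspot"
    chrom: str
    interval: GenomicInterval
    record_ids: tuple[str, ...]
    gene_ids: tuple[str, ...] = ()


@dataclass
class TruthTable:
    """Planted-site ground truth; every planted record id appears exactly once."""

    rows: dict[str, TruthRow] = field(default_factory=dict)
    n_background: int = 0

    def add(self, row: TruthRow) -> None:
        if row.site_id in self.rows:
            raise ValueError(f"duplicate truth row {row.site_id}")
        for other in self.rows.values():
            dup = set(other.record_ids) & set(row.record_ids)
            if dup:
                raise ValueError(f"record(s) {dup} in two truth rows")
        self.rows[row.site_id] = row

    @property
    def n_planted_records(self) -> int:
        return sum(len(r.record_ids) for r in self.rows.values())

    def merged(self, other: "TruthTable") -> "TruthTable":
        t = TruthTable(dict(self.rows), self.n_background + other.n_background)
        for row in other.rows.values():
            t.add(row)
        return t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": r.site_id,
                    "site_type": r.site_type,
                    "chrom": r.chrom,
                    "start_bp": r.interval.start_bp,
                    "end_bp": r.interval.end_bp,
                    "record_ids": ",".join(r.record_ids),
                    "gene_ids": ",".join(r.gene_ids),
                }
                for r in self.rows.values()
            ],
            columns=[
                "site_id",
                "site_type",
                "chrom",
                "start_bp",
                "end_bp",
                "record_ids",
                "gene_ids",
            ],
        )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# QTL studies
# ---------------------------------------------------------------------------


def _max_distinct_study_support(records: Sequence[QtlRecord]) -> int:
    """Highest number of distinct studies covering any single point."""
    per_study: dict[str, list[GenomicInterval]] = defaultdict(list)
    for r in records:
        per_study[r.study_id].append(r.interval)
    events: list[tuple[int, int]] = []
    for ivs in per_study.values():
        for iv in merge_overlapping(ivs):
            events.append((iv.start_bp, +1))
            events.append((iv.end_bp, -1))
    events.sort()
    depth = best = 0
    for _pos, delta in events:
        depth += delta
        best = max(best, depth)
    return best


def simulate_qtl_studies(cfg: SimulationConfig) -> tuple[list[QtlRecord], TruthTable]:
    """Generate normalized QTL records with planted co-location structure.

    Planted members all contain their site center (half-spans drawn uniformly
    within the spread); background intervals are uniform with lengths of
    1–10 Mb, rejection-sampled so that (a) background of a trait never
    touches that trait's planted member intervals and (b) background-only
    distinct-study support stays below ``min_studies`` at every point.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    studies = [f"S{i + 1:02d}" for i in range(cfg.n_studies)]
    records: list[QtlRecord] = []
    truth = TruthTable()

    planted_by_trait: dict[str, list[GenomicInterval]] = defaultdict(list)
    for site in cfg.planted_qtl_sites:
        chosen = rng.choice(cfg.n_studies, size=site.n_supporting_studies, replace=False)
        member_ivs, ids = [], []
        for k, si in enumerate(sorted(chosen)):
            min_half = max(50_000, site.span_spread_bp // 20)
            left = int(rng.integers(min_half, site.span_spread_bp + 1))
            right = int(rng.integers(min_half, site.span_spread_bp + 1))
            start = max(0, site.center_bp - left)
            end = min(cfg.chrom_length_bp, site.center_bp + right)
            iv = GenomicInterval(site.chrom, start, end)
            rid = f"P_{site.site_id}_{k + 1}"
            records.append(
                QtlRecord(
                    record_id=rid,
                    study_id=studies[si],
                    trait=site.trait,
                    chrom=site.chrom,
                    interval=iv,
                    source="planted",
                )
            )
            member_ivs.append(iv)
            ids.append(rid)
            planted_by_trait[site.trait].append(iv)
        truth.add(
            TruthRow(
                site_id=site.site_id,
                site_type="qtl_site",
                chrom=site.chrom,
                interval=union_span(member_ivs),
                record_ids=tuple(ids),
            )
        )

    n_bg = cfg.background_qtl_per_study_per_trait * cfg.n_studies * len(cfg.traits)
    for attempt in range(_MAX_RETRIES):
        background: list[QtlRecord] = []
        idx = 0
        ok = True
        for study in studies:
            for trait in cfg.traits:
                for _ in range(cfg.background_qtl_per_study_per_trait):
                    iv = None
                    for _try in range(100):
                        chrom = str(int(rng.integers(1, cfg.n_chromosomes + 1)))
                        length = int(rng.integers(1 * MB, 10 * MB))
                        start = int(rng.integers(0, cfg.chrom_length_bp - length))
                        cand = GenomicInterval(chrom, start, start + length)
                        if any(
                            cand.chrom == piv.chrom
                            and max(cand.start_bp, piv.start_bp)
                            < min(cand.end_bp, piv.end_bp)
                            for piv in planted_by_trait.get(trait, ())
                        ):
                            continue
                        iv = cand
                        break
                    if iv is None:
                        ok = False
                        break
                    idx += 1
                    background.append(
                        QtlRecord(
                            record_id=f"B_QTL_{idx:04d}",
                            study_id=study,
                            trait=trait,
                            chrom=iv.chrom,
                            interval=iv,
                            source="background",
                        )
                    )
                if not ok:
                    break
            if not ok:
                break
        if ok:
            # background-only support must stay below the clustering threshold
            grouped: dict[tuple[str, str], list[QtlRecord]] = defaultdict(list)
            for r in background:
                grouped[(r.trait, r.interval.chrom)].append(r)
            if all(
                _max_distinct_study_support(g) < cfg.min_studies
                for g in grouped.values()
            ):
                truth.n_background = len(background)
                return records + background, truth
    raise ConfigError(
        f"background QTL regime infeasible after {_MAX_RETRIES} retries "
        f"({n_bg} records requested)"
    )


# ---------------------------------------------------------------------------
# QTN panel
# ---------------------------------------------------------------------------


def simulate_qtn_panel(cfg: SimulationConfig) -> tuple[list[QtnRecord], TruthTable]:
    """Generate a QTN panel with planted hotspots and bounded background.

    Background positions per (trait, chromosome) are Poisson with the
    configured rate and rejection-sampled so that no three background
    positions of one trait fall inside one window and none lands within a
    window width of a same-trait planted hotspot center.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    studies = [f"G{i + 1:02d}" for i in range(cfg.n_studies)]
    records: list[QtnRecord] = []
    truth = TruthTable()

    hot_by_trait: dict[str, list[PlantedQtnHotspot]] = defaultdict(list)
    for hot in cfg.planted_qtn_hotspots:
        hot_by_trait[hot.trait].append(hot)
        half = hot.spread_bp // 2
        offsets = rng.integers(-half, half + 1, size=hot.n_qtns)
        offsets[0] = -half  # pin the extremes so the spread is realized
        offsets[-1] = half if hot.n_qtns > 1 else offsets[-1]
        positions = sorted(int(hot.center_bp + o) for o in offsets)
        ids = []
        for k, pos in enumerate(positions):
            rid = f"P_{hot.site_id}_{k + 1}"
            records.append(
                QtnRecord(
                    record_id=rid,
                    study_id=studies[int(rng.integers(0, len(studies)))],
                    trait=hot.trait,
                    chrom=hot.chrom,
                    pos_bp=pos,
                    source="planted",
                )
            )
            ids.append(rid)
        truth.add(
            TruthRow(
                site_id=hot.site_id,
                site_type="qtn_hotspot",
                chrom=hot.chrom,
                interval=GenomicInterval(hot.chrom, positions[0], positions[-1] + 1),
                record_ids=tuple(ids),
            )
        )

    idx = 0
    for trait in cfg.traits:
        for chrom in cfg.chroms:
            n = int(rng.poisson(cfg.background_qtn_per_trait_per_chrom))
            accepted: list[int] = []
            centers = [
                h.center_bp for h in hot_by_trait.get(trait, ()) if h.chrom == chrom
            ]
            for _ in range(n):
                placed = False
                for _try in range(_MAX_RETRIES):
                    pos = int(rng.integers(0, cfg.chrom_length_bp))
                    if any(abs(pos - c) < cfg.window_bp for c in centers):
                        continue
                    trial = sorted(accepted + [pos])
                    if any(
                        trial[i + cfg.min_qtn_count - 1] - trial[i] < cfg.window_bp
                        for i in range(len(trial) - cfg.min_qtn_count + 1)
                    ):
                        continue
                    accepted.append(pos)
                    placed = True
                    break
                if not placed:
                    raise ConfigError(
                        "background QTN regime infeasible: rejection sampling "
                        f"exhausted on chrom {chrom}, trait {trait}"
                    )
            for pos in accepted:
                idx += 1
                records.append(
                    QtnRecord(
                        record_id=f"B_QTN_{idx:04d}",
                        study_id=studies[int(rng.integers(0, len(studies)))],
                        trait=trait,
                        chrom=chrom,
                        pos_bp=pos,
                        source="background",
                    )
                )
    truth.n_background = idx
    return records, truth


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

_NEUTRAL_ANNOTATIONS = (
    "hypothetical protein",
    "uncharacterized protein",
    "protein of unknown function",
    "putative membrane protein",
)

_GENE_LENGTH_BP = 3_000


def _nominal_site_intervals(cfg: SimulationConfig) -> dict[str, GenomicInterval]:
    """Config-derived intervals guaranteed inside every member of a site."""
    out = {}
    for s in cfg.planted_qtl_sites:
        out[s.site_id] = GenomicInterval(
            s.chrom, s.center_bp - _GENE_LENGTH_BP, s.center_bp + _GENE_LENGTH_BP
        )
    for h in cfg.planted_qtn_hotspots:
        out[h.site_id] = GenomicInterval(
            h.chrom, h.center_bp - _GENE_LENGTH_BP, h.center_bp + _GENE_LENGTH_BP
        )
    return out


def simulate_genes(
    cfg: SimulationConfig,
    vocab: Optional[PathwayVocabulary] = None,
) -> tuple[list[GeneModel], TruthTable]:
    """Generate gene models: planted pathway genes inside truth sites plus
    neutral background genes with Bernoulli(0.5) IM expression."""
    cfg.validate()
    vocab = vocab or default_vocabulary()
    rng = _rng(cfg, 2)
    sites = _nominal_site_intervals(cfg)
    genes: list[GeneModel] = []
    truth = TruthTable()
    planted_at: dict[str, list[str]] = defaultdict(list)

    for i, pg in enumerate(cfg.planted_pathway_genes, start=1):
        if pg.site_id not in sites:
            raise ConfigError(f"planted gene references unknown site {pg.site_id}")
        if pg.pathway not in vocab.pathways:
            raise ConfigError(f"planted gene references unknown pathway {pg.pathway}")
        site_iv = sites[pg.site_id]
        keyword = vocab.pathways[pg.pathway][0]
        gid = f"PGENE{i:03d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=site_iv.chrom,
                interval=GenomicInterval(
                    site_iv.chrom, site_iv.start_bp, site_iv.start_bp + _GENE_LENGTH_BP
                ),
                strand="+",
                annotation=f"{keyword} domain protein",
                im_expressed=True,
            )
        )
        planted_at[pg.site_id].append(gid)

    for site_id, gids in planted_at.items():
        iv = sites[site_id]
        truth.add(
            TruthRow(
                site_id=f"GENES_{site_id}",
                site_type="planted_genes",
                chrom=iv.chrom,
                interval=iv,
                record_ids=(),
                gene_ids=tuple(gids),
            )
        )

    site_spans = list(sites.values())
    for i in range(cfg.n_genes):
        for _try in range(_MAX_RETRIES):
            chrom = str(int(rng.integers(1, cfg.n_chromosomes + 1)))
            start = int(rng.integers(0, cfg.chrom_length_bp - _GENE_LENGTH_BP))
            iv = GenomicInterval(chrom, start, start + _GENE_LENGTH_BP)
            # keep background genes out of planted sites so truth stays exact
            if not any(
                iv.chrom == s.chrom
                and max(iv.start_bp, s.start_bp) < min(iv.end_bp, s.end_bp)
                for s in site_spans
            ):
                break
        genes.append(
            GeneModel(
                gene_id=f"BGENE{i + 1:04d}",
                chrom=iv.chrom,
                interval=iv,
                strand="+" if rng.random() < 0.5 else "-",
                annotation=_NEUTRAL_ANNOTATIONS[
                    int(rng.integers(0, len(_NEUTRAL_ANNOTATIONS)))
                ],
                im_expressed=bool(rng.random() < 0.5),
            )
        )
    truth.n_background = cfg.n_genes
    return genes, truth


# ---------------------------------------------------------------------------
# Convenience bundle
# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    qtl_records: list[QtlRecord]
    qtn_records: list[QtnRecord]
    genes: list[GeneModel]
    truth: TruthTable

    @property
    def expressed_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes if g.im_expressed}


def simulate_all(cfg: SimulationConfig) -> SimBundle:
    """Run all three generators under one config/seed."""
    qtl, t1 = simulate_qtl_studies(cfg)
    qtn, t2 = simulate_qtn_panel(cfg)
    genes, t3 = simulate_genes(cfg)
    return SimBundle(qtl, qtn, genes, t1.merged(t2).merged(t3))
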