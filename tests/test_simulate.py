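"""Synthetic-data generator: planted structure, determinism, recovery."""

import pytest

from earmeta.candidate_genes import assign_candidates
from earmeta.core import MB, ConfigError, GenomicInterval, QtlCluster, overlaps
from earmeta.io import (
    read_gff3_genes,
    read_qtl_tsv,
    read_qtn_tsv,
    write_gff3_genes,
    write_qtl_tsv,
    write_qtn_tsv,
)
from earmeta.qtl_clustering import call_qtl_clusters
from earmeta.qtn_clustering import call_qtn_clusters
from earmeta.simulate import (
    PlantedGene,
    PlantedQtlSite,
    PlantedQtnHotspot,
    SimulationConfig,
    simulate_genes,
    simulate_qtl_studies,
    simulate_qtn_panel,
)
from earmeta.vocab import default_vocabulary


class TestQtlSimulation:
    def test_minimal_construction(self):
        cfg = SimulationConfig(
            planted_qtl_sites=(
                PlantedQtlSite("1", 50 * MB, "KRN", 3, 2 * MB),
                PlantedQtlSite("2", 80 * MB, "EL", 3, 2 * MB),
            ),
            background_qtl_per_study_per_trait=0,
            seed=1,
        )
        records, truth = simulate_qtl_studies(cfg)
        assert len(truth.rows) == 2
        assert len(records) == 6
        assert truth.n_planted_records == 6 and truth.n_background == 0

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=1)
        for name in ("a", "b"):
            records, _ = simulate_qtl_studies(cfg)
            write_qtl_tsv(records, tmp_path / f"{name}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_members_contain_site_center(self, sim_config):
        records, truth = simulate_qtl_studies(sim_config)
        by_id = {r.record_id: r for r in records}
        for site in sim_config.planted_qtl_sites:
            row = truth.rows[site.site_id]
            for rid in row.record_ids:
                assert by_id[rid].interval.contains_point(site.center_bp)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_planted_cluster_recovery(self, seed):
        cfg = SimulationConfig(seed=seed)
        records, truth = simulate_qtl_studies(cfg)
        clusters = call_qtl_clusters(records)
        truth_ivs = [r.interval for r in truth.rows.values()]
        # recall 1.0: every planted site overlapped by a called cluster
        for iv in truth_ivs:
            assert any(overlaps(c.interval, iv) for c in clusters)
        # no spurious cluster outside every truth interval
        for c in clusters:
            assert any(overlaps(c.interval, iv) for iv in truth_ivs)

    def test_infeasible_background_raises(self):
        cfg = SimulationConfig(
            n_chromosomes=1,
            chrom_length_bp=12 * MB,
            background_qtl_per_study_per_trait=4,
            background_qtn_per_trait_per_chrom=0.0,
            traits=("KRN",),
            planted_qtl_sites=(PlantedQtlSite("1", 6 * MB, "KRN", 3, 2 * MB),),
            seed=1,
        )
        with pytest.raises(ConfigError, match="infeasible"):
            simulate_qtl_studies(cfg)

    def test_generated_file_parses_cleanly(self, tmp_path, sim_config):
        records, _ = simulate_qtl_studies(sim_config)
        write_qtl_tsv(records, tmp_path / "qtl.tsv")
        res = read_qtl_tsv(tmp_path / "qtl.tsv")
        assert not res.errors and len(res.records) == len(records)


class TestQtnSimulation:
    def test_single_hotspot_single_cluster(self):
        cfg = SimulationConfig(
            planted_qtn_hotspots=(PlantedQtnHotspot("1", 50 * MB, "KRN", 3, 300_000),),
            background_qtn_per_trait_per_chrom=0.0,
            seed=1,
        )
        records, truth = simulate_qtn_panel(cfg)
        clusters = call_qtn_clusters(records)
        assert len(clusters) == 1
        assert len(truth.rows) == 1

    def test_two_qtn_hotspot_below_threshold(self):
        cfg = SimulationConfig(
            planted_qtn_hotspots=(PlantedQtnHotspot("1", 50 * MB, "KRN", 2, 200_000),),
            background_qtn_per_trait_per_chrom=0.0,
            seed=1,
        )
        records, _ = simulate_qtn_panel(cfg)
        assert call_qtn_clusters(records) == []

    def test_spread_wider_than_window_rejected(self):
        cfg = SimulationConfig(
            planted_qtn_hotspots=(PlantedQtnHotspot("1", 5 * MB, "KRN", 3, 700_000),),
        )
        with pytest.raises(ConfigError, match="spread"):
            simulate_qtn_panel(cfg)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_hotspot_recovery_and_bounded_false_positives(self, seed):
        cfg = SimulationConfig(seed=seed)
        records, truth = simulate_qtn_panel(cfg)
        clusters = call_qtn_clusters(records)
        truth_ivs = [r.interval for r in truth.rows.values()]
        for iv in truth_ivs:
            assert any(overlaps(c.interval, iv) for c in clusters)
        false_pos = [
            c for c in clusters
            if not any(overlaps(c.interval, iv) for iv in truth_ivs)
        ]
        assert len(false_pos) <= 1

    def test_determinism(self, tmp_path):
        cfg = SimulationConfig(seed=7)
        a, _ = simulate_qtn_panel(cfg)
        b, _ = simulate_qtn_panel(cfg)
        assert a == b

    def test_accounting_conserves_counts(self, sim_config):
        records, truth = simulate_qtn_panel(sim_config)
        assert truth.n_planted_records + truth.n_background == len(records)

    def test_generated_file_parses_cleanly(self, tmp_path, sim_config):
        records, _ = simulate_qtn_panel(sim_config)
        write_qtn_tsv(records, tmp_path / "qtn.tsv")
        res = read_qtn_tsv(tmp_path / "qtn.tsv")
        assert not res.errors and len(res.records) == len(records)


class TestGeneSimulation:
    def test_planted_genes_assigned_on_truth_clusters(self, sim_config):
        genes, _ = simulate_genes(sim_config)
        _, qtl_truth = simulate_qtl_studies(sim_config)
        _, qtn_truth = simulate_qtn_panel(sim_config)
        site_ivs = {**qtl_truth.rows, **qtn_truth.rows}
        truth_clusters = [
            QtlCluster(f"TC_{sid}", "KRN", row.chrom, row.interval)
            for sid, row in site_ivs.items()
        ]
        assignments = assign_candidates(truth_clusters, genes, default_vocabulary())
        planted_ids = {g.gene_id for g in genes if g.gene_id.startswith("PGENE")}
        assert {a.gene_id for a in assignments} == planted_ids
        assert len(planted_ids) == len(sim_config.planted_pathway_genes)

    def test_zero_planted_zero_assignments(self, sim_config):
        import dataclasses

        cfg = dataclasses.replace(sim_config, planted_pathway_genes=())
        genes, _ = simulate_genes(cfg)
        _, qtl_truth = simulate_qtl_studies(cfg)
        truth_clusters = [
            QtlCluster(f"TC_{sid}", "KRN", r.chrom, r.interval)
            for sid, r in qtl_truth.rows.items()
        ]
        assert assign_candidates(truth_clusters, genes, default_vocabulary()) == []

    def test_gff3_round_trip_matches_truth(self, tmp_path, sim_config):
        genes, _ = simulate_genes(sim_config)
        f = tmp_path / "genes.gff3"
        write_gff3_genes(genes, f)
        expressed = {g.gene_id for g in genes if g.im_expressed}
        back = read_gff3_genes(f, expressed, default_vocabulary())
        assert len(back) == len(genes)
        key = lambda g: (g.gene_id, g.chrom, g.interval, g.strand, g.im_expressed)
        assert sorted(map(key, back)) == sorted(map(key, genes))

    def test_unknown_site_reference_rejected(self, sim_config):
        import dataclasses

        cfg = dataclasses.replace(
            sim_config, planted_pathway_genes=(PlantedGene("NOPE", "auxin"),)
        )
        with pytest.raises(ConfigError, match="unknown site"):
            simulate_genes(cfg)
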