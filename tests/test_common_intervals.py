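"""Class1 (trait-matched) and Class2 (pleiotropic) common-interval detection."""

import itertools

import pytest

from earmeta.common_intervals import (
    classify_resource,
    find_class1,
    find_class2,
    overlay_known_genes,
)
from earmeta.core import (
    DataResource,
    GeneModel,
    GenomicInterval,
    QtlCluster,
    QtnCluster,
    intersection,
    overlaps,
)

MB = 1_000_000


def qtl_cluster(cid, trait, chrom, start_mb, end_mb):
    return QtlCluster(
        cid, trait, str(chrom), GenomicInterval.from_mb(str(chrom), start_mb, end_mb)
    )


def qtn_cluster(cid, trait, chrom, start_mb, end_mb):
    return QtnCluster(
        cid, trait, str(chrom), GenomicInterval.from_mb(str(chrom), start_mb, end_mb)
    )


class TestClass1:
    def test_fixture_reproduces_published_pair_count(self, fixtures):
        cis = find_class1(fixtures.table1_qtl_clusters(), fixtures.table1_qtn_clusters())
        assert len(cis) == 19

    def test_one_qtl_cluster_two_qtn_clusters_two_pairs(self):
        qtl = [qtl_cluster("L1", "KRN", 1, 293.44, 304.60)]
        qtn = [
            qtn_cluster("N1", "KRN", 1, 297.63, 298.13),
            qtn_cluster("N2", "KRN", 1, 299.78, 300.29),
        ]
        cis = find_class1(qtl, qtn)
        assert len(cis) == 2
        assert {ci.qtl_cluster_id for ci in cis} == {"L1"}

    def test_trait_gate(self):
        qtl = [qtl_cluster("L1", "KRN", 1, 10, 20)]
        qtn = [qtn_cluster("N1", "EL", 1, 12, 13)]
        assert find_class1(qtl, qtn) == []

    def test_overlap_region_contained_in_both_members(self, fixtures):
        for ci in find_class1(
            fixtures.table1_qtl_clusters(), fixtures.table1_qtn_clusters()
        ):
            assert ci.qtl_interval.contains(ci.overlap_region)
            assert ci.qtn_interval.contains(ci.overlap_region)

    def test_matches_quadratic_all_pairs_oracle(self, rng):
        traits = ["KRN", "EL", "ED"]
        for _ in range(20):
            qtl = [
                qtl_cluster(f"L{i}", rng.choice(traits), rng.choice([1, 2]),
                            s := rng.randrange(0, 90), s + rng.randrange(1, 10))
                for i in range(rng.randrange(1, 10))
            ]
            qtn = [
                qtn_cluster(f"N{i}", rng.choice(traits), rng.choice([1, 2]),
                            s := rng.randrange(0, 90), s + rng.randrange(1, 10))
                for i in range(rng.randrange(1, 10))
            ]
            expected = {
                (a.cluster_id, b.cluster_id)
                for a, b in itertools.product(qtl, qtn)
                if a.trait == b.trait and overlaps(a.interval, b.interval)
            }
            got = {(ci.qtl_cluster_id, ci.qtn_cluster_id) for ci in find_class1(qtl, qtn)}
            assert got == expected

    def test_count_invariant_to_input_order(self, fixtures):
        qtl, qtn = fixtures.table1_qtl_clusters(), fixtures.table1_qtn_clusters()
        a = find_class1(qtl, qtn)
        b = find_class1(list(reversed(qtl)), list(reversed(qtn)))
        assert len(a) == len(b)
        assert {(x.qtl_interval, x.qtn_interval) for x in a} == {
            (x.qtl_interval, x.qtn_interval) for x in b
        }


def exhaustive_class2(clusters):
    """Exponential oracle: all subsets, pairwise overlap, maximality, ≥2 traits."""
    n = len(clusters)
    pairwise_ok = []
    for size in range(2, n + 1):
        for combo in itertools.combinations(range(n), size):
            if all(
                overlaps(clusters[i].interval, clusters[j].interval)
                for i, j in itertools.combinations(combo, 2)
            ):
                pairwise_ok.append(frozenset(combo))
    maximal = [s for s in pairwise_ok if not any(s < t for t in pairwise_ok)]
    kept = [s for s in maximal if len({clusters[i].trait for i in s}) >= 2]
    kept = [s for s in kept if not any(s < t for t in kept)]
    return {frozenset(clusters[i].cluster_id for i in s) for s in kept}


class TestClass2:
    def test_two_trait_qtl_pair_shape(self):
        # the BA2 locus shape: two same-chromosome QTL clusters, traits KRN+KNPR
        a = qtl_cluster("L1", "KRN", 2, 60.0, 66.23)
        b = qtl_cluster("L2", "KNPR", 2, 65.94, 70.0)
        (ci,) = find_class2([a, b])
        assert ci.region == GenomicInterval.from_mb("2", 65.94, 66.23)
        assert classify_resource(ci) is DataResource.QTL_CLUSTER
        assert ci.traits == {"KRN", "KNPR"}

    def test_three_trait_mixed_resource_shape(self):
        clusters = [
            qtl_cluster("L1", "KRN", 8, 121.0, 121.5),
            qtl_cluster("L2", "CD", 8, 121.2, 121.4),
            qtn_cluster("N1", "EL", 8, 121.24, 121.74),
        ]
        (ci,) = find_class2(clusters)
        assert len(ci.traits) == 3
        assert classify_resource(ci) is DataResource.BOTH

    def test_single_trait_never_reported(self):
        a = qtl_cluster("L1", "KRN", 1, 10, 20)
        b = qtl_cluster("L2", "KRN", 1, 15, 25)
        assert find_class2([a, b]) == []

    def test_restriction_to_one_trait_empty(self, rng):
        clusters = [
            qtl_cluster(f"L{i}", rng.choice(["KRN", "EL"]), 1,
                        s := rng.randrange(0, 50), s + rng.randrange(1, 20))
            for i in range(10)
        ]
        krn_only = [c for c in clusters if c.trait == "KRN"]
        assert find_class2(krn_only) == []

    def test_matches_exhaustive_clique_oracle(self, rng):
        traits = ["KRN", "EL", "CD"]
        for _ in range(25):
            clusters = []
            for i in range(rng.randrange(2, 12)):
                s = rng.randrange(0, 60)
                make = qtl_cluster if rng.random() < 0.5 else qtn_cluster
                clusters.append(
                    make(f"C{i}", rng.choice(traits), 1, s, s + rng.randrange(1, 25))
                )
            got = {ci.member_cluster_ids for ci in find_class2(clusters)}
            assert got == exhaustive_class2(clusters)

    def test_region_is_intersection_of_all_members(self, rng):
        clusters = [
            qtl_cluster(f"L{i}", t, 1, s := rng.randrange(0, 40), s + rng.randrange(5, 30))
            for i, t in enumerate(["KRN", "EL", "CD", "KNPR", "EW"])
        ]
        by_id = {c.cluster_id: c for c in clusters}
        for ci in find_class2(clusters):
            members = [by_id[m].interval for m in ci.member_cluster_ids]
            assert ci.region == intersection(members)

    def test_output_order_invariant(self, rng):
        clusters = [
            qtl_cluster(f"L{i}", rng.choice(["KRN", "EL"]), 1,
                        s := rng.randrange(0, 50), s + rng.randrange(1, 20))
            for i in range(8)
        ]
        a = find_class2(clusters)
        shuffled = clusters[:]
        rng.shuffle(shuffled)
        b = find_class2(shuffled)
        assert {ci.member_cluster_ids for ci in a} == {ci.member_cluster_ids for ci in b}

    def test_chain_mode_merges_chained_components(self):
        # A-B overlap, B-C overlap, A-C do not: clique mode keeps two CIs,
        # chain mode one component
        a = qtl_cluster("A", "KRN", 1, 0, 10)
        b = qtl_cluster("B", "EL", 1, 8, 20)
        c = qtl_cluster("C", "CD", 1, 18, 30)
        assert len(find_class2([a, b, c])) == 2
        assert len(find_class2([a, b, c], class2_mode="chain")) == 1


class TestClassifyResource:
    def test_fixture_reproduces_published_breakdown(self, fixtures):
        cis = fixtures.table2_cis()
        res = [classify_resource(ci) for ci in cis]
        assert res.count(DataResource.BOTH) == 13
        assert sum(r is not DataResource.BOTH for r in res) == 27


class TestOverlayKnownGenes:
    def test_class1_fixture_marks_published_five(self, fixtures):
        cis = find_class1(fixtures.table1_qtl_clusters(), fixtures.table1_qtn_clusters())
        annotated = overlay_known_genes(cis, fixtures.table1_known_gene_models())
        assert sum(bool(ci.known_genes) for ci in annotated) == 5

    def test_class2_fixture_marks_published_two(self, fixtures):
        annotated = overlay_known_genes(
            fixtures.table2_cis(), fixtures.table2_known_gene_models()
        )
        hit = [ci for ci in annotated if ci.known_genes]
        assert len(hit) == 2
        assert {g for ci in hit for g in ci.known_genes} == {"BA2", "ACO2"}

    def test_empty_gene_list_empty_annotations(self, fixtures):
        cis = find_class1(fixtures.table1_qtl_clusters(), fixtures.table1_qtn_clusters())
        assert all(not ci.known_genes for ci in overlay_known_genes(cis, []))
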