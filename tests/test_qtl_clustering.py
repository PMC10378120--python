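"""QTL cluster calling: the ≥3-study rule with the >30 Mb escalation."""

import itertools

import pytest

from earmeta.core import MB, GenomicInterval, overlaps
from earmeta.qtl_clustering import call_qtl_clusters, qtl_components
from .conftest import make_qtl


def brute_force_components(records):
    """Transitive closure over the explicit pairwise-overlap matrix."""
    n = len(records)
    adj = [
        [i == j or overlaps(records[i].interval, records[j].interval) for j in range(n)]
        for i in range(n)
    ]
    for k, i, j in itertools.product(range(n), repeat=3):
        if adj[i][k] and adj[k][j]:
            adj[i][j] = True
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if adj[i][j]}
        seen |= comp
        comps.append(frozenset(records[j].record_id for j in comp))
    return set(comps)


def brute_force_clusters(records, min_studies=3, span_bp=30 * MB, min_large=5):
    out = set()
    for comp_ids in brute_force_components(records):
        members = [r for r in records if r.record_id in comp_ids]
        studies = {r.study_id for r in members}
        start = min(r.interval.start_bp for r in members)
        end = max(r.interval.end_bp for r in members)
        if len(studies) >= min_studies and (
            end - start <= span_bp or len(studies) >= min_large
        ):
            out.add((start, end, frozenset(studies), comp_ids))
    return out


def random_records(rng, n, trait="KRN", chrom="1", n_studies=6, hi=100 * MB):
    records = []
    for i in range(n):
        start = rng.randrange(0, hi - MB)
        length = rng.randrange(100_000, 20 * MB)
        records.append(
            make_qtl(
                f"R{i}", f"S{rng.randrange(n_studies)}", trait, chrom,
                start, min(start + length, hi),
            )
        )
    return records


class TestComponents:
    def test_chain_and_singleton(self):
        recs = [
            make_qtl("a", "S1", "KRN", 1, 10, 20),
            make_qtl("b", "S2", "KRN", 1, 15, 30),
            make_qtl("c", "S3", "KRN", 1, 40, 50),
        ]
        comps = qtl_components(recs)
        assert [{r.record_id for r in c} for c in comps] == [{"a", "b"}, {"c"}]

    def test_all_disjoint_all_singletons(self):
        recs = [make_qtl(f"r{i}", "S1", "KRN", 1, i * 100, i * 100 + 50) for i in range(5)]
        assert all(len(c) == 1 for c in qtl_components(recs))

    def test_unnormalized_record_rejected(self):
        from earmeta.core import QtlRecord

        with pytest.raises(ValueError, match="unnormalized"):
            qtl_components([QtlRecord("x", "S", "KRN")])

    def test_matches_brute_force_graph_oracle(self, rng):
        for _ in range(30):
            recs = random_records(rng, rng.randrange(2, 50))
            got = {frozenset(r.record_id for r in c) for c in qtl_components(recs)}
            assert got == brute_force_components(recs)


class TestCallClusters:
    def test_three_studies_make_a_cluster(self):
        recs = [
            make_qtl("a", "S1", "KRN", 1, 10 * MB, 11 * MB),
            make_qtl("b", "S2", "KRN", 1, 10_500_000, 11_500_000),
            make_qtl("c", "S3", "KRN", 1, 11_200_000, 12 * MB),
        ]
        (cluster,) = call_qtl_clusters(recs)
        assert cluster.n_studies == 3
        assert cluster.interval == GenomicInterval("1", 10 * MB, 12 * MB)
        cluster.validate(recs)

    def test_distinct_study_counting(self):
        # 4 overlapping intervals from only 2 studies: no cluster
        recs = [
            make_qtl(f"r{i}", f"S{i % 2}", "KRN", 1, 10 * MB + i, 11 * MB + i)
            for i in range(4)
        ]
        assert call_qtl_clusters(recs) == []

    def test_span_escalation_rule(self):
        def big_component(n_studies):
            return [
                make_qtl(
                    f"r{i}", f"S{i}", "KRN", 1, i * 8 * MB, i * 8 * MB + 9 * MB
                )
                for i in range(n_studies)
            ]

        assert call_qtl_clusters(big_component(4)) == []  # 33 Mb span, 4 studies
        (cluster,) = call_qtl_clusters(big_component(5))  # 41 Mb span, 5 studies
        assert cluster.interval.length_bp > 30 * MB and cluster.n_studies == 5

    def test_permutation_invariance(self, rng):
        recs = random_records(rng, 40)
        base = call_qtl_clusters(recs)
        shuffled = recs[:]
        rng.shuffle(shuffled)
        assert call_qtl_clusters(shuffled) == base

    def test_monotonicity_adding_records_never_removes_support(self, rng):
        # with the span escalation disabled, support counts never decrease,
        # so adding records can only keep or grow existing clusters
        big = 10**12
        recs = random_records(rng, 30)
        before = call_qtl_clusters(recs, span_threshold_bp=big)
        extra = random_records(rng, 5)
        renamed = [
            make_qtl(f"X{i}", r.study_id, r.trait, r.chrom,
                     r.interval.start_bp, r.interval.end_bp)
            for i, r in enumerate(extra)
        ]
        after = call_qtl_clusters(recs + renamed, span_threshold_bp=big)
        for c in before:
            assert any(
                overlaps(c.interval, c2.interval) and c2.n_studies >= c.n_studies
                for c2 in after
            )

    def test_oracle_equivalence_on_small_instances(self, rng):
        for _ in range(25):
            recs = random_records(rng, rng.randrange(3, 60))
            got = {
                (
                    c.interval.start_bp,
                    c.interval.end_bp,
                    c.supporting_studies,
                    c.member_ids,
                )
                for c in call_qtl_clusters(recs)
            }
            assert got == brute_force_clusters(recs)

    def test_emitted_clusters_satisfy_invariants(self, rng):
        recs = random_records(rng, 50)
        for c in call_qtl_clusters(recs):
            c.validate(recs)

    def test_groups_by_trait_and_chrom(self):
        recs = [
            make_qtl("a", "S1", "KRN", 1, 10, 100),
            make_qtl("b", "S2", "KRN", 1, 10, 100),
            make_qtl("c", "S3", "EL", 1, 10, 100),  # other trait: no mixing
        ]
        assert call_qtl_clusters(recs) == []


class TestCoverageMode:
    def test_coverage_region_is_tighter_than_union(self):
        # three studies overlap only in [2,3) Mb; union span is [0,5) Mb
        recs = [
            make_qtl("a", "S1", "KRN", 1, 0, 3 * MB),
            make_qtl("b", "S2", "KRN", 1, 2 * MB, 5 * MB),
            make_qtl("c", "S3", "KRN", 1, 2 * MB, 3 * MB),
        ]
        (union_c,) = call_qtl_clusters(recs, region_mode="union")
        (cov_c,) = call_qtl_clusters(recs, region_mode="coverage")
        assert union_c.interval == GenomicInterval("1", 0, 5 * MB)
        assert cov_c.interval == GenomicInterval("1", 2 * MB, 3 * MB)
        assert union_c.interval.contains(cov_c.interval)

    def test_one_study_counts_once_per_point(self):
        # S1 contributes two stacked intervals; still only 2 distinct studies
        recs = [
            make_qtl("a", "S1", "KRN", 1, 0, 10 * MB),
            make_qtl("b", "S1", "KRN", 1, 1 * MB, 9 * MB),
            make_qtl("c", "S2", "KRN", 1, 2 * MB, 8 * MB),
        ]
        assert call_qtl_clusters(recs, region_mode="coverage") == []
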