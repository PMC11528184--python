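import random

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import oracles
from modclust.annotation import AnnotationTable
from modclust.clustering import Partition
from modclust.enrichment import (
    CustomAnnotations,
    EnrichmentRecord,
    annotation_matrix,
    bh_adjust,
    cluster_analysis_table,
    cluster_list_table,
    enrich_all_clusters,
    hypergeom_upper_tail,
    majority_pass,
    term_analysis_table,
    write_table,
)
from modclust.network import Network


def _record(k, n, n_nodes=None, **kw):
    defaults = dict(
        cluster_id=1, term="T", k=k, n_annotated=n, n_nodes=n_nodes or n,
        K=k, N=100, p_raw=0.5, p_adj=0.5, enriched=False, majority_pass=False,
    )
    defaults.update(kw)
    return EnrichmentRecord(**defaults)


class TestHypergeom:
    @pytest.mark.parametrize(
        "k, n, K, N, expected",
        [
            (0, 5, 4, 10, 1.0),
            (3, 5, 4, 10, 66 / 252),
            (3, 3, 3, 10, 1 / 120),
        ],
    )
    def test_known_values(self, k, n, K, N, expected):
        assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    def test_matches_draw_enumeration(self):
        # full enumeration over every C(N, n) draw for a slice of cases;
        # the acceptance suite sweeps all N <= 12
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    tails = oracles.hypergeom_tails_all_k(n, K, N)
                    for k, tail in enumerate(tails):
                        got = hypergeom_upper_tail(k, n, K, N)
                        assert abs(got - float(tail)) <= 1e-12

    def test_matches_scipy_sf(self):
        from scipy.stats import hypergeom

        rng = random.Random(4)
        for _ in range(50):
            N = rng.randint(2, 500)
            K = rng.randint(0, N)
            n = rng.randint(1, N)
            k = rng.randint(0, min(n, K))
            assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
                hypergeom.sf(k - 1, N, K, n), abs=1e-10
            )

    def test_bounds_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 10, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 4, 11, 10)


class TestBH:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.04, 0.03, 0.005]) == pytest.approx(
            [0.02, 0.04, 0.04, 0.02]
        )

    def test_degenerate_lists(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.07]) == [0.07]
        assert bh_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_independent_reference_and_statsmodels(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m).tolist()
            mine = bh_adjust(p)
            assert mine == pytest.approx(oracles.bh_reference(p), abs=1e-12)
            assert mine == pytest.approx(
                multipletests(p, method="fdr_bh")[1].tolist(), abs=1e-12
            )


class TestMajorityRule:
    def test_quarter_fails_default_threshold(self):
        assert not majority_pass(_record(k=2, n=8), 50.0)

    def test_boundary_counts_as_pass(self):
        assert majority_pass(_record(k=4, n=8), 50.0)

    def test_full_annotation_passes_strictest(self):
        assert majority_pass(_record(k=8, n=8), 100.0)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            majority_pass(_record(k=1, n=2), 150.0)


def planted_fixture():
    """Two clusters of 20; term T on 15 nodes of cluster 1 and 1 node of
    cluster 2; a catch-all term keeps every node annotated."""
    c1 = [f"a{i:02d}" for i in range(20)]
    c2 = [f"b{i:02d}" for i in range(20)]
    edges = list(zip(c1, c1[1:])) + list(zip(c2, c2[1:])) + [(c1[-1], c2[0])]
    g = Network(edges)
    p = Partition({1: c1, 2: c2})
    node_terms = {v: {"BASE"} for v in c1 + c2}
    for v in c1[:15] + c2[:1]:
        node_terms[v] = node_terms[v] | {"T"}
    a = AnnotationTable(node_terms, g.nodes)
    return g, p, a


class TestEnrichAllClusters:
    def test_planted_term_enriched_in_its_cluster_only(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a, alpha=0.05)
        flags = {(r.cluster_id, r.term): r.enriched for r in records}
        assert flags[(1, "T")] is True
        assert flags[(2, "T")] is False

    def test_universal_term_never_enriched(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        for r in records:
            if r.term == "BASE":  # K = N forces P(X >= k) = 1
                assert r.p_raw == 1.0 and not r.enriched

    def test_small_clusters_filtered(self):
        g, p, a = planted_fixture()
        p3 = Partition(
            {1: list(p.clusters[1]), 2: sorted(p.clusters[2])[3:], 3: sorted(p.clusters[2])[:3]}
        )
        records = enrich_all_clusters(g, p3, a, min_cluster_size=5)
        assert {r.cluster_id for r in records} == {1, 2}

    def test_no_annotations_rejected(self):
        g, p, _ = planted_fixture()
        with pytest.raises(ValueError, match="annotated"):
            enrich_all_clusters(g, p, AnnotationTable({}, g.nodes))

    def test_shared_node_counts_in_every_cluster(self):
        g = Network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        p = Partition({1: {"A", "B", "C"}, 2: {"C", "D", "E"}})
        a = AnnotationTable({v: {"T"} for v in "ABCDE"}, g.nodes)
        records = enrich_all_clusters(g, p, a, min_cluster_size=1)
        by = {(r.cluster_id, r.term): r for r in records}
        assert by[(1, "T")].k == 3 and by[(2, "T")].k == 3
        assert by[(1, "T")].N == 5  # background counted once on the graph

    def test_all_nodes_background_changes_counts(self):
        g, p, a = planted_fixture()
        # drop BASE from 5 nodes of cluster 2 so universes differ
        node_terms = {v: set(t) for v, t in a.node_terms.items()}
        for v in sorted(p.clusters[2])[10:15]:
            del node_terms[v]
        a2 = AnnotationTable(node_terms, g.nodes)
        r_ann = enrich_all_clusters(g, p, a2, background="annotated")
        r_all = enrich_all_clusters(g, p, a2, background="all-nodes")
        assert {r.N for r in r_ann} == {35}
        assert {r.N for r in r_all} == {40}
        assert {r.n_annotated for r in r_all if r.cluster_id == 2} == {15}

    def test_per_cluster_bh_scope(self):
        g, p, a = planted_fixture()
        r_global = enrich_all_clusters(g, p, a, bh_scope="global")
        r_local = enrich_all_clusters(g, p, a, bh_scope="per-cluster")
        assert len(r_global) == len(r_local)
        # within one cluster, local BH uses a smaller family
        t1_global = next(r for r in r_global if (r.cluster_id, r.term) == (1, "T"))
        t1_local = next(r for r in r_local if (r.cluster_id, r.term) == (1, "T"))
        assert t1_local.p_adj <= t1_global.p_adj + 1e-12


class TestTables:
    def test_cluster_list_counts(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        table = cluster_list_table(records, p, a)
        row1 = table[table["cluster"] == 1].iloc[0]
        assert row1["n_annotated"] == 20
        assert row1["n_terms"] == 2
        assert row1["n_enriched"] == 1
        assert row1["total_annotations"] == "T"

    def test_majority_statistic_drives_listing(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        table = cluster_list_table(records, p, a, stat="majority")
        assert table[table["cluster"] == 1]["total_annotations"].item() == "BASE;T"
        assert table[table["cluster"] == 2]["total_annotations"].item() == "BASE"
        with pytest.raises(ValueError):
            cluster_list_table(records, p, a, stat="bogus")

    def test_cluster_without_annotated_nodes_gets_zero_row(self):
        g, p, a = planted_fixture()
        node_terms = {v: a.node_terms[v] for v in p.clusters[1]}
        a2 = AnnotationTable(node_terms, g.nodes)
        records = enrich_all_clusters(g, p, a2)
        row2 = cluster_list_table(records, p, a2)
        row2 = row2[row2["cluster"] == 2].iloc[0]
        assert (
            row2["n_annotated"], row2["n_terms"], row2["n_enriched"], row2["n_majority"]
        ) == (0, 0, 0, 0)
        assert row2["total_annotations"] == ""

    def test_cluster_analysis_sorted_by_adjusted_p(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        table = cluster_analysis_table(records, 1, p)
        assert table.iloc[0]["term"] == "T"
        assert list(table["p_adj"]) == sorted(table["p_adj"])

    def test_unknown_cluster_rejected(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        with pytest.raises(KeyError):
            cluster_analysis_table(records, 99, p)

    def test_term_analysis_rows(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        t = term_analysis_table(records, "T")
        assert len(t) == 2
        assert bool(t[t["cluster"] == 1]["enriched"].item()) is True
        assert term_analysis_table(records, "absent").empty

    def test_annotation_matrix_counts(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        mat = annotation_matrix(records, p, a)
        assert mat.loc[1, "T"] == 15
        assert mat.loc[2, "T"] == 1
        assert mat.loc[1, "BASE"] == 20
        assert mat.sum(axis=1).loc[1] == 35

    def test_p_values_exported_in_scientific_notation(self, tmp_path):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        f = tmp_path / "records.tsv"
        from modclust.enrichment import records_table

        write_table(records_table(records), f)
        body = f.read_text().splitlines()[1]
        assert "e-" in body or "e+" in body


class TestCustomAnnotations:
    def test_manual_tag_listed_and_idempotent(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        custom = CustomAnnotations(p)
        custom.add(1, "endocytosis-related")
        custom.add(1, "endocytosis-related")
        table = cluster_list_table(records, p, a, custom=custom)
        listing = table[table["cluster"] == 1]["total_annotations"].item()
        assert listing == "T;endocytosis-related (manual)"

    def test_removal_restores_listing(self):
        g, p, a = planted_fixture()
        records = enrich_all_clusters(g, p, a)
        custom = CustomAnnotations(p)
        custom.add(1, "tag")
        custom.remove(1, "tag")
        table = cluster_list_table(records, p, a, custom=custom)
        assert table[table["cluster"] == 1]["total_annotations"].item() == "T"

    def test_unknown_cluster_rejected(self):
        _, p, _ = planted_fixture()
        custom = CustomAnnotations(p)
        with pytest.raises(KeyError):
            custom.add(99, "tag")
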