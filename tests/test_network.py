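"""Tripartite network construction, metrics, keystones, aggregation, export."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from holovir import (HostLink, aggregate_links, build_graph, export_graph,
                     keystone_rank, node_metrics, read_graph)


def _links(pairs):
    return pd.DataFrame(pairs, columns=["virus_id", "host_id", "evidence"])


def _ann(rows):
    return pd.DataFrame(rows, columns=["virus_id", "gene_id", "pathway"])


class TestBuild:
    def test_genes_as_edges_shared_gene(self):
        ann = _ann([("v1", "gA", "p"), ("v2", "gA", "p")])
        g = build_graph(_links([]), ann, mode="genes_as_edges")
        assert g.has_edge("v1", "v2")
        assert g["v1"]["v2"]["kind"] == "shared_gene"
        assert "gA" not in g

    def test_genes_as_nodes(self):
        ann = _ann([("v1", "gA", "p"), ("v2", "gA", "p")])
        g = build_graph(_links([]), ann, mode="genes_as_nodes")
        assert g.nodes["gA"]["kind"] == "gene"
        assert g.degree["gA"] == 2
        assert not g.has_edge("v1", "v2")

    def test_dual_evidence_merges_into_one_edge(self):
        links = _links([("v1", "h1", "crispr"), ("v1", "h1", "provirus")])
        g = build_graph(links)
        assert g.number_of_edges() == 1
        assert g["v1"]["h1"]["evidence"] == "crispr,provirus"

    def test_unknown_virus_id_rejected(self):
        with pytest.raises(ValueError, match="vX"):
            build_graph(_links([("vX", "h1", "crispr")]), known_viruses={"v1"})

    def test_accepts_hostlink_objects(self):
        g = build_graph([HostLink("v1", "h1", "crispr")])
        assert g.nodes["v1"]["kind"] == "virus"
        assert g.nodes["h1"]["kind"] == "host"

    def test_mode_consistency_shared_pairs(self, rng):
        """Virus pairs at distance 2 through a gene node = shared_gene pairs."""
        rows = [(f"v{rng.integers(0, 8)}", f"g{rng.integers(0, 5)}", "p")
                for _ in range(40)]
        ann = _ann(rows).drop_duplicates()
        nodes_mode = build_graph(_links([]), ann, mode="genes_as_nodes")
        edges_mode = build_graph(_links([]), ann, mode="genes_as_edges")
        via_gene = set()
        for gene in [n for n, d in nodes_mode.nodes(data=True) if d["kind"] == "gene"]:
            for u, v in itertools.combinations(sorted(nodes_mode[gene]), 2):
                via_gene.add((u, v))
        shared = {tuple(sorted(e)) for e in edges_mode.edges
                  if edges_mode.edges[e]["kind"] == "shared_gene"}
        assert via_gene == shared


def _bfs_metrics(g):
    """Independent brute-force degree/closeness/clustering."""
    out = {}
    for node in g.nodes:
        dist = {node: 0}
        q = deque([node])
        while q:
            u = q.popleft()
            for w in g[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        others = [d for n2, d in dist.items() if n2 != node]
        cc = (len(others) / sum(others)) if others and sum(others) else 0.0
        nbrs = list(g[node])
        k = len(nbrs)
        if k < 2:
            clust = 0.0
        else:
            e_n = sum(1 for a, b in itertools.combinations(nbrs, 2)
                      if g.has_edge(a, b))
            clust = 2 * e_n / (k * (k - 1))
        out[node] = (k, cc, clust)
    return out


class TestMetrics:
    def test_path_graph_hand_values(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        nx.set_node_attributes(g, "virus", "kind")
        m = node_metrics(g).set_index("node")
        assert m.loc["B", "cc"] == pytest.approx(1.0)
        assert m.loc["A", "cc"] == pytest.approx(2 / 3)
        assert (m["clust"] == 0).all()

    def test_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        m = node_metrics(g)
        assert (m["k"] == 2).all()
        assert np.allclose(m["cc"], 1.0)
        assert np.allclose(m["clust"], 1.0)

    def test_isolated_node_conventions(self):
        g = nx.Graph()
        g.add_node("lonely", kind="virus")
        m = node_metrics(g).iloc[0]
        assert (m["k"], m["cc"], m["clust"]) == (0, 0.0, 0.0)

    def test_equivalence_with_bruteforce_bfs_on_random_graphs(self):
        for seed in (1, 2, 3):
            g = nx.gnp_random_graph(150, 0.02, seed=seed)
            m = node_metrics(g).set_index("node")
            ref = _bfs_metrics(g)
            for node, (k, cc, clust) in ref.items():
                assert m.loc[node, "k"] == k
                assert m.loc[node, "cc"] == pytest.approx(cc)
                assert m.loc[node, "clust"] == pytest.approx(clust)

    def test_hosts_with_nonadjacent_neighbours_have_zero_clustering(self):
        # several viruses infect one host but share no genes: clust(host)=0
        links = _links([(f"v{i}", "h1", "crispr") for i in range(4)])
        g = build_graph(links)
        m = node_metrics(g).set_index("node")
        assert m.loc["h1", "clust"] == 0.0


class TestKeystones:
    def test_hand_computed_rank_aggregation(self):
        m = pd.DataFrame({
            "node": ["A", "B", "C"], "kind": ["virus"] * 3,
            "k": [5, 3, 1], "cc": [0.8, 0.9, 0.1], "clust": [0.5, 0.2, 0.0]})
        out = keystone_rank(m)
        assert list(out["node"]) == ["A", "B", "C"]
        assert out.loc[0, "avg_rank"] == pytest.approx(4 / 3)
        assert out.loc[1, "avg_rank"] == pytest.approx(5 / 3)
        assert out.loc[2, "avg_rank"] == pytest.approx(3.0)

    def test_total_tie_orders_by_id(self):
        m = pd.DataFrame({"node": ["z", "a", "m"], "kind": ["virus"] * 3,
                          "k": [2, 2, 2], "cc": [0.5] * 3, "clust": [0.1] * 3})
        out = keystone_rank(m)
        assert list(out["node"]) == ["a", "m", "z"]
        assert out["avg_rank"].nunique() == 1

    def test_single_virus(self):
        m = pd.DataFrame({"node": ["v"], "kind": ["virus"],
                          "k": [3], "cc": [0.5], "clust": [0.0]})
        assert keystone_rank(m).loc[0, "avg_rank"] == 1.0

    def test_invariant_under_monotone_metric_transform(self, rng):
        m = pd.DataFrame({
            "node": [f"v{i}" for i in range(8)], "kind": ["virus"] * 8,
            "k": rng.integers(0, 10, 8), "cc": rng.random(8),
            "clust": rng.random(8)})
        base = list(keystone_rank(m)["node"])
        m2 = m.assign(k=np.exp(m["k"]), cc=m["cc"] ** 3 + 1,
                      clust=5 * m["clust"] - 2)
        assert list(keystone_rank(m2)["node"]) == base

    def test_hosts_and_genes_excluded(self):
        m = pd.DataFrame({"node": ["v", "h"], "kind": ["virus", "host"],
                          "k": [1, 99], "cc": [0.1, 1.0], "clust": [0, 1]})
        out = keystone_rank(m)
        assert list(out["node"]) == ["v"]


class TestAggregation:
    def test_share_arithmetic(self):
        links = _links([("v%d" % i, "hX", "crispr") for i in range(6)]
                       + [("v%d" % i, "hY", "crispr") for i in range(6, 10)])
        tax = {"hX": "X", "hY": "Y"}
        out = aggregate_links(links, host_taxonomy=tax)["class_share"]
        x = out[(out["host_class"] == "X")]["share_pct"].iloc[0]
        assert x == pytest.approx(60.0)

    def test_small_class_collapsed_into_others(self):
        rows = [("v%d" % i, "big", "crispr") for i in range(103)] \
            + [("v200", "tiny", "crispr"), ("v201", "tiny2", "crispr")]
        tax = {"big": "Big", "tiny": "Tiny", "tiny2": "Tiny2"}
        out = aggregate_links(_links(rows), host_taxonomy=tax,
                              others_threshold=0.02)["class_share"]
        assert "others" in set(out["host_class"])
        assert "Tiny" not in set(out["host_class"])
        # shares still sum to 100
        assert out["share_pct"].sum() == pytest.approx(100.0)

    def test_empty_links_give_empty_tables(self):
        out = aggregate_links(_links([]))
        assert all(df.empty for df in out.values())

    def test_unmapped_taxa_become_unclassified(self):
        out = aggregate_links(_links([("v1", "h1", "provirus")]))
        cf = out["class_family"]
        assert set(cf["host_class"]) == {"Unclassified"}


class TestExport:
    def test_graphml_round_trip_preserves_structure_and_attrs(self, tmp_path):
        links = _links([("v1", "h1", "crispr"), ("v2", "h1", "provirus")])
        ann = _ann([("v1", "gA", "p"), ("v2", "gA", "p")])
        g = build_graph(links, ann)
        metrics = node_metrics(g)
        path = tmp_path / "net.graphml"
        export_graph(g, path, "graphml", metrics)
        back = read_graph(path, "graphml")
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        byn = metrics.set_index("node")
        for n in back.nodes:
            assert back.nodes[n]["kind"] == g.nodes[n]["kind"]
            assert back.nodes[n]["cc"] == pytest.approx(byn.loc[n, "cc"])

    def test_edge_tsv_round_trip(self, tmp_path):
        g = build_graph(_links([("v1", "h1", "crispr")]))
        path = tmp_path / "edges.tsv"
        export_graph(g, path, "edge_tsv")
        back = read_graph(path, "edge_tsv")
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))

    def test_empty_graph_valid_file(self, tmp_path):
        g = nx.Graph()
        export_graph(g, tmp_path / "empty.graphml", "graphml")
        assert read_graph(tmp_path / "empty.graphml").number_of_edges() == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_graph(nx.Graph(), tmp_path / "x", "dot")
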