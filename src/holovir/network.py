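"""Tripartite bacteria-phage-gene network and keystone-virus ranking.

Nodes are typed (host, virus, gene); edges are typed virus-host links
(crispr / provirus evidence, merged into a single edge carrying an
evidence set), virus-gene `encodes` edges, or virus-virus `shared_gene`
edges when genes are treated as linkages rather than nodes.  Per-node
metrics are degree k, closeness centrality cc (reciprocal mean shortest
path within the node's connected component, 0 for isolated nodes) and
clustering coefficient clust (0 when k < 2).  Keystone viruses are the
top average fractional rank across the three metrics, each ranked
descending.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

NODE_KINDS = ("host", "virus", "gene")
EDGE_KINDS = ("crispr", "provirus", "encodes", "shared_gene")


def _links_frame(host_links) -> pd.DataFrame:
    if isinstance(host_links, pd.DataFrame):
        df = host_links[["virus_id", "host_id", "evidence"]].copy()
    else:
        df = pd.DataFrame([(l.virus_id, l.host_id, l.evidence) for l in host_links],
                          columns=["virus_id", "host_id", "evidence"])
    bad = set(df["evidence"]) - {"crispr", "provirus"}
    if bad:
        raise ValueError(f"unknown evidence kinds: {sorted(bad)}")
    return df


def build_graph(host_links, gene_annotations: pd.DataFrame | None = None,
                mode: str = "genes_as_nodes",
                known_viruses=None,
                weighted_shared_genes: bool = False) -> nx.Graph:
    """Assemble the tripartite graph (simple, undirected).

    ``mode='genes_as_nodes'`` adds gene nodes with `encodes` edges;
    ``mode='genes_as_edges'`` instead connects virus pairs sharing >=1 gene
    with `shared_gene` edges (optionally weighted by the number of shared
    genes).  Host-virus edges from both evidence kinds merge into one edge
    with an `evidence` attribute.
    """
    if mode not in ("genes_as_nodes", "genes_as_edges"):
        raise ValueError(f"unknown mode: {mode}")
    links = _links_frame(host_links)
    if known_viruses is not None:
        unknown = sorted(set(links["virus_id"]) - set(known_viruses))
        if unknown:
            raise ValueError(f"links reference unknown virus ids: {unknown}")
    g = nx.Graph()
    for _, row in links.iterrows():
        v, h = row["virus_id"], row["host_id"]
        g.add_node(v, kind="virus")
        g.add_node(h, kind="host")
        if g.has_edge(v, h):
            ev = set(g[v][h]["evidence"].split(",")) | {row["evidence"]}
            g[v][h]["evidence"] = ",".join(sorted(ev))
        else:
            g.add_edge(v, h, kind="host_virus", evidence=row["evidence"])
    if gene_annotations is not None and len(gene_annotations):
        ann = gene_annotations[["virus_id", "gene_id"]].drop_duplicates()
        for v in ann["virus_id"].unique():
            g.add_node(v, kind="virus")
        if mode == "genes_as_nodes":
            for _, row in ann.iterrows():
                g.add_node(row["gene_id"], kind="gene")
                g.add_edge(row["virus_id"], row["gene_id"], kind="encodes")
        else:
            by_gene = ann.groupby("gene_id")["virus_id"].apply(sorted)
            shared: dict[tuple[str, str], int] = {}
            for viruses in by_gene:
                for u, v in combinations(viruses, 2):
                    shared[(u, v)] = shared.get((u, v), 0) + 1
            for (u, v), w in sorted(shared.items()):
                attrs = {"kind": "shared_gene"}
                if weighted_shared_genes:
                    attrs["weight"] = w
                g.add_edge(u, v, **attrs)
    return g


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Degree, closeness centrality and clustering coefficient per node.

    Closeness uses the within-component reciprocal-mean-distance form
    (wf_improved=False), matching tools that analyse components separately.
    """
    cc = nx.closeness_centrality(graph, wf_improved=False)
    clust = nx.clustering(graph)
    rows = [{"node": n, "kind": graph.nodes[n].get("kind", ""),
             "k": graph.degree[n], "cc": cc[n], "clust": clust[n]}
            for n in graph.nodes]
    return pd.DataFrame(rows).sort_values("node").reset_index(drop=True)


def keystone_rank(metrics: pd.DataFrame) -> pd.DataFrame:
    """Average-rank keystone table over virus nodes.

    Each metric is ranked descending (rank 1 = largest) with fractional
    (mid) ranks for ties; the output is sorted ascending by average rank,
    ties broken by virus id.
    """
    viruses = metrics[metrics["kind"] == "virus"].copy()
    if viruses.empty:
        raise ValueError("no virus nodes in metrics table")
    for col in ("k", "cc", "clust"):
        viruses[f"rank_{col}"] = viruses[col].rank(ascending=False, method="average")
    viruses["avg_rank"] = viruses[["rank_k", "rank_cc", "rank_clust"]].mean(axis=1)
    viruses = viruses.sort_values(["avg_rank", "node"]).reset_index(drop=True)
    return viruses[["node", "k", "cc", "clust",
                    "rank_k", "rank_cc", "rank_clust", "avg_rank"]]


def aggregate_links(host_links, host_taxonomy: dict[str, str] | None = None,
                    virus_taxonomy: dict[str, str] | None = None,
                    gene_annotations: pd.DataFrame | None = None,
                    others_threshold: float = 0.02) -> dict[str, pd.DataFrame]:
    """Class x family x gene aggregation tables from host links.

    Returns three tables: `class_family` (link counts by bacterial class,
    viral family and evidence kind), `class_share` (per-class percentage of
    links within each evidence kind, classes below ``others_threshold``
    collapsed into "others"), and `family_pathway` (viral family x gene
    pathway counts).  Unmapped taxa become "Unclassified".
    """
    links = _links_frame(host_links)
    empty = {"class_family": pd.DataFrame(columns=["host_class", "virus_family",
                                                   "evidence", "n_links"]),
             "class_share": pd.DataFrame(columns=["evidence", "host_class",
                                                  "share_pct"]),
             "family_pathway": pd.DataFrame(columns=["virus_family", "pathway",
                                                     "n"])}
    if links.empty:
        return empty
    host_taxonomy = host_taxonomy or {}
    virus_taxonomy = virus_taxonomy or {}
    links["host_class"] = links["host_id"].map(host_taxonomy).fillna("Unclassified")
    links["virus_family"] = links["virus_id"].map(virus_taxonomy).fillna("Unclassified")

    class_family = (links.groupby(["host_class", "virus_family", "evidence"])
                    .size().rename("n_links").reset_index())

    shares = []
    for ev, sub in links.groupby("evidence"):
        counts = sub["host_class"].value_counts()
        share = counts / counts.sum()
        share = share.rename(index=lambda c: c if share[c] >= others_threshold else "others")
        share = share.groupby(level=0).sum()
        for cls, frac in share.sort_values(ascending=False).items():
            shares.append({"evidence": ev, "host_class": cls,
                           "share_pct": 100.0 * frac})
    class_share = pd.DataFrame(shares)

    if gene_annotations is not None and len(gene_annotations) and \
            "pathway" in gene_annotations.columns:
        ann = gene_annotations[["virus_id", "gene_id", "pathway"]].drop_duplicates()
        ann = ann.assign(virus_family=ann["virus_id"].map(virus_taxonomy)
                         .fillna("Unclassified"))
        family_pathway = (ann.groupby(["virus_family", "pathway"])
                          .size().rename("n").reset_index())
    else:
        family_pathway = empty["family_pathway"]
    return {"class_family": class_family, "class_share": class_share,
            "family_pathway": family_pathway}


def export_graph(graph: nx.Graph, path, fmt: str = "graphml",
                 metrics: pd.DataFrame | None = None) -> None:
    """Write GraphML (node kind + metrics as attributes) or a TSV edge list."""
    g = graph.copy()
    if metrics is not None:
        byn = metrics.set_index("node")
        for n in g.nodes:
            if n in byn.index:
                g.nodes[n]["k"] = int(byn.loc[n, "k"])
                g.nodes[n]["cc"] = float(byn.loc[n, "cc"])
                g.nodes[n]["clust"] = float(byn.loc[n, "clust"])
    if fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "edge_tsv":
        rows = [{"u": u, "v": v, "edge_kind": d.get("kind", "")}
                for u, v, d in sorted(g.edges(data=True))]
        pd.DataFrame(rows, columns=["u", "v", "edge_kind"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format: {fmt}")


def read_graph(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["u"], row["v"], kind=row["edge_kind"])
        return g
    raise ValueError(f"unknown format: {fmt}")
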