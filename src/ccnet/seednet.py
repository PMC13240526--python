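"""Seed-gene-centered PPI network construction.

Loads STRING-style edge lists, restricts them to seed-containing co-expression
modules, extracts the first neighbors (proximal proteins) of the seed genes,
merges the per-module neighborhoods into one network, and ranks hubs by
unweighted degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_STRING_COLUMNS = ("protein1", "protein2", "combined_score")


@dataclass
class SeedNetwork:
    """First-neighbor subnetwork around seed genes.

    ``provenance`` records, per node, the module labels through which the node
    entered the merged network.
    """

    graph: nx.Graph
    seed_flags: dict[str, bool] = field(default_factory=dict)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def degree(self) -> dict[str, int]:
        return {n: d for n, d in self.graph.degree()}

    def seeds(self) -> set[str]:
        return {n for n, flag in self.seed_flags.items() if flag}


def load_string_edges(path, threshold: float = 0.4, id_map: pd.DataFrame | None = None) -> nx.Graph:
    """Load a STRING export TSV into an undirected confidence-weighted graph.

    The score dialect is auto-detected: any combined_score > 1 means the
    0-1000 STRING scale and scores are divided by 1000. Edges with normalized
    score >= ``threshold`` (inclusive) are kept; duplicate pairs keep the
    maximum score; self-loops are dropped.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_STRING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"STRING file missing columns: {missing}")
    scores = df["combined_score"].astype(float)
    if (scores > 1).any():
        scores = scores / 1000.0
    df = df.assign(score=scores)
    if id_map is not None:
        mapping = dict(zip(id_map.iloc[:, 0].astype(str), id_map.iloc[:, 1].astype(str)))
        n_before = len(df)
        df = df.assign(
            protein1=df["protein1"].astype(str).map(mapping),
            protein2=df["protein2"].astype(str).map(mapping),
        ).dropna(subset=["protein1", "protein2"])
        dropped = n_before - len(df)
        if dropped:
            logger.warning("dropped %d edges with unmapped protein IDs", dropped)
    g = nx.Graph()
    kept = df[df["score"] >= threshold]
    for p1, p2, score in kept[["protein1", "protein2", "score"]].itertuples(index=False):
        if p1 == p2:
            continue
        if g.has_edge(p1, p2):
            g[p1][p2]["score"] = max(g[p1][p2]["score"], float(score))
        else:
            g.add_edge(p1, p2, score=float(score))
    return g


def module_subgraph(ppi: nx.Graph, module_genes) -> nx.Graph:
    """Induced PPI subgraph on a module's genes.

    Module genes absent from the PPI graph are kept as isolated nodes so they
    remain visible downstream.
    """
    genes = set(module_genes)
    if not genes:
        raise ValueError("module_genes must be nonempty")
    present = genes & set(ppi.nodes)
    if not present:
        logger.warning("no module gene present in the PPI graph")
    absent = genes - present
    if absent:
        logger.info("%d module genes absent from PPI; kept isolated", len(absent))
    sub = nx.Graph(ppi.subgraph(present))
    sub.add_nodes_from(genes)
    return sub


def first_neighbors(graph: nx.Graph, seeds, module_label: str | None = None) -> SeedNetwork:
    """Depth-1 neighborhood of the seed genes with all induced edges.

    Node set = seeds present in the graph plus their direct neighbors; the
    edge set is every graph edge among those nodes (neighbor-neighbor edges
    are retained, not just the seed star). Seeds absent from the graph are
    kept as isolated flagged nodes.
    """
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("seeds must be nonempty")
    present = [s for s in seeds if s in graph]
    absent = [s for s in seeds if s not in graph]
    if not present and not absent:
        raise ValueError("no seed gene available")
    if not present:
        raise ValueError(f"no seed gene present in the graph: {absent}")
    if absent:
        logger.warning("seed genes absent from graph, kept isolated: %s", absent)
    nodes = set(present)
    for s in present:
        nodes.update(graph.neighbors(s))
    sub = nx.Graph(graph.subgraph(nodes))
    sub.add_nodes_from(absent)
    flags = {n: n in set(seeds) for n in sub.nodes}
    prov = {n: ({module_label} if module_label else set()) for n in sub.nodes}
    return SeedNetwork(graph=sub, seed_flags=flags, provenance=prov)


def merge_networks(nets) -> SeedNetwork:
    """Union of seed networks: nodes, edges, seed flags and provenance."""
    merged = nx.Graph()
    flags: dict[str, bool] = {}
    prov: dict[str, set[str]] = {}
    for net in nets:
        merged.add_nodes_from(net.graph.nodes(data=True))
        for u, v, data in net.graph.edges(data=True):
            if merged.has_edge(u, v):
                merged[u][v]["score"] = max(merged[u][v].get("score", 0.0),
                                            data.get("score", 0.0))
            else:
                merged.add_edge(u, v, **data)
        for n in net.graph.nodes:
            flags[n] = flags.get(n, False) or net.seed_flags.get(n, False)
            prov.setdefault(n, set()).update(net.provenance.get(n, set()))
    return SeedNetwork(graph=merged, seed_flags=flags, provenance=prov)


def hub_ranking(net: SeedNetwork, top_n: int = 15) -> pd.DataFrame:
    """Degree-ranked hub table (ties broken alphabetically by gene symbol)."""
    rows = [
        {"gene": n, "degree": int(d), "is_seed": bool(net.seed_flags.get(n, False))}
        for n, d in net.graph.degree()
    ]
    if not rows:
        return pd.DataFrame(columns=["gene", "degree", "is_seed"])
    table = pd.DataFrame(rows).sort_values(
        ["degree", "gene"], ascending=[False, True], kind="mergesort"
    )
    return table.head(min(top_n, len(table))).reset_index(drop=True)


def build_seed_network(partition, selection, seeds, ppi: nx.Graph) -> SeedNetwork:
    """Compose the per-module first-neighbor networks into the merged network.

    ``selection`` is the output of :func:`ccnet.coexpr.seed_modules`; for each
    selected module, the PPI graph is restricted to the module's genes, the
    seeds falling in that module are expanded to their first neighbors, and
    the per-module networks are merged.
    """
    nets = []
    for label in selection.labels:
        module_genes = partition.module_genes(label)
        module_seeds = [s for s in seeds
                        if selection.seed_to_module.get(s) == label]
        if not module_seeds:
            continue
        sub = module_subgraph(ppi, module_genes)
        nets.append(first_neighbors(sub, module_seeds, module_label=label))
    return merge_networks(nets)


def write_edgelist_tsv(net: SeedNetwork, path) -> None:
    rows = [{"gene1": u, "gene2": v, "score": d.get("score", "")}
            for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene1", "gene2", "score"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(net: SeedNetwork, path) -> None:
    g = nx.Graph(net.graph)
    degree = net.degree
    for n in g.nodes:
        g.nodes[n]["is_seed"] = bool(net.seed_flags.get(n, False))
        g.nodes[n]["degree"] = int(degree[n])
        g.nodes[n]["provenance"] = ",".join(sorted(net.provenance.get(n, set())))
        if "ortholog_status" in g.nodes[n] and g.nodes[n]["ortholog_status"] is None:
            del g.nodes[n]["ortholog_status"]
    nx.write_graphml(g, path)
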