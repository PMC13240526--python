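"""Ortholog filtering, cross-species gene classification and conservation.

Gene symbols are compared case-insensitively after whitespace stripping
(mouse symbols are capitalized differently from human); display case is
preserved in all outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .seednet import SeedNetwork
from .utils import norm_symbol

logger = logging.getLogger(__name__)

VENN_REGIONS = ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")


class OrthologMap:
    """One-to-one gene mapping with case-insensitive lookup.

    Stores display symbols for both species; keys are normalized internally.
    """

    def __init__(self, pairs):
        self._forward: dict[str, str] = {}
        self._display_a: dict[str, str] = {}
        for a, b in pairs:
            key = norm_symbol(a)
            self._forward[key] = b
            self._display_a[key] = a

    def __len__(self) -> int:
        return len(self._forward)

    def __contains__(self, gene) -> bool:
        return norm_symbol(gene) in self._forward

    def __getitem__(self, gene) -> str:
        return self._forward[norm_symbol(gene)]

    def get(self, gene, default=None):
        return self._forward.get(norm_symbol(gene), default)

    def items(self):
        for key, b in self._forward.items():
            yield self._display_a[key], b

    def domain(self) -> set[str]:
        return set(self._display_a.values())

    def inverse(self) -> "OrthologMap":
        return OrthologMap((b, a) for a, b in self.items())


@dataclass
class ConservationReport:
    """Per-category conservation between species A and B.

    ``index_a`` = |shared| / (|shared| + |a_only|) is the A-centered
    conservation index (fraction of A's category genes with a partner in B's
    set); ``index_b`` analogous; ``jaccard`` = shared / union.
    """

    category: str
    shared: set
    a_only: set
    b_only: set
    index_a: float
    index_b: float
    jaccard: float


def one_to_one_orthologs(table: pd.DataFrame) -> OrthologMap:
    """Strict one-to-one filtering of an ortholog pair table.

    A pair survives iff its A-gene occurs exactly once in the gene_a column
    and its B-gene exactly once in the gene_b column (the reciprocal
    uniqueness required of bidirectional best hits). The result is a
    bijection between its domain and range.
    """
    if table.empty:
        raise ValueError("ortholog table is empty")
    df = table[["gene_a", "gene_b"]].astype(str)
    key_a = df["gene_a"].map(norm_symbol)
    key_b = df["gene_b"].map(norm_symbol)
    count_a = key_a.value_counts()
    count_b = key_b.value_counts()
    keep = key_a.map(count_a).eq(1) & key_b.map(count_b).eq(1)
    return OrthologMap(df[keep].itertuples(index=False, name=None))


def classify_status(genes_a, genes_b, omap: OrthologMap):
    """Split two species' gene sets into shared pairs and species-only genes."""
    genes_a, genes_b = set(genes_a), set(genes_b)
    keys_b = {norm_symbol(g) for g in genes_b}
    shared: set[tuple[str, str]] = set()
    shared_a_keys: set[str] = set()
    shared_b_keys: set[str] = set()
    for a in genes_a:
        b = omap.get(a)
        if b is not None and norm_symbol(b) in keys_b:
            shared.add((a, b))
            shared_a_keys.add(norm_symbol(a))
            shared_b_keys.add(norm_symbol(b))
    a_only = {g for g in genes_a if norm_symbol(g) not in shared_a_keys}
    b_only = {g for g in genes_b if norm_symbol(g) not in shared_b_keys}
    return shared, a_only, b_only


def conservation_indices(category_genes_a, category_genes_b, omap: OrthologMap,
                         category: str = "") -> ConservationReport:
    """The three conservation metrics for one functional category."""
    genes_a, genes_b = set(category_genes_a), set(category_genes_b)
    if not genes_a and not genes_b:
        raise ValueError("both category gene sets are empty; indices undefined")
    shared, a_only, b_only = classify_status(genes_a, genes_b, omap)
    s, ao, bo = len(shared), len(a_only), len(b_only)
    index_a = s / (s + ao) if (s + ao) else 0.0
    index_b = s / (s + bo) if (s + bo) else 0.0
    jaccard = s / (s + ao + bo) if (s + ao + bo) else 0.0
    return ConservationReport(category=category, shared=shared, a_only=a_only,
                              b_only=b_only, index_a=index_a, index_b=index_b,
                              jaccard=jaccard)


def threeway_overlap(net_a, net_b, net_c, map_ab: OrthologMap,
                     map_ac: OrthologMap, map_bc: OrthologMap):
    """Standard 7-region Venn counts across three species' gene sets.

    Genes are translated into a canonical namespace (species-A symbols where a
    mapping exists) before set placement. Pairwise maps are checked for mutual
    consistency; a gene whose A->B and A->C images disagree with the B->C map
    is logged and excluded from translation.
    """
    set_a, set_b, set_c = set(net_a), set(net_b), set(net_c)
    inconsistent: set[str] = set()
    for a in set_a:
        b, c = map_ab.get(a), map_ac.get(a)
        if b is not None and c is not None and b in map_bc:
            if norm_symbol(map_bc[b]) != norm_symbol(c):
                inconsistent.add(norm_symbol(a))
    if inconsistent:
        logger.warning("excluding %d genes with inconsistent pairwise maps",
                       len(inconsistent))

    inv_ab, inv_ac, inv_bc = map_ab.inverse(), map_ac.inverse(), map_bc.inverse()

    def canon_a(a):
        key = norm_symbol(a)
        return ("A", key) if key not in inconsistent else ("A!", key)

    def canon_b(b):
        a = inv_ab.get(b)
        if a is not None and norm_symbol(a) not in inconsistent:
            return ("A", norm_symbol(a))
        return ("B", norm_symbol(b))

    def canon_c(c):
        a = inv_ac.get(c)
        if a is not None and norm_symbol(a) not in inconsistent:
            return ("A", norm_symbol(a))
        b = inv_bc.get(c)
        if b is not None:
            return canon_b(b)
        return ("C", norm_symbol(c))

    ids_a = {canon_a(g): g for g in set_a}
    ids_b = {canon_b(g) for g in set_b}
    ids_c = {canon_c(g) for g in set_c}
    universe = set(ids_a) | ids_b | ids_c
    counts = {region: 0 for region in VENN_REGIONS}
    core: list[str] = []
    for uid in universe:
        in_a, in_b, in_c = uid in ids_a, uid in ids_b, uid in ids_c
        region = "".join(s for s, flag in zip("abc", (in_a, in_b, in_c)) if flag)
        region = region if len(region) > 1 else f"{region}_only"
        counts[region] += 1
        if in_a and in_b and in_c:
            core.append(ids_a[uid])
    return counts, sorted(core)


def homologous_network(net_a: SeedNetwork, net_b: SeedNetwork,
                       omap: OrthologMap) -> SeedNetwork:
    """Intersection of two species' seed networks on one-to-one orthologs.

    Nodes are the ortholog pairs present in both networks, named by the
    species-A symbol. An edge is retained when it is present in either
    species' induced subgraph (edge attribute ``support`` records which).
    """
    nodes_b_keys = {norm_symbol(n): n for n in net_b.graph.nodes}
    kept: dict[str, str] = {}
    for a in net_a.graph.nodes:
        b = omap.get(a)
        if b is not None and norm_symbol(b) in nodes_b_keys:
            kept[a] = nodes_b_keys[norm_symbol(b)]
    if not kept:
        logger.warning("homologous network is empty: no shared one-to-one orthologs")
    g = nx.Graph()
    g.add_nodes_from(kept)
    kept_items = sorted(kept.items())
    for i, (a1, b1) in enumerate(kept_items):
        for a2, b2 in kept_items[i + 1:]:
            in_a = net_a.graph.has_edge(a1, a2)
            in_b = net_b.graph.has_edge(b1, b2)
            if in_a or in_b:
                support = "both" if (in_a and in_b) else ("a" if in_a else "b")
                g.add_edge(a1, a2, support=support)
    flags = {
        a: bool(net_a.seed_flags.get(a, False) or net_b.seed_flags.get(b, False))
        for a, b in kept.items()
    }
    prov = {
        a: set(net_a.provenance.get(a, set())) | set(net_b.provenance.get(b, set()))
        for a, b in kept.items()
    }
    return SeedNetwork(graph=g, seed_flags=flags, provenance=prov)
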