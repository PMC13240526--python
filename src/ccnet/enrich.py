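"""Over-representation analysis and functional category rollup.

Hypergeometric upper-tail tests of a query gene set against a GMT collection
with Benjamini-Hochberg FDR control, plus classification of significant terms
into the five principal functional categories used for cross-species
comparison of chondrogenic networks.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .seednet import SeedNetwork
from .utils import norm_symbol

logger = logging.getLogger(__name__)

CATEGORIES = (
    "ECM and structural tissue constituent",
    "cell fate, differentiation and development",
    "cytoskeleton",
    "microenvironmental response",
    "signaling networks",
)
UNCLASSIFIED = "unclassified"

#: Ordered keyword rules (first match wins). User-editable via config files;
#: this default covers the common GO/KEGG vocabulary of each category.
DEFAULT_CATEGORY_RULES: list[tuple[str, list[str]]] = [
    (CATEGORIES[0], ["extracellular matrix", "collagen", "ecm", "proteoglycan",
                     "basement membrane", "structural constituent"]),
    (CATEGORIES[1], ["differentiation", "development", "cell fate", "morphogenesis",
                     "chondrocyte", "ossification", "cartilage", "skeletal"]),
    (CATEGORIES[2], ["cytoskeleton", "actin", "microtubule", "stress fiber",
                     "filament"]),
    (CATEGORIES[3], ["hypoxia", "oxidative stress", "mechanical stimulus",
                     "mechanosens", "wound", "inflammat", "response to"]),
    (CATEGORIES[4], ["signaling", "signal transduction", "pathway", "kinase",
                     "smad", "tgf", "hippo", "wnt", "pi3k", "mapk", "igf",
                     "egfr", "hif"]),
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: term<TAB>description<TAB>gene...</line>."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def hypergeom_ora(query, collection: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` against each term.

    For each term with overlap k > 0, p = P(X >= k) with population size N
    (universe), K successes (term genes in universe) and n draws (query genes
    in universe). BH adjustment runs across all tested terms. Genes outside
    the universe are dropped with a logged count; comparisons are
    case-insensitive.
    """
    uni_keys = {norm_symbol(g) for g in universe}
    if len(uni_keys) < 2:
        raise ValueError("universe must contain at least 2 genes")
    query_keys = {norm_symbol(g) for g in query}
    dropped = len(query_keys - uni_keys)
    if dropped:
        logger.warning("dropped %d query genes outside the universe", dropped)
    query_keys &= uni_keys
    if not query_keys:
        warnings.warn("query empty after universe filtering")
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p_value",
                                     "q_value", "category", "overlap_genes"])
    N, n = len(uni_keys), len(query_keys)
    rows = []
    for term, genes in collection.items():
        term_keys = {norm_symbol(g) for g in genes} & uni_keys
        K = len(term_keys)
        overlap = term_keys & query_keys
        k = len(overlap)
        if k == 0:
            continue
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0),
                     "overlap_genes": ",".join(sorted(overlap))})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p_value",
                                     "q_value", "category", "overlap_genes"])
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df["category"] = UNCLASSIFIED
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def categorize_terms(results: pd.DataFrame,
                     category_rules=None) -> pd.DataFrame:
    """Assign each term to a principal functional category.

    ``category_rules`` is an ordered list of (category, [keywords]); the first
    rule whose keyword occurs in the lower-cased term name wins; unmatched
    terms stay "unclassified".
    """
    rules = DEFAULT_CATEGORY_RULES if category_rules is None else category_rules
    for category, keywords in rules:
        if not isinstance(category, str) or not isinstance(keywords, (list, tuple)):
            raise ValueError("malformed category rules: expected (category, [keywords])")
    out = results.copy()
    cats = []
    for term in out["term"].astype(str):
        lower = term.lower()
        for category, keywords in rules:
            if any(kw.lower() in lower for kw in keywords):
                cats.append(category)
                break
        else:
            cats.append(UNCLASSIFIED)
    out["category"] = cats
    return out


def category_counts(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.Series:
    """Number of significant terms per principal category."""
    sig = results[results["q_value"] < q_threshold]
    counts = sig["category"].value_counts()
    return counts.reindex([*CATEGORIES, UNCLASSIFIED], fill_value=0)


def pathway_subnetwork(net: SeedNetwork, term_genes, status=None) -> nx.Graph:
    """Induced seed-network subgraph for one term, with ortholog annotations.

    Keeps the term genes plus all seed genes; ``status`` is the
    (shared, a_only, b_only) triple from ``classify_status`` used to color
    nodes by ortholog status.
    """
    term_keys = {norm_symbol(g) for g in term_genes}
    seeds = net.seeds()
    keep = [n for n in net.graph.nodes
            if norm_symbol(n) in term_keys or n in seeds]
    if not any(norm_symbol(n) in term_keys for n in keep):
        warnings.warn("term does not overlap the network; only seed nodes kept")
    sub = nx.Graph(net.graph.subgraph(keep))
    shared_keys, a_keys, b_keys = set(), set(), set()
    if status is not None:
        shared, a_only, b_only = status
        shared_keys = {norm_symbol(a) for a, _b in shared} | {norm_symbol(b) for _a, b in shared}
        a_keys = {norm_symbol(g) for g in a_only}
        b_keys = {norm_symbol(g) for g in b_only}
    for n in sub.nodes:
        key = norm_symbol(n)
        if key in shared_keys:
            label = "shared"
        elif key in a_keys:
            label = "a_only"
        elif key in b_keys:
            label = "b_only"
        else:
            label = "unknown"
        sub.nodes[n]["ortholog_status"] = label
        sub.nodes[n]["is_seed"] = n in seeds
    return sub
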