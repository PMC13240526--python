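"""End-to-end orchestration of the per-species and cross-species analysis.

A single YAML/dict config drives the whole run; one master seed is split
deterministically into per-stage seeds so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import coexpr, enrich, io, orthomap, seednet, stability
from .coexpr import CoexprParams
from .utils import split_seed

logger = logging.getLogger(__name__)

DEFAULTS = {
    "ppi_threshold": 0.4,
    "bootstrap_n_iter": 10,
    "bootstrap_frac": 0.8,
    "leaveout_frac": 0.1,
    "alpha": 0.05,
    "q_threshold": 0.05,
    "hub_top_n": 15,
    "seed": 0,
    "sc_profile": "hipsc",
}


class ConfigError(ValueError):
    """Raised with every validation problem collected in one pass."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid config:\n" + "\n".join(f"- {p}" for p in self.problems))


@dataclass
class SpeciesInputs:
    expression: str
    metadata: str
    ppi: str
    gmt: str | None = None
    seeds: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    species: dict[str, SpeciesInputs]
    outdir: str
    ortholog_tables: dict[tuple[str, str], str] = field(default_factory=dict)
    coexpr: CoexprParams = field(default_factory=CoexprParams)
    ppi_threshold: float = DEFAULTS["ppi_threshold"]
    bootstrap_n_iter: int = DEFAULTS["bootstrap_n_iter"]
    bootstrap_frac: float = DEFAULTS["bootstrap_frac"]
    leaveout_frac: float = DEFAULTS["leaveout_frac"]
    alpha: float = DEFAULTS["alpha"]
    q_threshold: float = DEFAULTS["q_threshold"]
    hub_top_n: int = DEFAULTS["hub_top_n"]
    seed: int = DEFAULTS["seed"]
    sc_profile: str = DEFAULTS["sc_profile"]

    def digest(self) -> str:
        payload = json.dumps({
            "species": {k: vars(v) for k, v in sorted(self.species.items())},
            "params": {k: getattr(self, k) for k in DEFAULTS},
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(source) -> RunConfig:
    """Parse and validate a config file or dict, reporting all problems at once."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    problems: list[str] = []
    species_cfg = raw.get("species") or {}
    if not species_cfg:
        problems.append("no species configured")
    species: dict[str, SpeciesInputs] = {}
    for name, entry in species_cfg.items():
        entry = entry or {}
        si = SpeciesInputs(
            expression=entry.get("expression", ""),
            metadata=entry.get("metadata", ""),
            ppi=entry.get("ppi", ""),
            gmt=entry.get("gmt"),
            seeds=list(entry.get("seeds") or []),
        )
        for label in ("expression", "metadata", "ppi"):
            path = getattr(si, label)
            if not path:
                problems.append(f"{name}: missing {label} path")
            elif not Path(path).exists():
                problems.append(f"{name}: {label} path does not exist: {path}")
        if si.gmt and not Path(si.gmt).exists():
            problems.append(f"{name}: gmt path does not exist: {si.gmt}")
        if not si.seeds:
            problems.append(f"{name}: seed gene list is empty")
        species[name] = si
    ortho_cfg = raw.get("ortholog_tables") or {}
    ortholog_tables: dict[tuple[str, str], str] = {}
    for key, path in ortho_cfg.items():
        pair = tuple(key.split(":")) if isinstance(key, str) else tuple(key)
        if len(pair) != 2:
            problems.append(f"bad ortholog table key: {key!r} (expected 'a:b')")
            continue
        if not Path(path).exists():
            problems.append(f"ortholog table path does not exist: {path}")
        ortholog_tables[pair] = path
    params = {k: raw.get(k, v) for k, v in DEFAULTS.items()}
    if not 0 <= params["ppi_threshold"] <= 1:
        problems.append("ppi_threshold must lie in [0, 1]")
    outdir = raw.get("outdir", "")
    if not outdir:
        problems.append("missing outdir")
    coexpr_params = CoexprParams(**(raw.get("coexpr") or {}))
    if problems:
        raise ConfigError(problems)
    return RunConfig(species=species, outdir=outdir,
                     ortholog_tables=ortholog_tables, coexpr=coexpr_params,
                     **params)


@dataclass
class SpeciesBundle:
    partition: coexpr.ModulePartition
    selection: coexpr.SeedModuleSelection
    network: seednet.SeedNetwork
    hubs: "object"
    stability_report: stability.StabilityReport
    retention: stability.RetentionReport | None
    enrichment: "object"


def run_species(config: RunConfig, species: str) -> SpeciesBundle:
    """coexpr -> seednet -> stability -> enrich for one species."""
    if species not in config.species:
        raise KeyError(f"species '{species}' not in config")
    si = config.species[species]
    outdir = Path(config.outdir) / species
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"ccnet config={config.digest()} species={species}"
    stage_seeds = split_seed(config.seed, 8)

    expr = io.read_expression(si.expression, si.metadata)
    ppi = seednet.load_string_edges(si.ppi, threshold=config.ppi_threshold)

    params = config.coexpr
    partition = stability._run_partition(expr.values, params)
    partition = coexpr.module_eigengenes(expr.values, partition)
    if partition.eigengenes is None or not len(partition.eigengenes):
        raise RuntimeError(f"stage coexpr failed for {species}: no module detected")
    trait = coexpr.module_trait_correlation(partition.eigengenes, expr.day)
    partition.trait_cor = trait
    selection = coexpr.seed_modules(partition, si.seeds, trait, alpha=config.alpha)
    network = seednet.build_seed_network(partition, selection, si.seeds, ppi)
    hubs = seednet.hub_ranking(network, top_n=config.hub_top_n)
    boot = stability.bootstrap_stability(expr, params, config.bootstrap_n_iter,
                                         config.bootstrap_frac, seed=stage_seeds[0])
    try:
        retention = stability.leaveout_retention(expr, params, si.seeds, ppi,
                                                 config.leaveout_frac,
                                                 seed=stage_seeds[1],
                                                 alpha=config.alpha)
        boot.retention_rate = retention.retention_rate
    except ValueError as exc:
        logger.warning("leave-out retention unavailable for %s: %s", species, exc)
        retention = None
    enrichment = None
    if si.gmt:
        collection = enrich.read_gmt(si.gmt)
        enrichment = enrich.hypergeom_ora(network.nodes, collection,
                                          universe=set(expr.genes))
        enrichment = enrich.categorize_terms(enrichment)

    io.write_table(partition.labels.rename("module").to_frame(),
                   outdir / "partition.tsv", stamp)
    io.write_table(partition.eigengenes, outdir / "eigengenes.tsv", stamp)
    io.write_table(trait, outdir / "trait_correlation.tsv", stamp)
    io.write_table(hubs, outdir / "hubs.tsv", stamp, index=False)
    seednet.write_edgelist_tsv(network, outdir / "seed_network_edges.tsv")
    seednet.write_graphml(network, outdir / "seed_network.graphml")
    with open(outdir / "stability.json", "w") as fh:
        json.dump(boot.to_dict(), fh, indent=2)
    if retention is not None:
        io.write_table(
            _retention_frame(retention), outdir / "retention_genes.tsv",
            stamp, index=False)
    if enrichment is not None:
        io.write_table(enrichment, outdir / "enrichment.tsv", stamp, index=False)
        io.write_table(enrich.category_counts(enrichment, config.q_threshold)
                       .rename("n_terms").to_frame(),
                       outdir / "category_counts.tsv", stamp)
    return SpeciesBundle(partition=partition, selection=selection, network=network,
                         hubs=hubs, stability_report=boot, retention=retention,
                         enrichment=enrichment)


def _retention_frame(retention: stability.RetentionReport):
    import pandas as pd

    rows = [{"gene": g, "status": "retained"} for g in sorted(retention.retained_genes)]
    rows += [{"gene": g, "status": "lost"} for g in sorted(retention.lost_genes)]
    rows += [{"gene": g, "status": "gained"} for g in sorted(retention.gained_genes)]
    return pd.DataFrame(rows, columns=["gene", "status"])


def run_crossspecies(config: RunConfig, species_a: str, species_b: str,
                     species_c: str | None = None,
                     bundles: dict[str, SpeciesBundle] | None = None) -> dict:
    """Ortholog-based conservation analysis of two (or three) species bundles."""
    bundles = bundles or {}
    for sp in filter(None, (species_a, species_b, species_c)):
        if sp not in bundles:
            bundles[sp] = run_species(config, sp)
    table_path = (config.ortholog_tables.get((species_a, species_b))
                  or config.ortholog_tables.get((species_b, species_a)))
    if table_path is None:
        raise ConfigError([f"no ortholog table for pair ({species_a}, {species_b})"])
    table = io.read_ortholog_table(table_path)
    if (species_a, species_b) not in config.ortholog_tables:
        table = table.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
    omap = orthomap.one_to_one_orthologs(table)

    net_a, net_b = bundles[species_a].network, bundles[species_b].network
    overall = orthomap.conservation_indices(net_a.nodes, net_b.nodes, omap,
                                            category="network")
    reports = [overall]
    gmt_path = config.species[species_a].gmt
    if gmt_path:
        collection = enrich.read_gmt(gmt_path)
        for term, genes in collection.items():
            keys = {g.strip().casefold() for g in genes}
            cat_a = {g for g in net_a.nodes if g.strip().casefold() in keys}
            cat_b = _category_genes_b(net_b, genes, omap)
            if not cat_a and not cat_b:
                continue
            reports.append(orthomap.conservation_indices(cat_a, cat_b, omap,
                                                         category=term))
    homolog = orthomap.homologous_network(net_a, net_b, omap)

    outdir = Path(config.outdir) / f"{species_a}_vs_{species_b}"
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"ccnet config={config.digest()} pair={species_a}:{species_b}"
    io.write_table(_conservation_frame(reports), outdir / "conservation.tsv",
                   stamp, index=False)
    seednet.write_graphml(homolog, outdir / "homologous_network.graphml")

    result = {"conservation": reports, "homologous_network": homolog}
    if species_c is not None:
        pairs = {}
        for x, y in ((species_a, species_b), (species_a, species_c),
                     (species_b, species_c)):
            path = (config.ortholog_tables.get((x, y))
                    or config.ortholog_tables.get((y, x)))
            if path is None:
                raise ConfigError([f"no ortholog table for pair ({x}, {y})"])
            t = io.read_ortholog_table(path)
            if (x, y) not in config.ortholog_tables:
                t = t.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
            pairs[(x, y)] = orthomap.one_to_one_orthologs(t)
        counts, core = orthomap.threeway_overlap(
            bundles[species_a].network.nodes,
            bundles[species_b].network.nodes,
            bundles[species_c].network.nodes,
            pairs[(species_a, species_b)],
            pairs[(species_a, species_c)],
            pairs[(species_b, species_c)],
        )
        with open(Path(config.outdir) / "venn_counts.json", "w") as fh:
            json.dump({"counts": counts, "core": core}, fh, indent=2)
        result["venn_counts"] = counts
        result["core_genes"] = core
    return result


def _category_genes_b(net_b, term_genes, omap: orthomap.OrthologMap) -> set:
    """Species-B network genes whose A-side ortholog lies in the term set."""
    keys = {g.strip().casefold() for g in term_genes}
    inv = omap.inverse()
    out = set()
    for g in net_b.nodes:
        a = inv.get(g)
        if a is not None and a.strip().casefold() in keys:
            out.add(g)
        elif g.strip().casefold() in keys:
            out.add(g)
    return out


def _conservation_frame(reports):
    import pandas as pd

    return pd.DataFrame([
        {"category": r.category, "n_shared": len(r.shared),
         "n_a_only": len(r.a_only), "n_b_only": len(r.b_only),
         "index_a": r.index_a, "index_b": r.index_b, "jaccard": r.jaccard}
        for r in reports
    ])
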