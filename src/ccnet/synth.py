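"""Synthetic multi-species fixtures with known ground truth.

Generates everything the pipeline consumes — time-course bulk expression with
planted co-expression modules containing CCN-like seed genes, PPI graphs
denser inside planted modules, ortholog tables mixing one-to-one, one-to-many
and species-specific genes, GMT collections overlapping the planted modules,
and single-cell count matrices with a planted high-activity population — so
every downstream stage can be tested against the planted truth. All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

SPECIES = ("human", "mouse", "chicken")

#: CCN-family seed genes per species; the chicken genome lacks a CCN6
#: ortholog, which downstream stages must tolerate.
SEED_GENES = {
    "human": ["CCN1", "CCN2", "CCN3", "CCN4", "CCN5", "CCN6"],
    "mouse": ["Ccn1", "Ccn2", "Ccn3", "Ccn4", "Ccn5", "Ccn6"],
    "chicken": ["CCN1", "CCN2", "CCN3", "CCN4", "CCN5"],
}

_GENE_STYLE = {
    "human": "GENE{:04d}",
    "mouse": "Gene{:04d}",
    "chicken": "CHGENE{:04d}",
}

BACKGROUND = "none"

_GMT_NAMES = (
    "extracellular matrix organization",
    "cartilage development",
    "cytoskeleton organization",
    "response to hypoxia",
    "TGF-beta signaling pathway",
    "chondrocyte differentiation",
    "collagen fibril organization",
    "PI3K-Akt signaling pathway",
)


@dataclass
class BulkTruth:
    """Planted structure behind one species' bulk expression matrix."""

    module_of_gene: dict[str, str]
    seed_genes: list[str]
    day_of_sample: dict[str, float]
    noise_sd: float
    ortholog_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == label]

    def planted_labels(self) -> list[str]:
        labels = sorted({m for m in self.module_of_gene.values() if m != BACKGROUND})
        return labels


@dataclass
class ScTruth:
    """Planted structure behind the single-cell fixture."""

    population_of_cell: dict[str, str]
    time_of_cell: dict[str, str]
    active_set: str
    mito_genes: list[str]
    active_population: str = ""
    active_genes: list[str] = field(default_factory=list)
    lr_pair: tuple[str, str] = ("CCN1", "ITGB1")
    senders: list[str] = field(default_factory=list)
    receivers: list[str] = field(default_factory=list)
    qc_violators: dict[str, str] = field(default_factory=dict)


def _latent_profile(module_index: int, day: np.ndarray) -> np.ndarray:
    """Low-order monotone/polynomial maturation profile of culture day."""
    t = (day - day.mean()) / (day.std() if day.std() > 0 else 1.0)
    kind = module_index % 3
    if kind == 0:
        profile = t  # monotone maturation
    elif kind == 1:
        profile = -t  # monotone decline
    else:
        profile = t**2  # transient peak/valley
    sd = profile.std()
    if sd > 0:
        profile = (profile - profile.mean()) / sd
    return profile


def generate_bulk_multispecies(
    n_genes: int = 120,
    timepoints=(1.0, 3.0, 6.0, 10.0),
    reps_per_timepoint: int = 3,
    n_modules: int = 3,
    module_size: int = 30,
    trait_effect: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    species=SPECIES,
):
    """Per-species expression matrices with planted day-driven modules.

    Genes in the same planted module share a common day-dependent latent
    profile (per-gene loading x trait_effect x latent + Gaussian noise);
    non-module genes are pure noise. Seed genes occupy the first planted
    module. Returns ``(exprs, truths)``, two dicts keyed by species.
    """
    timepoints = [float(t) for t in timepoints]
    if len(timepoints) < 2:
        raise ValueError("at least 2 timepoints required (trait degenerate otherwise)")
    if sorted(timepoints) != timepoints or len(set(timepoints)) != len(timepoints):
        raise ValueError("timepoints must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_modules * module_size > n_genes:
        raise ValueError("module capacity exceeded: n_modules * module_size > n_genes")
    rng = np.random.default_rng(seed)
    day = np.repeat(timepoints, reps_per_timepoint).astype(float)
    n_samples = day.size
    latents = {m: _latent_profile(m, day) for m in range(n_modules)}

    exprs: dict[str, ExpressionMatrix] = {}
    truths: dict[str, BulkTruth] = {}
    for sp in species:
        seeds = list(SEED_GENES.get(sp, []))
        style = _GENE_STYLE.get(sp, sp[:2].upper() + "G{:04d}")
        generic = [style.format(i) for i in range(n_genes)]
        module_of_gene: dict[str, str] = {}
        gene_rows: list[str] = []
        cursor = 0
        for m in range(n_modules):
            label = f"planted{m + 1}"
            members: list[str] = []
            if m == 0:
                members.extend(seeds[: module_size])
            while len(members) < module_size and cursor < n_genes:
                members.append(generic[cursor])
                cursor += 1
            for g in members:
                module_of_gene[g] = label
            gene_rows.extend(members)
        for g in generic[cursor:]:
            module_of_gene[g] = BACKGROUND
            gene_rows.append(g)

        X = np.empty((len(gene_rows), n_samples))
        for i, g in enumerate(gene_rows):
            label = module_of_gene[g]
            if label == BACKGROUND:
                X[i] = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else 0.0
            else:
                m = int(label.removeprefix("planted")) - 1
                loading = rng.uniform(0.8, 1.2)
                noise = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else 0.0
                X[i] = loading * trait_effect * latents[m] + noise
        sample_ids = [f"{sp}_d{int(d) if float(d).is_integer() else d}_r{r + 1}"
                      for d, r in zip(day, np.tile(range(reps_per_timepoint),
                                                   len(timepoints)))]
        values = pd.DataFrame(X, index=gene_rows, columns=sample_ids)
        meta = pd.DataFrame({
            "species": sp,
            "day": day,
            "replicate": np.tile(range(1, reps_per_timepoint + 1), len(timepoints)),
        }, index=sample_ids)
        exprs[sp] = ExpressionMatrix(values, meta)
        truths[sp] = BulkTruth(
            module_of_gene=module_of_gene,
            seed_genes=seeds,
            day_of_sample=dict(zip(sample_ids, day)),
            noise_sd=noise_sd,
        )
    return exprs, truths


def generate_ppi(truth: BulkTruth, p_within: float = 0.8, p_between: float = 0.05,
                 score_range=(0.4, 1.0), seed: int = 0) -> nx.Graph:
    """STRING-like PPI graph, denser inside planted modules.

    Edge presence is Bernoulli with probability ``p_within`` for gene pairs of
    the same planted module and ``p_between`` otherwise; confidence scores are
    uniform in ``score_range``.
    """
    lo, hi = float(score_range[0]), float(score_range[1])
    if not (0 <= p_within <= 1 and 0 <= p_between <= 1):
        raise ValueError("edge probabilities must lie in [0, 1]")
    if p_within < p_between:
        raise ValueError("p_within must be >= p_between")
    if not (0 <= lo <= hi <= 1):
        raise ValueError("score_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    genes = list(truth.module_of_gene)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, gi in enumerate(genes):
        mi = truth.module_of_gene[gi]
        for gj in genes[i + 1:]:
            mj = truth.module_of_gene[gj]
            p = p_within if (mi == mj and mi != BACKGROUND) else p_between
            if p > 0 and rng.random() < p:
                g.add_edge(gi, gj, score=float(rng.uniform(lo, hi)))
    return g


def _base_index(symbol: str, style: str) -> int | None:
    prefix, suffix = style.split("{:04d}")
    if symbol.startswith(prefix) and symbol.endswith(suffix):
        digits = symbol[len(prefix):len(symbol) - len(suffix) if suffix else None]
        if digits.isdigit():
            return int(digits)
    return None


def generate_orthologs_and_genesets(
    truths: dict[str, BulkTruth],
    frac_one2one: float = 0.7,
    frac_species_only: float = 0.15,
    n_sets: int = 6,
    seed: int = 0,
):
    """Ortholog pair tables for every species pair plus per-species GMTs.

    Generic genes are assigned a homology type (one2one / one2many /
    species-specific) with the requested fractions; seed genes are always
    one-to-one where both species carry them. One-to-many genes are emitted
    as two rows sharing partners, so strict one-to-one filtering removes
    them. Each GMT set is built around one planted module, guaranteeing
    overlap with the module structure.

    Returns ``(tables, gmts, type_of_base)`` where ``tables`` maps an ordered
    species pair to its DataFrame(gene_a, gene_b, homology_type).
    """
    if frac_one2one + frac_species_only > 1:
        raise ValueError("frac_one2one + frac_species_only must not exceed 1")
    rng = np.random.default_rng(seed)
    species = list(truths)
    # shared base-gene ids present in every species
    base_ids = None
    for sp, truth in truths.items():
        style = _GENE_STYLE.get(sp, sp[:2].upper() + "G{:04d}")
        ids = {_base_index(g, style) for g in truth.module_of_gene}
        ids.discard(None)
        base_ids = ids if base_ids is None else (base_ids & ids)
    base_ids = sorted(base_ids or set())
    n = len(base_ids)
    n_one = int(round(frac_one2one * n))
    n_only = int(round(frac_species_only * n))
    n_many = max(n - n_one - n_only, 0)
    types = (["one2one"] * n_one + ["none"] * n_only + ["one2many"] * n_many)
    types = types[:n]
    perm = rng.permutation(n)
    type_of_base = {base_ids[perm[i]]: types[i] for i in range(n)}

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            style_a = _GENE_STYLE.get(a, a[:2].upper() + "G{:04d}")
            style_b = _GENE_STYLE.get(b, b[:2].upper() + "G{:04d}")
            rows = []
            seeds_a = {g.upper(): g for g in truths[a].seed_genes}
            seeds_b = {g.upper(): g for g in truths[b].seed_genes}
            for key in sorted(seeds_a.keys() & seeds_b.keys()):
                rows.append((seeds_a[key], seeds_b[key], "one2one"))
            one2one_ids = [bid for bid in base_ids if type_of_base[bid] == "one2one"]
            many_ids = [bid for bid in base_ids if type_of_base[bid] == "one2many"]
            for bid in one2one_ids:
                rows.append((style_a.format(bid), style_b.format(bid), "one2one"))
            # one-to-many: pair up pool members so each A gene maps to two B
            # genes and each involved B gene appears under two A genes
            for j, bid in enumerate(many_ids):
                partner = many_ids[(j + 1) % len(many_ids)]
                if partner == bid:
                    continue
                rows.append((style_a.format(bid), style_b.format(bid), "one2many"))
                rows.append((style_a.format(bid), style_b.format(partner), "one2many"))
            table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "homology_type"])
            table = table.drop_duplicates(["gene_a", "gene_b"]).reset_index(drop=True)
            tables[(a, b)] = table
            truths[a].ortholog_pairs.extend(
                tuple(r) for r in table.itertuples(index=False))

    gmts: dict[str, dict[str, set[str]]] = {}
    for sp, truth in truths.items():
        labels = truth.planted_labels()
        background = truth.module_genes(BACKGROUND)
        sets: dict[str, set[str]] = {}
        for j in range(n_sets):
            name = _GMT_NAMES[j % len(_GMT_NAMES)]
            if name in sets:
                name = f"{name} {j}"
            module = truth.module_genes(labels[j % len(labels)])
            take = max(3, int(0.6 * len(module)))
            members = set(rng.choice(module, size=min(take, len(module)),
                                     replace=False))
            if background:
                members |= set(rng.choice(background,
                                          size=min(3, len(background)),
                                          replace=False))
            sets[name] = members
        gmts[sp] = sets
    return tables, gmts, type_of_base


def generate_singlecell(
    n_cells: int = 500,
    populations=("mesenchyme_1", "mesenchyme_2", "chondrocytes_1", "chondrocytes_2"),
    timepoints=("D1", "D7", "D14"),
    active_set_size: int = 20,
    activity_shift: float = 2.0,
    mito_frac_spec=("beta", 2.0, 38.0),
    n_genes: int = 300,
    n_mito: int = 10,
    seed: int = 0,
):
    """Negative-binomial single-cell counts with a planted active population.

    One population (the first) carries the "ccn_network" gene set with mean
    expression multiplied by exp(activity_shift); a CCN1 ligand is elevated in
    the mesenchymal (sender) populations and an ITGB1 receptor in the
    chondrocyte (receiver) populations. Three sentinel cells violating each QC
    rule (near-empty, everything-detected, high mitochondrial content) are
    always planted so QC filters are exercised. Returns ``(AnnData, ScTruth)``.
    """
    populations = list(populations)
    if len(populations) < 2:
        raise ValueError("at least 2 populations required for a planted contrast")
    if active_set_size < 1:
        raise ValueError("active_set_size must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"SCG{i:04d}" for i in range(n_genes)]
    mito_genes = [f"MT-SCG{i:04d}" for i in range(n_mito)]
    ligand, receptor = "CCN1", "ITGB1"
    all_genes = genes + mito_genes + [ligand, receptor]
    active_genes = genes[:active_set_size]
    active_population = populations[0]
    senders = [p for p in populations if "mesen" in p.lower()] or populations[:1]
    receivers = [p for p in populations if "chondro" in p.lower()] or populations[-1:]

    cells = [f"cell{i:05d}" for i in range(n_cells)]
    pop = rng.choice(populations, size=n_cells)
    time = rng.choice(list(timepoints), size=n_cells)
    # guarantee every population and time point occurs
    for j, p in enumerate(populations):
        pop[j + 3] = p
    for j, t in enumerate(timepoints):
        time[len(populations) + j + 3] = t

    base_mean = rng.gamma(shape=2.0, scale=1.0, size=n_genes) + 0.1
    mito_base = rng.gamma(shape=2.0, scale=1.0, size=n_mito) + 0.1
    if callable(mito_frac_spec):
        mito_frac = np.asarray(mito_frac_spec(rng, n_cells), dtype=float)
    else:
        dist, p1, p2 = mito_frac_spec
        if dist == "beta":
            mito_frac = rng.beta(p1, p2, size=n_cells)
        elif dist == "uniform":
            mito_frac = rng.uniform(p1, p2, size=n_cells)
        else:
            raise ValueError(f"unknown mito fraction sampler: {dist}")
    mito_frac = np.clip(mito_frac, 0.0, 0.95)

    depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    dispersion = 2.0  # fixed NB dispersion
    X = np.zeros((n_cells, len(all_genes)), dtype=np.int64)

    def nb(mu):
        mu = np.maximum(mu, 1e-9)
        p = dispersion / (dispersion + mu)
        return rng.negative_binomial(dispersion, p)

    lig_mean, rec_mean = 2.0, 2.0
    for c in range(n_cells):
        mu = base_mean * depth[c]
        if pop[c] == active_population:
            mu = mu.copy()
            mu[:active_set_size] *= np.exp(activity_shift)
        mu_l = lig_mean * depth[c] * (20.0 if pop[c] in senders else 0.2)
        mu_r = rec_mean * depth[c] * (20.0 if pop[c] in receivers else 0.2)
        non_mito_total = mu.sum() + mu_l + mu_r
        f = mito_frac[c]
        mu_m = mito_base / mito_base.sum() * (f / (1.0 - f)) * non_mito_total
        X[c, :n_genes] = nb(mu)
        X[c, n_genes:n_genes + n_mito] = nb(mu_m)
        X[c, -2] = nb(np.array([mu_l]))[0]
        X[c, -1] = nb(np.array([mu_r]))[0]

    qc_violators = {}
    if n_cells >= 3:
        X[0] = 0
        X[0, :3] = 1  # near-empty cell: fails any min-genes rule
        qc_violators[cells[0]] = "min_genes"
        X[1] = np.maximum(X[1], 1)  # everything detected: fails max-genes rules
        qc_violators[cells[1]] = "max_genes"
        X[2, n_genes:n_genes + n_mito] = max(int(X[2].sum()), 100)  # mito-dominated
        qc_violators[cells[2]] = "mito"

    obs = pd.DataFrame({"population": pop, "time_point": time}, index=cells)
    var = pd.DataFrame({"mito": [g.startswith("MT-") for g in all_genes]},
                       index=all_genes)
    adata = ad.AnnData(X=X.astype(float), obs=obs, var=var)
    truth = ScTruth(
        population_of_cell=dict(zip(cells, pop)),
        time_of_cell=dict(zip(cells, time)),
        active_set="ccn_network",
        mito_genes=mito_genes,
        active_population=active_population,
        active_genes=active_genes,
        lr_pair=(ligand, receptor),
        senders=senders,
        receivers=receivers,
        qc_violators=qc_violators,
    )
    return adata, truth
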