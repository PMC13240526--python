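"""Resampling-based robustness of module detection and the seed network.

Two metrics, mirroring common practice for co-expression pipelines:

* bootstrap stability — rerun module detection on random 80% sample subsets
  (drawn without replacement) and compare each partition to the full-data
  reference with a best-match, size-weighted Jaccard index;
* leave-out retention — drop 10% of samples once, rerun the whole
  module -> seed-network chain, and report the fraction of reference
  seed-network genes still recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coexpr, seednet
from .containers import ExpressionMatrix
from .coexpr import GREY, CoexprParams, ModulePartition

#: Metric definitions recorded with every report, for transparency: the
#: single-number summaries depend on these declared choices.
METRIC_DEFINITIONS = {
    "jaccard": "best-match, size-weighted Jaccard of non-grey reference modules",
    "sampling": "uniform subsample without replacement",
    "retention": "|reduced seed-network genes ∩ reference| / |reference|",
}


@dataclass
class StabilityReport:
    per_iteration_jaccard: list[float]
    mean_jaccard: float
    n_iterations: int
    sample_fraction: float
    seed: int
    retention_rate: float | None = None
    metric_definitions: dict = field(default_factory=lambda: dict(METRIC_DEFINITIONS))

    def to_dict(self) -> dict:
        return {
            "per_iteration_jaccard": list(self.per_iteration_jaccard),
            "mean_jaccard": self.mean_jaccard,
            "n_iterations": self.n_iterations,
            "sample_fraction": self.sample_fraction,
            "seed": self.seed,
            "retention_rate": self.retention_rate,
            "metric_definitions": self.metric_definitions,
        }


@dataclass
class RetentionReport:
    retention_rate: float
    reference_genes: set[str]
    retained_genes: set[str]
    lost_genes: set[str]
    gained_genes: set[str]
    left_out_samples: list[str]
    metric_definitions: dict = field(default_factory=lambda: dict(METRIC_DEFINITIONS))


def _labels_of(partition) -> pd.Series:
    if isinstance(partition, ModulePartition):
        return partition.labels
    return pd.Series(partition)


def partition_jaccard(ref, alt) -> float:
    """Best-match, size-weighted Jaccard between two gene partitions.

    For each non-grey reference module M the best Jaccard overlap with any
    non-grey module of ``alt`` is found; the module scores are averaged
    weighted by reference module size. Grey (unassigned) genes are excluded
    from both partitions.
    """
    ref_labels, alt_labels = _labels_of(ref), _labels_of(alt)
    common = ref_labels.index.intersection(alt_labels.index)
    ref_modules = {
        lab: set(common[ref_labels.loc[common] == lab])
        for lab in ref_labels.loc[common].unique() if lab != GREY
    }
    ref_modules = {lab: g for lab, g in ref_modules.items() if g}
    if not ref_modules:
        raise ValueError("reference partition has no non-grey module; metric undefined")
    alt_modules = [
        set(common[alt_labels.loc[common] == lab])
        for lab in alt_labels.loc[common].unique() if lab != GREY
    ]
    total = sum(len(g) for g in ref_modules.values())
    weighted = 0.0
    for genes in ref_modules.values():
        best = 0.0
        for alt_genes in alt_modules:
            inter = len(genes & alt_genes)
            if inter:
                best = max(best, inter / len(genes | alt_genes))
        weighted += len(genes) * best
    return weighted / total


def _run_partition(values: pd.DataFrame, params: CoexprParams) -> ModulePartition:
    values = coexpr.drop_constant_genes(values)
    if params.soft_power is None:
        power = coexpr.pick_soft_power(values, params.candidate_powers,
                                       params.r2_target, params.fallback_power).power
    else:
        power = params.soft_power
    adj = coexpr.adjacency_signed_hybrid(values, power)
    tom = coexpr.tom_similarity(adj)
    return coexpr.detect_modules(tom, params.min_module_size, params.cut_height_frac)


def bootstrap_stability(expr: ExpressionMatrix, params: CoexprParams,
                        n_iter: int = 10, frac: float = 0.8,
                        seed: int = 0) -> StabilityReport:
    """Module-partition stability under repeated sample subsampling."""
    n = expr.n_samples
    n_sub = int(np.floor(frac * n))
    if n_sub < 3:
        raise ValueError("too few samples for the requested subsample fraction")
    reference = _run_partition(expr.values, params)
    rng = np.random.default_rng(seed)
    jaccards = []
    for _ in range(n_iter):
        keep = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = expr.values.iloc[:, keep]
        part = _run_partition(sub, params)
        jaccards.append(partition_jaccard(reference, part))
    return StabilityReport(
        per_iteration_jaccard=jaccards,
        mean_jaccard=float(np.mean(jaccards)),
        n_iterations=n_iter,
        sample_fraction=frac,
        seed=seed,
    )


def _seed_network_genes(expr: ExpressionMatrix, params: CoexprParams, seeds,
                        ppi, alpha: float) -> set[str]:
    partition = _run_partition(expr.values, params)
    partition = coexpr.module_eigengenes(expr.values, partition)
    if partition.eigengenes is None or not len(partition.eigengenes):
        return set()
    trait = coexpr.module_trait_correlation(partition.eigengenes, expr.day)
    try:
        selection = coexpr.seed_modules(partition, seeds, trait, alpha=alpha)
    except LookupError:
        return set()
    net = seednet.build_seed_network(partition, selection, seeds, ppi)
    return net.nodes


def leaveout_retention(expr: ExpressionMatrix, params: CoexprParams, seeds,
                       ppi, frac_out: float = 0.1, seed: int = 0,
                       alpha: float = 0.05) -> RetentionReport:
    """Single leave-out analysis of seed-network gene retention."""
    n = expr.n_samples
    n_out = int(np.floor(frac_out * n))
    if n_out < 1:
        raise ValueError("frac_out removes no sample at this sample size")
    full = _seed_network_genes(expr, params, seeds, ppi, alpha)
    if not full:
        raise ValueError("full-run seed network is empty; retention undefined")
    rng = np.random.default_rng(seed)
    out_idx = np.sort(rng.choice(n, size=n_out, replace=False))
    keep = [s for i, s in enumerate(expr.values.columns) if i not in set(out_idx)]
    reduced_expr = expr.subset_samples(keep)
    reduced = _seed_network_genes(reduced_expr, params, seeds, ppi, alpha)
    retained = reduced & full
    return RetentionReport(
        retention_rate=len(retained) / len(full),
        reference_genes=full,
        retained_genes=retained,
        lost_genes=full - reduced,
        gained_genes=reduced - full,
        left_out_samples=[expr.values.columns[i] for i in out_idx],
    )
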