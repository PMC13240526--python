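"""Weighted co-expression module detection.

Implements a signed-hybrid adjacency (positive correlations raised to a soft
power, negative ones zeroed), topological overlap, average-linkage clustering
with a static height cut, module eigengenes and module-trait correlation. The
module labels follow the conventional color sequence with the largest module
named "turquoise" and unassigned genes collected in "grey".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

GREY = "grey"

#: Module color sequence, assigned in decreasing module-size order.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class CoexprParams:
    """Tunable parameters of the co-expression stage."""

    soft_power: int | None = None  # None -> pick via scale-free criterion
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    fallback_power: int = 9
    min_module_size: int = 30
    cut_height_frac: float = 0.98
    correlation: str = "pearson"

    def __post_init__(self) -> None:
        if self.soft_power is not None and self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.cut_height_frac <= 1:
            raise ValueError("cut_height_frac must be in (0, 1]")


@dataclass
class ModulePartition:
    """Gene -> module assignment with optional eigengene summaries."""

    labels: pd.Series
    eigengenes: pd.DataFrame | None = None
    trait_cor: pd.DataFrame | None = None
    variance_explained: pd.Series | None = None

    @property
    def module_labels(self) -> list[str]:
        """Non-grey labels in decreasing size order."""
        counts = self.labels[self.labels != GREY].value_counts()
        order = sorted(counts.index, key=lambda c: (-counts[c], c))
        return order

    def module_genes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class PowerFit:
    power: int
    table: pd.DataFrame
    fallback_used: bool = False


@dataclass
class SeedModuleSelection:
    labels: list[str]
    seed_to_module: dict[str, str]
    unassigned_seeds: list[str]


def _as_values(expr) -> pd.DataFrame:
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    return pd.DataFrame(expr)


def drop_constant_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance genes; correlation is undefined for them."""
    sd = values.std(axis=1, ddof=0)
    constant = sd <= 0
    if constant.any():
        logger.warning("dropping %d constant-expression genes", int(constant.sum()))
    return values.loc[~constant]


def adjacency_signed_hybrid(expr, beta: int) -> pd.DataFrame:
    """Signed-hybrid adjacency: a_ij = cor(i, j)**beta if cor > 0 else 0."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    values = drop_constant_genes(_as_values(expr))
    if values.shape[1] < 3:
        raise ValueError("at least 3 samples required for co-expression adjacency")
    if values.shape[0] == 0:
        raise ValueError("no non-constant genes left")
    cor = np.corrcoef(values.to_numpy(dtype=float))
    cor = np.atleast_2d(cor)
    adj = np.where(cor > 0, np.clip(cor, 0, 1) ** beta, 0.0)
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=values.index, columns=values.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity distribution.

    Bins connectivity into equal-width bins and linearly regresses
    log10(frequency) on log10(mean connectivity). Returns (r_squared, slope);
    ``(nan, nan)`` when fewer than 5 non-empty bins are available.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 5:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        log_freq.append(np.log10(mask.sum() / k.size))
        log_k.append(np.log10(k[mask].mean()))
    if len(log_k) < 5:
        return float("nan"), float("nan")
    slope, _intercept, r, _p, _se = st.linregress(log_k, log_freq)
    return float(r**2), float(slope)


def pick_soft_power(
    expr,
    candidate_powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    fallback: int = 9,
) -> PowerFit:
    """Smallest candidate power whose scale-free fit reaches ``r2_target``.

    A candidate qualifies only when the log-log fit has a negative slope over
    at least five non-empty connectivity bins. When none qualifies the
    declared fallback is returned with ``fallback_used=True``.
    """
    candidates = list(candidate_powers)
    if not candidates:
        raise ValueError("candidate_powers must be nonempty")
    if not 0 < r2_target <= 1:
        raise ValueError("r2_target must be in (0, 1]")
    values = drop_constant_genes(_as_values(expr))
    if values.shape[0] == 0:
        raise ValueError("all genes constant; cannot evaluate soft power")
    cor = np.atleast_2d(np.corrcoef(values.to_numpy(dtype=float)))
    pos = np.where(cor > 0, np.clip(cor, 0, 1), 0.0)
    rows = []
    chosen = None
    for beta in candidates:
        adj = pos**beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        r2, slope = scale_free_fit(k)
        qualifies = np.isfinite(r2) and r2 >= r2_target and slope < 0
        rows.append({"power": beta, "r_squared": r2, "slope": slope,
                     "mean_connectivity": float(k.mean()), "qualifies": qualifies})
        if qualifies and chosen is None:
            chosen = beta
    table = pd.DataFrame(rows)
    if chosen is None:
        logger.warning("no candidate power reached R^2 >= %.2f; using fallback %d",
                       r2_target, fallback)
        return PowerFit(power=fallback, table=table, fallback_used=True)
    return PowerFit(power=chosen, table=table, fallback_used=False)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the adjacency row sum excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0  # (u=i, u=j) terms vanish because diag(a0)=0
    k = a0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a0) / (kmin + 1.0 - a0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return pd.DataFrame(tom)


def _assign_colors(raw_labels: np.ndarray, genes: pd.Index,
                   min_module_size: int) -> pd.Series:
    labels = pd.Series(GREY, index=genes, dtype=object)
    sizes: list[tuple[int, str, np.ndarray]] = []
    for lab in np.unique(raw_labels):
        mask = raw_labels == lab
        if mask.sum() < min_module_size:
            continue
        first_gene = min(str(g) for g in genes[mask])
        sizes.append((int(mask.sum()), first_gene, mask))
    # decreasing size; ties broken by the lexicographically smallest member
    sizes.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_size, _first, mask) in enumerate(sizes):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[np.flatnonzero(mask)] = color
    return labels


def detect_modules(tom: pd.DataFrame, min_module_size: int = 30,
                   cut_height_frac: float = 0.98) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The tree is cut at ``cut_height_frac`` times the maximum merge height;
    clusters smaller than ``min_module_size`` fall into "grey".
    """
    if not 0 < cut_height_frac <= 1:
        raise ValueError("cut_height_frac must be in (0, 1]")
    genes = tom.index
    n = len(genes)
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes grey")
        return ModulePartition(labels=pd.Series(GREY, index=genes, dtype=object))
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    linkage = sch.linkage(condensed, method="average")
    cut = cut_height_frac * linkage[:, 2].max()
    raw = sch.fcluster(linkage, t=cut, criterion="distance")
    return ModulePartition(labels=_assign_colors(raw, genes, min_module_size))


def module_eigengenes(expr, partition: ModulePartition) -> ModulePartition:
    """First singular vector of each module's z-scored submatrix.

    The eigengene (one value per sample, unit norm) is sign-oriented so its
    correlation with the module's mean expression profile is nonnegative,
    which makes results independent of gene-row ordering. Returns a new
    partition with ``eigengenes`` (module x sample) and ``variance_explained``
    filled in.
    """
    values = _as_values(expr)
    eig_rows, var_rows = {}, {}
    for label in partition.module_labels:
        genes = [g for g in partition.module_genes(label) if g in values.index]
        if not genes:
            warnings.warn(f"module {label} has no genes in the expression matrix")
            continue
        sub = values.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        orient = float(np.dot(eig, mean_profile))
        if orient < 0:
            eig = -eig
        elif orient == 0:
            nz = np.flatnonzero(eig)
            if nz.size and eig[nz[0]] < 0:
                eig = -eig
        eig_rows[label] = eig
        total = float((s**2).sum())
        var_rows[label] = float(s[0] ** 2 / total) if total > 0 else 0.0
    eigengenes = pd.DataFrame(eig_rows, index=values.columns).T
    return ModulePartition(
        labels=partition.labels,
        eigengenes=eigengenes,
        variance_explained=pd.Series(var_rows, dtype=float),
        trait_cor=partition.trait_cor,
    )


def module_trait_correlation(eigengenes: pd.DataFrame, day_of_sample) -> pd.DataFrame:
    """Pearson correlation of each eigengene with numeric day.

    Two-sided p-values come from the t-distribution with n - 2 degrees of
    freedom via t = r * sqrt((n - 2) / (1 - r^2)).
    """
    day = np.asarray(pd.Series(day_of_sample).loc[list(eigengenes.columns)], dtype=float)
    n = day.size
    if n < 3:
        raise ValueError("at least 3 samples required for trait correlation")
    if np.ptp(day) == 0:
        raise ValueError("trait (day) is constant; correlation undefined")
    rows = []
    for label, eig in eigengenes.iterrows():
        r, p = st.pearsonr(np.asarray(eig, dtype=float), day)
        rows.append({"module": label, "cor": float(r), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("module")


def seed_modules(partition: ModulePartition, seed_genes, trait_cor: pd.DataFrame,
                 alpha: float = 0.05) -> SeedModuleSelection:
    """Non-grey, trait-significant modules that contain at least one seed gene."""
    seeds = list(seed_genes)
    if not seeds:
        raise ValueError("seed_genes must be nonempty")
    missing = [s for s in seeds if s not in partition.labels.index]
    if len(missing) == len(seeds):
        raise LookupError(f"no seed gene present in the expression data: {missing}")
    if missing:
        logger.warning("seed genes absent from expression data: %s", missing)
    seed_to_module: dict[str, str] = {}
    unassigned: list[str] = []
    selected: list[str] = []
    for s in seeds:
        if s in missing:
            continue
        label = partition.labels[s]
        seed_to_module[s] = label
        if label == GREY:
            unassigned.append(s)
            continue
        p = float(trait_cor.loc[label, "p_value"]) if label in trait_cor.index else 1.0
        if p < alpha and label not in selected:
            selected.append(label)
    return SeedModuleSelection(labels=selected, seed_to_module=seed_to_module,
                               unassigned_seeds=unassigned)


class CoexpressionModules(BaseEstimator):
    """Co-expression module detector with a scikit-learn estimator surface.

    Clusters *features* (genes), in the spirit of
    :class:`sklearn.cluster.FeatureAgglomeration`: ``fit`` takes a
    samples x genes matrix (DataFrame columns are gene symbols) and exposes
    one label per gene in ``labels_``. An optional ``y`` of per-sample day
    values enables module-trait correlation.

    Parameters
    ----------
    soft_power : int or None
        Soft-thresholding power; ``None`` picks the smallest candidate
        reaching the scale-free fit target (fallback ``fallback_power``).
    min_module_size, cut_height_frac
        Static tree-cut parameters; clusters below the minimum size are grey.
    """

    def __init__(self, soft_power=None, candidate_powers=tuple(range(1, 21)),
                 r2_target=0.8, fallback_power=9, min_module_size=30,
                 cut_height_frac=0.98):
        self.soft_power = soft_power
        self.candidate_powers = candidate_powers
        self.r2_target = r2_target
        self.fallback_power = fallback_power
        self.min_module_size = min_module_size
        self.cut_height_frac = cut_height_frac

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            values = X.T  # genes x samples
        else:
            X = np.asarray(X, dtype=float)
            values = pd.DataFrame(
                X.T, index=[f"g{i}" for i in range(X.shape[1])])
        values = drop_constant_genes(values)
        if self.soft_power is None:
            fit = pick_soft_power(values, self.candidate_powers,
                                  self.r2_target, self.fallback_power)
            self.power_, self.power_table_ = fit.power, fit.table
            self.power_fallback_used_ = fit.fallback_used
        else:
            self.power_ = int(self.soft_power)
            self.power_table_ = None
            self.power_fallback_used_ = False
        adj = adjacency_signed_hybrid(values, self.power_)
        tom = tom_similarity(adj)
        partition = detect_modules(tom, self.min_module_size, self.cut_height_frac)
        partition = module_eigengenes(values, partition)
        if y is not None and partition.eigengenes is not None and len(partition.eigengenes):
            day = pd.Series(np.asarray(y, dtype=float), index=values.columns)
            partition.trait_cor = module_trait_correlation(partition.eigengenes, day)
        self.partition_ = partition
        self.feature_names_in_ = np.asarray(values.index, dtype=object)
        self.labels_ = partition.labels.to_numpy()
        self.eigengenes_ = partition.eigengenes
        self.variance_explained_ = partition.variance_explained
        self.trait_correlation_ = partition.trait_cor
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
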