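"""Single-cell stage: QC, gene-set activity scoring and communication.

Cells live in an :class:`anndata.AnnData` (cells x genes) whose ``obs`` holds
``time_point`` and ``population`` labels and whose ``var`` carries a boolean
``mito`` flag. Activity scoring offers a recovery-curve AUC (per-cell ranking
of expression, scoring how early the set's genes appear) and a rank-sum
(Mann-Whitney-U-based) alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix
from .utils import norm_symbol

logger = logging.getLogger(__name__)

#: Named QC threshold profiles: (min_genes, max_genes, max_mito, min_cells_per_gene).
QC_PROFILES = {
    "hipsc": (200, 7000, 0.05, 3),
    "embryonic_limb": (200, 6000, 0.10, 1),
}


@dataclass
class ActivityScores:
    score: pd.Series  # cell -> score in [0, 1]
    method: str
    gene_set: str
    top_frac: float | None = None
    max_rank: int | None = None


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def _mito_mask(adata: ad.AnnData) -> np.ndarray:
    if "mito" in adata.var.columns:
        return adata.var["mito"].to_numpy(dtype=bool)
    return np.array([str(g).upper().startswith("MT-") for g in adata.var_names])


def qc_filter(adata: ad.AnnData, min_genes: int = 200, max_genes: int = 7000,
              max_mito: float = 0.05, min_cells_per_gene: int = 3):
    """Standard count-matrix QC: cells first, then genes.

    Cells are removed when their detected-gene count is strictly below
    ``min_genes`` or strictly above ``max_genes``, or when the mitochondrial
    count fraction is strictly above ``max_mito`` ("more than" thresholds
    remove strictly-greater values, so a cell exactly at a boundary is kept).
    Genes detected in fewer than ``min_cells_per_gene`` surviving cells are
    then removed. Returns ``(filtered AnnData, report dict)``.
    """
    if min_genes <= 0 or max_genes <= 0 or min_cells_per_gene <= 0:
        raise ValueError("QC thresholds must be positive")
    if max_genes <= min_genes:
        raise ValueError("max_genes must exceed min_genes")
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    mito = _mito_mask(adata)
    mito_counts = X[:, mito].sum(axis=1) if mito.any() else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    fail_min = detected < min_genes
    fail_max = detected > max_genes
    fail_mito = mito_frac > max_mito
    keep_cells = ~(fail_min | fail_max | fail_mito)
    report = {
        "n_cells_in": int(X.shape[0]),
        "removed_min_genes": int(fail_min.sum()),
        "removed_max_genes": int(fail_max.sum()),
        "removed_mito": int(fail_mito.sum()),
    }
    if not keep_cells.any():
        dominant = max(("min_genes", fail_min.sum()), ("max_genes", fail_max.sum()),
                       ("mito", fail_mito.sum()), key=lambda t: t[1])[0]
        raise ValueError(f"all cells removed by QC; dominant rule: {dominant}")
    filtered = adata[keep_cells].copy()
    detected_per_gene = (_dense(filtered.X) > 0).sum(axis=0)
    keep_genes = detected_per_gene >= min_cells_per_gene
    report["removed_genes"] = int((~keep_genes).sum())
    filtered = filtered[:, keep_genes].copy()
    report["n_cells_out"] = int(filtered.n_obs)
    report["n_genes_out"] = int(filtered.n_vars)
    report["thresholds"] = {"min_genes": min_genes, "max_genes": max_genes,
                            "max_mito": max_mito,
                            "min_cells_per_gene": min_cells_per_gene}
    return filtered, report


def normalize_log(adata: ad.AnnData) -> ad.AnnData:
    """Depth-normalize each cell to the median total count, then log1p.

    Zero-total cells are removed with a warning. The median depth used is
    recorded in ``uns['median_depth']``.
    """
    X = _dense(adata.X)
    totals = X.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"removing {int((~keep).sum())} zero-total cells")
    out = adata[keep].copy()
    X = X[keep]
    totals = totals[keep]
    median = float(np.median(totals))
    out.X = np.log1p(X * (median / totals)[:, None])
    out.uns["median_depth"] = median
    return out


def _expr_frame(data) -> pd.DataFrame:
    """Cells x genes DataFrame from AnnData or DataFrame input."""
    if isinstance(data, ad.AnnData):
        return pd.DataFrame(_dense(data.X), index=data.obs_names,
                            columns=data.var_names)
    return pd.DataFrame(data)


def _rank_order(frame: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Per-cell gene ordering by decreasing expression.

    Ties are broken lexicographically by gene symbol (columns are pre-sorted
    by name, then a stable descending argsort is applied), giving a
    deterministic total order on every platform.
    """
    cols = frame.columns.sortlevel()[0] if isinstance(frame.columns, pd.MultiIndex) \
        else pd.Index(sorted(frame.columns, key=str))
    frame = frame[cols]
    order = np.argsort(-frame.to_numpy(dtype=float), axis=1, kind="stable")
    return order, cols


def _set_mask(columns: pd.Index, gene_set, set_name: str) -> np.ndarray:
    keys = {norm_symbol(g) for g in gene_set}
    mask = np.array([norm_symbol(g) in keys for g in columns])
    if not mask.any():
        raise LookupError(f"gene set '{set_name}' has no gene in the matrix")
    return mask


def aucell_score(data, gene_set, top_frac: float = 0.05,
                 set_name: str = "gene_set") -> ActivityScores:
    """Recovery-curve AUC activity of a gene set in each cell.

    Genes are ranked per cell by decreasing expression; with T =
    ceil(top_frac * n_genes) top ranks considered and m countable set genes
    (m = min(set size in universe, T)), the score is the cumulative-hit sum
    over the top T ranks normalized by its maximum Σ_{t<=T} min(t, m), so a
    cell whose set genes occupy the very top ranks scores exactly 1.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    frame = _expr_frame(data)
    order, cols = _rank_order(frame)
    mask = _set_mask(cols, gene_set, set_name)
    n_genes = len(cols)
    T = int(np.ceil(top_frac * n_genes))
    m = min(int(mask.sum()), T)
    hits = mask[order[:, :T]]  # cells x T membership in rank order
    cum = np.cumsum(hits, axis=1)
    max_sum = np.minimum(np.arange(1, T + 1), m).sum()
    scores = cum.sum(axis=1) / max_sum
    return ActivityScores(score=pd.Series(scores, index=frame.index, name=set_name),
                          method="auc", gene_set=set_name, top_frac=top_frac)


def rank_sum_score(data, gene_set, max_rank: int = 1500,
                   set_name: str = "gene_set") -> ActivityScores:
    """Rank-sum (Mann-Whitney-U-based) gene-set activity per cell.

    With set-gene ranks clipped at ``max_rank``,
    U = Σ ranks - m(m+1)/2 and score = 1 - U / (m * max_rank), clipped to
    [0, 1]; the best case (set genes at ranks 1..m) scores exactly 1.
    """
    if max_rank < 1:
        raise ValueError("max_rank must be positive")
    frame = _expr_frame(data)
    order, cols = _rank_order(frame)
    mask = _set_mask(cols, gene_set, set_name)
    m = int(mask.sum())
    ranks = np.empty_like(order)
    n_cells, n_genes = order.shape
    row_idx = np.arange(n_cells)[:, None]
    ranks[row_idx, order] = np.arange(1, n_genes + 1)
    set_ranks = np.minimum(ranks[:, mask], max_rank)
    u = set_ranks.sum(axis=1) - m * (m + 1) / 2.0
    scores = np.clip(1.0 - u / (m * max_rank), 0.0, 1.0)
    return ActivityScores(score=pd.Series(scores, index=frame.index, name=set_name),
                          method="rank_sum", gene_set=set_name, max_rank=max_rank)


def population_proportions(cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point population composition (rows sum to 1)."""
    if cell_meta.empty:
        raise ValueError("cell metadata is empty")
    if cell_meta[["time_point", "population"]].isna().any().any():
        raise ValueError("every cell must carry time_point and population labels")
    counts = pd.crosstab(cell_meta["time_point"], cell_meta["population"])
    return counts.div(counts.sum(axis=1), axis=0)


def lr_strength(data, cell_meta: pd.DataFrame, lr_pairs, senders, receivers) -> pd.DataFrame:
    """Simplified ligand-receptor interaction strength.

    strength(sender, receiver, (L, R)) = mean normalized expression of the
    ligand L in the sender population times the mean of the receptor R in the
    receiver population. Pairs referencing unknown genes are skipped with a
    log message.
    """
    frame = _expr_frame(data)
    key_of = {norm_symbol(g): g for g in frame.columns}
    pops = set(cell_meta["population"])
    for pop in list(senders) + list(receivers):
        if pop not in pops:
            raise ValueError(f"population '{pop}' not present in metadata")
    rows = []
    for ligand, receptor in lr_pairs:
        lg, rg = key_of.get(norm_symbol(ligand)), key_of.get(norm_symbol(receptor))
        if lg is None or rg is None:
            logger.warning("skipping pair (%s, %s): gene not in matrix", ligand, receptor)
            continue
        for s in senders:
            s_cells = cell_meta.index[cell_meta["population"] == s]
            if len(s_cells) == 0:
                raise ValueError(f"sender population '{s}' is empty")
            lig_mean = float(frame.loc[s_cells, lg].mean())
            for r in receivers:
                r_cells = cell_meta.index[cell_meta["population"] == r]
                if len(r_cells) == 0:
                    raise ValueError(f"receiver population '{r}' is empty")
                rec_mean = float(frame.loc[r_cells, rg].mean())
                rows.append({"sender": s, "receiver": r, "ligand": ligand,
                             "receptor": receptor,
                             "strength": lig_mean * rec_mean})
    return pd.DataFrame(rows).sort_values("strength", ascending=False,
                                          kind="mergesort").reset_index(drop=True)


def percent_of_reference(expr: ExpressionMatrix, ref_day: float,
                         tol: float = 1e-12):
    """Per-gene mean expression by day as a percentage of a reference day.

    Genes whose reference-day mean is at or below ``tol`` are excluded from
    the table and returned in a flagged list.
    """
    day = expr.day
    days = sorted(day.unique())
    if ref_day not in days:
        raise ValueError(f"reference day {ref_day} not present in metadata")
    means = pd.DataFrame(
        {d: expr.values.loc[:, day[day == d].index].mean(axis=1) for d in days})
    ref = means[ref_day]
    flagged = list(means.index[ref.abs() <= tol])
    table = 100.0 * means.loc[ref.abs() > tol].div(ref[ref.abs() > tol], axis=0)
    return table, flagged


def pca_scores(expr: ExpressionMatrix):
    """Sample-space principal components of a bulk expression matrix.

    Genes are centered and unit-scaled (when their variance is positive)
    before singular value decomposition. Returns (scores, variance_explained)
    with one score column per component; variance_explained sums to 1. Each
    component's sign is fixed so the loading of the lexicographically first
    gene with a nonzero loading is nonnegative.
    """
    values = expr.values
    if values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    M = values.T.to_numpy(dtype=float)  # samples x genes
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (M - mu) / scale
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    gene_order = np.argsort([str(g) for g in values.index])
    for comp in range(len(s)):
        for gi in gene_order:
            loading = vt[comp, gi]
            if loading != 0:
                if loading < 0:
                    vt[comp] = -vt[comp]
                    u[:, comp] = -u[:, comp]
                break
    scores = u * s
    total = float((s**2).sum())
    var_explained = (s**2 / total) if total > 0 else np.zeros_like(s)
    score_df = pd.DataFrame(scores, index=values.columns,
                            columns=[f"PC{i + 1}" for i in range(len(s))])
    return score_df, var_explained


class GeneSetActivity(BaseEstimator, TransformerMixin):
    """Per-cell gene-set activity scoring as a scikit-learn transformer.

    Parameters
    ----------
    gene_sets : mapping of set name -> iterable of gene symbols
    method : "auc" (recovery-curve) or "rank_sum"
    top_frac : top-rank fraction for the AUC method
    max_rank : rank clip for the rank-sum method

    ``transform`` accepts a cells x genes DataFrame or AnnData and returns a
    cells x sets DataFrame of scores in [0, 1].
    """

    def __init__(self, gene_sets=None, method="auc", top_frac=0.05, max_rank=1500):
        self.gene_sets = gene_sets
        self.method = method
        self.top_frac = top_frac
        self.max_rank = max_rank

    def fit(self, X, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets must be provided")
        if self.method not in ("auc", "rank_sum"):
            raise ValueError("method must be 'auc' or 'rank_sum'")
        frame = _expr_frame(X)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "feature_names_in_"):
            raise ValueError("GeneSetActivity must be fitted before transform")
        frame = _expr_frame(X)
        out = {}
        for name, genes in self.gene_sets.items():
            if self.method == "auc":
                res = aucell_score(frame, genes, self.top_frac, set_name=name)
            else:
                res = rank_sum_score(frame, genes, self.max_rank, set_name=name)
            out[name] = res.score
        return pd.DataFrame(out, index=frame.index)
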