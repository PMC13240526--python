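"""Single-cell stage: QC, normalization, activity scores, L-R strength, PCA."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ccnet import sc, synth
from ccnet.containers import ExpressionMatrix
from ccnet.sc import (GeneSetActivity, aucell_score, lr_strength, normalize_log,
                      pca_scores, percent_of_reference, population_proportions,
                      qc_filter, rank_sum_score)


def make_adata(X, mito_mask=None, genes=None, pops=None, times=None):
    X = np.asarray(X, dtype=float)
    n_cells, n_genes = X.shape
    genes = genes or [f"g{i:03d}" for i in range(n_genes)]
    obs = pd.DataFrame({
        "population": pops or ["p0"] * n_cells,
        "time_point": times or ["t0"] * n_cells,
    }, index=[f"c{i:03d}" for i in range(n_cells)])
    var = pd.DataFrame({"mito": mito_mask if mito_mask is not None
                        else [False] * n_genes}, index=genes)
    return ad.AnnData(X=X, obs=obs, var=var)


class TestQCFilter:
    def test_min_genes_boundary_strictly_fewer_removed(self):
        X = np.zeros((3, 6))
        X[0, :2] = 1   # 2 detected -> removed at min_genes=3
        X[1, :3] = 1   # exactly 3 -> kept
        X[2, :5] = 1
        filtered, report = qc_filter(make_adata(X), min_genes=3, max_genes=6,
                                     max_mito=0.5, min_cells_per_gene=1)
        assert filtered.n_obs == 2 and report["removed_min_genes"] == 1

    def test_mito_boundary_kept_at_exact_threshold(self):
        # 5% mito exactly -> kept; above -> removed ("more than" rule)
        X = np.zeros((2, 21))
        X[0, :19] = 1
        X[0, 20] = 1   # mito 1/20 = 0.05 exactly
        X[1, :18] = 1
        X[1, 20] = 2   # mito 2/20 = 0.10
        mito = [False] * 20 + [True]
        filtered, report = qc_filter(make_adata(X, mito), min_genes=2,
                                     max_genes=25, max_mito=0.05,
                                     min_cells_per_gene=1)
        assert list(filtered.obs_names) == ["c000"]
        assert report["removed_mito"] == 1

    def test_gene_filter_applied_after_cells(self):
        X = np.zeros((4, 4))
        X[0] = [1, 1, 1, 0]
        X[1] = [1, 1, 0, 0]
        X[2] = [1, 1, 0, 1]
        X[3, 3] = 1  # fails min_genes -> removed before gene tally
        filtered, report = qc_filter(make_adata(X), min_genes=2, max_genes=4,
                                     max_mito=0.5, min_cells_per_gene=2)
        assert report["removed_genes"] == 2  # g2 (1 cell) and g3 (1 surviving cell)
        assert filtered.n_vars == 2

    def test_idempotent(self, sc_fixture):
        adata, _ = sc_fixture
        once, _ = qc_filter(adata, 50, 280, 0.2, 3)
        twice, _ = qc_filter(once, 50, 280, 0.2, 3)
        assert once.shape == twice.shape
        assert np.array_equal(once.X, twice.X)

    def test_planted_violators_removed(self, sc_fixture):
        adata, truth = sc_fixture
        filtered, _ = qc_filter(adata, 50, 280, 0.2, 3)
        assert not set(truth.qc_violators) & set(filtered.obs_names)

    def test_all_cells_removed_names_dominant_rule(self):
        X = np.ones((3, 5))
        with pytest.raises(ValueError, match="min_genes"):
            qc_filter(make_adata(X), min_genes=6, max_genes=10, max_mito=0.5,
                      min_cells_per_gene=1)

    def test_bad_thresholds_rejected(self):
        X = np.ones((2, 5))
        with pytest.raises(ValueError):
            qc_filter(make_adata(X), min_genes=10, max_genes=5, max_mito=0.1,
                      min_cells_per_gene=1)


class TestNormalizeLog:
    def test_zero_total_cell_removed(self):
        X = np.array([[0, 0, 0], [1, 2, 3]], dtype=float)
        with pytest.warns(UserWarning, match="zero-total"):
            out = normalize_log(make_adata(X))
        assert out.n_obs == 1

    def test_proportional_cells_identical_after_normalization(self):
        X = np.array([[1, 2, 3], [2, 4, 6], [10, 20, 30]], dtype=float)
        out = normalize_log(make_adata(X))
        np.testing.assert_allclose(out.X[0], out.X[1])
        np.testing.assert_allclose(out.X[0], out.X[2])

    def test_depth_equals_median_before_log(self, sc_fixture):
        adata, _ = sc_fixture
        filtered, _ = qc_filter(adata, 50, 280, 0.2, 3)
        out = normalize_log(filtered)
        sums = np.expm1(out.X).sum(axis=1)
        np.testing.assert_allclose(sums, out.uns["median_depth"], rtol=1e-6)


def brute_force_auc(row, columns, gene_set, top_frac):
    """Independent recovery-curve integration, one cell at a time."""
    order = sorted(columns, key=lambda g: (-row[g], g))
    members = {g.strip().casefold() for g in gene_set}
    T = math.ceil(top_frac * len(columns))
    m = min(sum(1 for g in columns if g.strip().casefold() in members), T)
    hits = 0
    area = 0
    for t in range(T):
        if order[t].strip().casefold() in members:
            hits += 1
        area += hits
    max_area = sum(min(t, m) for t in range(1, T + 1))
    return area / max_area


class TestAUCellScore:
    def _frame(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        return pd.DataFrame([values], index=["cell0"], columns=genes)

    def test_set_at_top_ranks_scores_one(self):
        frame = self._frame([10, 9, 5, 4, 3, 2, 1, 0.5, 0.2, 0.1])
        res = aucell_score(frame, {"g0", "g1"}, top_frac=0.5)
        assert res.score["cell0"] == pytest.approx(1.0)

    def test_hand_evaluated_mid_ranks(self):
        # set genes at ranks 4 and 5 of 10, T=5: hits (0,0,0,1,2) -> 3/9
        frame = self._frame([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        res = aucell_score(frame, {"g3", "g4"}, top_frac=0.5)
        assert res.score["cell0"] == pytest.approx(3 / 9)

    def test_set_outside_top_ranks_scores_zero(self):
        frame = self._frame([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        res = aucell_score(frame, {"g8", "g9"}, top_frac=0.5)
        assert res.score["cell0"] == 0.0

    def test_missing_set_error(self):
        frame = self._frame([1.0, 2.0])
        with pytest.raises(LookupError, match="nope"):
            aucell_score(frame, {"zzz"}, set_name="nope")

    @pytest.mark.parametrize("top_frac", [0.25, 0.5])
    def test_matches_brute_force_on_random_matrices(self, top_frac):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n_cells, n_genes = int(rng.integers(2, 11)), int(rng.integers(5, 21))
            genes = [f"g{i:02d}" for i in range(n_genes)]
            frame = pd.DataFrame(
                rng.poisson(2.0, size=(n_cells, n_genes)).astype(float),
                index=[f"c{i}" for i in range(n_cells)], columns=genes)
            gene_set = set(rng.choice(genes, size=int(rng.integers(1, 5)),
                                      replace=False))
            res = aucell_score(frame, gene_set, top_frac=top_frac)
            for cell in frame.index:
                expected = brute_force_auc(frame.loc[cell], genes, gene_set, top_frac)
                assert res.score[cell] == pytest.approx(expected)

    def test_gene_column_permutation_invariant(self, sc_fixture):
        adata, truth = sc_fixture
        filtered, _ = qc_filter(adata, 50, 280, 0.2, 3)
        norm = normalize_log(filtered)
        frame = sc._expr_frame(norm)
        rng = np.random.default_rng(0)
        shuffled = frame[rng.permutation(frame.columns)]
        r1 = aucell_score(frame, truth.active_genes)
        r2 = aucell_score(shuffled, truth.active_genes)
        pd.testing.assert_series_equal(r1.score, r2.score)


class TestRankSumScore:
    def _frame(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        return pd.DataFrame([values], index=["cell0"], columns=genes)

    def test_best_case_scores_one(self):
        frame = self._frame([9, 8, 1, 1, 1, 1, 1, 0, 0, 0])
        res = rank_sum_score(frame, {"g0", "g1"}, max_rank=10)
        assert res.score["cell0"] == pytest.approx(1.0)

    def test_worst_case_clipped_ranks(self):
        # m=2, both set genes at/beyond max_rank=10: U = 20 - 3 = 17 -> 0.15
        values = list(range(12, 0, -1))
        frame = self._frame(values)
        res = rank_sum_score(frame, {"g10", "g11"}, max_rank=10)
        assert res.score["cell0"] == pytest.approx(0.15)

    def test_promoting_a_set_gene_never_decreases_score(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 5, 15)
        frame = self._frame(values)
        gene_set = {"g7", "g12"}
        base = rank_sum_score(frame, gene_set, max_rank=10).score["cell0"]
        better = frame.copy()
        better.loc["cell0", "g7"] = better.to_numpy().max() + 1
        promoted = rank_sum_score(better, gene_set, max_rank=10).score["cell0"]
        assert promoted >= base


class TestPopulationsAndLR:
    def test_proportions_rows_sum_to_one(self):
        meta = pd.DataFrame({
            "time_point": ["t0"] * 4 + ["t1"] * 2,
            "population": ["A", "A", "B", "B", "A", "A"],
        }, index=[f"c{i}" for i in range(6)])
        table = population_proportions(meta)
        assert table.loc["t0", "A"] == pytest.approx(0.5)
        assert table.loc["t1", "B"] == pytest.approx(0.0)
        np.testing.assert_allclose(table.sum(axis=1), 1.0)

    def test_proportions_match_brute_force_tally(self, sc_fixture):
        adata, _ = sc_fixture
        table = population_proportions(adata.obs)
        for t in adata.obs["time_point"].unique():
            sub = adata.obs[adata.obs["time_point"] == t]
            for p in adata.obs["population"].unique():
                assert table.loc[t, p] == pytest.approx(
                    (sub["population"] == p).mean())

    def test_empty_metadata_error(self):
        with pytest.raises(ValueError):
            population_proportions(pd.DataFrame(columns=["time_point", "population"]))

    def test_lr_zero_receptor_zero_strength(self):
        X = np.array([[5.0, 0.0], [5.0, 0.0]])
        adata = make_adata(X, genes=["L", "R"], pops=["S", "T"])
        out = lr_strength(adata, adata.obs, [("L", "R")], ["S"], ["T"])
        assert out.loc[0, "strength"] == 0.0

    def test_lr_bilinear_in_ligand_mean(self):
        X = np.array([[2.0, 0.0], [0.0, 3.0]])
        adata = make_adata(X, genes=["L", "R"], pops=["S", "T"])
        base = lr_strength(adata, adata.obs, [("L", "R")], ["S"], ["T"])
        X2 = X.copy()
        X2[0, 0] *= 2
        doubled = lr_strength(make_adata(X2, genes=["L", "R"], pops=["S", "T"]),
                              adata.obs, [("L", "R")], ["S"], ["T"])
        assert doubled.loc[0, "strength"] == pytest.approx(
            2 * base.loc[0, "strength"])

    def test_planted_pair_ranks_first(self, sc_fixture):
        adata, truth = sc_fixture
        filtered, _ = qc_filter(adata, 50, 280, 0.2, 3)
        norm = normalize_log(filtered)
        decoys = [("SCG0100", "SCG0200"), ("SCG0150", "SCG0250")]
        out = lr_strength(norm, norm.obs, [truth.lr_pair, *decoys],
                          truth.senders, truth.receivers)
        assert (out.loc[0, "ligand"], out.loc[0, "receptor"]) == truth.lr_pair

    def test_unknown_gene_pair_skipped(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        adata = make_adata(X, genes=["L", "R"], pops=["S", "T"])
        out = lr_strength(adata, adata.obs, [("L", "R"), ("L", "NOPE")],
                          ["S"], ["T"])
        assert len(out) == 1


class TestPercentOfReference:
    def _expr(self):
        values = pd.DataFrame(
            {"s1": [2.0, 0.0], "s2": [2.0, 0.0], "s3": [4.0, 1.0], "s4": [4.0, 1.0]},
            index=["gA", "gB"])
        meta = pd.DataFrame({"species": "human", "day": [1.0, 1.0, 10.0, 10.0],
                             "replicate": [1, 2, 1, 2]}, index=values.columns)
        return ExpressionMatrix(values, meta)

    def test_reference_day_is_100_and_doubling_200(self):
        table, flagged = percent_of_reference(self._expr(), ref_day=1.0)
        assert table.loc["gA", 1.0] == pytest.approx(100.0)
        assert table.loc["gA", 10.0] == pytest.approx(200.0)

    def test_zero_reference_gene_flagged_and_excluded(self):
        table, flagged = percent_of_reference(self._expr(), ref_day=1.0)
        assert flagged == ["gB"] and "gB" not in table.index

    def test_missing_reference_day_error(self):
        with pytest.raises(ValueError, match="reference day"):
            percent_of_reference(self._expr(), ref_day=3.0)


class TestPCAScores:
    def test_two_samples_single_nonzero_component(self):
        values = pd.DataFrame([[1.0, 2.0], [0.0, 5.0], [2.0, 1.0]],
                              index=["g1", "g2", "g3"], columns=["s1", "s2"])
        meta = pd.DataFrame({"species": "x", "day": [1.0, 2.0], "replicate": 1},
                            index=["s1", "s2"])
        scores, var = pca_scores(ExpressionMatrix(values, meta))
        nonzero = (np.abs(scores) > 1e-10).any(axis=0).sum()
        assert nonzero == 1
        assert var.sum() == pytest.approx(1.0)

    def test_day_driven_fixture_pc1_tracks_day(self, standard_bulk):
        exprs, _ = standard_bulk
        expr = exprs["human"]
        scores, var = pca_scores(expr)
        r = np.corrcoef(scores["PC1"], expr.day)[0, 1]
        assert abs(r) >= 0.9
        assert var.sum() == pytest.approx(1.0)

    def test_gene_row_order_invariance(self, standard_bulk):
        exprs, _ = standard_bulk
        expr = exprs["mouse"]
        shuffled = ExpressionMatrix(expr.values.sample(frac=1.0, random_state=1),
                                    expr.samples)
        s1, _ = pca_scores(expr)
        s2, _ = pca_scores(shuffled)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-8)


class TestGeneSetActivityEstimator:
    def test_sklearn_contract_and_transform(self, sc_fixture):
        adata, truth = sc_fixture
        filtered, _ = qc_filter(adata, 50, 280, 0.2, 3)
        norm = normalize_log(filtered)
        est = GeneSetActivity(gene_sets={"active": truth.active_genes,
                                         "decoy": ["SCG0100", "SCG0200"]},
                              method="auc", top_frac=0.1)
        cloned = clone(est)
        scores = cloned.fit(norm).transform(norm)
        assert list(scores.columns) == ["active", "decoy"]
        assert scores.to_numpy().min() >= 0 and scores.to_numpy().max() <= 1
        by_pop = scores["active"].groupby(norm.obs["population"]).mean()
        assert by_pop.idxmax() == truth.active_population

    def test_active_population_ranks_first_both_methods(self, sc_fixture):
        adata, truth = sc_fixture
        filtered, _ = qc_filter(adata, 50, 280, 0.2, 3)
        norm = normalize_log(filtered)
        for method, kw in (("auc", {"top_frac": 0.1}), ("rank_sum", {"max_rank": 150})):
            est = GeneSetActivity(gene_sets={"a": truth.active_genes},
                                  method=method, **kw)
            scores = est.fit(norm).transform(norm)["a"]
            means = scores.groupby(norm.obs["population"]).mean()
            assert means.idxmax() == truth.active_population

    def test_zero_shift_populations_indistinguishable(self):
        adata, truth = synth.generate_singlecell(seed=7, activity_shift=0.0)
        filtered, _ = qc_filter(adata, 50, 280, 0.2, 3)
        norm = normalize_log(filtered)
        scores = aucell_score(norm, truth.active_genes, top_frac=0.1).score
        means = scores.groupby(norm.obs["population"]).mean()
        assert means.max() - means.min() < 0.05

    def test_unfitted_transform_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            GeneSetActivity(gene_sets={"s": ["g0"]}).transform(
                pd.DataFrame([[1.0]], columns=["g0"]))
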