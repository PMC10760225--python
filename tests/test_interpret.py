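"""SHAP additivity, enrichment statistics and adjacency interactions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from histopheno.interpret import (
    adjacency_interactions,
    bh_adjust,
    cluster_interaction_heatmap,
    decode_heatmap,
    hpc_heatmap,
    linear_shap,
    spearman_enrichment,
)


def shapley_brute_force(coef, intercept, x, background):
    """Exhaustive Shapley values over all coalitions for a linear model."""
    d = len(coef)
    import math

    def value(subset):
        z = np.where([i in subset for i in range(d)], x, background)
        return float(coef @ z + intercept)

    phi = np.zeros(d)
    for k in range(d):
        others = [i for i in range(d) if i != k]
        for r in range(d):
            for subset in itertools.combinations(others, r):
                weight = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)
                phi[k] += weight * (value(set(subset) | {k}) - value(set(subset)))
    return phi


class TestLinearShap:
    def test_background_point_gets_zero_contributions(self):
        coef = np.array([1.0, -2.0, 0.5])
        bg = np.array([0.2, 0.1, 0.3])
        shap = linear_shap(coef, 0.7, bg[None, :], bg)
        np.testing.assert_allclose(shap.values.to_numpy(), 0.0, atol=1e-12)
        assert shap.base_value == pytest.approx(coef @ bg + 0.7)

    def test_additivity_exact_per_patient(self):
        rng = np.random.default_rng(0)
        coef = rng.normal(size=6)
        X = rng.normal(size=(40, 6))
        bg = X.mean(axis=0)
        shap = linear_shap(coef, 1.3, X, bg)
        preds = X @ coef + 1.3
        assert shap.check_additivity(preds, tol=1e-9)

    def test_matches_exhaustive_shapley_enumeration(self):
        coef = np.array([0.8, -1.1, 2.0])
        x = np.array([1.0, 0.5, -0.2])
        bg = np.array([0.3, 0.3, 0.3])
        shap = linear_shap(coef, 0.4, x[None, :], bg)
        oracle = shapley_brute_force(coef, 0.4, x, bg)
        np.testing.assert_allclose(shap.values.to_numpy().ravel(), oracle, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linear_shap(np.ones(3), 0.0, np.ones((2, 4)), np.ones(3))


class TestSpearman:
    def frame(self, cols):
        return pd.DataFrame(cols, index=[f"p{i}" for i in range(len(next(iter(cols.values()))))])

    def test_monotone_compositions_give_unit_rho(self):
        comp = self.frame({"HPC0": [0.1, 0.2, 0.3, 0.4], "HPC1": [0.9, 0.8, 0.7, 0.6]})
        target = pd.Series([0, 1, 2, 3], index=comp.index)
        out = spearman_enrichment(comp, target).set_index("hpc")
        assert out.loc["HPC0", "rho"] == pytest.approx(1.0)
        assert out.loc["HPC1", "rho"] == pytest.approx(-1.0)

    def test_tied_fixture_matches_rank_formula(self):
        x = np.array([0.1, 0.3, 0.3, 0.5, 0.7, 0.9])
        y = pd.Series([1, 2, 3, 4, 5, 6], index=[f"p{i}" for i in range(6)])
        comp = self.frame({"HPC0": x})
        out = spearman_enrichment(comp, y).set_index("hpc")

        def ranks(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v), float)
            r[order] = np.arange(1, len(v) + 1)
            for val in np.unique(v):
                mask = v == val
                r[mask] = r[mask].mean()
            return r

        rx, ry = ranks(x), ranks(y.to_numpy())
        rho_hand = np.corrcoef(rx, ry)[0, 1]
        assert out.loc["HPC0", "rho"] == pytest.approx(rho_hand, abs=1e-9)

    def test_constant_target_reported_missing(self):
        comp = self.frame({"HPC0": [0.1, 0.5, 0.4]})
        target = pd.Series([1, 1, 1], index=comp.index)
        out = spearman_enrichment(comp, target)
        assert out["rho"].isna().all()


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12)

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_simulation_controls_fdr(self):
        # 200 replicates of 26 null p-values: BH at 0.01 should keep the
        # empirical false discovery rate at or below ~1%
        rng = np.random.default_rng(2)
        fdrs = []
        for _ in range(200):
            q = bh_adjust(rng.uniform(size=26))
            n_rej = int((q < 0.01).sum())
            fdrs.append(1.0 if n_rej else 0.0)  # all rejections are false here
        assert np.mean(fdrs) <= 0.015

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestAdjacencyInteractions:
    def uniform_slide(self, n=5, hpc=0):
        rows = [
            {"slide_id": "s", "grid_row": r, "grid_col": c, "hpc_id": hpc}
            for r in range(n)
            for c in range(n)
        ]
        return pd.DataFrame(rows)

    def checkerboard(self, n=10):
        rows = [
            {"slide_id": "s", "grid_row": r, "grid_col": c, "hpc_id": (r + c) % 2}
            for r in range(n)
            for c in range(n)
        ]
        return pd.DataFrame(rows)

    def test_single_hpc_slide_is_self_one_hot(self):
        m = adjacency_interactions(self.uniform_slide(), n_clusters=2)
        assert m.loc["HPC0", "HPC0"] == 1.0
        assert m["HPC1"].isna().all()

    def test_checkerboard_under_4_connectivity_is_cross_one_hot(self):
        m = adjacency_interactions(self.checkerboard(), neighborhood=4)
        assert m.loc["HPC1", "HPC0"] == 1.0
        assert m.loc["HPC0", "HPC1"] == 1.0
        assert m.loc["HPC0", "HPC0"] == 0.0

    def test_matches_exhaustive_neighbor_counting(self):
        rng = np.random.default_rng(3)
        tiles = self.checkerboard(6)
        tiles["hpc_id"] = rng.integers(0, 3, size=len(tiles))
        m = adjacency_interactions(tiles, n_clusters=3, neighborhood=8)
        # brute force: walk every tile and its 8 neighbors
        grid = {(r.grid_row, r.grid_col): r.hpc_id for r in tiles.itertuples()}
        counts = np.zeros((3, 3))
        for (r, c), k in grid.items():
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    if (r + dr, c + dc) in grid:
                        counts[grid[(r + dr, c + dc)], k] += 1
        expected = counts / counts.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(m.to_numpy(), expected, atol=1e-12)

    def test_columns_sum_to_one(self):
        m = adjacency_interactions(self.checkerboard(8), neighborhood=8)
        np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-12)

    def test_invariant_to_traversal_order(self):
        tiles = self.checkerboard(6)
        shuffled = tiles.sample(frac=1.0, random_state=4).reset_index(drop=True)
        m1 = adjacency_interactions(tiles, neighborhood=4)
        m2 = adjacency_interactions(shuffled, neighborhood=4)
        pd.testing.assert_frame_equal(m1, m2)

    def test_no_adjacent_pairs_rejected(self):
        tiles = pd.DataFrame(
            [{"slide_id": "s", "grid_row": 0, "grid_col": 0, "hpc_id": 0}]
        )
        with pytest.raises(ValueError, match="no adjacent"):
            adjacency_interactions(tiles, n_clusters=1)

    def test_exclude_self_zeroes_diagonal(self):
        rng = np.random.default_rng(5)
        tiles = self.checkerboard(6)
        tiles["hpc_id"] = rng.integers(0, 3, size=len(tiles))
        m = adjacency_interactions(tiles, n_clusters=3, include_self=False)
        assert np.diag(m.to_numpy()).max() == 0.0


class TestInteractionHeatmapOrdering:
    def block_matrix(self, perm=None):
        m = np.array(
            [
                [0.8, 0.7, 0.05, 0.1],
                [0.7, 0.9, 0.02, 0.08],
                [0.1, 0.05, 0.9, 0.75],
                [0.05, 0.1, 0.8, 0.85],
            ]
        )
        labels = ["A", "B", "C", "D"]
        df = pd.DataFrame(m, index=labels, columns=labels)
        if perm:
            df = df.iloc[perm, perm]
        return df

    def test_planted_blocks_grouped_contiguously(self):
        out = cluster_interaction_heatmap(self.block_matrix())
        order = out["row_order"]
        assert {order[0], order[1]} in ({"A", "B"}, {"C", "D"})

    def test_permutation_recovers_same_blocks(self):
        out = cluster_interaction_heatmap(self.block_matrix(perm=[0, 2, 1, 3]))
        order = out["row_order"]
        assert {order[0], order[1]} in ({"A", "B"}, {"C", "D"})
        assert {order[2], order[3]} in ({"A", "B"}, {"C", "D"})

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_interaction_heatmap(pd.DataFrame([[1.0]]))


class TestHeatmapExport:
    def tiles(self):
        rng = np.random.default_rng(6)
        rows = []
        for r in range(4):
            for c in range(5):
                if (r, c) == (2, 2):  # a rejected/absent position
                    continue
                rows.append(
                    {"slide_id": "s1", "grid_row": r, "grid_col": c, "hpc_id": int(rng.integers(0, 3))}
                )
        return pd.DataFrame(rows)

    def test_legend_percentages_equal_slide_composition(self):
        tiles = self.tiles()
        _, legend = hpc_heatmap(tiles, "s1", n_clusters=3)
        counts = tiles["hpc_id"].value_counts().reindex(range(3), fill_value=0)
        np.testing.assert_allclose(
            legend["tile_pct"].to_numpy(), counts / counts.sum() * 100
        )

    def test_missing_positions_are_transparent(self):
        img, _ = hpc_heatmap(self.tiles(), "s1", n_clusters=3, block_px=4)
        block = img[2 * 4 : 3 * 4, 2 * 4 : 3 * 4]
        assert block[..., 3].max() == 0

    def test_round_trip_decode_recovers_assignment(self):
        tiles = self.tiles()
        img, legend = hpc_heatmap(tiles, "s1", n_clusters=3, block_px=4)
        decoded = decode_heatmap(img, legend, block_px=4)
        merged = tiles.merge(decoded, on=["grid_row", "grid_col"], suffixes=("", "_dec"))
        assert len(merged) == len(tiles)
        assert (merged["hpc_id"] == merged["hpc_id_dec"]).all()
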