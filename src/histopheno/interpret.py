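"""Model interpretation: SHAP, forest summaries, enrichment and spatial interactions.

For linear models the Shapley decomposition has a closed form: with
independent features and a linear predictor ``f(x) = w . x + b``, the
contribution of feature k relative to a background point is exactly
``phi_k = w_k (x_k - background_k)``, and the contributions plus the base
value reproduce the prediction identically (the additivity property that
approximate SHAP estimators only satisfy in expectation).

Spatial structure is summarized by the tile-adjacency interaction matrix:
entry (j, k) is the normalized proportion of grid neighbors of cluster-k
tiles that belong to cluster j, under an 8- (default) or 4-connectivity
neighborhood.  Columns sum to one; bi-hierarchical clustering of the matrix
exposes groups of mutually adjacent phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .models import CVReport

__all__ = [
    "ShapMatrix",
    "adjacency_interactions",
    "bh_adjust",
    "cluster_interaction_heatmap",
    "forest_summary",
    "hpc_heatmap",
    "linear_shap",
    "spearman_enrichment",
]

_NEIGHBORHOODS = {
    4: [(-1, 0), (1, 0), (0, -1), (0, 1)],
    8: [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
}


# ---------------------------------------------------------------------------
# SHAP


@dataclass
class ShapMatrix:
    values: pd.DataFrame  # patients x features
    base_value: float
    model_ref: str = ""

    def check_additivity(self, predictions: np.ndarray, tol: float = 1e-9) -> bool:
        total = self.base_value + self.values.sum(axis=1).to_numpy()
        return bool(np.all(np.abs(total - np.asarray(predictions, float)) <= tol))


def linear_shap(
    coef: np.ndarray,
    intercept: float,
    X: pd.DataFrame | np.ndarray,
    background: np.ndarray,
    model_ref: str = "",
) -> ShapMatrix:
    """Exact Shapley contributions of a linear predictor against a background.

    ``background`` is conventionally the training-set feature mean; the base
    value is the model's prediction at the background.
    """
    if isinstance(X, pd.DataFrame):
        index, columns, Xv = X.index, list(X.columns), X.to_numpy(float)
    else:
        Xv = np.asarray(X, float)
        index, columns = range(len(Xv)), [f"x{j}" for j in range(Xv.shape[1])]
    coef = np.asarray(coef, float)
    background = np.asarray(background, float)
    if Xv.shape[1] != len(coef) or len(background) != len(coef):
        raise ValueError("feature dimension mismatch")
    phi = (Xv - background) * coef
    base = float(coef @ background + intercept)
    return ShapMatrix(
        values=pd.DataFrame(phi, index=index, columns=columns),
        base_value=base,
        model_ref=model_ref,
    )


# ---------------------------------------------------------------------------
# forest summary


def forest_summary(report: CVReport, counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster forest-plot table from a Cox cross-validation report.

    Columns: mean log hazard ratio across folds, Fisher-combined Wald p, and
    the percentage of patients with at least one tile in the cluster
    (``counts`` is the patients x clusters tile-count table).
    """
    names = report.feature_names
    presence = (counts.reindex(columns=names).fillna(0) > 0).mean(axis=0) * 100.0
    combined = (
        report.combined_pvalues
        if report.combined_pvalues is not None
        else np.full(len(names), np.nan)
    )
    return pd.DataFrame(
        {
            "hpc": names,
            "mean_log_hr": report.mean_coef,
            "fisher_p": combined,
            "patient_presence_pct": presence.to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# enrichment


def spearman_enrichment(
    compositions: pd.DataFrame, target: pd.Series, alpha: float = 0.01
) -> pd.DataFrame:
    """Spearman rank correlation of each cluster's proportion with a target label.

    The target may be binary or ordinal (e.g. whole-slide diagnosis, or
    local recurrence vs overall metastasis, nodal and distant combined);
    p-values are BH-adjusted into q-values and significance is called at
    ``alpha`` on the q-values.  Computed on raw proportions by default.
    """
    if len(compositions) < 3:
        raise ValueError("need at least 3 patients")
    y = target.reindex(compositions.index)
    if y.isna().any():
        raise ValueError("target missing for some patients")
    if y.dtype.kind in "OUS":
        y = pd.Series(pd.factorize(y, sort=True)[0], index=y.index)
    rows = []
    for col in compositions.columns:
        x = compositions[col].to_numpy(float)
        if np.ptp(y.to_numpy(float)) == 0 or np.ptp(x) == 0:
            rows.append({"hpc": col, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(x, y.to_numpy(float))
        rows.append({"hpc": col, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# adjacency interactions


def adjacency_interactions(
    tiles: pd.DataFrame,
    n_clusters: int | None = None,
    neighborhood: int = 8,
    include_self: bool = True,
) -> pd.DataFrame:
    """Normalized tile-adjacency interaction matrix between clusters.

    ``tiles`` needs columns ``slide_id``, ``grid_row``, ``grid_col`` and
    ``hpc_id`` for the kept tiles.  For every tile, the cluster labels of
    its existing grid neighbors are tallied against the tile's own cluster;
    entry (j, k) of the result is the proportion of neighbors of cluster-k
    tiles that belong to cluster j, so each observed column sums to 1.
    ``include_self=False`` zeroes same-cluster interactions before
    normalizing.  Columns of clusters with no observed neighbor pairs are NaN.
    """
    if neighborhood not in _NEIGHBORHOODS:
        raise ValueError("neighborhood must be 4 or 8")
    K = n_clusters or int(tiles["hpc_id"].max()) + 1
    base = tiles[["slide_id", "grid_row", "grid_col", "hpc_id"]].copy()
    counts = np.zeros((K, K), float)
    for dr, dc in _NEIGHBORHOODS[neighborhood]:
        shifted = base.copy()
        shifted["grid_row"] = shifted["grid_row"] + dr
        shifted["grid_col"] = shifted["grid_col"] + dc
        merged = base.merge(
            shifted,
            on=["slide_id", "grid_row", "grid_col"],
            suffixes=("_focal", "_neighbor"),
        )
        if len(merged):
            np.add.at(
                counts,
                (merged["hpc_id_neighbor"].to_numpy(int), merged["hpc_id_focal"].to_numpy(int)),
                1.0,
            )
    if counts.sum() == 0:
        raise ValueError("no adjacent tile pairs found")
    if not include_self:
        np.fill_diagonal(counts, 0.0)
    col_sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = counts / col_sums
    norm[:, col_sums == 0] = np.nan
    labels = [f"HPC{k}" for k in range(K)]
    return pd.DataFrame(norm, index=labels, columns=labels)


def cluster_interaction_heatmap(
    matrix: pd.DataFrame, method: str = "average", metric: str = "correlation"
) -> dict:
    """Bi-hierarchical ordering of the interaction matrix.

    Agglomerative clustering (correlation distance, average linkage) on the
    rows and on the columns; returns leaf orders, linkages and the reordered
    matrix.  Columns that are entirely NaN are dropped first.
    """
    m = matrix.dropna(axis=1, how="all").dropna(axis=0, how="all")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    vals = m.to_numpy(float)
    vals = np.nan_to_num(vals)
    row_link = linkage(_safe_pdist(vals, metric), method=method)
    col_link = linkage(_safe_pdist(vals.T, metric), method=method)
    row_order = leaves_list(row_link)
    col_order = leaves_list(col_link)
    ordered = m.iloc[row_order, col_order]
    return {
        "row_order": [m.index[i] for i in row_order],
        "col_order": [m.columns[i] for i in col_order],
        "row_linkage": row_link,
        "col_linkage": col_link,
        "ordered": ordered,
    }


def _safe_pdist(X: np.ndarray, metric: str) -> np.ndarray:
    # correlation distance is undefined for constant rows; fall back to
    # euclidean for degenerate inputs
    if metric == "correlation" and np.any(X.std(axis=1) == 0):
        metric = "euclidean"
    d = pdist(X, metric=metric)
    return np.nan_to_num(d)


# ---------------------------------------------------------------------------
# heatmap export


# 2-7-1 qualitative palette, extended by golden-angle HSV sampling for K > 16
_BASE_PALETTE = np.array(
    [
        (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
        (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
        (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
        (152, 223, 138), (255, 152, 150), (197, 176, 213), (196, 156, 148),
    ],
    dtype=np.uint8,
)


def hpc_palette(n_clusters: int) -> np.ndarray:
    """Distinct RGB color per cluster (uint8, shape (K, 3))."""
    if n_clusters <= len(_BASE_PALETTE):
        return _BASE_PALETTE[:n_clusters].copy()
    import colorsys

    extra = []
    for i in range(n_clusters - len(_BASE_PALETTE)):
        h = (i * 0.61803398875) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.75, 0.85)
        extra.append((int(r * 255), int(g * 255), int(b * 255)))
    return np.vstack([_BASE_PALETTE, np.asarray(extra, np.uint8)])


def hpc_heatmap(
    tiles: pd.DataFrame,
    slide_id: str,
    n_clusters: int,
    block_px: int = 8,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simplified slide representation: one colored block per kept tile.

    Returns an RGBA image (rejected/absent grid positions are transparent)
    and a legend table with each cluster's color and its share of the
    slide's kept tiles — the slide composition.
    """
    sl = tiles[tiles["slide_id"] == slide_id]
    if len(sl) == 0:
        raise ValueError(f"slide {slide_id!r} has no kept tiles")
    palette = hpc_palette(n_clusters)
    n_rows = int(sl["grid_row"].max()) + 1
    n_cols = int(sl["grid_col"].max()) + 1
    img = np.zeros((n_rows * block_px, n_cols * block_px, 4), np.uint8)
    for _, row in sl.iterrows():
        r, c, k = int(row["grid_row"]), int(row["grid_col"]), int(row["hpc_id"])
        img[r * block_px : (r + 1) * block_px, c * block_px : (c + 1) * block_px, :3] = palette[k]
        img[r * block_px : (r + 1) * block_px, c * block_px : (c + 1) * block_px, 3] = 255
    counts = sl["hpc_id"].value_counts().reindex(range(n_clusters), fill_value=0)
    legend = pd.DataFrame(
        {
            "hpc": [f"HPC{k}" for k in range(n_clusters)],
            "color_rgb": [tuple(int(v) for v in palette[k]) for k in range(n_clusters)],
            "tile_pct": counts.to_numpy() / counts.sum() * 100.0,
        }
    )
    return img, legend


def decode_heatmap(img: np.ndarray, legend: pd.DataFrame, block_px: int = 8) -> pd.DataFrame:
    """Recover (grid_row, grid_col, hpc_id) from a heatmap image + legend."""
    color_to_hpc = {tuple(c): i for i, c in enumerate(legend["color_rgb"])}
    n_rows = img.shape[0] // block_px
    n_cols = img.shape[1] // block_px
    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            block = img[r * block_px : (r + 1) * block_px, c * block_px : (c + 1) * block_px]
            if block[..., 3].max() == 0:
                continue
            key = tuple(int(v) for v in block[0, 0, :3])
            rows.append({"grid_row": r, "grid_col": c, "hpc_id": color_to_hpc[key]})
    return pd.DataFrame(rows)


def save_heatmap_png(img: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(img, mode="RGBA").save(path)
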