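"""kNN graph construction, Leiden phenotype clustering and resolution selection.

Tile embeddings are linked into an undirected k-nearest-neighbour graph and
partitioned with the Leiden algorithm at a chosen resolution.  The workflow
runs Leiden twice: an over-clustering pass at a high resolution (the source
workflow used r=7) whose near-white clusters are flagged as artifacts and
removed, and a final pass (r=0.75 there) on the retained tiles.

Resolution selection follows the presence heuristics: for each candidate
resolution, the average percentage of patients (and institutions) that have
at least one tile — or at least 1% of their tiles — in each cluster is
computed; resolutions where these averages decline produce patient- or
institution-specific clusters and are treated as over-fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterConfig",
    "HPCAssignment",
    "PresenceMetrics",
    "build_knn_graph",
    "filter_artifact_hpcs",
    "leiden_cluster",
    "presence_metrics",
    "propose_artifact_clusters",
    "resolution_sweep",
    "select_resolution",
]


@dataclass
class ClusterConfig:
    k_neighbors: int = 50
    metric: str = "cosine"
    resolution: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class HPCAssignment:
    """Tile -> histomorphological phenotype cluster map at one resolution."""

    tile_ids: np.ndarray  # object array of tile ids
    labels: np.ndarray  # int array, contiguous 0..n_clusters-1
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tile_id": self.tile_ids, "hpc_id": self.labels})

    def to_tsv(self, path, tile_table: pd.DataFrame | None = None) -> None:
        df = self.to_frame()
        if tile_table is not None:
            df = df.merge(
                tile_table[["tile_id", "slide_id", "grid_row", "grid_col"]], on="tile_id"
            )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class PresenceMetrics:
    resolution: float
    n_clusters: int
    avg_patient_presence_any: float  # %
    avg_patient_presence_1pct: float  # %
    avg_institution_presence_any: float  # %
    avg_institution_presence_1pct: float  # %


def build_knn_graph(embeddings: np.ndarray, k: int, metric: str = "cosine") -> ig.Graph:
    """Undirected kNN graph over the rows of ``embeddings``; edges deduplicated."""
    X = np.asarray(embeddings)
    n = len(X)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(n):
        neighbors = [j for j in idx[i] if j != i][:k]
        # if a point duplicates i exactly, self may be excluded by the slice;
        # ensure k links regardless
        for j in neighbors:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    g.simplify()
    return g


def leiden_cluster(
    graph: ig.Graph,
    resolution: float,
    seed: int = 0,
    tile_ids: np.ndarray | None = None,
) -> HPCAssignment:
    """Leiden partition of the graph maximizing RB-configuration modularity at ``resolution``.

    Cluster labels are relabeled contiguously by decreasing cluster size, so
    ids are stable under tile-order permutations of equal partitions.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    labels = _relabel_by_size(labels)
    if tile_ids is None:
        tile_ids = np.arange(graph.vcount())
    return HPCAssignment(
        tile_ids=np.asarray(tile_ids, object), labels=labels, resolution=resolution
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.asarray([remap[int(l)] for l in labels])


def filter_artifact_hpcs(
    assignment: HPCAssignment, artifact_hpc_ids: list[int]
) -> np.ndarray:
    """Boolean mask of tiles retained after removing the listed clusters."""
    existing = set(range(assignment.n_clusters))
    unknown = [c for c in artifact_hpc_ids if c not in existing]
    if unknown:
        raise ValueError(f"unknown cluster ids: {unknown}")
    return ~np.isin(assignment.labels, list(artifact_hpc_ids))


def propose_artifact_clusters(
    assignment: HPCAssignment,
    tile_luminance: np.ndarray,
    luminance_threshold: float = 215.0,
) -> pd.DataFrame:
    """Rank clusters by mean tile luminance to propose artifact candidates.

    Artifact identification is a manual, visual step in production use; this
    helper orders clusters by how close to white glass their tiles are
    (near-white bubbles / blank smudges score highest) and flags those whose
    mean luminance exceeds ``luminance_threshold``.
    """
    df = pd.DataFrame({"hpc_id": assignment.labels, "luminance": np.asarray(tile_luminance, float)})
    summary = (
        df.groupby("hpc_id")["luminance"]
        .agg(mean_luminance="mean", n_tiles="size")
        .reset_index()
        .sort_values("mean_luminance", ascending=False, ignore_index=True)
    )
    summary["artifact_candidate"] = summary["mean_luminance"] > luminance_threshold
    return summary


def tile_luminance(images: np.ndarray) -> np.ndarray:
    """Mean Rec.709 luma per tile."""
    w = np.array([0.2126, 0.7152, 0.0722])
    return (np.asarray(images, float) * w).sum(axis=-1).mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# presence metrics


def presence_metrics(
    assignment: HPCAssignment,
    tile_meta: pd.DataFrame,
) -> PresenceMetrics:
    """Average patient / institution representation across clusters.

    ``tile_meta`` must carry ``tile_id``, ``patient_id`` and ``institution``
    for every assigned tile.  For each cluster, the percentage of patients
    (institutions) with at least one tile in it — and with at least 1% of
    their own tiles in it — is computed; the averages over clusters are
    returned.
    """
    df = assignment.to_frame().merge(
        tile_meta[["tile_id", "patient_id", "institution"]], on="tile_id", how="left"
    )
    if df[["patient_id", "institution"]].isna().any().any():
        raise ValueError("tile_meta does not cover every assigned tile")
    return PresenceMetrics(
        resolution=assignment.resolution,
        n_clusters=assignment.n_clusters,
        avg_patient_presence_any=_presence(df, "patient_id", 0.0),
        avg_patient_presence_1pct=_presence(df, "patient_id", 0.01),
        avg_institution_presence_any=_presence(df, "institution", 0.0),
        avg_institution_presence_1pct=_presence(df, "institution", 0.01),
    )


def _presence(df: pd.DataFrame, level: str, threshold: float) -> float:
    n_entities = df[level].nunique()
    counts = df.groupby([level, "hpc_id"], observed=True).size().rename("n").reset_index()
    totals = df.groupby(level).size()
    counts["frac"] = counts["n"] / counts[level].map(totals).to_numpy()
    if threshold > 0:
        counts = counts[counts["frac"] >= threshold]
    per_cluster = counts.groupby("hpc_id")[level].nunique()
    per_cluster = per_cluster.reindex(range(df["hpc_id"].max() + 1), fill_value=0)
    return float((per_cluster / n_entities).mean() * 100.0)


# ---------------------------------------------------------------------------
# resolution sweep


def resolution_sweep(
    embeddings: np.ndarray,
    tile_meta: pd.DataFrame,
    resolutions: list[float],
    k_neighbors: int = 50,
    metric: str = "cosine",
    seed: int = 0,
    score_fn=None,
) -> pd.DataFrame:
    """Cluster at each resolution and tabulate presence metrics (+ optional scores).

    ``score_fn(assignment) -> dict`` can attach downstream cross-validation
    metrics per resolution.  The ``presence_declined`` column flags
    resolutions where the 1%-threshold patient presence has dropped below its
    running maximum — the over-fitting signal used to freeze the resolution.
    """
    if not resolutions:
        raise ValueError("empty resolution grid")
    graph = build_knn_graph(embeddings, k_neighbors, metric)
    rows = []
    for r in resolutions:
        assignment = leiden_cluster(graph, r, seed=seed, tile_ids=tile_meta["tile_id"].to_numpy())
        pm = presence_metrics(assignment, tile_meta)
        row = {
            "resolution": r,
            "n_clusters": pm.n_clusters,
            "avg_patient_presence_any": pm.avg_patient_presence_any,
            "avg_patient_presence_1pct": pm.avg_patient_presence_1pct,
            "avg_institution_presence_any": pm.avg_institution_presence_any,
            "avg_institution_presence_1pct": pm.avg_institution_presence_1pct,
        }
        if score_fn is not None:
            row.update(score_fn(assignment))
        rows.append(row)
    sweep = pd.DataFrame(rows).sort_values("resolution", ignore_index=True)
    running_max = sweep["avg_patient_presence_1pct"].cummax()
    sweep["presence_declined"] = sweep["avg_patient_presence_1pct"] < running_max - 1e-9
    return sweep


def select_resolution(sweep: pd.DataFrame, decline_tolerance: float = 2.0) -> float:
    """Largest resolution before patient presence declines by more than the tolerance.

    ``decline_tolerance`` is in percentage points of the 1%-threshold patient
    presence relative to its running maximum.  If presence never declines the
    largest swept resolution is returned.
    """
    presence = sweep["avg_patient_presence_1pct"].to_numpy()
    running_max = np.maximum.accumulate(presence)
    declined = presence < running_max - decline_tolerance
    if declined.any():
        first_bad = int(np.argmax(declined))
        if first_bad == 0:
            return float(sweep["resolution"].iloc[0])
        return float(sweep["resolution"].iloc[first_bad - 1])
    return float(sweep["resolution"].iloc[-1])


# ---------------------------------------------------------------------------
# visualization delegation


def umap_paga(embeddings: np.ndarray, labels: np.ndarray, seed: int = 0):
    """UMAP layout and PAGA cluster-connectivity graph via scanpy (plotting only).

    Returns an :class:`anndata.AnnData` with ``obsm['X_umap']`` and
    ``uns['paga']`` filled in.  Requires the optional ``viz`` dependencies.
    """
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(np.asarray(embeddings, np.float32))
    adata.obs["hpc"] = pd.Categorical([str(l) for l in labels])
    sc.pp.neighbors(adata, use_rep="X", random_state=seed)
    sc.tl.umap(adata, random_state=seed)
    sc.tl.paga(adata, groups="hpc")
    return adata
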