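"""Slide/patient composition vectors and the centered log-ratio transform.

After clustering, a slide is summarized by the fraction of its kept tiles
falling in each phenotype cluster; a patient's vector pools tile counts
across all of the patient's slides before normalizing (so a slide with
three times the tiles carries three times the weight).  Compositions live
on the simplex, so the centered log-ratio (CLR) transform — log of each
part over the geometric mean — maps them to zero-sum real vectors before
any linear modelling.  Zeros are handled with an additive pseudocount of
one tile by default; multiplicative replacement is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.composition import multi_replace as _multi_replace

from .clustering import HPCAssignment

__all__ = [
    "CompositionVector",
    "clr_matrix",
    "clr_transform",
    "composition_matrix",
    "inverse_clr",
    "patient_composition",
    "slide_composition",
]


@dataclass
class CompositionVector:
    entity_id: str
    proportions: np.ndarray  # length K, sums to 1
    n_tiles: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, float)
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be a probability vector")


def _counts(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    return np.bincount(np.asarray(labels, int), minlength=n_clusters).astype(float)


def slide_composition(
    assignment: HPCAssignment, tile_table: pd.DataFrame, slide_id: str, n_clusters: int | None = None
) -> CompositionVector:
    """Fraction of the slide's kept tiles in each cluster."""
    K = n_clusters or assignment.n_clusters
    df = assignment.to_frame().merge(tile_table[["tile_id", "slide_id"]], on="tile_id")
    labels = df.loc[df["slide_id"] == slide_id, "hpc_id"].to_numpy()
    if len(labels) == 0:
        raise ValueError(f"slide {slide_id!r} has no kept tiles")
    counts = _counts(labels, K)
    return CompositionVector(slide_id, counts / counts.sum(), int(counts.sum()))


def patient_composition(
    assignment: HPCAssignment,
    tile_table: pd.DataFrame,
    patient_slides: list[str],
    patient_id: str = "",
    n_clusters: int | None = None,
) -> CompositionVector:
    """Tile counts pooled across the patient's slides, then normalized."""
    if not patient_slides:
        raise ValueError("patient has no slides")
    K = n_clusters or assignment.n_clusters
    df = assignment.to_frame().merge(tile_table[["tile_id", "slide_id"]], on="tile_id")
    labels = df.loc[df["slide_id"].isin(patient_slides), "hpc_id"].to_numpy()
    if len(labels) == 0:
        raise ValueError(f"patient {patient_id!r} has no kept tiles")
    counts = _counts(labels, K)
    return CompositionVector(patient_id or ";".join(sorted(patient_slides)), counts / counts.sum(), int(counts.sum()))


def composition_matrix(
    assignment: HPCAssignment,
    tile_meta: pd.DataFrame,
    level: str = "patient_id",
    n_clusters: int | None = None,
    as_counts: bool = False,
) -> pd.DataFrame:
    """Entities x clusters composition table (proportions, or raw tile counts).

    ``tile_meta`` maps tile_id to the grouping column (``patient_id`` or
    ``slide_id``).  Entities never observed in a cluster get structural
    zeros; K is fixed by the frozen clustering (or ``n_clusters``).
    """
    K = n_clusters or assignment.n_clusters
    df = assignment.to_frame().merge(tile_meta[["tile_id", level]], on="tile_id", how="left")
    if df[level].isna().any():
        raise ValueError(f"tile_meta does not cover every assigned tile for level {level!r}")
    table = (
        df.groupby([level, "hpc_id"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(K), fill_value=0)
        .astype(float)
    )
    table.columns = [f"HPC{c}" for c in table.columns]
    if as_counts:
        return table
    return table.div(table.sum(axis=1), axis=0)


def clr_transform(
    composition: np.ndarray,
    pseudocount: float = 0.0,
    n_tiles: int | None = None,
    method: str = "additive",
) -> np.ndarray:
    """CLR of one composition: ln(x'_k) - mean_j ln(x'_j).

    ``pseudocount`` is in tile counts when ``n_tiles`` is given (the default
    workflow adds one pseudo-tile per cluster before normalizing) and in
    proportion units otherwise.  ``method="multiplicative"`` replaces zeros
    with the scikit-bio multiplicative replacement instead.  Output sums to
    zero to numerical precision.
    """
    x = np.asarray(composition, float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("composition must be a vector of length >= 2")
    if method == "multiplicative":
        if np.any(x == 0):
            x = _multi_replace(x.reshape(1, -1)).ravel()
    else:
        shift = pseudocount / n_tiles if n_tiles else pseudocount
        x = x + shift
    if np.any(x <= 0):
        raise ValueError("zero proportions require a positive pseudocount")
    x = x / x.sum()
    return _skbio_clr(x)


def clr_matrix(compositions: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """CLR-transform an entities x clusters table.

    The default workflow passes the tile-count table, where the default
    pseudocount of one tile handles structural zeros; a proportion table
    works too if the pseudocount is scaled accordingly (rows are
    renormalized either way).
    """
    # CLR is scale-invariant, so adding the pseudocount in count or proportion
    # units only differs in its magnitude relative to the row totals
    X = compositions.to_numpy(float) + pseudocount
    X = X / X.sum(axis=1, keepdims=True)
    if np.any(X <= 0):
        raise ValueError("zero proportions require a positive pseudocount")
    return pd.DataFrame(_skbio_clr(X), index=compositions.index, columns=compositions.columns)


def inverse_clr(values: np.ndarray) -> np.ndarray:
    """Softmax inverse: recovers the (pseudocounted) composition from a CLR vector."""
    v = np.asarray(values, float)
    e = np.exp(v - v.max())
    return e / e.sum()
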