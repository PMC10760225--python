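"""HDF5-backed tile store.

One store holds, per slide, the kept/rejected tile images (uint8 RGB), their
grid coordinates, background fractions, and — once the encoder has run — a
float32 embedding matrix aligned with the tile order.  Tile ids are
``"<slide_id>:<grid_row>:<grid_col>"`` and are unique within a store.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["SlideTiles", "TileStore", "tile_id"]


def tile_id(slide_id: str, grid_row: int, grid_col: int) -> str:
    return f"{slide_id}:{int(grid_row)}:{int(grid_col)}"


@dataclass
class SlideTiles:
    """Tiles of one slide, in row-major grid order."""

    slide_id: str
    images: np.ndarray | None  # (n, px, px, 3) uint8, or None for image-free stores
    grid_row: np.ndarray
    grid_col: np.ndarray
    background_fraction: np.ndarray
    kept: np.ndarray
    embeddings: np.ndarray | None = None  # (n, d) float32, aligned with tiles

    @property
    def n_tiles(self) -> int:
        return len(self.grid_row)

    def tile_ids(self) -> list[str]:
        return [tile_id(self.slide_id, r, c) for r, c in zip(self.grid_row, self.grid_col)]


@dataclass
class TileStore:
    """In-memory mapping slide_id -> :class:`SlideTiles` with HDF5 persistence."""

    slides: dict[str, SlideTiles] = field(default_factory=dict)
    tile_px: int | None = None
    provenance: dict = field(default_factory=dict)

    def add(self, tiles: SlideTiles) -> None:
        if tiles.slide_id in self.slides:
            raise ValueError(f"slide {tiles.slide_id!r} already in store")
        self.slides[tiles.slide_id] = tiles

    def __contains__(self, slide_id: str) -> bool:
        return slide_id in self.slides

    def __getitem__(self, slide_id: str) -> SlideTiles:
        return self.slides[slide_id]

    @property
    def n_tiles(self) -> int:
        return sum(s.n_tiles for s in self.slides.values())

    def tile_table(self, kept_only: bool = False) -> pd.DataFrame:
        """Flat table of tiles: tile_id, slide_id, grid_row, grid_col, kept."""
        rows = []
        for sid in sorted(self.slides):
            s = self.slides[sid]
            for i in range(s.n_tiles):
                if kept_only and not s.kept[i]:
                    continue
                rows.append(
                    (
                        tile_id(sid, s.grid_row[i], s.grid_col[i]),
                        sid,
                        int(s.grid_row[i]),
                        int(s.grid_col[i]),
                        bool(s.kept[i]),
                        float(s.background_fraction[i]),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["tile_id", "slide_id", "grid_row", "grid_col", "kept", "background_fraction"],
        )

    def embedding_matrix(self, kept_only: bool = True) -> tuple[np.ndarray, pd.DataFrame]:
        """Stack embeddings across slides; returns (matrix, matching tile table)."""
        mats, tabs = [], []
        for sid in sorted(self.slides):
            s = self.slides[sid]
            if s.embeddings is None:
                raise ValueError(f"slide {sid!r} has no embeddings")
            mask = s.kept.astype(bool) if kept_only else np.ones(s.n_tiles, bool)
            mats.append(np.asarray(s.embeddings)[mask])
            tab = pd.DataFrame(
                {
                    "tile_id": np.asarray(s.tile_ids(), dtype=object)[mask],
                    "slide_id": sid,
                    "grid_row": s.grid_row[mask],
                    "grid_col": s.grid_col[mask],
                }
            )
            tabs.append(tab)
        if not mats:
            raise ValueError("store is empty")
        return np.vstack(mats), pd.concat(tabs, ignore_index=True)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = 1
            if self.tile_px is not None:
                f.attrs["tile_px"] = int(self.tile_px)
            f.attrs["provenance"] = json.dumps(self.provenance)
            for sid, s in self.slides.items():
                g = f.create_group(sid)
                if s.images is not None:
                    g.create_dataset("images", data=np.asarray(s.images, dtype=np.uint8))
                g.create_dataset("grid_row", data=np.asarray(s.grid_row, dtype=np.int32))
                g.create_dataset("grid_col", data=np.asarray(s.grid_col, dtype=np.int32))
                g.create_dataset(
                    "background_fraction",
                    data=np.asarray(s.background_fraction, dtype=np.float32),
                )
                g.create_dataset("kept", data=np.asarray(s.kept, dtype=bool))
                if s.embeddings is not None:
                    g.create_dataset("embeddings", data=np.asarray(s.embeddings, dtype=np.float32))

    @classmethod
    def load(cls, path: str | Path) -> "TileStore":
        store = cls()
        with h5py.File(path, "r") as f:
            store.tile_px = int(f.attrs["tile_px"]) if "tile_px" in f.attrs else None
            store.provenance = json.loads(f.attrs.get("provenance", "{}"))
            for sid in f:
                g = f[sid]
                store.add(
                    SlideTiles(
                        slide_id=sid,
                        images=g["images"][...] if "images" in g else None,
                        grid_row=g["grid_row"][...],
                        grid_col=g["grid_col"][...],
                        background_fraction=g["background_fraction"][...],
                        kept=g["kept"][...],
                        embeddings=g["embeddings"][...] if "embeddings" in g else None,
                    )
                )
        return store
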