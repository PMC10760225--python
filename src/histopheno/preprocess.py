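"""Slide tessellation, background rejection and Reinhard color normalization.

A slide image is rescaled to the working resolution (default 0.5 um/px, the
usual 20x embedding scale for slides scanned at 40x/0.25 um), cut into a
non-overlapping grid of square tiles in row-major order with partial edge
tiles discarded, and each tile is scored for background content.  Tiles
where background covers more than the rejection threshold (default 75%) are
flagged as rejected.  Kept tiles can then be color-normalized with the
Reinhard mean/std transfer in the l-alpha-beta perceptual color space.

Background definition: a pixel is background when, after a 3x3 mean filter,
all three channels are at or above a white-glass intensity threshold
(default 220/255).  This is the standard detection of unstained glass; pen
marks, bubbles and blur are deliberately left to the downstream artifact
cluster filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .store import SlideTiles, TileStore

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "SlideImage",
    "background_fraction",
    "compute_reinhard_stats",
    "preprocess_slide",
    "reinhard_normalize",
    "tessellate",
]


@dataclass
class SlideImage:
    """One slide: RGB pixel array plus its scan resolution in microns/pixel."""

    slide_id: str
    pixels: np.ndarray  # (h, w, 3) uint8
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (h, w, 3) RGB")


@dataclass
class PreprocessConfig:
    tile_px: int = 224
    target_mpp: float = 0.5
    background_reject_threshold: float = 0.75
    background_intensity: int = 220  # min-channel white-glass cutoff, 0-255
    reinhard_target: "ReinhardStats | None" = None


@dataclass
class ReinhardStats:
    """Per-channel mean/std in l-alpha-beta space."""

    mean: np.ndarray  # (3,)
    std: np.ndarray  # (3,)


# ---------------------------------------------------------------------------
# tessellation


def _rescale_to_mpp(pixels: np.ndarray, mpp: float, target_mpp: float) -> np.ndarray:
    """Rescale so one output pixel spans ``target_mpp`` microns.

    Area averaging (via anti-aliased resampling) for downscales, bilinear for
    upscales; identity when the resolutions already match.
    """
    scale = mpp / target_mpp
    if np.isclose(scale, 1.0):
        return pixels
    h = int(np.floor(pixels.shape[0] * scale))
    w = int(np.floor(pixels.shape[1] * scale))
    out = resize(
        pixels.astype(float),
        (h, w, 3),
        order=1,
        anti_aliasing=scale < 1,
        preserve_range=True,
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def tessellate(slide: SlideImage, config: PreprocessConfig) -> SlideTiles:
    """Cut a slide into a row-major grid of ``tile_px`` tiles at the target resolution.

    Pixel windows are half-open ``[r*s, (r+1)*s)``; the partial remainder at
    the right/bottom edge is dropped.  Returns a :class:`SlideTiles` whose
    ``kept`` flags reflect the background filter.
    """
    px = _rescale_to_mpp(slide.pixels, slide.microns_per_pixel, config.target_mpp)
    s = config.tile_px
    n_rows, n_cols = px.shape[0] // s, px.shape[1] // s
    if n_rows == 0 or n_cols == 0:
        logger.warning(
            "slide %s smaller than one %dpx tile after rescaling; no tiles", slide.slide_id, s
        )
        return SlideTiles(
            slide_id=slide.slide_id,
            images=np.zeros((0, s, s, 3), np.uint8),
            grid_row=np.zeros(0, np.int32),
            grid_col=np.zeros(0, np.int32),
            background_fraction=np.zeros(0, np.float32),
            kept=np.zeros(0, bool),
        )
    images, rows, cols, bgs = [], [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            tile = px[r * s : (r + 1) * s, c * s : (c + 1) * s]
            images.append(tile)
            rows.append(r)
            cols.append(c)
            bgs.append(background_fraction(tile, config))
    bgs = np.asarray(bgs, np.float32)
    return SlideTiles(
        slide_id=slide.slide_id,
        images=np.stack(images),
        grid_row=np.asarray(rows, np.int32),
        grid_col=np.asarray(cols, np.int32),
        background_fraction=bgs,
        kept=bgs <= config.background_reject_threshold,
    )


def background_fraction(tile: np.ndarray, config: PreprocessConfig | None = None) -> float:
    """Fraction of pixels classified as unstained background."""
    config = config or PreprocessConfig()
    smoothed = np.stack(
        [ndimage.uniform_filter(tile[..., c].astype(float), size=3) for c in range(3)], axis=-1
    )
    background = smoothed.min(axis=-1) >= config.background_intensity
    return float(background.mean())


# ---------------------------------------------------------------------------
# Reinhard normalization (l-alpha-beta space, Ruderman decomposition)

_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LOGLMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], float
)
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)
_EPS = 1e-6


def _rgb_to_lab(rgb01: np.ndarray) -> np.ndarray:
    lms = np.clip(rgb01 @ _RGB2LMS.T, _EPS, None)
    return np.log10(lms) @ _LOGLMS2LAB.T


def _lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    loglms = lab @ _LAB2LOGLMS.T
    lms = np.power(10.0, loglms)
    return lms @ _LMS2RGB.T


def compute_reinhard_stats(tiles: np.ndarray | list[np.ndarray]) -> ReinhardStats:
    """Pooled per-channel l-alpha-beta mean/std over a set of (tissue) tiles."""
    if isinstance(tiles, list):
        tiles = np.stack(tiles)
    lab = _rgb_to_lab(np.asarray(tiles, float).reshape(-1, 3) / 255.0)
    return ReinhardStats(mean=lab.mean(axis=0), std=lab.std(axis=0))


def reinhard_normalize(
    tile: np.ndarray,
    target: ReinhardStats,
    *,
    as_uint8: bool = False,
) -> np.ndarray:
    """Match the tile's per-channel l-alpha-beta mean/std to the target's.

    Returns a float RGB array in [0, 1] by default (so the channel statistics
    of the output can be verified to tolerance without quantization noise);
    set ``as_uint8`` for an 8-bit image.  A channel with zero spread in the
    source is only mean-shifted.
    """
    rgb01 = np.asarray(tile, float) / 255.0
    shape = rgb01.shape
    lab = _rgb_to_lab(rgb01.reshape(-1, 3))
    mean, std = lab.mean(axis=0), lab.std(axis=0)
    out = np.empty_like(lab)
    for c in range(3):
        if std[c] < 1e-12:
            logger.warning("zero variance in Reinhard channel %d; applying mean shift only", c)
            out[:, c] = lab[:, c] - mean[c] + target.mean[c]
        else:
            out[:, c] = (lab[:, c] - mean[c]) / std[c] * target.std[c] + target.mean[c]
    rgb = np.clip(_lab_to_rgb(out), 0.0, 1.0).reshape(shape)
    if as_uint8:
        return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return rgb


# ---------------------------------------------------------------------------
# driver


def preprocess_slide(
    slide: SlideImage,
    config: PreprocessConfig,
    target: ReinhardStats | None = None,
) -> SlideTiles:
    """Tessellate, filter and (optionally) normalize one slide."""
    tiles = tessellate(slide, config)
    target = target or config.reinhard_target
    if target is not None and tiles.n_tiles:
        imgs = tiles.images.astype(np.uint8)
        normed = np.stack(
            [
                reinhard_normalize(imgs[i], target, as_uint8=True) if tiles.kept[i] else imgs[i]
                for i in range(tiles.n_tiles)
            ]
        )
        tiles.images = normed
    return tiles


def preprocess_slides(
    slides: list[SlideImage],
    config: PreprocessConfig,
) -> TileStore:
    """Tessellate a set of slides into a tile store.

    When no Reinhard target is configured, the pooled statistics of the kept
    (tissue) tiles across the run are computed once and used as the target,
    so all cohorts are mapped to a common color frame.
    """
    tessellated = [tessellate(s, config) for s in slides]
    target = config.reinhard_target
    if target is None:
        kept = [t.images[t.kept.astype(bool)] for t in tessellated if t.kept.any()]
        if kept:
            target = compute_reinhard_stats(np.concatenate(kept))
    store = TileStore(tile_px=config.tile_px)
    for t in tessellated:
        if target is not None and t.n_tiles:
            t.images = np.stack(
                [
                    reinhard_normalize(t.images[i], target, as_uint8=True)
                    if t.kept[i]
                    else t.images[i]
                    for i in range(t.n_tiles)
                ]
            )
        store.add(t)
    return store
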