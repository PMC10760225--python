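"""Barlow-Twins self-supervised tile encoder.

The Barlow-Twins objective takes two stochastically augmented views of each
tile in a batch, embeds both with the same network, batch-normalizes each
embedding dimension, and forms the empirical cross-correlation matrix

    C_ij = (1/n) sum_b  zA_hat[b, i] * zB_hat[b, j].

The loss pushes C toward the identity: sum_i (1 - C_ii)^2 penalizes
decorrelation of a dimension with itself across views (invariance term),
and lambda * sum_{i!=j} C_ij^2 penalizes redundancy between dimensions.

At desk scale the encoder is a small fully connected network on
down-sampled tile pixels, written directly in numpy with hand-derived
gradients (the loss, batch-norm and dense-layer backward passes are each
verified against finite differences in the test suite).  The contract is
only tile -> z (default 128-d); the training recipe — 40% of tiles per
institution, Adam, a linear projector head — is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from ._rng import substream
from .store import TileStore

__all__ = [
    "AugmentConfig",
    "EncoderConfig",
    "EncoderState",
    "LossReport",
    "barlow_twins_loss",
    "embed",
    "make_views",
    "train_encoder",
    "train_on_images",
]

_BN_EPS = 1e-6


# ---------------------------------------------------------------------------
# augmentations


@dataclass
class AugmentConfig:
    """Strengths of the two-view augmentations; all zero means identity views."""

    crop_scale_min: float = 0.6  # 1.0 disables random crop-resize
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    color_jitter: float = 0.3  # brightness/contrast/channel-shift strength
    blur_sigma_max: float = 1.0  # 0 disables Gaussian blur

    def is_identity(self) -> bool:
        return (
            self.crop_scale_min >= 1.0
            and self.hflip_prob == 0
            and self.vflip_prob == 0
            and self.color_jitter == 0
            and self.blur_sigma_max == 0
        )


def _augment(img01: np.ndarray, rng: np.random.Generator, aug: AugmentConfig) -> np.ndarray:
    out = img01
    h, w = out.shape[:2]
    if aug.crop_scale_min < 1.0:
        scale = rng.uniform(aug.crop_scale_min, 1.0)
        ch, cw = max(1, round(h * scale)), max(1, round(w * scale))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = out[top : top + ch, left : left + cw]
        out = resize(crop, (h, w, 3), order=1, anti_aliasing=False)
    if aug.hflip_prob > 0 and rng.random() < aug.hflip_prob:
        out = out[:, ::-1]
    if aug.vflip_prob > 0 and rng.random() < aug.vflip_prob:
        out = out[::-1]
    if aug.color_jitter > 0:
        j = aug.color_jitter
        out = out * (1.0 + rng.uniform(-j, j))  # brightness
        m = out.mean()
        out = (out - m) * (1.0 + rng.uniform(-j, j)) + m  # contrast
        out = out + rng.uniform(-j / 2, j / 2, size=3)  # channel shift
    if aug.blur_sigma_max > 0:
        sigma = rng.uniform(0, aug.blur_sigma_max)
        if sigma > 0.1:
            from scipy.ndimage import gaussian_filter

            out = gaussian_filter(out, sigma=(sigma, sigma, 0))
    return np.clip(out, 0.0, 1.0)


def make_views(
    tile: np.ndarray, seed: int, aug: AugmentConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one tile, deterministic per seed."""
    aug = aug or AugmentConfig()
    img01 = np.asarray(tile, float)
    if img01.max() > 1.5:  # uint8 input
        img01 = img01 / 255.0
    if aug.is_identity():
        return img01.copy(), img01.copy()
    view_a = _augment(img01, substream(seed, "view", 0), aug)
    view_b = _augment(img01, substream(seed, "view", 1), aug)
    return view_a, view_b


# ---------------------------------------------------------------------------
# loss


@dataclass
class LossReport:
    """Cross-correlation matrix and the decomposed Barlow-Twins loss."""

    C: np.ndarray
    on_diag_term: float
    off_diag_term: float
    lambda_offdiag: float

    @property
    def total(self) -> float:
        return self.on_diag_term + self.lambda_offdiag * self.off_diag_term


def _batch_normalize(Z: np.ndarray, strict: bool, view: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = Z.mean(axis=0)
    var = Z.var(axis=0)
    if strict:
        dead = np.nonzero(var < 1e-12)[0]
        if dead.size:
            raise ValueError(f"zero-variance embedding column {int(dead[0])} in view {view}")
    sigma = np.sqrt(var + _BN_EPS)
    return (Z - mu) / sigma, sigma, mu


def barlow_twins_loss(
    ZA: np.ndarray, ZB: np.ndarray, lambda_offdiag: float = 5e-3, *, strict: bool = True
) -> LossReport:
    """Barlow-Twins loss of two embedding batches (batch x d).

    Columns are batch-normalized before the cross-correlation is formed; the
    target cross-correlation is the identity.
    """
    ZA, ZB = np.asarray(ZA, float), np.asarray(ZB, float)
    if ZA.shape != ZB.shape:
        raise ValueError("view batches must have the same shape")
    if ZA.shape[0] < 2:
        raise ValueError("batch must contain at least 2 samples")
    n = ZA.shape[0]
    Ahat, _, _ = _batch_normalize(ZA, strict, "A")
    Bhat, _, _ = _batch_normalize(ZB, strict, "B")
    C = Ahat.T @ Bhat / n
    diag = np.diag(C)
    on = float(np.sum((1.0 - diag) ** 2))
    off = float(np.sum(C**2) - np.sum(diag**2))
    return LossReport(C=C, on_diag_term=on, off_diag_term=off, lambda_offdiag=lambda_offdiag)


def barlow_twins_grad(
    ZA: np.ndarray, ZB: np.ndarray, lambda_offdiag: float = 5e-3
) -> tuple[LossReport, np.ndarray, np.ndarray]:
    """Loss plus analytic gradients with respect to the raw embeddings."""
    ZA, ZB = np.asarray(ZA, float), np.asarray(ZB, float)
    n = ZA.shape[0]
    Ahat, sigA, _ = _batch_normalize(ZA, False, "A")
    Bhat, sigB, _ = _batch_normalize(ZB, False, "B")
    C = Ahat.T @ Bhat / n
    diag = np.diag(C)
    report = LossReport(
        C=C,
        on_diag_term=float(np.sum((1.0 - diag) ** 2)),
        off_diag_term=float(np.sum(C**2) - np.sum(diag**2)),
        lambda_offdiag=lambda_offdiag,
    )
    G = 2.0 * lambda_offdiag * C
    np.fill_diagonal(G, -2.0 * (1.0 - diag))
    dAhat = Bhat @ G.T / n
    dBhat = Ahat @ G / n
    dZA = _bn_backward(dAhat, Ahat, sigA)
    dZB = _bn_backward(dBhat, Bhat, sigB)
    return report, dZA, dZB


def _bn_backward(g: np.ndarray, xhat: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    # standard per-column batch-norm backward (biased variance, eps in sqrt)
    return (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) / sigma


# ---------------------------------------------------------------------------
# network


@dataclass
class EncoderConfig:
    z_dim: int = 128
    input_px: int = 16  # tiles are down-sampled to this side before flattening
    hidden_dims: tuple[int, ...] = (512,)
    projector_dims: tuple[int, ...] = (128,)
    lambda_offdiag: float = 5e-3  # original Barlow-Twins setting
    batch_size: int = 64
    epochs: int = 5
    learning_rate: float = 1e-3
    train_fraction: float = 0.40  # fraction of tiles per institution used for training
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.z_dim < 2:
            raise ValueError("z_dim must be >= 2")
        if self.lambda_offdiag <= 0:
            raise ValueError("lambda_offdiag must be positive")
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclass
class EncoderState:
    """Serialized network: list of (W, b) per dense layer, ReLU in between."""

    config: EncoderConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    version: int = 1

    @property
    def z_layer(self) -> int:
        """Index of the dense layer whose output is the tile embedding z."""
        return len(self.config.hidden_dims)

    def save(self, path: str | Path) -> None:
        import json

        cfg = asdict(self.config)
        cfg["augment"] = asdict(self.config.augment)
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(
            path,
            __meta__=np.frombuffer(
                json.dumps({"version": self.version, "config": cfg}).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "EncoderState":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            cfg = dict(meta["config"])
            cfg["augment"] = AugmentConfig(**cfg["augment"])
            cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
            cfg["projector_dims"] = tuple(cfg["projector_dims"])
            config = EncoderConfig(**cfg)
            n_layers = sum(1 for k in data.files if k.startswith("W"))
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
        return cls(config=config, weights=weights, biases=biases, version=meta["version"])


def _init_state(config: EncoderConfig) -> EncoderState:
    dims = (
        [config.input_px * config.input_px * 3]
        + list(config.hidden_dims)
        + [config.z_dim]
        + list(config.projector_dims)
    )
    rng = substream(config.seed, "init")
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return EncoderState(config=config, weights=weights, biases=biases)


def _forward(state: EncoderState, X: np.ndarray) -> list[np.ndarray]:
    """Pre-activation outputs of every dense layer (ReLU applied between)."""
    acts = []
    h = X
    for i, (W, b) in enumerate(zip(state.weights, state.biases)):
        if i > 0:
            h = np.maximum(h, 0.0)
        h = h @ W + b
        acts.append(h)
    return acts


def _backward(
    state: EncoderState, X: np.ndarray, acts: list[np.ndarray], grad_out: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    grads = [None] * len(state.weights)
    g = grad_out
    for i in range(len(state.weights) - 1, -1, -1):
        inp = X if i == 0 else np.maximum(acts[i - 1], 0.0)
        grads[i] = (inp.T @ g, g.sum(axis=0))
        if i > 0:
            g = (g @ state.weights[i].T) * (acts[i - 1] > 0)
    return grads


def _to_input(images: np.ndarray, input_px: int) -> np.ndarray:
    """Down-sample tiles to the network input size and flatten, centered on 0.5."""
    imgs = np.asarray(images, float)
    if imgs.max() > 1.5:
        imgs = imgs / 255.0
    if imgs.shape[1] != input_px:
        imgs = np.stack(
            [resize(im, (input_px, input_px, 3), order=1, anti_aliasing=True) for im in imgs]
        )
    return imgs.reshape(len(imgs), -1) - 0.5


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train_on_images(
    images: np.ndarray, config: EncoderConfig
) -> tuple[EncoderState, list[LossReport]]:
    """Train the encoder on a stack of tile images; returns state + epoch loss trace."""
    config.validate()
    n = len(images)
    if n < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} tiles, got {n}")
    state = _init_state(config)
    if config.epochs == 0:
        return state, []
    imgs01 = np.asarray(images, float)
    if imgs01.max() > 1.5:
        imgs01 = imgs01 / 255.0
    params = state.weights + state.biases
    opt = _Adam([p.shape for p in params], config.learning_rate)
    trace: list[LossReport] = []
    for epoch in range(config.epochs):
        rng = substream(config.seed, "epoch", epoch)
        order = rng.permutation(n)
        epoch_reports = []
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start : start + config.batch_size]
            views_a, views_b = [], []
            for j, i in enumerate(idx):
                va = _augment(imgs01[i], substream(config.seed, "aug", epoch, start, j, 0), config.augment)
                vb = _augment(imgs01[i], substream(config.seed, "aug", epoch, start, j, 1), config.augment)
                views_a.append(va)
                views_b.append(vb)
            XA = _to_input(np.stack(views_a), config.input_px)
            XB = _to_input(np.stack(views_b), config.input_px)
            acts_a = _forward(state, XA)
            acts_b = _forward(state, XB)
            report, dZA, dZB = barlow_twins_grad(acts_a[-1], acts_b[-1], config.lambda_offdiag)
            grads_a = _backward(state, XA, acts_a, dZA)
            grads_b = _backward(state, XB, acts_b, dZB)
            flat = [ga[0] + gb[0] for ga, gb in zip(grads_a, grads_b)] + [
                ga[1] + gb[1] for ga, gb in zip(grads_a, grads_b)
            ]
            opt.step(params, flat)
            epoch_reports.append(report)
        mean_lam = config.lambda_offdiag
        trace.append(
            LossReport(
                C=epoch_reports[-1].C,
                on_diag_term=float(np.mean([r.on_diag_term for r in epoch_reports])),
                off_diag_term=float(np.mean([r.off_diag_term for r in epoch_reports])),
                lambda_offdiag=mean_lam,
            )
        )
    return state, trace


def select_training_tiles(
    store: TileStore, manifest: pd.DataFrame, train_fraction: float, seed: int
) -> np.ndarray:
    """Draw ``train_fraction`` of kept tiles per institution (without replacement)."""
    inst_of_slide = manifest.set_index("slide_id")["institution"].to_dict()
    selected = []
    by_inst: dict[str, list[tuple[str, int]]] = {}
    for sid in sorted(store.slides):
        s = store.slides[sid]
        inst = inst_of_slide.get(sid, "?")
        for i in np.nonzero(s.kept)[0]:
            by_inst.setdefault(inst, []).append((sid, int(i)))
    for inst in sorted(by_inst):
        pool = by_inst[inst]
        k = max(1, int(round(train_fraction * len(pool))))
        rng = substream(seed, "train-tiles", inst)
        pick = rng.choice(len(pool), size=k, replace=False)
        selected.extend(pool[int(p)] for p in pick)
    return np.stack([store[sid].images[i] for sid, i in selected])


def train_encoder(
    store: TileStore, manifest: pd.DataFrame, config: EncoderConfig
) -> tuple[EncoderState, list[LossReport]]:
    """Train on ``train_fraction`` of each institution's kept tiles."""
    images = select_training_tiles(store, manifest, config.train_fraction, config.seed)
    return train_on_images(images, config)


def embed_images(images: np.ndarray, state: EncoderState) -> np.ndarray:
    """Deterministic embeddings (augmentations disabled): the z-layer output."""
    X = _to_input(images, state.config.input_px)
    acts = _forward(state, X)
    return acts[state.z_layer].astype(np.float32)


def embed(store: TileStore, state: EncoderState) -> TileStore:
    """Attach embeddings to every slide of the store (all tiles, in tile order)."""
    missing = [sid for sid, s in store.slides.items() if s.images is None]
    if missing:
        raise ValueError(f"slides without images: {sorted(missing)}")
    for sid in sorted(store.slides):
        s = store.slides[sid]
        if s.n_tiles:
            s.embeddings = embed_images(s.images, state)
        else:
            s.embeddings = np.zeros((0, state.config.z_dim), np.float32)
    return store
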