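"""Per-pair descriptors and the convolutional feature encoder.

A drug-disease pair is described by concatenating the pair's fused
drug-similarity row and disease-similarity row, zero-padding to the next
perfect square and reshaping row-major into an s x s grid.  A small
convolutional network (conv -> sigmoid -> 2x2 max-pool -> dense sigmoid ->
logistic output unit) is trained on association labels with binary
cross-entropy plus an L2 weight penalty; the penultimate dense activations
are the learned feature vectors handed to the downstream classifier.

The network is implemented directly on numpy (im2col convolution, exact
backpropagation, Adam or plain SGD updates) so that every stage can be
checked against brute-force oracles and runs are bit-reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .dataio import SimilarityMatrix

__all__ = [
    "PairDescriptor",
    "EncoderConfig",
    "ConvolutionalEncoder",
    "grid_side",
    "build_pair_descriptor",
    "build_descriptor_grids",
    "conv2d_valid",
    "max_pool",
    "binary_cross_entropy",
]


def grid_side(n_drugs: int, n_diseases: int) -> int:
    """Side of the square descriptor grid: ceil(sqrt(n_drugs + n_diseases))."""
    return math.isqrt(n_drugs + n_diseases - 1) + 1 if n_drugs + n_diseases > 0 else 0


@dataclass
class PairDescriptor:
    """One drug-disease pair's similarity descriptor and its 2D grid layout."""

    drug_row: np.ndarray
    disease_row: np.ndarray
    grid: np.ndarray

    @property
    def side(self) -> int:
        return self.grid.shape[0]


def _to_grid(concat: np.ndarray, side: int) -> np.ndarray:
    grid = np.zeros(side * side, dtype=float)
    grid[: concat.size] = concat
    return grid.reshape(side, side)


def build_pair_descriptor(
    rsim: SimilarityMatrix, sim: SimilarityMatrix, drug_id: str, disease_id: str
) -> PairDescriptor:
    """Assemble the descriptor for one pair from fused similarity rows."""
    drug_row = rsim.row(drug_id).astype(float)
    disease_row = sim.row(disease_id).astype(float)
    side = grid_side(drug_row.size, disease_row.size)
    concat = np.concatenate([drug_row, disease_row])
    return PairDescriptor(drug_row, disease_row, _to_grid(concat, side))


def build_descriptor_grids(
    rsim: SimilarityMatrix,
    sim: SimilarityMatrix,
    pairs: list[tuple[str, str]],
) -> np.ndarray:
    """Stack descriptor grids for many (drug_id, disease_id) pairs: (n, s, s)."""
    di = {e: i for i, e in enumerate(rsim.entity_ids)}
    ei = {e: i for i, e in enumerate(sim.entity_ids)}
    side = grid_side(rsim.n, sim.n)
    out = np.zeros((len(pairs), side, side), dtype=float)
    for k, (drug_id, disease_id) in enumerate(pairs):
        concat = np.concatenate([rsim.values[di[drug_id]], sim.values[ei[disease_id]]])
        out[k] = _to_grid(concat, side)
    return out


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and training hyperparameters of the encoder.

    conv_kernel is the side of the square convolution window (16 whenever
    the grid allows), pool the side of the max-pool window, l2 the weight
    of the (lambda/2)||W||^2 penalty and lr the Adam/SGD learning rate.
    """

    conv_kernel: int = 16
    pool: int = 2
    n_filters: int = 16
    dense_units: int = 64
    epochs: int = 200
    batch_size: int = 32
    lr: float = 5e-3
    l2: float = 1e-4
    optimizer: str = "adam"  # "adam" | "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_kernel < 1 or self.pool < 1:
            raise ValueError("conv_kernel and pool must be >= 1")
        if self.n_filters < 1 or self.dense_units < 1:
            raise ValueError("n_filters and dense_units must be >= 1")
        if self.lr <= 0 or self.l2 < 0:
            raise ValueError("lr must be > 0 and l2 >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def for_grid(cls, side: int, **overrides) -> "EncoderConfig":
        """Config whose convolution window fits the grid.

        Uses the reference 16x16 window whenever the grid is large enough to
        leave a non-trivial feature map, otherwise shrinks to side - 4
        (floor 2) so small benchmark instances remain trainable.
        """
        kernel = max(2, min(16, side - 4))
        return cls(conv_kernel=kernel, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_seed(self, seed: int) -> "EncoderConfig":
        return replace(self, seed=seed)


def conv2d_valid(grids: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid (no padding) cross-correlation of (n, s, s) grids with (F, k, k) kernels.

    Returns the pre-activation feature maps, shape (n, s-k+1, s-k+1, F).
    """
    cols, oh, ow = _im2col(grids, kernels.shape[1])
    F = kernels.shape[0]
    z = cols @ kernels.reshape(F, -1).T + bias
    return z.reshape(grids.shape[0], oh, ow, F)


def _im2col(grids: np.ndarray, k: int) -> tuple[np.ndarray, int, int]:
    n, s, _ = grids.shape
    if k > s:
        raise ValueError(f"convolution kernel {k} larger than grid side {s}")
    oh = ow = s - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(grids, (k, k), axis=(1, 2))
    cols = windows.reshape(n, oh * ow, k * k)
    return np.ascontiguousarray(cols), oh, ow


def _pad_for_pool(maps: np.ndarray, p: int) -> np.ndarray:
    """Pad feature maps with -inf so both spatial dims are multiples of p (ceil mode)."""
    n, h, w, f = maps.shape
    ph, pw = (-h) % p, (-w) % p
    if ph or pw:
        maps = np.pad(maps, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
    return maps


def max_pool(maps: np.ndarray, p: int = 2) -> np.ndarray:
    """Non-overlapping p x p block maximum over (n, h, w, f) maps, ceil mode at edges."""
    padded = _pad_for_pool(maps, p)
    n, h, w, f = padded.shape
    blocks = padded.reshape(n, h // p, p, w // p, p, f)
    return blocks.max(axis=(2, 4))


def _max_pool_with_argmax(maps: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, tuple]:
    padded = _pad_for_pool(maps, p)
    n, h, w, f = padded.shape
    blocks = padded.reshape(n, h // p, p, w // p, p, f).transpose(0, 1, 3, 5, 2, 4)
    flat = blocks.reshape(n, h // p, w // p, f, p * p)
    arg = flat.argmax(axis=-1)  # first max wins ties
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, arg, padded.shape


def _unpool(grad: np.ndarray, arg: np.ndarray, padded_shape: tuple, p: int, orig_hw: tuple) -> np.ndarray:
    n, h, w, f = padded_shape
    flat = np.zeros((n, h // p, w // p, f, p * p))
    np.put_along_axis(flat, arg[..., None], grad[..., None], axis=-1)
    blocks = flat.reshape(n, h // p, w // p, f, p, p).transpose(0, 1, 4, 2, 5, 3)
    padded = blocks.reshape(n, h, w, f)
    oh, ow = orig_hw
    return padded[:, :oh, :ow, :]


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of probabilities p against 0/1 labels y."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvolutionalEncoder:
    """conv -> sigmoid -> max-pool -> dense sigmoid -> logistic unit, on numpy.

    Trained end-to-end on binary cross-entropy plus an L2 penalty on all
    weight matrices; ``encode`` returns the penultimate dense activations.
    Weight initialisation, batching and updates are driven by a single seed,
    so identical seeds and data give bit-identical results.
    """

    def __init__(self, cfg: EncoderConfig, side: int):
        if cfg.conv_kernel > side:
            raise ValueError(
                f"conv kernel {cfg.conv_kernel} exceeds descriptor grid side {side}"
            )
        self.cfg = cfg
        self.side = side
        k, F, p = cfg.conv_kernel, cfg.n_filters, cfg.pool
        oh = side - k + 1
        ph = -(-oh // p)
        self._flat_dim = ph * ph * F
        rng = np.random.default_rng(cfg.seed)
        self.Wc = rng.normal(0.0, math.sqrt(2.0 / (k * k + F)), size=(F, k, k))
        self.bc = np.zeros(F)
        self.W1 = rng.normal(0.0, math.sqrt(2.0 / (self._flat_dim + cfg.dense_units)),
                             size=(self._flat_dim, cfg.dense_units))
        self.b1 = np.zeros(cfg.dense_units)
        self.W2 = rng.normal(0.0, math.sqrt(2.0 / (cfg.dense_units + 1)),
                             size=(cfg.dense_units, 1))
        self.b2 = np.zeros(1)
        self._rng = rng
        self.loss_history: list[float] = []

    # -- forward ---------------------------------------------------------

    def _forward(self, grids: np.ndarray, cache: bool = False):
        cfg = self.cfg
        cols, oh, ow = _im2col(grids, cfg.conv_kernel)
        z1 = cols @ self.Wc.reshape(cfg.n_filters, -1).T + self.bc
        a1 = _sigmoid(z1).reshape(grids.shape[0], oh, ow, cfg.n_filters)
        pooled, arg, padded_shape = _max_pool_with_argmax(a1, cfg.pool)
        h = pooled.reshape(grids.shape[0], -1)
        z2 = h @ self.W1 + self.b1
        a2 = _sigmoid(z2)
        z3 = a2 @ self.W2 + self.b2
        out = _sigmoid(z3)[:, 0]
        if not cache:
            return a2, out
        return a2, out, (cols, a1, arg, padded_shape, (oh, ow), h)

    def encode(self, grids: np.ndarray) -> np.ndarray:
        """Feature vectors (penultimate dense activations) for (n, s, s) grids."""
        grids = self._check(grids)
        return self._forward(grids)[0]

    def predict_proba(self, grids: np.ndarray) -> np.ndarray:
        """Output-unit association probabilities (used only for diagnostics)."""
        grids = self._check(grids)
        return self._forward(grids)[1]

    def _check(self, grids: np.ndarray) -> np.ndarray:
        grids = np.asarray(grids, dtype=float)
        if grids.ndim == 2:
            grids = grids[None]
        if grids.shape[1:] != (self.side, self.side):
            raise ValueError(f"expected grids of side {self.side}, got {grids.shape[1:]}")
        return grids

    # -- loss ------------------------------------------------------------

    def _penalty(self) -> float:
        w2 = float((self.Wc ** 2).sum() + (self.W1 ** 2).sum() + (self.W2 ** 2).sum())
        return 0.5 * self.cfg.l2 * w2

    def loss(self, grids: np.ndarray, labels: np.ndarray) -> float:
        """Regularised training objective: mean BCE + (lambda/2)||W||^2."""
        grids = self._check(grids)
        _, out = self._forward(grids)
        return binary_cross_entropy(out, labels) + self._penalty()

    # -- training --------------------------------------------------------

    def fit(self, grids: np.ndarray, labels: np.ndarray) -> "ConvolutionalEncoder":
        grids = self._check(grids)
        y = np.asarray(labels, dtype=float)
        if y.shape[0] != grids.shape[0]:
            raise ValueError("labels and descriptors differ in length")
        if len(np.unique(y)) < 2:
            raise ValueError("encoder training requires both classes present")
        cfg = self.cfg
        params = [self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2]
        opt = _Adam(params, cfg.lr) if cfg.optimizer == "adam" else None
        n = grids.shape[0]
        self.loss_history = [self.loss(grids, y)]
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                grads = self._gradients(grids[idx], y[idx])
                if opt is not None:
                    opt.step(params, grads)
                else:
                    for p, g in zip(params, grads):
                        p -= cfg.lr * g
            self.loss_history.append(self.loss(grids, y))
        return self

    def _gradients(self, grids: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        cfg = self.cfg
        B = grids.shape[0]
        a2, out, (cols, a1, arg, padded_shape, orig_hw, h) = self._forward(grids, cache=True)
        dz3 = (out - y)[:, None] / B  # BCE + sigmoid shortcut
        gW2 = a2.T @ dz3 + cfg.l2 * self.W2
        gb2 = dz3.sum(axis=0)
        da2 = dz3 @ self.W2.T
        dz2 = da2 * a2 * (1.0 - a2)
        gW1 = h.T @ dz2 + cfg.l2 * self.W1
        gb1 = dz2.sum(axis=0)
        dh = dz2 @ self.W1.T
        dpool = dh.reshape(B, *_pool_out_shape(padded_shape, cfg.pool))
        da1 = _unpool(dpool, arg, padded_shape, cfg.pool, orig_hw)
        dz1 = (da1 * a1 * (1.0 - a1)).reshape(B, -1, cfg.n_filters)
        gWc = np.einsum("bpf,bpk->fk", dz1, cols).reshape(self.Wc.shape) + cfg.l2 * self.Wc
        gbc = dz1.sum(axis=(0, 1))
        return [gWc, gbc, gW1, gb1, gW2, gb2]


def _pool_out_shape(padded_shape: tuple, p: int) -> tuple:
    n, h, w, f = padded_shape
    return (h // p, w // p, f)
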