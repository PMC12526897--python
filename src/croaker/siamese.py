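"""Twin-embedding similarity validation of reconstructed calls.

Calls are compared in an embedding space learned from their spectrograms:
two weight-sharing encoders map a pair of dB-scaled, [0, 1]-normalized
spectrograms to embeddings whose cosine similarity measures call likeness.
Training uses the contrastive loss on the cosine distance
``d = 1 - cos(e_a, e_b)``,

    L = (1 - y) * d^2 + y * max(0, margin - d)^2,

with label 0 for same-chain (positive) and 1 for different-chain
(negative) pairs, the Adam optimizer, periodic held-out evaluation and
early stopping on stalled loss.

The encoder is a compact multilayer perceptron over an average-pooled
spectrogram, implemented directly in numpy with hand-derived gradients;
the embedding width defaults to 512.  It is deliberately small — enough
capacity to separate chain classes of the synthetic datasets on a single
CPU — and its parameter count is reported, not asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import stft

from .wavelets import Waveform


# ---------------------------------------------------------------------------
# spectrograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT and normalization settings.

    dB values at or below ``db_floor`` map to 0, at or above ``db_ceil``
    to 1.  The output is bilinearly resized to ``out_size`` pixels.
    """

    out_size: tuple[int, int] = (224, 224)
    db_floor: float = 60.0
    db_ceil: float = 120.0
    nperseg: int = 1024
    hop: int | None = None

    def __post_init__(self):
        if not self.db_floor < self.db_ceil:
            raise ValueError("db_floor must be < db_ceil")


def _resize_bilinear(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Separable bilinear resize (rows then columns)."""
    r0, c0 = img.shape
    r1, c1 = shape
    out = np.empty((r1, c0))
    xi = np.linspace(0, r0 - 1, r1)
    x = np.arange(r0)
    for j in range(c0):
        out[:, j] = np.interp(xi, x, img[:, j])
    out2 = np.empty((r1, c1))
    xi = np.linspace(0, c0 - 1, c1)
    x = np.arange(c0)
    for i in range(r1):
        out2[i] = np.interp(xi, x, out[i])
    return out2


def make_spectrogram(w: Waveform,
                     cfg: SpectrogramConfig | None = None) -> np.ndarray:
    """dB-magnitude STFT clipped to [floor, ceil] dB and mapped to [0, 1]."""
    cfg = cfg or SpectrogramConfig()
    x = np.asarray(w.samples, dtype=float)
    if len(x) < cfg.nperseg:
        raise ValueError(
            f"waveform ({len(x)} samples) shorter than one STFT window "
            f"({cfg.nperseg})")
    hop = cfg.hop or max(1, (len(x) - cfg.nperseg)
                         // max(1, cfg.out_size[1] - 1) + 1)
    _, _, Z = stft(x, fs=w.fs, nperseg=cfg.nperseg,
                   noverlap=cfg.nperseg - hop, boundary=None, padded=False)
    mag = np.abs(Z)
    db = 20.0 * np.log10(np.maximum(mag, 1e-300))
    db = np.clip(db, cfg.db_floor, cfg.db_ceil)
    img = (db - cfg.db_floor) / (cfg.db_ceil - cfg.db_floor)
    return _resize_bilinear(img, cfg.out_size)


def db_to_unit(db: np.ndarray, cfg: SpectrogramConfig | None = None):
    """The affine dB -> [0, 1] map alone (useful for calibration checks)."""
    cfg = cfg or SpectrogramConfig()
    db = np.clip(db, cfg.db_floor, cfg.db_ceil)
    return (db - cfg.db_floor) / (cfg.db_ceil - cfg.db_floor)


# ---------------------------------------------------------------------------
# pairs and loss
# ---------------------------------------------------------------------------


@dataclass
class PairSample:
    """A labelled spectrogram pair: label 0 = same chain, 1 = different."""

    spectrogram_a: np.ndarray
    spectrogram_b: np.ndarray
    label: int


def sample_pairs(dataset: dict[int, list[np.ndarray]], n: int,
                 rng: np.random.Generator,
                 balanced: bool = True) -> list[PairSample]:
    """Draw labelled pairs per chain class.

    Positives sample two examples from one class, negatives one example
    from each of two classes; half of ``n`` each when ``balanced``.
    """
    classes = [c for c in dataset if len(dataset[c]) > 0]
    if len(classes) < 2:
        raise ValueError("need at least two chain classes for negatives")
    multi = [c for c in classes if len(dataset[c]) >= 2]
    if not multi:
        raise ValueError("need a class with >= 2 examples for positives")
    pairs = []
    n_pos = n // 2 if balanced else n // 2
    for i in range(n):
        if i < n_pos:
            c = classes[rng.integers(len(classes))]
            if len(dataset[c]) < 2:
                c = multi[rng.integers(len(multi))]
            a, b = rng.choice(len(dataset[c]), size=2, replace=False)
            pairs.append(PairSample(dataset[c][a], dataset[c][b], 0))
        else:
            i1, i2 = rng.choice(len(classes), size=2, replace=False)
            c1, c2 = classes[i1], classes[i2]
            a = rng.integers(len(dataset[c1]))
            b = rng.integers(len(dataset[c2]))
            pairs.append(PairSample(dataset[c1][a], dataset[c2][b], 1))
    return pairs


def contrastive_loss(d, y, margin: float = 0.3):
    """Contrastive loss on a distance ``d >= 0`` with binary label ``y``."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    return (1.0 - y) * d ** 2 + y * np.maximum(0.0, margin - d) ** 2


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


def _avg_pool(x: np.ndarray, k: int) -> np.ndarray:
    """Non-overlapping k x k average pooling over the last two axes."""
    if k <= 1:
        return x
    *lead, r, c = x.shape
    r2, c2 = r // k, c // k
    x = x[..., : r2 * k, : c2 * k]
    return x.reshape(*lead, r2, k, c2, k).mean(axis=(-3, -1))


class EmbeddingNet:
    """Weight-sharing spectrogram encoder (numpy MLP).

    ``pool`` average-pools the input spectrogram before flattening; two
    ReLU hidden layers feed a linear embedding layer of width
    ``embed_dim``.  ``architecture`` describes the stack; ``n_parameters``
    reports the trainable weight count.
    """

    def __init__(self, input_shape: tuple[int, int], embed_dim: int = 512,
                 hidden: tuple[int, ...] = (256, 256), pool: int = 8,
                 seed: int = 0):
        self.input_shape = input_shape
        self.pool = pool
        pooled = (input_shape[0] // pool, input_shape[1] // pool)
        dims = [pooled[0] * pooled[1], *hidden, embed_dim]
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        self.embed_dim = embed_dim
        self.architecture = (
            f"avg-pool {pool}x{pool} -> flatten {dims[0]} -> "
            + " -> ".join(f"dense {d} (ReLU)" for d in hidden)
            + f" -> dense {embed_dim} (linear embedding)")

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.weights,
                                                       self.biases)))

    def forward(self, X: np.ndarray, keep_cache: bool = False):
        """Embed a batch of spectrograms, shape (B, H, W) -> (B, D)."""
        a = _avg_pool(X, self.pool).reshape(X.shape[0], -1)
        cache = [a]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if i < len(self.weights) - 1:
                a = np.maximum(a, 0.0)
            cache.append(a)
        return (a, cache) if keep_cache else a

    def backward(self, cache, grad_out: np.ndarray):
        """Gradients of weights/biases given d(loss)/d(embedding)."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.weights)
        g = grad_out
        for i in range(len(self.weights) - 1, -1, -1):
            a_in = cache[i]
            if i < len(self.weights) - 1:
                g = g * (cache[i + 1] > 0)
            grads_w[i] = a_in.T @ g
            grads_b[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return grads_w, grads_b

    def embed(self, spectrograms: list[np.ndarray]) -> np.ndarray:
        return self.forward(np.stack(spectrograms))


def cosine_similarity(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity of two embedding batches."""
    num = (ea * eb).sum(axis=-1)
    den = np.linalg.norm(ea, axis=-1) * np.linalg.norm(eb, axis=-1)
    return num / np.maximum(den, 1e-300)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization protocol of the twin encoder."""

    learning_rate: float = 1e-5
    margin: float = 0.3
    batch: int = 64
    max_steps: int = 2000
    eval_every: int = 100
    early_stop_patience: int = 5
    split: float = 0.7
    embed_dim: int = 512
    hidden: tuple[int, ...] = (256, 256)
    pool: int = 8
    seed: int = 0

    def validate(self):
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0, 1)")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class TrainHistory:
    steps: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_pos_cos: list[float] = field(default_factory=list)
    val_neg_cos: list[float] = field(default_factory=list)
    stopped_at: int = 0


def _pair_loss_and_grads(model: EmbeddingNet, pairs: list[PairSample],
                         margin: float):
    A = np.stack([p.spectrogram_a for p in pairs])
    B = np.stack([p.spectrogram_b for p in pairs])
    y = np.array([p.label for p in pairs], dtype=float)
    ea, cache_a = model.forward(A, keep_cache=True)
    eb, cache_b = model.forward(B, keep_cache=True)
    na = np.linalg.norm(ea, axis=1, keepdims=True)
    nb = np.linalg.norm(eb, axis=1, keepdims=True)
    na = np.maximum(na, 1e-30)
    nb = np.maximum(nb, 1e-30)
    cos = (ea * eb).sum(axis=1, keepdims=True) / (na * nb)
    d = 1.0 - cos[:, 0]
    losses = contrastive_loss(d, y, margin)
    loss = float(losses.mean())
    # dL/dd, then dd/de = -dcos/de
    hinge = np.maximum(0.0, margin - d)
    dl_dd = (2 * (1 - y) * d - 2 * y * hinge) / len(pairs)
    dcos_dea = eb / (na * nb) - cos * ea / na ** 2
    dcos_deb = ea / (na * nb) - cos * eb / nb ** 2
    ga = -dl_dd[:, None] * dcos_dea
    gb = -dl_dd[:, None] * dcos_deb
    gwa, gba = model.backward(cache_a, ga)
    gwb, gbb = model.backward(cache_b, gb)
    grads_w = [a + b for a, b in zip(gwa, gwb)]
    grads_b = [a + b for a, b in zip(gba, gbb)]
    return loss, grads_w, grads_b, d, y


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def split_dataset(dataset: dict[int, list], split: float,
                  rng: np.random.Generator):
    """Disjoint per-class split into (train, validation)."""
    train, val = {}, {}
    for c, items in dataset.items():
        idx = rng.permutation(len(items))
        k = max(1, int(round(split * len(items)))) if len(items) > 1 else 1
        k = min(k, len(items) - 1) if len(items) > 1 else 1
        train[c] = [items[i] for i in idx[:k]]
        val[c] = [items[i] for i in idx[k:]]
    return train, {c: v for c, v in val.items() if v}


def train_siamese(dataset: dict[int, list[np.ndarray]],
                  cfg: TrainConfig | None = None):
    """Train the twin encoder on chain-labelled spectrograms.

    ``dataset`` maps chain labels to spectrogram arrays (all one shape).
    Returns ``(model, history)``; training stops early after
    ``early_stop_patience`` evaluations without validation-loss
    improvement, or on divergence (NaN loss raises).
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    train, val = split_dataset(dataset, cfg.split, rng)
    shape = next(iter(dataset.values()))[0].shape
    model = EmbeddingNet(shape, cfg.embed_dim, cfg.hidden, cfg.pool,
                         seed=cfg.seed)
    params = model.weights + model.biases
    opt = _Adam(params, cfg.learning_rate)
    hist = TrainHistory()
    best_val = np.inf
    bad_evals = 0
    val_pairs = sample_pairs(val, max(cfg.batch, 64), rng) if len(val) >= 2 \
        else None
    for step in range(1, cfg.max_steps + 1):
        pairs = sample_pairs(train, cfg.batch, rng)
        loss, gw, gb, _, _ = _pair_loss_and_grads(model, pairs, cfg.margin)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at step {step} (loss={loss})")
        opt.step(params, gw + gb)
        if step % cfg.eval_every == 0:
            if val_pairs is not None:
                vloss, _, _, vd, vy = _pair_loss_and_grads(
                    model, val_pairs, cfg.margin)
            else:
                vloss, vd, vy = loss, np.array([0.0]), np.array([1.0])
            vcos = 1.0 - vd
            pos = float(vcos[vy == 0].mean()) if (vy == 0).any() else np.nan
            neg = float(vcos[vy == 1].mean()) if (vy == 1).any() else np.nan
            hist.steps.append(step)
            hist.train_loss.append(loss)
            hist.val_loss.append(float(vloss))
            hist.val_pos_cos.append(pos)
            hist.val_neg_cos.append(neg)
            if vloss < best_val - 1e-12:
                best_val = vloss
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= cfg.early_stop_patience:
                    hist.stopped_at = step
                    break
    if hist.stopped_at == 0:
        hist.stopped_at = cfg.max_steps
    return model, hist


def evaluate_similarity(model: EmbeddingNet,
                        set_a: dict[int, list[np.ndarray]],
                        set_b: dict[int, list[np.ndarray]]):
    """Chain-wise mean cosine similarity between two spectrogram sets.

    Pairs are matched by index within each chain (up to the shorter set);
    chains present in only one set are omitted with a warning.  Returns a
    DataFrame with one row per chain plus an ``average`` row.
    """
    import logging

    import pandas as pd

    rows = []
    sims_all = []
    for chain in sorted(set(set_a) | set(set_b)):
        if chain not in set_a or chain not in set_b or \
                not set_a[chain] or not set_b[chain]:
            logging.getLogger(__name__).warning(
                "chain %s missing from one set; omitted", chain)
            continue
        n = min(len(set_a[chain]), len(set_b[chain]))
        ea = model.embed(set_a[chain][:n])
        eb = model.embed(set_b[chain][:n])
        sims = cosine_similarity(ea, eb)
        rows.append({"chain": chain, "cosine_similarity": float(sims.mean()),
                     "n_pairs": n})
        sims_all.extend(sims.tolist())
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = pd.concat([
            pd.DataFrame([{"chain": "average",
                           "cosine_similarity": float(np.mean(sims_all)),
                           "n_pairs": len(sims_all)}]),
            frame], ignore_index=True)
    return frame
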