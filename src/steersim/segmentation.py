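"""Multiclass risk segmentation of low-dose projections.

Two interchangeable segmenters are provided:

* :class:`UNetSegmenter` — a U-Net-style 2D encoder-decoder (3x3 convolutions,
  ReLU, max-pool downsampling, nearest-neighbour upsampling with skip
  concatenation, softmax head) trained with Adam on the weighted
  cross-entropy loss, with early stopping on validation loss. The network,
  backpropagation and optimiser are implemented directly on numpy arrays so
  the pipeline is fully deterministic and dependency-light; capacities are
  deliberately small (CPU-scale).
* :class:`PatchLogisticSegmenter` — a multinomial logistic regression on
  per-pixel neighbourhood features; fast and convex, used as a deterministic
  baseline for exercising the downstream calibration/evaluation stages.

Both consume :class:`~steersim.ground_truth.TrainingPair` lists and emit
per-pixel 4-class :class:`ProbabilityMap` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AlignmentError, InvalidParameterError
from .ground_truth import N_RISK_CLASSES, TrainingPair

_EPS = 1e-12


@dataclass
class ProbabilityMap:
    """Per-pixel vector of the four risk-class probabilities."""

    probs: np.ndarray                 # (H, W, 4), rows sum to 1
    phantom_id: int | None = None
    calibrated: bool = False


@dataclass(frozen=True)
class SegmenterConfig:
    depth: int = 3                    # resolution levels (depth-1 poolings)
    base_channels: int = 16
    batch_size: int = 6
    learning_rate: float = 3e-4
    max_epochs: int = 250
    patience: int = 20
    class_weights: tuple[float, ...] | None = None   # None -> inverse freq
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.depth < 1:
            raise InvalidParameterError("batch_size and depth must be >= 1")
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise InvalidParameterError("class weights must be positive")


def weighted_cross_entropy(probs: np.ndarray, target: np.ndarray,
                           class_weights) -> float:
    """Mean class-weighted negative log-likelihood over pixels.

    ``-(1/Npix) * sum_pixels weight[target] * ln probs[target]``, with
    probabilities clamped at 1e-12 so saturated predictions stay finite.
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    if probs.shape[:-1] != target.shape:
        raise AlignmentError(
            f"probs {probs.shape} and target {target.shape} do not align")
    w = np.asarray(class_weights, dtype=np.float64)
    p_true = np.take_along_axis(probs, target[..., None].astype(int),
                                axis=-1)[..., 0]
    return float(-np.mean(w[target] * np.log(np.clip(p_true, _EPS, None))))


def inverse_frequency_weights(pairs: list[TrainingPair],
                              n_classes: int = N_RISK_CLASSES) -> np.ndarray:
    """Inverse pixel-frequency class weights, normalised to mean 1."""
    counts = np.zeros(n_classes)
    for p in pairs:
        counts += np.bincount(p.target.ravel(), minlength=n_classes)
    w = 1.0 / np.maximum(counts, 1.0)
    return w / w.mean()


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------- layers

class _Conv3x3:
    """Same-padded 3x3 convolution (+ optional ReLU) with explicit backprop."""

    def __init__(self, c_in: int, c_out: int, rng, relu: bool = True):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.relu = relu
        self._cols = None
        self._mask = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        out = (cols @ self.W.T + self.b).reshape(n, h, w, -1)
        out = out.transpose(0, 3, 1, 2)
        if self.relu:
            mask = out > 0
            out = out * mask
        else:
            mask = None
        if train:
            self._cols, self._mask, self._shape = cols, mask, (n, c, h, w)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        if self.relu:
            g = g * self._mask
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, self.W.shape[0])
        self.dW += g2.T @ self._cols
        self.db += g2.sum(axis=0)
        dcols = (g2 @ self.W).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j] \
                    .transpose(0, 3, 1, 2)
        self._cols = self._mask = None
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def _pool2(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    m = xr.max(axis=(3, 5))
    mask = xr == m[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    return m, mask


def _pool2_back(g, mask):
    return (g[:, :, :, None, :, None] * mask).reshape(
        mask.shape[0], mask.shape[1],
        mask.shape[2] * 2, mask.shape[4] * 2)


def _up2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_back(g):
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------- network

class _UNet:
    """Encoder-decoder with skip connections on (N, C, H, W) arrays."""

    def __init__(self, cfg: SegmenterConfig, n_classes: int, rng):
        d, c0 = cfg.depth, cfg.base_channels
        self.depth = d
        self.enc = []
        c_in = 1
        for lvl in range(d):
            c = c0 * (2 ** lvl)
            self.enc.append((_Conv3x3(c_in, c, rng), _Conv3x3(c, c, rng)))
            c_in = c
        self.dec = []
        for lvl in range(d - 2, -1, -1):
            c = c0 * (2 ** lvl)
            self.dec.append((_Conv3x3(c * 2 + c, c, rng), _Conv3x3(c, c, rng)))
        self.head = _Conv3x3(c0, n_classes, rng, relu=False)

    def layers(self):
        out = []
        for a, b in self.enc:
            out += [a, b]
        for a, b in self.dec:
            out += [a, b]
        out.append(self.head)
        return out

    def forward(self, x, train=False):
        skips = []
        self._pool_masks = []
        h = x
        for lvl, (a, b) in enumerate(self.enc):
            h = b.forward(a.forward(h, train), train)
            if lvl < self.depth - 1:
                skips.append(h)
                h, mask = _pool2(h)
                self._pool_masks.append(mask if train else None)
        self._skip_channels = []
        for (a, b), skip in zip(self.dec, reversed(skips)):
            h = np.concatenate([_up2(h), skip], axis=1)
            self._skip_channels.append(skip.shape[1])
            h = b.forward(a.forward(h, train), train)
        return self.head.forward(h, train)

    def backward(self, g):
        g = self.head.backward(g)
        skip_grads = []
        for (a, b), c_skip in zip(reversed(self.dec),
                                  reversed(self._skip_channels)):
            g = a.backward(b.backward(g))
            skip_grads.append(g[:, -c_skip:])
            g = _up2_back(g[:, :-c_skip])
        for lvl in range(self.depth - 1, -1, -1):
            a, b = self.enc[lvl]
            if lvl < self.depth - 1:
                g = _pool2_back(g, self._pool_masks[lvl])
                g = g + skip_grads[lvl]
            g = a.backward(b.backward(g))
        return g


class _Adam:
    def __init__(self, layers, lr):
        self.layers = layers
        self.lr = lr
        self.t = 0
        self.state = [
            [(np.zeros_like(p), np.zeros_like(p)) for p, _ in lay.params()]
            for lay in layers
        ]

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for lay, st in zip(self.layers, self.state):
            for (p, g), (m, v) in zip(lay.params(), st):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mh = m / (1 - b1 ** self.t)
                vh = v / (1 - b2 ** self.t)
                p -= self.lr * mh / (np.sqrt(vh) + eps)
                g[...] = 0.0


# ---------------------------------------------------------------- training

@dataclass
class SegmenterState:
    """Trained segmenter: network, input normalisation, training curves."""

    net: object
    config: SegmenterConfig
    norm_mean: float
    norm_std: float
    class_weights: np.ndarray
    history: dict = field(default_factory=dict)
    best_epoch: int = -1


def _normalise(images: np.ndarray, mean: float, std: float) -> np.ndarray:
    return (np.log1p(np.maximum(images, 0.0)) - mean) / std


def _stack(pairs):
    x = np.stack([p.image for p in pairs]).astype(np.float64)
    y = np.stack([p.target for p in pairs]).astype(np.int64)
    return x, y


class UNetSegmenter:
    """Trainable encoder-decoder segmenter (see module docstring)."""

    def __init__(self, config: SegmenterConfig | None = None):
        self.config = config or SegmenterConfig()
        self.state: SegmenterState | None = None

    def fit(self, train_pairs, val_pairs) -> SegmenterState:
        return train_segmenter(train_pairs, val_pairs, self.config, self)

    def predict_probabilities(self, image) -> ProbabilityMap:
        return predict_probabilities(self.state, image)


def train_segmenter(train_pairs, val_pairs, config: SegmenterConfig,
                    segmenter: UNetSegmenter | None = None) -> SegmenterState:
    """Adam + weighted cross-entropy with early stopping on validation loss.

    Training stops when the validation loss has not improved for
    ``config.patience`` epochs (or at ``max_epochs``); the best-validation
    parameters are restored. Fully deterministic for a fixed config/seed.
    """
    if not train_pairs or not val_pairs:
        raise InvalidParameterError("train and validation sets must be nonempty")
    cfg = config
    xtr, ytr = _stack(train_pairs)
    xva, yva = _stack(val_pairs)
    h, w = xtr.shape[1:]
    if h % 2 ** (cfg.depth - 1) or w % 2 ** (cfg.depth - 1):
        raise InvalidParameterError(
            f"image dims {h}x{w} must be divisible by 2^(depth-1)")
    logs = np.log1p(np.maximum(xtr, 0.0))
    mean, std = float(logs.mean()), float(logs.std() + 1e-9)
    xtr = _normalise(xtr, mean, std)
    xva = _normalise(xva, mean, std)

    if cfg.class_weights is None:
        weights = inverse_frequency_weights(train_pairs)
    else:
        weights = np.asarray(cfg.class_weights, dtype=np.float64)

    rng = np.random.default_rng(cfg.seed)
    net = _UNet(cfg, N_RISK_CLASSES, rng)
    opt = _Adam(net.layers(), cfg.learning_rate)

    def eval_loss(x, y):
        total, npx = 0.0, 0
        for i in range(0, len(x), cfg.batch_size):
            xb, yb = x[i:i + cfg.batch_size], y[i:i + cfg.batch_size]
            p = softmax(net.forward(xb[:, None]), axis=1)
            p = np.moveaxis(p, 1, -1)
            total += weighted_cross_entropy(p, yb, weights) * yb.size
            npx += yb.size
        return total / npx

    best_loss, best_epoch, best_params = np.inf, -1, None
    hist = {"train_loss": [], "val_loss": []}
    n = len(xtr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_px = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = xtr[idx][:, None], ytr[idx]
            logits = net.forward(xb, train=True)          # (b,4,h,w)
            p = softmax(logits, axis=1)
            onehot = np.eye(N_RISK_CLASSES)[yb].transpose(0, 3, 1, 2)
            wpix = weights[yb][:, None]                   # (b,1,h,w)
            npx = yb.size
            if not np.isfinite(logits).all():
                raise FloatingPointError(
                    f"non-finite activations at epoch {epoch}")
            loss = weighted_cross_entropy(
                np.moveaxis(p, 1, -1), yb, weights)
            net.backward(wpix * (p - onehot) / npx)
            opt.step()
            ep_loss += loss * npx
            ep_px += npx
        hist["train_loss"].append(ep_loss / ep_px)
        vl = eval_loss(xva, yva)
        hist["val_loss"].append(vl)
        if vl < best_loss - 1e-12:
            best_loss, best_epoch = vl, epoch
            best_params = [[p.copy() for p, _ in lay.params()]
                           for lay in net.layers()]
        if epoch - best_epoch >= cfg.patience:
            break
    if best_params is not None:
        for lay, saved in zip(net.layers(), best_params):
            for (p, _), s in zip(lay.params(), saved):
                p[...] = s
    state = SegmenterState(net=net, config=cfg, norm_mean=mean, norm_std=std,
                           class_weights=weights, history=hist,
                           best_epoch=best_epoch)
    if segmenter is not None:
        segmenter.state = state
    return state


def predict_probabilities(state: SegmenterState, image) -> ProbabilityMap:
    """Softmax class probabilities for one image on the trained network."""
    x = _normalise(np.asarray(image, dtype=np.float64),
                   state.norm_mean, state.norm_std)
    logits = state.net.forward(x[None, None])
    probs = softmax(logits, axis=1)[0]
    return ProbabilityMap(probs=np.moveaxis(probs, 0, -1).copy(),
                          calibrated=False)


def save_state(state: SegmenterState, path) -> None:
    """Single-file checkpoint: parameters, config echo, normalisation."""
    import dataclasses
    import json

    arrays = {}
    for li, lay in enumerate(state.net.layers()):
        for pi, (p, _) in enumerate(lay.params()):
            arrays[f"param_{li}_{pi}"] = p
    cfg = dataclasses.asdict(state.config)
    meta = {"config": cfg, "norm_mean": state.norm_mean,
            "norm_std": state.norm_std,
            "class_weights": list(map(float, state.class_weights)),
            "history": state.history, "best_epoch": state.best_epoch}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_state(path) -> SegmenterState:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = dict(meta["config"])
        if cfg_d.get("class_weights") is not None:
            cfg_d["class_weights"] = tuple(cfg_d["class_weights"])
        cfg = SegmenterConfig(**cfg_d)
        rng = np.random.default_rng(cfg.seed)
        net = _UNet(cfg, N_RISK_CLASSES, rng)
        for li, lay in enumerate(net.layers()):
            for pi, (p, _) in enumerate(lay.params()):
                p[...] = data[f"param_{li}_{pi}"]
    return SegmenterState(net=net, config=cfg,
                          norm_mean=meta["norm_mean"],
                          norm_std=meta["norm_std"],
                          class_weights=np.asarray(meta["class_weights"]),
                          history=meta["history"],
                          best_epoch=meta["best_epoch"])


# ---------------------------------------------------------- baseline model

class PatchLogisticSegmenter:
    """Multinomial logistic regression on per-pixel neighbourhood features.

    Features: normalised log-signal, 3x3 and 9x9 box means, 9x9 box standard
    deviation, and the normalised posteroanterior coordinate. Convex and fast;
    intended for deterministic end-to-end tests of the calibration and
    evaluation stages rather than for segmentation quality.
    """

    def __init__(self, pixels_per_image: int = 4000, seed: int = 0,
                 C: float = 1.0):
        self.pixels_per_image = pixels_per_image
        self.seed = seed
        self.C = C
        self._model = None
        self._norm = None

    def _features(self, image: np.ndarray) -> np.ndarray:
        from scipy import ndimage
        x = np.log1p(np.maximum(np.asarray(image, dtype=np.float64), 0.0))
        mean, std = self._norm
        x = (x - mean) / std
        m3 = ndimage.uniform_filter(x, 3)
        m9 = ndimage.uniform_filter(x, 9)
        s9 = np.sqrt(np.maximum(
            ndimage.uniform_filter(x * x, 9) - m9 * m9, 0.0))
        rr = np.broadcast_to(
            np.linspace(0, 1, x.shape[0])[:, None], x.shape)
        return np.stack([x, m3, m9, s9, rr], axis=-1)

    def fit(self, train_pairs, val_pairs=None):
        from sklearn.linear_model import LogisticRegression
        logs = np.concatenate([np.log1p(np.maximum(p.image, 0.0)).ravel()
                               for p in train_pairs])
        self._norm = (float(logs.mean()), float(logs.std() + 1e-9))
        rng = np.random.default_rng(self.seed)
        feats, labs = [], []
        for p in train_pairs:
            f = self._features(p.image).reshape(-1, 5)
            y = p.target.ravel()
            take = min(self.pixels_per_image, y.size)
            idx = rng.choice(y.size, size=take, replace=False)
            # make sure rare classes are represented
            for c in range(N_RISK_CLASSES):
                cls = np.flatnonzero(y == c)
                if cls.size:
                    idx = np.concatenate(
                        [idx, rng.choice(cls, min(cls.size, 200),
                                         replace=False)])
            feats.append(f[idx])
            labs.append(y[idx])
        X = np.concatenate(feats)
        Y = np.concatenate(labs)
        self._model = LogisticRegression(
            max_iter=400, C=self.C).fit(X, Y)
        return self

    def predict_probabilities(self, image) -> ProbabilityMap:
        f = self._features(image).reshape(-1, 5)
        p = self._model.predict_proba(f)
        full = np.full((f.shape[0], N_RISK_CLASSES), _EPS)
        full[:, self._model.classes_.astype(int)] = p
        full /= full.sum(axis=1, keepdims=True)
        return ProbabilityMap(
            probs=full.reshape(*np.asarray(image).shape, N_RISK_CLASSES),
            calibrated=False)
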