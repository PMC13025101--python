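"""The peak-probability network: gated 1D convolutions over cross-objectives.

The network maps a "cross-objective" — one centered 64-point 1D section per
spectral dimension through a probed grid point — to the probability that
the probed point is a peak maximum.  Each section is digested by its own
stack of gated convolutions (kernel 2, stride 2, no padding, 10 channels;
each layer computes tanh(conv_a(x)) * sigmoid(conv_b(x))), halving the
length 64 -> 32 -> 16 -> 8 -> 4 -> 2, so every branch emits 2 x 10 = 20
features.  The concatenated features feed a gated dense head with hidden
sizes 20 and 10 and a single sigmoid output unit.  For three dimensions
this is about 8000 trainable parameters.

Training minimizes binary cross-entropy with Adam.  Everything is plain
numpy (float32, BLAS matmuls): the model is small enough that CPU
mini-batches of 2**16 samples run in seconds, and bit-level reproducibility
under a fixed seed comes for free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra import Spectrum

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "MRAiModel",
    "build_model",
    "count_parameters",
    "extract_cross",
    "extract_crosses",
    "resample_training_points",
    "train",
    "predict_map",
    "save_model",
    "load_model",
]


def _sigmoid(x):
    # logistic via tanh: same SIMD-vectorized code path as the tanh gate
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class ModelSpec:
    n_dims: int
    cross_length: int = 64
    channels: int = 10
    hidden: tuple[int, ...] = (20, 10)

    def __post_init__(self):
        if self.n_dims not in (2, 3):
            raise ValueError("n_dims must be 2 or 3")
        L = self.cross_length
        if L < 2 or L & (L - 1):
            raise ValueError("cross_length must be a power of two")

    @property
    def n_layers(self) -> int:
        # forced by the stride-2 kernel-2 unpadded convolutions: the input
        # halves per layer until 2 positions remain
        return int(np.log2(self.cross_length)) - 1

    @property
    def branch_features(self) -> int:
        return 2 * self.channels


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    #: "none" keeps the rate constant; "cosine" anneals it to ~0 over
    #: max_epochs, which buys a sizable late-training improvement when the
    #: epoch budget is tight
    lr_schedule: str = "none"
    batch_size: int = 2 ** 16
    max_epochs: int = 2 ** 10
    patience: int = 32
    class_ratio: float = 0.01
    #: when set, predictions are recalibrated to this deployment
    #: positive:negative ratio by a constant logit offset (exact for a
    #: uniformly undersampled majority class)
    recalibrate_to_ratio: float | None = None
    val_fraction: float = 0.2  # 4:1 train/validation split
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if not (0 < self.class_ratio <= 1):
            raise ValueError("class ratio must lie in (0, 1]")


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form trainable-parameter count of the architecture."""
    c = spec.channels
    per_branch = 2 * (2 * 1 * c + c)  # first gated layer, 1 input channel
    per_branch += (spec.n_layers - 1) * 2 * (2 * c * c + c)
    total = spec.n_dims * per_branch
    n_in = spec.n_dims * spec.branch_features
    for h in spec.hidden:
        total += 2 * (n_in * h + h)
        n_in = h
    total += n_in + 1  # final sigmoid unit
    return total


# ---------------------------------------------------------------------------
# layers


class _GatedConv:
    """Gated 1D convolution, kernel 2, stride 2, no padding."""

    def __init__(self, c_in, c_out, rng):
        lim_w = np.sqrt(6.0 / (2 * c_in + c_out))
        self.Wt = rng.uniform(-lim_w, lim_w, size=(2, c_in, c_out)).astype(np.float32)
        self.Ws = rng.uniform(-lim_w, lim_w, size=(2, c_in, c_out)).astype(np.float32)
        self.bt = np.zeros(c_out, dtype=np.float32)
        self.bs = np.zeros(c_out, dtype=np.float32)

    def params(self):
        return [self.Wt, self.bt, self.Ws, self.bs]

    def forward(self, x, cache=None):
        # the two gate convolutions run as one GEMM; the logistic gate is
        # evaluated through the same tanh pass as the tanh gate
        B, C, L = x.shape
        I = L // 2
        p = x.reshape(B, C, I, 2).transpose(0, 2, 3, 1).reshape(B * I, 2 * C)
        O = self.Wt.shape[2]
        W = np.concatenate([self.Wt.reshape(2 * C, O),
                            0.5 * self.Ws.reshape(2 * C, O)], axis=1)
        a = p @ W
        a[:, :O] += self.bt
        a[:, O:] += 0.5 * self.bs
        np.tanh(a, out=a)
        T = a[:, :O]
        S = 0.5 * (a[:, O:] + 1.0)
        h = (T * S).reshape(B, I, O).transpose(0, 2, 1)
        if cache is not None:
            cache.append((p, T, S, (B, C, I, O)))
        return h

    def backward(self, dh, cache, grads):
        p, T, S, (B, C, I, O) = cache
        d = dh.transpose(0, 2, 1).reshape(B * I, O)
        dS = d * S
        da = np.empty((B * I, 2 * O), dtype=np.float32)
        np.multiply(dS, 1.0 - T * T, out=da[:, :O])          # d at
        np.multiply(dS * T, 1.0 - S, out=da[:, O:])          # d as
        dW = p.T @ da
        db = da.sum(axis=0)
        grads.append(db[O:])
        grads.append(dW[:, O:].reshape(2, C, O))
        grads.append(db[:O])
        grads.append(dW[:, :O].reshape(2, C, O))
        Wcat = np.concatenate([self.Wt.reshape(2 * C, O),
                               self.Ws.reshape(2 * C, O)], axis=1)
        dp = da @ Wcat.T
        dx = dp.reshape(B, I, 2, C).transpose(0, 3, 1, 2).reshape(B, C, 2 * I)
        return dx


class _GatedDense:
    def __init__(self, n_in, n_out, rng):
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.Wt = rng.uniform(-lim, lim, size=(n_in, n_out)).astype(np.float32)
        self.Ws = rng.uniform(-lim, lim, size=(n_in, n_out)).astype(np.float32)
        self.bt = np.zeros(n_out, dtype=np.float32)
        self.bs = np.zeros(n_out, dtype=np.float32)

    def params(self):
        return [self.Wt, self.bt, self.Ws, self.bs]

    def forward(self, x, cache=None):
        T = np.tanh(x @ self.Wt + self.bt)
        S = _sigmoid(x @ self.Ws + self.bs)
        if cache is not None:
            cache.append((x, T, S))
        return T * S

    def backward(self, dh, cache, grads):
        x, T, S = cache
        dat = dh * S * (1.0 - T * T)
        das = dh * T * S * (1.0 - S)
        grads.append(das.sum(axis=0))
        grads.append(x.T @ das)
        grads.append(dat.sum(axis=0))
        grads.append(x.T @ dat)
        return dat @ self.Wt.T + das @ self.Ws.T


class _Output:
    def __init__(self, n_in, rng):
        lim = np.sqrt(6.0 / (n_in + 1))
        self.w = rng.uniform(-lim, lim, size=(n_in,)).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, cache=None):
        if cache is not None:
            cache.append(x)
        return x @ self.w + self.b[0]

    def backward(self, dz, cache, grads):
        x = cache
        grads.append(np.array([dz.sum()], dtype=np.float32))
        grads.append(x.T @ dz)
        return np.outer(dz, self.w)


# ---------------------------------------------------------------------------
# model


class MRAiModel:
    """Gated convolutional peak-probability network (see module docstring)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c = spec.channels
        self.branches = []
        for _ in range(spec.n_dims):
            layers = [_GatedConv(1, c, rng)]
            layers += [_GatedConv(c, c, rng) for _ in range(spec.n_layers - 1)]
            self.branches.append(layers)
        n_in = spec.n_dims * spec.branch_features
        self.head = []
        for h in spec.hidden:
            self.head.append(_GatedDense(n_in, h, rng))
            n_in = h
        self.out = _Output(n_in, rng)
        #: constant logit offset recalibrating predictions to the
        #: deployment base rate when training used an enriched class mix
        self.logit_offset: float = 0.0
        self.train_meta: dict = {}

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self):
        ps = []
        for layers in self.branches:
            for l in layers:
                ps += l.params()
        for l in self.head:
            ps += l.params()
        ps += self.out.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def set_parameters(self, values):
        for p, v in zip(self.parameters(), values):
            p[...] = np.asarray(v, dtype=np.float32).reshape(p.shape)

    # -- forward / backward ----------------------------------------------
    def logits(self, x, caches=None):
        """x: (B, n_dims, L) float32 -> (B,) pre-sigmoid scores."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        B = x.shape[0]
        feats = []
        for b, layers in enumerate(self.branches):
            h = x[:, b, :][:, None, :]
            for l in layers:
                h = l.forward(h, caches)
            feats.append(h.reshape(B, -1))
        z = np.concatenate(feats, axis=1)
        for l in self.head:
            z = l.forward(z, caches)
        return self.out.forward(z, caches)

    def predict(self, x, batch: int = 1 << 16):
        """Peak-maximum probabilities, (B,) in (0, 1)."""
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for i in range(0, len(x), batch):
            z = self.logits(x[i:i + batch]) + np.float32(self.logit_offset)
            outs.append(_sigmoid(z))
        return np.concatenate(outs) if outs else np.zeros(0, dtype=np.float32)

    def loss_and_grads(self, x, y):
        """Mean BCE (computed on logits for stability) and parameter grads."""
        caches: list = []
        z = self.logits(x, caches)
        y = np.asarray(y, dtype=np.float32)
        # log(1+e^-|z|) + max(z,0) - z*y
        loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * y))
        p = _sigmoid(z)
        dz = (p - y).astype(np.float32) / len(y)

        grads_rev: list = []
        dz_head = self.out.backward(dz, caches.pop(), grads_rev)
        for l in reversed(self.head):
            dz_head = l.backward(dz_head, caches.pop(), grads_rev)
        F = self.spec.branch_features
        for b in reversed(range(self.spec.n_dims)):
            dfeat = dz_head[:, b * F:(b + 1) * F]
            B = dfeat.shape[0]
            dh = dfeat.reshape(B, self.spec.channels, 2)
            for l in reversed(self.branches[b]):
                dh = l.backward(dh, caches.pop(), grads_rev)
        grads = list(reversed(grads_rev))
        return loss, grads

    def bce(self, x, y, batch: int = 1 << 16):
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        tot, n = 0.0, 0
        for i in range(0, len(x), batch):
            z = self.logits(x[i:i + batch])
            yi = y[i:i + batch]
            tot += float(np.sum(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * yi))
            n += len(yi)
        return tot / max(n, 1)


def build_model(spec: ModelSpec, seed: int = 0) -> MRAiModel:
    return MRAiModel(spec, seed)


# ---------------------------------------------------------------------------
# cross-objective extraction


def _scaled_data(spectrum: Spectrum, sigma: float | None) -> np.ndarray:
    if sigma is None:
        sigma = spectrum.sigma_noise
    if sigma is None:
        from .noise import robust_sigma
        sigma = robust_sigma(spectrum.data)
    if sigma <= 0:
        raise ValueError("spectrum noise sigma must be positive")
    data = np.asarray(spectrum.data, dtype=np.float32)
    # center at the median: skyline projections carry a positive baseline
    # (max over noise) while the training noise is mean-zero
    scaled = (data - np.float32(np.median(data))) / np.float32(sigma)
    # signed-log compression: intensities span a 1:200 dynamic range in
    # sigma-units, which would pin the tanh/sigmoid gates of the first
    # layer; arcsinh is linear around the noise level and logarithmic for
    # strong peaks, so amplitude information survives in a trainable range
    return np.arcsinh(scaled)


def extract_crosses(spectrum: Spectrum, indices: np.ndarray,
                    length: int = 64, sigma: float | None = None) -> np.ndarray:
    """Cross-objectives for many probed points at once.

    indices : (M, n) integer grid indices
    returns (M, n, length) float32; the probed point sits at position
    length//2 of every section; off-grid positions are zero-filled, which
    after sigma scaling is the baseline value of a noise-free region.
    """
    data = _scaled_data(spectrum, sigma)
    n = data.ndim
    idx = np.atleast_2d(np.asarray(indices, dtype=np.intp))
    if idx.shape[1] != n:
        raise ValueError("index rank does not match spectrum dimensionality")
    half = length // 2
    offs = np.arange(-half, length - half)
    out = np.empty((idx.shape[0], n, length), dtype=np.float32)
    for d in range(n):
        pad_width = [(0, 0)] * n
        pad_width[d] = (half, length - half)
        padded = np.pad(data, pad_width)
        gather = [idx[:, k][:, None] for k in range(n)]
        gather[d] = idx[:, d][:, None] + offs[None, :] + half
        out[:, d, :] = padded[tuple(gather)]
    return out


def extract_cross(spectrum: Spectrum, index, length: int = 64,
                  sigma: float | None = None) -> np.ndarray:
    """Single cross-objective, shape (n_dims, length)."""
    index = tuple(int(i) for i in np.atleast_1d(index))
    if any(not (0 <= i < s) for i, s in zip(index, spectrum.data.shape)):
        raise ValueError("probed index outside the grid")
    return extract_crosses(spectrum, np.array([index]), length, sigma)[0]


# ---------------------------------------------------------------------------
# resampling


def resample_training_points(mask: np.ndarray, ratio: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Class-rebalanced training indices: all positives, subsampled negatives.

    ``ratio`` is the target positive:negative ratio (0.01 means 1:100).
    When fewer negatives exist than the ratio asks for, all are kept; no
    oversampling.  Returns (M, n) integer indices, shuffled.
    """
    mask = np.asarray(mask)
    pos = np.argwhere(mask == 1)
    if len(pos) == 0:
        raise ValueError("mask contains no positive points")
    neg = np.argwhere(mask == 0)
    n_neg = min(len(neg), int(round(len(pos) / ratio)))
    keep = rng.choice(len(neg), size=n_neg, replace=False)
    out = np.concatenate([pos, neg[keep]], axis=0)
    rng.shuffle(out, axis=0)
    return out


# ---------------------------------------------------------------------------
# training


def train(model: MRAiModel, X: np.ndarray, y: np.ndarray,
          config: TrainConfig, X_val=None, y_val=None, verbose: bool = False):
    """Adam/BCE training with early stopping on validation BCE.

    Without an explicit validation set the data is split 4:1.  Returns the
    model (best-validation weights restored) and a history dict.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    if X_val is None:
        perm = rng.permutation(len(X))
        n_val = max(1, int(round(config.val_fraction * len(X))))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]

    # start the output unit at the base-rate logit so the early epochs are
    # spent learning peak shapes rather than the class prior
    pi = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    model.out.b[0] = np.float32(np.log(pi / (1 - pi)))

    params = model.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best = (np.inf, None)
    history = {"train_bce": [], "val_bce": []}
    since_best = 0
    for epoch in range(config.max_epochs):
        if config.lr_schedule == "cosine":
            lr_epoch = config.learning_rate * 0.5 * (
                1 + np.cos(np.pi * epoch / config.max_epochs))
        else:
            lr_epoch = config.learning_rate
        perm = rng.permutation(len(X))
        ep_loss, n_batches = 0.0, 0
        for i in range(0, len(X), config.batch_size):
            sel = perm[i:i + config.batch_size]
            loss, grads = model.loss_and_grads(X[sel], y[sel])
            step += 1
            lr_t = lr_epoch * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
            for j, (p, g) in enumerate(zip(params, grads)):
                g = np.asarray(g, dtype=np.float32).reshape(p.shape)
                m[j] = b1 * m[j] + (1 - b1) * g
                v[j] = b2 * v[j] + (1 - b2) * g * g
                p -= lr_t * m[j] / (np.sqrt(v[j]) + eps)
            ep_loss += loss
            n_batches += 1
        val = model.bce(X_val, y_val)
        history["train_bce"].append(ep_loss / max(n_batches, 1))
        history["val_bce"].append(val)
        if verbose and (epoch % 10 == 0 or epoch == config.max_epochs - 1):
            print(f"epoch {epoch:4d} train {history['train_bce'][-1]:.5f} val {val:.5f}")
        if val < best[0] - 1e-7:
            best = (val, [p.copy() for p in params])
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best[1] is not None:
        model.set_parameters(best[1])
    if config.recalibrate_to_ratio is not None:
        train_odds = pi / (1 - pi)
        model.logit_offset = float(np.log(config.recalibrate_to_ratio)
                                   - np.log(train_odds))
    model.train_meta = {"epochs_run": len(history["val_bce"]),
                        "best_val_bce": best[0],
                        "config": asdict(config)}
    return model, history


# ---------------------------------------------------------------------------
# map prediction


def predict_map(model: MRAiModel, spectrum: Spectrum, roi_mask=None,
                batch: int = 1 << 16, sigma: float | None = None) -> np.ndarray:
    """Peak-maximum probability for every grid point (or ROI points only).

    Points outside the ROI get probability exactly 0.
    """
    if spectrum.n_dims != model.spec.n_dims:
        raise ValueError("spectrum dimensionality does not match the model")
    shape = spectrum.data.shape
    out = np.zeros(shape, dtype=np.float32)
    if roi_mask is not None:
        roi = np.asarray(roi_mask, dtype=bool)
        if roi.shape != shape:
            raise ValueError("ROI shape mismatch")
        idx = np.argwhere(roi)
        if len(idx) == 0:
            return out
    else:
        idx = np.stack(np.unravel_index(np.arange(int(np.prod(shape))), shape), axis=1)
    L = model.spec.cross_length
    for i in range(0, len(idx), batch):
        chunk = idx[i:i + batch]
        x = extract_crosses(spectrum, chunk, L, sigma)
        out[tuple(chunk.T)] = model.predict(x, batch=batch)
    return out


# ---------------------------------------------------------------------------
# persistence


def save_model(model: MRAiModel, path) -> None:
    """JSON checkpoint: ModelSpec + flat parameter list (framework-free)."""
    payload = {
        "spec": asdict(model.spec),
        "seed": model.seed,
        "logit_offset": model.logit_offset,
        "train_meta": model.train_meta,
        "params": [p.astype(float).ravel().tolist() for p in model.parameters()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> MRAiModel:
    with open(path) as fh:
        payload = json.load(fh)
    spec_d = payload["spec"]
    spec_d["hidden"] = tuple(spec_d["hidden"])
    spec = ModelSpec(**spec_d)
    model = MRAiModel(spec, payload.get("seed", 0))
    model.set_parameters(payload["params"])
    model.logit_offset = float(payload.get("logit_offset", 0.0))
    model.train_meta = payload.get("train_meta", {})
    return model
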