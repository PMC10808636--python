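"""The deep-learning arm: a 2-D CNN separating NOISE from non-noise ICs.

Architecture (tuned defaults): three 3 x 3 convolution layers with 64, 64
and 256 filters, each followed by 2 x 2 max pooling; a 704-unit dense ReLU
layer with dropout 0.33; a sigmoid output.  Trained with binary
cross-entropy and Adam at learning rate 1e-4, with early stopping on
validation loss.  Input montages are resized to 270 x 470 x 3 and scaled to
[0, 1].

The network is implemented directly on numpy (im2col convolution, explicit
backward passes, Adam); everything is driven by a single seeded generator,
so training is bit-reproducible.  A ``small`` configuration (downscaled
input, fewer filters) exists for fast experiments; the defaults remain the
tuned values above.

A secondary 3-class mode (softmax over NOISE/RSN/SOZ with cost-sensitive
class weights) provides the CNN-only baseline that the hybrid method is
compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BINARY_LABELS = ("NOISE", "NON_NOISE")  # non-noise (RSN or SOZ) is encoded as 1


@dataclass
class CnnConfig:
    conv_filters: tuple[int, ...] = (64, 64, 256)
    kernel: int = 3
    pool: int = 2
    dense_units: int = 704
    learning_rate: float = 1e-4
    dropout: float = 0.33
    input_size: tuple[int, int] = (270, 470)
    channels: int = 3
    n_classes: int = 1  # 1 = binary sigmoid head, >1 = softmax head
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dropout < 1.0):
            raise ValueError("dropout must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if len(self.conv_filters) < 1:
            raise ValueError("need at least one convolution layer")

    @classmethod
    def small(cls, **overrides) -> "CnnConfig":
        """Downscaled configuration for fast runs: 54 x 94 input, fewer
        filters, larger learning rate, shorter schedule."""
        kw = dict(
            conv_filters=(8, 16, 32),
            dense_units=64,
            learning_rate=1e-3,
            input_size=(54, 94),
            max_epochs=10,
            patience=3,
        )
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv2D:
    def __init__(self, filters: int, kernel: int):
        self.filters, self.kernel = filters, kernel
        self.W = self.b = None
        self._cache = None

    def out_shape(self, shape):
        h, w, _ = shape
        k = self.kernel
        return (h - k + 1, w - k + 1, self.filters)

    def init(self, shape, rng):
        h, w, c = shape
        k = self.kernel
        fan_in = k * k * c
        self.W = (
            rng.standard_normal((fan_in, self.filters)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.b = np.zeros(self.filters, dtype=np.float32)

    def forward(self, x, train, rng):
        k = self.kernel
        n, h, w, c = x.shape
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (n, h', w', c, k, k)
        patches = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            -1, k * k * c
        )
        y = patches @ self.W + self.b
        if train:
            self._cache = (patches, x.shape)
        return y.reshape(n, h - k + 1, w - k + 1, self.filters)

    def backward(self, dy):
        patches, x_shape = self._cache
        k = self.kernel
        n, h, w, c = x_shape
        dy_flat = dy.reshape(-1, self.filters)
        self.dW = patches.T @ dy_flat
        self.db = dy_flat.sum(axis=0)
        dpatch = (dy_flat @ self.W.T).reshape(n, h - k + 1, w - k + 1, k, k, c)
        dx = np.zeros(x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + h - k + 1, j : j + w - k + 1, :] += dpatch[:, :, :, i, j, :]
        self._cache = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _MaxPool2:
    def out_shape(self, shape):
        h, w, c = shape
        return (h // 2, w // 2, c)

    def init(self, shape, rng):
        pass

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = (
            x[:, : 2 * h2, : 2 * w2, :]
            .reshape(n, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h2, w2, c, 4)
        )
        idx = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dy):
        idx, x_shape = self._cache
        n, h, w, c = x_shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dxr.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, 2 * h2, 2 * w2, c)
        )
        self._cache = None
        return dx

    def params(self):
        return []


class _ReLU:
    def out_shape(self, shape):
        return shape

    def init(self, shape, rng):
        pass

    def forward(self, x, train, rng):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _Flatten:
    def out_shape(self, shape):
        return (int(np.prod(shape)),)

    def init(self, shape, rng):
        pass

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, units: int):
        self.units = units
        self.W = self.b = None

    def out_shape(self, shape):
        return (self.units,)

    def init(self, shape, rng):
        fan_in = shape[0]
        self.W = (
            rng.standard_normal((fan_in, self.units)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.b = np.zeros(self.units, dtype=np.float32)

    def forward(self, x, train, rng):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def out_shape(self, shape):
        return shape

    def init(self, shape, rng):
        pass

    def forward(self, x, train, rng):
        if not train:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class NoiseCnn:
    """Conv-pool stack -> dense -> dropout -> sigmoid/softmax head.

    Weight allocation is deferred to :meth:`build` so the architecture can
    be introspected cheaply even at the full 270 x 470 input size.
    """

    def __init__(self, config: CnnConfig):
        self.config = config
        self.layers: list = []
        for f in config.conv_filters:
            self.layers += [_Conv2D(f, config.kernel), _ReLU(), _MaxPool2()]
        self.layers += [
            _Flatten(),
            _Dense(config.dense_units),
            _ReLU(),
            _Dropout(config.dropout),
            _Dense(config.n_classes if config.n_classes > 1 else 1),
        ]
        self.built = False
        self._rng = None
        # input standardization state (mean image + global std), fitted on
        # the training set; raw inputs stay on the [0, 1] scale at the API
        self.input_mean: np.ndarray | None = None
        self.input_std: float = 1.0

    # -- introspection ------------------------------------------------------
    @property
    def conv_filters(self) -> tuple[int, ...]:
        return tuple(l.filters for l in self.layers if isinstance(l, _Conv2D))

    @property
    def dense_units(self) -> int:
        return next(l.units for l in self.layers if isinstance(l, _Dense))

    def layer_summary(self) -> list[str]:
        out = []
        k = self.config.kernel
        for l in self.layers:
            if isinstance(l, _Conv2D):
                out.append(f"conv {k}x{k}x{l.filters}")
            elif isinstance(l, _MaxPool2):
                out.append("maxpool 2x2")
            elif isinstance(l, _ReLU):
                out.append("relu")
            elif isinstance(l, _Flatten):
                out.append("flatten")
            elif isinstance(l, _Dense):
                out.append(f"dense {l.units}")
            elif isinstance(l, _Dropout):
                out.append(f"dropout {l.rate}")
        return out

    # -- lifecycle ----------------------------------------------------------
    def build(self, rng: np.random.Generator) -> None:
        shape = (*self.config.input_size, self.config.channels)
        for l in self.layers:
            if any(d <= 0 for d in np.atleast_1d(shape)):
                raise ValueError("input too small for the configured conv/pool chain")
            l.init(shape, rng)
            shape = l.out_shape(shape)
        self.built = True

    def forward(self, x, train=False, rng=None):
        for l in self.layers:
            x = l.forward(x, train, rng if rng is not None else self._rng)
        return x

    def backward(self, dz):
        for l in reversed(self.layers):
            dz = l.backward(dz)

    def parameters(self):
        for l in self.layers:
            for name, owner in l.params():
                yield name, owner

    def get_weights(self):
        return [getattr(owner, name).copy() for name, owner in self.parameters()]

    def set_weights(self, weights):
        for (name, owner), w in zip(self.parameters(), weights):
            setattr(owner, name, w.copy())

    def prep(self, x: np.ndarray) -> np.ndarray:
        """Standardize a [0, 1] input batch with the fitted statistics."""
        x = np.asarray(x, dtype=np.float32)
        if self.input_mean is None:
            return x
        return (x - self.input_mean) / self.input_std

    def predict_logits(self, X, batch_size=64):
        outs = []
        X = self.prep(X)
        for k in range(0, len(X), batch_size):
            outs.append(self.forward(X[k : k + batch_size]))
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X, batch_size=64):
        z = self.predict_logits(X, batch_size)
        if self.config.n_classes <= 1:
            return _sigmoid(z[:, 0])
        return _softmax(z)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, model: NoiseCnn, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(getattr(o, n)) for n, o in model.parameters()]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in model.parameters()]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, owner) in enumerate(self.model.parameters()):
            g = getattr(owner, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p = getattr(owner, name)
            setattr(owner, name, (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def relabel_for_noise(labels: list[str]) -> list[str]:
    """Collapse 3-class labels to the binary noise task: NOISE is kept, RSN
    and SOZ both become the complement class NON_NOISE."""
    out = []
    for lab in labels:
        if lab == "NOISE":
            out.append("NOISE")
        elif lab in ("RSN", "SOZ"):
            out.append("NON_NOISE")
        else:
            raise ValueError(f"unknown label {lab!r}")
    return out


def build_model(config: CnnConfig | None = None) -> NoiseCnn:
    return NoiseCnn(config or CnnConfig())


def _loss_and_grad(model, xb, yb, class_weights=None):
    z = model.forward(model.prep(xb), train=True)
    n = len(xb)
    eps = 1e-7
    if model.config.n_classes <= 1:
        p = _sigmoid(z[:, 0])
        loss = float(-np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)))
        dz = ((p - yb) / n).astype(np.float32)[:, None]
    else:
        p = _softmax(z)
        w = np.ones(n) if class_weights is None else class_weights[yb]
        loss = float(np.sum(w * -np.log(p[np.arange(n), yb] + eps)) / w.sum())
        onehot = np.zeros_like(p)
        onehot[np.arange(n), yb] = 1.0
        dz = (w[:, None] * (p - onehot) / w.sum()).astype(np.float32)
    return loss, dz


def _eval_loss(model, X, y, class_weights=None, batch_size=64):
    eps = 1e-7
    p = model.predict_proba(X, batch_size)
    if model.config.n_classes <= 1:
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    w = np.ones(len(y)) if class_weights is None else class_weights[y]
    return float(np.sum(w * -np.log(p[np.arange(len(y)), y] + eps)) / w.sum())


def train(
    model: NoiseCnn,
    X: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray | None = None,
    verbose: bool = False,
) -> dict:
    """Fit the network and return the loss history.

    ``X`` is (n, H, W, 3) scaled to [0, 1]; ``y`` is 0/1 for the binary head
    or integer class indices for the softmax head (``class_weights`` enables
    cost-sensitive training).  Adam on (weighted) cross-entropy, validation
    split with early stopping on validation loss, best-epoch weights
    restored.  All randomness (initialization, shuffling, dropout,
    validation split) derives from ``config.seed``.
    """
    cfg = model.config
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    X = np.asarray(X, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)
    model._rng = rng
    if not model.built:
        model.build(rng)
    # dark, largely constant anatomy dominates the raw images; centering on
    # the mean training image makes the activation geometry the signal
    model.input_mean = X.mean(axis=0)
    model.input_std = float(X.std()) or 1.0

    n = len(X)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = _Adam(model, cfg.learning_rate)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    best_loss, best_weights, bad = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for k in range(0, len(Xtr), cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            loss, dz = _loss_and_grad(model, Xtr[idx], ytr[idx], class_weights)
            model.backward(dz)
            opt.step()
            losses.append(loss)
        val_loss = _eval_loss(model, Xval, yval, class_weights)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {np.mean(losses):.4f} val {val_loss:.4f}")
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, bad = val_loss, model.get_weights(), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    model._rng = None
    return history


def save_model(model: NoiseCnn, path) -> None:
    """Checkpoint: config (JSON), weights and input statistics in one npz."""
    import json
    from dataclasses import asdict

    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(
        path,
        config=json.dumps(asdict(model.config)),
        input_std=np.float64(model.input_std),
        input_mean=(
            model.input_mean if model.input_mean is not None else np.zeros(0)
        ),
        **arrays,
    )


def load_model(path) -> NoiseCnn:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        for key in ("conv_filters", "input_size"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = NoiseCnn(CnnConfig(**cfg_dict))
        model.build(np.random.default_rng(0))
        weights = [data[f"w{i}"] for i in range(sum(1 for _ in model.parameters()))]
        model.set_weights(weights)
        mean = data["input_mean"]
        model.input_mean = mean if mean.size else None
        model.input_std = float(data["input_std"])
    return model


def predict_noise(
    model: NoiseCnn, x: np.ndarray, threshold: float = 0.5
) -> tuple[float, str]:
    """Non-noise probability and thresholded label for one prepared input;
    p >= threshold (ties included) is NON_NOISE."""
    x = np.asarray(x, dtype=np.float32)
    if x.shape != (*model.config.input_size, model.config.channels):
        raise ValueError(
            f"input shape {x.shape} does not match configured "
            f"{(*model.config.input_size, model.config.channels)}"
        )
    p = float(model.predict_proba(x[None])[0])
    return p, ("NON_NOISE" if p >= threshold else "NOISE")
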