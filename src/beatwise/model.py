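"""A 1D convolutional network for beat-wise ECG classification.

The classifier is a stack of convolutional blocks — 1D convolution (stride
1, length-preserving padding), batch normalisation, ReLU, max pooling —
followed by global average pooling, one fully connected layer and a softmax
over the two diagnostic categories (preserved vs reduced ejection
fraction).  The default configuration has 9 convolutional blocks plus the
fully connected layer, i.e. 10 weighted layers.  The same block stack
serves 3 s strips (12 x 1500), single beats (12 x 375), two-beat tensors
(24 x 375) and reduced-lead tensors (1-12 x 375): only the input channel
count changes.

Forward and backward passes are implemented directly in numpy (im2col
convolutions); optimisation is Adam on a class-weighted cross-entropy that
supports the soft labels produced by MixUp augmentation.  The estimator
front-end, :class:`Conv1dNetClassifier`, follows scikit-learn conventions
(``fit``/``predict_proba``/``get_params``) and selects the epoch checkpoint
with the best development-set AUC when a development set is supplied.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

_EPS = 1e-12


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the block CNN.

    ``fc_width`` = 0 connects the pooled features directly to the class
    logits (the default, giving n_blocks + 1 weighted layers); a positive
    value inserts one hidden fully connected layer of that width.
    """

    in_channels: int = 12
    input_len: int = 375
    n_blocks: int = 9
    filters: list[int] = field(
        default_factory=lambda: [16, 16, 32, 32, 64, 64, 64, 64, 64])
    kernels: list[int] = field(
        default_factory=lambda: [7, 5, 5, 3, 3, 3, 3, 3, 3])
    pools: list[int] = field(
        default_factory=lambda: [2, 2, 2, 2, 2, 2, 1, 1, 1])
    fc_width: int = 0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.in_channels <= 24:
            raise ValueError(f"in_channels must be 1-24, got {self.in_channels}")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        for name, lst in (("filters", self.filters), ("kernels", self.kernels),
                          ("pools", self.pools)):
            if len(lst) != self.n_blocks:
                raise ValueError(
                    f"{name} must list one value per block "
                    f"({self.n_blocks}), got {len(lst)}")
        length = self.input_len
        for i, p in enumerate(self.pools):
            length = length // p
            if length < 1:
                raise ValueError(
                    f"temporal length collapses to zero after block {i}")

    @property
    def n_weighted_layers(self) -> int:
        return self.n_blocks + (1 if self.fc_width > 0 else 0) + 1


class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Conv1d:
    """Stride-1, length-preserving 1D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.k = k
        self.c_in = c_in
        self.W = _Param(rng.normal(0.0, scale, (c_out, c_in * k)
                                   ).astype(np.float32))
        self.b = _Param(np.zeros(c_out, dtype=np.float32))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        pl = self.k // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(n, length, c * self.k)
        self._cols = cols if train else None
        self._in_shape = (n, c, length)
        out = cols @ self.W.value.T + self.b.value
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        d = dout.transpose(0, 2, 1)  # (n, L, F)
        cols = self._cols
        self.W.grad = np.tensordot(d, cols, axes=([0, 1], [0, 1])
                                   ).astype(np.float32)
        self.b.grad = d.sum(axis=(0, 1)).astype(np.float32)
        dcols = (d @ self.W.value).reshape(n, length, c, self.k)
        pl = self.k // 2
        pr = self.k - 1 - pl
        dxp = np.zeros((n, c, length + pl + pr), dtype=np.float32)
        for j in range(self.k):
            dxp[:, :, j:j + length] += dcols[:, :, :, j].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, pl:pl + length]


class _BatchNorm1d:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = _Param(np.ones(channels, dtype=np.float32))
        self.beta = _Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        if train:
            self._xhat = xhat
            self._inv = inv
        return self.gamma.value[None, :, None] * xhat \
            + self.beta.value[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dout.shape[0] * dout.shape[2]
        dgamma = (dout * xhat).sum(axis=(0, 2))
        dbeta = dout.sum(axis=(0, 2))
        self.gamma.grad = dgamma.astype(np.float32)
        self.beta.grad = dbeta.astype(np.float32)
        g = self.gamma.value * inv
        dx = g[None, :, None] * (
            dout - dbeta[None, :, None] / m - xhat * dgamma[None, :, None] / m)
        self._xhat = None
        return dx.astype(np.float32)


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool1d:
    """Non-overlapping max pooling; trailing samples beyond a full window
    are truncated."""

    params: list = []

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.size == 1:
            self._passthrough = True
            return x
        self._passthrough = False
        n, c, length = x.shape
        l_out = length // self.size
        xr = x[:, :, :l_out * self.size].reshape(n, c, l_out, self.size)
        out = xr.max(axis=3)
        if train:
            self._argmax = xr.argmax(axis=3)
            self._in_shape = (n, c, length)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._passthrough:
            return dout
        n, c, length = self._in_shape
        l_out = dout.shape[2]
        dx = np.zeros((n, c, l_out, self.size), dtype=np.float32)
        idx = self._argmax
        ni, ci, li = np.ogrid[:n, :c, :l_out]
        dx[ni, ci, li, idx] = dout
        dx = dx.reshape(n, c, l_out * self.size)
        if l_out * self.size < length:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, length - l_out * self.size)))
        return dx


class _GlobalAvgPool:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._length, axis=2) / self._length


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = _Param(rng.normal(0.0, scale, (d_out, d_in)).astype(np.float32))
        self.b = _Param(np.zeros(d_out, dtype=np.float32))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad = (dout.T @ self._x).astype(np.float32)
        self.b.grad = dout.sum(axis=0).astype(np.float32)
        self._x = None
        return dout @ self.W.value


class _ReLUFlat(_ReLU):
    pass


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """The assembled block CNN with manual forward/backward passes."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.layers = []
        c = config.in_channels
        for i in range(config.n_blocks):
            f = config.filters[i]
            self.layers.append(_Conv1d(c, f, config.kernels[i], rng))
            self.layers.append(_BatchNorm1d(f))
            self.layers.append(_ReLU())
            self.layers.append(_MaxPool1d(config.pools[i]))
            c = f
        self.layers.append(_GlobalAvgPool())
        if config.fc_width > 0:
            self.layers.append(_Dense(c, config.fc_width, rng))
            self.layers.append(_ReLUFlat())
            c = config.fc_width
        self.layers.append(_Dense(c, config.n_classes, rng))

    @property
    def params(self) -> list[_Param]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def n_weighted_layers(self) -> int:
        return sum(1 for layer in self.layers
                   if isinstance(layer, (_Conv1d, _Dense)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (batch, channels, length) input."""
        h = np.asarray(x, dtype=np.float32)
        if h.ndim != 3:
            raise ValueError(f"expected 3-D input, got shape {h.shape}")
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities (rows on the simplex), evaluation mode."""
        x = np.asarray(x, dtype=np.float32)
        out = [softmax(self.forward(x[i:i + batch_size], train=False))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.empty((0, self.config.n_classes))

    def state_dict(self) -> list:
        state = []
        for layer in self.layers:
            entry = [p.value.copy() for p in layer.params]
            if isinstance(layer, _BatchNorm1d):
                entry += [layer.running_mean.copy(), layer.running_var.copy()]
            state.append(entry)
        return state

    def load_state_dict(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for p, v in zip(layer.params, entry):
                p.value = v.copy()
            if isinstance(layer, _BatchNorm1d):
                layer.running_mean = entry[2].copy()
                layer.running_var = entry[3].copy()


def build_classifier(config: ModelConfig,
                     rng: np.random.Generator | int | None = 0) -> Network:
    """Instantiate the block CNN for a validated configuration."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Network(config, rng)


class Adam:
    def __init__(self, params: list[_Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# MixUp and the weighted loss
# ---------------------------------------------------------------------------

def mixup(batch_x: np.ndarray, batch_y_onehot: np.ndarray, alpha: float,
          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """MixUp augmentation: convex combinations of a batch with a permuted
    copy of itself, using a single Beta(alpha, alpha) weight for the batch.

    A batch of one is returned unchanged.
    """
    if alpha <= 0:
        raise ValueError("mixup alpha must be positive")
    if len(batch_x) < 2:
        return batch_x, batch_y_onehot
    lam = float(rng.beta(alpha, alpha))
    perm = rng.permutation(len(batch_x))
    mixed_x = lam * batch_x + (1.0 - lam) * batch_x[perm]
    mixed_y = lam * batch_y_onehot + (1.0 - lam) * batch_y_onehot[perm]
    return mixed_x, mixed_y


def _as_soft_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros((len(labels), n_classes))
        onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
        return onehot
    return labels.astype(float)


def weighted_loss(probabilities: np.ndarray, labels: np.ndarray,
                  class_weights) -> float:
    """Class-weighted cross-entropy over predicted probabilities.

    Each sample's cross-entropy is multiplied by its class weight; soft
    (MixUp) labels weight linearly, i.e. the effective sample weight is the
    label-weighted mixture of the class weights.  Zero probabilities are
    clipped at machine epsilon.
    """
    p = np.asarray(probabilities, dtype=float)
    w = np.asarray(class_weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    y = _as_soft_labels(labels, p.shape[1])
    ce = -(y * np.log(np.clip(p, _EPS, 1.0))).sum(axis=1)
    sample_w = y @ w
    return float(np.mean(sample_w * ce))


def _loss_and_grad(logits: np.ndarray, y_soft: np.ndarray,
                   class_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted soft-label cross-entropy computed from logits, with the
    gradient w.r.t. the logits."""
    p = softmax(logits)
    ce = -(y_soft * np.log(np.clip(p, _EPS, 1.0))).sum(axis=1)
    sample_w = y_soft @ class_weights
    loss = float(np.mean(sample_w * ce))
    n = len(logits)
    dlogits = sample_w[:, None] * (p - y_soft) / n
    return loss, dlogits


# ---------------------------------------------------------------------------
# Estimator front-end
# ---------------------------------------------------------------------------

class Conv1dNetClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style front-end for the block CNN.

    Parameters mirror :class:`ModelConfig` plus the training loop: Adam
    learning rate, batch size, epoch budget, MixUp alpha (0 disables MixUp),
    and the per-class loss weights (default 1:2 for preserved vs reduced
    ejection fraction).  When a development set is passed to :meth:`fit`,
    the epoch checkpoint with the best development AUC is kept.

    Input ``X`` is a (n_samples, channels, length) array; channel count and
    length are taken from the data at fit time.
    """

    def __init__(self, n_blocks: int = 4,
                 filters=(8, 16, 16, 32),
                 kernels=(7, 5, 3, 3),
                 pools=(4, 2, 2, 2),
                 fc_width: int = 0,
                 lr: float = 1e-3,
                 batch_size: int = 64,
                 epochs: int = 10,
                 mixup_alpha: float = 0.2,
                 class_weight=(1.0, 2.0),
                 random_state: int = 0,
                 verbose: int = 0):
        self.n_blocks = n_blocks
        self.filters = filters
        self.kernels = kernels
        self.pools = pools
        self.fc_width = fc_width
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.mixup_alpha = mixup_alpha
        self.class_weight = class_weight
        self.random_state = random_state
        self.verbose = verbose

    def _validate_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_samples, channels, length), got shape {X.shape}")
        return X

    def fit(self, X, y, X_dev=None, y_dev=None, dev_case_ids=None):
        """Train with Adam on the weighted cross-entropy.

        If ``X_dev``/``y_dev`` are given, per-epoch development AUC is
        logged (aggregated to case level when ``dev_case_ids`` is given)
        and the best-AUC checkpoint is restored at the end.
        """
        from .train_eval import compute_auc  # local import, no cycle at load

        if self.epochs < 1:
            raise ValueError("epoch budget must be >= 1")
        X = self._validate_x(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected 2 classes, got {self.classes_}")
        y_idx = np.searchsorted(self.classes_, y)
        config = ModelConfig(
            in_channels=X.shape[1], input_len=X.shape[2],
            n_blocks=self.n_blocks, filters=list(self.filters),
            kernels=list(self.kernels), pools=list(self.pools),
            fc_width=self.fc_width)
        rng = np.random.default_rng(self.random_state)
        self.network_ = Network(config, rng)
        opt = Adam(self.network_.params, lr=self.lr)
        weights = np.asarray(self.class_weight, dtype=np.float32)
        if np.any(weights <= 0):
            raise ValueError("class weights must be positive")
        n = len(X)
        onehot = np.zeros((n, 2), dtype=np.float32)
        onehot[np.arange(n), y_idx] = 1.0

        self.history_ = []
        best_auc, best_state = -np.inf, None
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                bx, by = X[idx], onehot[idx]
                if self.mixup_alpha > 0 and len(idx) >= 2:
                    bx, by = mixup(bx, by, self.mixup_alpha, rng)
                logits = self.network_.forward(bx, train=True)
                loss, dlogits = _loss_and_grad(logits, by, weights)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}")
                self.network_.backward(dlogits)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            entry = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
            if X_dev is not None and y_dev is not None:
                scores = self.predict_proba(X_dev)[:, 1]
                labels = (np.asarray(y_dev) == self.classes_[1]).astype(int)
                if dev_case_ids is not None:
                    import pandas as pd
                    df = pd.DataFrame({"case": dev_case_ids, "score": scores,
                                       "label": labels})
                    agg = df.groupby("case").mean()
                    scores, labels = agg["score"].to_numpy(), \
                        (agg["label"].to_numpy() > 0.5).astype(int)
                auc = compute_auc(scores, labels)
                entry["dev_auc"] = auc
                if auc > best_auc:
                    best_auc = auc
                    best_state = self.network_.state_dict()
            self.history_.append(entry)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(
                    f"{k}={v:.4f}" for k, v in entry.items() if k != "epoch"))
        if best_state is not None:
            self.network_.load_state_dict(best_state)
            self.best_dev_auc_ = best_auc
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise ValueError("classifier is not fitted")
        return self.network_.predict_proba(self._validate_x(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
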