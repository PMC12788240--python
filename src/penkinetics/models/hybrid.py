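"""Hybrid 1D-CNN + bidirectional-LSTM classifier, implemented in NumPy.

No deep-learning framework is assumed: every layer carries its own forward
pass and analytic backward pass, trained with Adam on binary cross-entropy.
The architecture is fixed (two ReLU convolution blocks with max-pooling and
batch normalization, a concat-merge bidirectional LSTM emitting its final
state, a ReLU dense layer with dropout, and a sigmoid output):

======================  ============  =======================================
Layer                   Output shape  Configuration
======================  ============  =======================================
Input                   (1084, 18)    18 kinematic channels
Conv1D                  (1084, 64)    64 filters, kernel 7, stride 1, same pad
MaxPooling1D            (542, 64)     pool size 2
BatchNormalization      (542, 64)     momentum 0.99, epsilon 0.001
Conv1D                  (542, 128)    128 filters, kernel 5, stride 1, same pad
MaxPooling1D            (271, 128)    pool size 2
BatchNormalization      (271, 128)    momentum 0.99, epsilon 0.001
Bidirectional LSTM      (256,)        128 units/direction, concat, last step
BatchNormalization      (256,)        momentum 0.99, epsilon 0.001
Dense                   (128,)        ReLU
Dropout                 (128,)        rate 0.5
Output                  (1,)          sigmoid
======================  ============  =======================================

Everything runs in float32; training is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: named parameters, gradients, forward/backward."""

    name = "layer"

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot_uniform(rng, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _orthogonal(rng, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(F32)


class Conv1D(Layer):
    """Stride-1 'same'-padded 1D convolution over (batch, time, channels)."""

    name = "Conv1D"

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, compute_input_grad: bool = True):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("same-padding Conv1D requires an odd kernel")
        self.kernel = kernel
        self.compute_input_grad = compute_input_grad
        self.params["W"] = _glorot_uniform(rng, kernel * c_in, c_out, (kernel, c_in, c_out))
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x, training=False, rng=None):
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._win = sliding_window_view(xp, self.kernel, axis=1)  # (B, T, c_in, k)
        return np.tensordot(self._win, self.params["W"], axes=([3, 2], [0, 1])) + self.params["b"]

    def backward(self, g):
        k, p = self.kernel, self.kernel // 2
        W = self.params["W"]
        dW = np.tensordot(self._win, g, axes=([0, 1], [0, 1]))  # (c_in, k, c_out)
        self.grads["W"] = np.transpose(dW, (1, 0, 2)).astype(F32)
        self.grads["b"] = g.sum(axis=(0, 1)).astype(F32)
        if not self.compute_input_grad:  # first layer: input gradient unused
            return np.zeros_like(self._win[:, :, :, 0])
        gp = np.pad(g, ((0, 0), (p, p), (0, 0)))
        gwin = sliding_window_view(gp, k, axis=1)  # (B, T, c_out, k)
        return np.tensordot(gwin, W[::-1], axes=([3, 2], [0, 2])).astype(F32)


class ReLU(Layer):
    name = "ReLU"

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g):
        return np.where(self._mask, g, 0)


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling (pool size 2 by default)."""

    name = "MaxPooling1D"

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        B, T, C = x.shape
        self._in_T = T
        Tp = T // self.pool
        xr = x[:, : Tp * self.pool].reshape(B, Tp, self.pool, C)
        self._idx = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, g):
        B, Tp, C = g.shape
        gz = np.zeros((B, Tp, self.pool, C), dtype=g.dtype)
        np.put_along_axis(gz, self._idx[:, :, None, :], g[:, :, None, :], axis=2)
        out = np.zeros((B, self._in_T, C), dtype=g.dtype)
        out[:, : Tp * self.pool] = gz.reshape(B, Tp * self.pool, C)
        return out


class BatchNorm(Layer):
    """Batch normalization over the batch (and time, for sequence inputs)."""

    name = "BatchNormalization"

    def __init__(self, n_features: int, axes: Tuple[int, ...], momentum: float = 0.99,
                 eps: float = 0.001):
        super().__init__()
        self.axes = axes
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(n_features, dtype=F32)
        self.params["beta"] = np.zeros(n_features, dtype=F32)
        self.running_mean = np.zeros(n_features, dtype=F32)
        self.running_var = np.ones(n_features, dtype=F32)
        self._collect: Optional[list] = None

    def forward(self, x, training=False, rng=None):
        # training may be True, False, or "batch_eval": normalize with batch
        # statistics (running stats are meaningless early at momentum 0.99)
        # but do not update the running buffers.
        if training:
            mu = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            if training is True:
                m = self.momentum
                self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(F32)
                self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
                if self._collect is not None:
                    self._collect.append((mu.copy(), var.copy()))
        else:
            mu, var = self.running_mean, self.running_var
        self._ivar = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = ((x - mu) * self._ivar).astype(F32)
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        n = np.prod([g.shape[a] for a in self.axes])
        dgamma = (g * self._xhat).sum(axis=self.axes)
        dbeta = g.sum(axis=self.axes)
        self.grads["gamma"] = dgamma.astype(F32)
        self.grads["beta"] = dbeta.astype(F32)
        gx = self.params["gamma"] * self._ivar / n
        return (gx * (n * g - dbeta - self._xhat * dgamma)).astype(F32)


class BiLSTM(Layer):
    """Bidirectional LSTM returning the concatenated final states (B, 2H)."""

    name = "Bidirectional LSTM"

    def __init__(self, c_in: int, units: int, rng):
        super().__init__()
        self.H = units
        for d in ("f", "b"):
            self.params[f"Wx_{d}"] = _glorot_uniform(rng, c_in, 4 * units, (c_in, 4 * units))
            self.params[f"Wh_{d}"] = np.concatenate(
                [_orthogonal(rng, units) for _ in range(4)], axis=1)
            bias = np.zeros(4 * units, dtype=F32)
            bias[units:2 * units] = 1.0  # forget-gate bias
            self.params[f"bias_{d}"] = bias

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def _stacked(self, name):
        # both directions run through one loop as a leading broadcast axis
        return np.stack([self.params[f"{name}_f"], self.params[f"{name}_b"]])

    def forward(self, x, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=F32)
        self._x = x
        H = self.H
        B, T, _ = x.shape
        xs = np.stack([x, x[:, ::-1]])                       # (2, B, T, C)
        self._xs = xs
        Wx, Wh, bias = self._stacked("Wx"), self._stacked("Wh"), self._stacked("bias")
        C = xs.shape[-1]
        P = np.matmul(xs.reshape(2, B * T, C), Wx).reshape(2, B, T, 4 * H)
        P += bias[:, None, None]                             # (2, B, T, 4H)
        cache = {k: np.empty((T, 2, B, H), dtype=F32)
                 for k in ("i", "f", "g", "o", "tc", "hprev", "cprev")}
        h = np.zeros((2, B, H), dtype=F32)
        c = np.zeros((2, B, H), dtype=F32)
        z = np.empty((2, B, 4 * H), dtype=F32)
        tmp = np.empty((2, B, H), dtype=F32)
        for t in range(T):
            np.matmul(h, Wh, out=z)
            z += P[:, :, t]
            cache["hprev"][t] = h
            cache["cprev"][t] = c
            # gate activations computed in place, straight into the cache
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            self._sigmoid_into(z[..., :H], i)
            self._sigmoid_into(z[..., H:2 * H], f)
            np.tanh(z[..., 2 * H:3 * H], out=g)
            self._sigmoid_into(z[..., 3 * H:], o)
            c = cache["cprev"][t] * f          # new array each step (c is cached anyway)
            np.multiply(i, g, out=tmp)
            c += tmp
            tc = cache["tc"][t]
            np.tanh(c, out=tc)
            h = o * tc
        self._cache = cache
        return np.concatenate([h[0], h[1]], axis=1)          # (B, 2H)

    @staticmethod
    def _sigmoid_into(z, out):
        np.multiply(z, -1.0, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)

    def backward(self, g):
        H = self.H
        xs, cache = self._xs, self._cache
        _, B, T, C = xs.shape
        Wh, Wx = self._stacked("Wh"), self._stacked("Wx")
        WhT = np.ascontiguousarray(Wh.transpose(0, 2, 1))
        dZ = np.empty((T, 2, B, 4 * H), dtype=F32)
        dh = np.ascontiguousarray(np.stack([g[:, :H], g[:, H:]]), dtype=F32)
        dc = np.zeros((2, B, H), dtype=F32)
        t1 = np.empty((2, B, H), dtype=F32)
        for t in range(T - 1, -1, -1):
            i, f, gg = cache["i"][t], cache["f"][t], cache["g"][t]
            o, tc, cprev = cache["o"][t], cache["tc"][t], cache["cprev"][t]
            dz = dZ[t]
            di_, df_, dg_, do_ = (dz[..., :H], dz[..., H:2 * H],
                                  dz[..., 2 * H:3 * H], dz[..., 3 * H:])
            # do = dh*tc * o*(1-o)
            np.multiply(dh, tc, out=do_)
            do_ *= o
            np.subtract(1.0, o, out=t1)
            do_ *= t1
            # dc += dh*o*(1-tc^2)
            np.multiply(tc, tc, out=t1)
            np.subtract(1.0, t1, out=t1)
            t1 *= o
            t1 *= dh
            dc += t1
            # di = dc*g * i*(1-i)
            np.multiply(dc, gg, out=di_)
            di_ *= i
            np.subtract(1.0, i, out=t1)
            di_ *= t1
            # df = dc*cprev * f*(1-f)
            np.multiply(dc, cprev, out=df_)
            df_ *= f
            np.subtract(1.0, f, out=t1)
            df_ *= t1
            # dg = dc*i * (1-g^2)
            np.multiply(gg, gg, out=t1)
            np.subtract(1.0, t1, out=t1)
            t1 *= i
            np.multiply(dc, t1, out=dg_)
            dc *= f
            dh = dz @ WhT
        hprev = cache["hprev"]                               # (T, 2, B, H)
        dWh = np.einsum("tdbh,tdbf->dhf", hprev, dZ, optimize=True)
        dZt = np.ascontiguousarray(dZ.transpose(1, 2, 0, 3)) # (2, B, T, 4H)
        xsr = xs.reshape(2, B * T, C)
        dWx = np.matmul(xsr.transpose(0, 2, 1), dZt.reshape(2, B * T, 4 * H))
        db = dZ.sum(axis=(0, 2))
        for d_idx, d in enumerate(("f", "b")):
            self.grads[f"Wh_{d}"] = dWh[d_idx].astype(F32)
            self.grads[f"Wx_{d}"] = dWx[d_idx].astype(F32)
            self.grads[f"bias_{d}"] = db[d_idx].astype(F32)
        dxs = np.matmul(dZt.reshape(2, B * T, 4 * H),
                        Wx.transpose(0, 2, 1)).reshape(2, B, T, C)
        return (dxs[0] + dxs[1][:, ::-1]).astype(F32)


class Dense(Layer):
    name = "Dense"

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.params["W"] = _glorot_uniform(rng, c_in, c_out, (c_in, c_out))
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = (self._x.T @ g).astype(F32)
        self.grads["b"] = g.sum(axis=0).astype(F32)
        return (g @ self.params["W"].T).astype(F32)


class Dropout(Layer):
    name = "Dropout"

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if training is not True or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class HybridArchitectureSpec:
    """Layer-by-layer description of the hybrid network (defaults are fixed)."""

    seq_len: int = 1084
    n_channels: int = 18
    conv_filters: Tuple[int, int] = (64, 128)
    conv_kernels: Tuple[int, int] = (7, 5)
    pool_size: int = 2
    lstm_units: int = 128
    dense_units: int = 128
    dropout_rate: float = 0.5
    bn_momentum: float = 0.99
    bn_eps: float = 0.001

    def expected_output_shapes(self) -> List[Tuple[str, tuple]]:
        """The realized shape table the built model must match exactly."""
        T = self.seq_len
        f1, f2 = self.conv_filters
        T1 = T // self.pool_size
        T2 = T1 // self.pool_size
        merged = 2 * self.lstm_units
        return [
            ("Input", (T, self.n_channels)),
            ("Conv1D", (T, f1)),
            ("MaxPooling1D", (T1, f1)),
            ("BatchNormalization", (T1, f1)),
            ("Conv1D", (T1, f2)),
            ("MaxPooling1D", (T2, f2)),
            ("BatchNormalization", (T2, f2)),
            ("Bidirectional LSTM", (merged,)),
            ("BatchNormalization", (merged,)),
            ("Dense", (self.dense_units,)),
            ("Dropout", (self.dense_units,)),
            ("Output", (1,)),
        ]


class HybridModel:
    """The assembled network with forward/backward and Adam state."""

    def __init__(self, spec: HybridArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f1, f2 = spec.conv_filters
        k1, k2 = spec.conv_kernels
        self.conv1 = Conv1D(spec.n_channels, f1, k1, rng, compute_input_grad=False)
        self.relu1 = ReLU()
        self.pool1 = MaxPool1D(spec.pool_size)
        self.bn1 = BatchNorm(f1, axes=(0, 1), momentum=spec.bn_momentum, eps=spec.bn_eps)
        self.conv2 = Conv1D(f1, f2, k2, rng)
        self.relu2 = ReLU()
        self.pool2 = MaxPool1D(spec.pool_size)
        self.bn2 = BatchNorm(f2, axes=(0, 1), momentum=spec.bn_momentum, eps=spec.bn_eps)
        self.bilstm = BiLSTM(f2, spec.lstm_units, rng)
        self.bn3 = BatchNorm(2 * spec.lstm_units, axes=(0,), momentum=spec.bn_momentum,
                             eps=spec.bn_eps)
        self.dense1 = Dense(2 * spec.lstm_units, spec.dense_units, rng)
        self.relu3 = ReLU()
        self.dropout = Dropout(spec.dropout_rate)
        self.out = Dense(spec.dense_units, 1, rng)
        # (table-row name, [layers executed for that row])
        self._rows = [
            ("Conv1D", [self.conv1, self.relu1]),
            ("MaxPooling1D", [self.pool1]),
            ("BatchNormalization", [self.bn1]),
            ("Conv1D", [self.conv2, self.relu2]),
            ("MaxPooling1D", [self.pool2]),
            ("BatchNormalization", [self.bn2]),
            ("Bidirectional LSTM", [self.bilstm]),
            ("BatchNormalization", [self.bn3]),
            ("Dense", [self.dense1, self.relu3]),
            ("Dropout", [self.dropout]),
            ("Output", [self.out]),
        ]
        self.layers = [layer for _, row in self._rows for layer in row]
        self._adam_m: Optional[dict] = None
        self._adam_v: Optional[dict] = None
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, X: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        h = np.ascontiguousarray(X, dtype=F32)
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
        return h[:, 0]

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        g = dlogits[:, None].astype(F32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Positive-class probability per item (inference mode)."""
        out = []
        for start in range(0, len(X), batch_size):
            logits = self.forward_logits(X[start:start + batch_size], training=False)
            out.append(1.0 / (1.0 + np.exp(-logits.astype(np.float64))))
        return np.concatenate(out) if out else np.empty(0)

    # -- introspection ------------------------------------------------------

    def output_shapes(self) -> List[Tuple[str, tuple]]:
        """Realized per-row output shapes from an actual forward pass."""
        x = np.zeros((1, self.spec.seq_len, self.spec.n_channels), dtype=F32)
        rows = [("Input", x.shape[1:])]
        h = x
        for name, row in self._rows:
            for layer in row:
                h = layer.forward(h, training=False)
            rows.append((name, h.shape[1:]))
        return rows

    def parameter_names(self) -> List[str]:
        return [f"{i}.{k}" for i, layer in enumerate(self.layers) for k in layer.params]

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def get_weights(self) -> dict:
        return {f"{i}.{k}": v.copy() for i, layer in enumerate(self.layers)
                for k, v in layer.params.items()}

    def set_weights(self, weights: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = weights[f"{i}.{k}"].copy()

    # -- optimizer ----------------------------------------------------------

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-7) -> None:
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(self._get_param(k)) for k in self.parameter_names()}
            self._adam_v = {k: np.zeros_like(self._get_param(k)) for k in self.parameter_names()}
        self._adam_t += 1
        t = self._adam_t
        for key in self.parameter_names():
            i, name = key.split(".", 1)
            layer = self.layers[int(i)]
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * g
            v = self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            layer.params[name] = (layer.params[name] - lr * mhat / (np.sqrt(vhat) + eps)).astype(F32)

    def _get_param(self, key: str) -> np.ndarray:
        i, name = key.split(".", 1)
        return self.layers[int(i)].params[name]

    # -- batch-norm calibration --------------------------------------------

    def calibrate_batchnorm(self, X: np.ndarray, batch_size: int = 64) -> None:
        """Replace BN running statistics by dataset-level batch moments.

        With few optimization steps the momentum-0.99 exponential running
        stats stay close to their (0, 1) initialization, which skews
        inference; a single calibration pass over the training set fixes the
        inference statistics without touching learned weights.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for bn in bns:
            bn._collect = []
        rng = np.random.default_rng(0)  # dropout sits after every BN; mask is irrelevant here
        for start in range(0, len(X), batch_size):
            self.forward_logits(X[start:start + batch_size], training=True, rng=rng)
        for bn in bns:
            if bn._collect:
                bn.running_mean = np.mean([m for m, _ in bn._collect], axis=0).astype(F32)
                bn.running_var = np.mean([v for _, v in bn._collect], axis=0).astype(F32)
            bn._collect = None


def build_hybrid(spec: Optional[HybridArchitectureSpec] = None, seed: int = 0) -> HybridModel:
    """Construct the hybrid network and audit its realized layer shapes.

    Raises ``ValueError`` naming the offending layer if any realized output
    shape deviates from the architecture table.
    """
    spec = spec or HybridArchitectureSpec()
    model = HybridModel(spec, seed=seed)
    realized = model.output_shapes()
    expected = spec.expected_output_shapes()
    for (name_r, shape_r), (name_e, shape_e) in zip(realized, expected):
        if name_r != name_e or tuple(shape_r) != tuple(shape_e):
            raise ValueError(
                f"layer {name_e}: realized shape {tuple(shape_r)} != expected {tuple(shape_e)}"
            )
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings (the architecture itself is fixed elsewhere)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.max_epochs < 0 or self.patience < 0:
            raise ValueError("max_epochs and patience must be non-negative")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must lie in [0, 1)")


def _bce_loss(logits: np.ndarray, y: np.ndarray) -> float:
    # numerically stable binary cross-entropy with logits
    z = logits.astype(np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def train_hybrid(model: HybridModel, X: np.ndarray, y: np.ndarray,
                 cfg: Optional[TrainConfig] = None) -> Tuple[HybridModel, dict]:
    """Train with Adam on binary cross-entropy, early-stopping on a
    validation split carved from the training data.

    Returns ``(model, history)`` where history holds per-epoch train/val
    losses.  Zero ``max_epochs`` leaves the model untouched with an empty
    history.  A NaN loss aborts with diagnostics.  After training, batch-norm
    inference statistics are recalibrated over the training portion.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    X = np.ascontiguousarray(X, dtype=F32)
    y = np.asarray(y, dtype=np.float64)
    history = {"train_loss": [], "val_loss": [], "n_epochs": 0}
    if cfg.max_epochs == 0:
        return model, history
    if len(np.unique(y)) < 2:
        raise ValueError("train_hybrid requires both classes present")

    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    # stratified validation carve-out
    val_idx = np.array([], dtype=int)
    if cfg.val_fraction > 0:
        parts = []
        for cls in (0.0, 1.0):
            cls_idx = np.flatnonzero(y == cls)
            rng.shuffle(cls_idx)
            k = int(round(cfg.val_fraction * len(cls_idx)))
            parts.append(cls_idx[:k])
        val_idx = np.concatenate(parts)
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    use_early_stop = len(val_idx) >= 2 and len(np.unique(y[val_idx])) == 2

    best_val = np.inf
    best_weights = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward_logits(X[idx], training=True, rng=rng)
            loss = _bce_loss(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start} "
                    f"(lr={cfg.learning_rate}, batch={cfg.batch_size})"
                )
            probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
            dlogits = (probs - y[idx]) / len(idx)
            model.backward_from_logits(dlogits)
            model.adam_step(cfg.learning_rate)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if use_early_stop:
            # evaluate with batch statistics: the momentum-0.99 running stats
            # are not yet representative after few optimization steps
            val_logits = np.concatenate([
                model.forward_logits(X[val_idx[s:s + cfg.batch_size]], training="batch_eval")
                for s in range(0, len(val_idx), cfg.batch_size)
            ])
            val_loss = _bce_loss(val_logits, y[val_idx])
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = model.get_weights()
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    history["n_epochs"] = len(history["train_loss"])
    if best_weights is not None:
        model.set_weights(best_weights)
    model.calibrate_batchnorm(X[train_idx], batch_size=cfg.batch_size)
    return model, history
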