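"""Dual-path CNN-LSTM classifier for 1-D gripping-force sequences.

The network joins two paths over the same force window:

* CNN path — a stem convolution (kernel 7) with batch normalization, then
  three bottleneck residual blocks (1x1 reduce -> 3x3 -> 1x1 expand on both
  a trunk and a branch, summed, ReLU), with max-pooling after the first
  block and dropout after the last two; global average pooling yields the
  local-morphology feature vector.
* LSTM path — an LSTM producing a 64-dimensional temporal feature sequence,
  batch-normalized, then a second LSTM reducing to 20 values (the final
  hidden state); each LSTM is followed by dropout.

The two feature vectors are concatenated into a fully connected layer whose
width equals the number of classes; per-class scores are sigmoids of the
logits (binary-cross-entropy-compatible) and the predicted label is the
argmax.

Everything — convolution, batch norm, LSTM, pooling, dropout and their
gradients — is implemented directly on NumPy float32 arrays, which keeps the
model dependency-light, deterministic per seed, and fast enough on a single
CPU for the sequence lengths used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConfig",
    "NetworkSpec",
    "CNNLSTM",
    "build_model",
    "bottleneck_forward",
    "forward",
]

_F32 = np.float32


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 500  # samples per window (5 s at 100 Hz)
    n_classes: int = 2
    cnn_stem_channels: int = 32
    stem_kernel: int = 7
    bottleneck_channels: tuple[int, int, int] = (16, 16, 32)
    pool_size: int = 2
    dropout_cnn: float = 0.2
    lstm_hidden_1: int = 64
    lstm_out: int = 20
    dropout_lstm: float = 0.3
    third_lstm: bool = False  # optional extra LSTM layer before reduction

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0 <= self.dropout_cnn < 1 and 0 <= self.dropout_lstm < 1):
            raise ValueError("dropout probabilities must be in [0, 1)")
        min_len = 32
        if self.input_length < min_len:
            raise ValueError(
                f"input_length {self.input_length} too short for the "
                f"convolution/pooling stack; minimum is {min_len}"
            )
        if self.bottleneck_channels[2] != self.cnn_stem_channels:
            raise ValueError(
                "bottleneck expand width must equal cnn_stem_channels"
            )


@dataclass(frozen=True)
class NetworkSpec:
    """Static description of a built network."""

    layers: tuple[tuple[str, str], ...]  # (name, output shape description)
    n_parameters: int
    cnn_path_width: int
    lstm_path_width: int
    n_classes: int


class Param:
    __slots__ = ("name", "v", "g")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.v = value.astype(_F32)
        self.g = np.zeros_like(self.v)


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


# ---------------------------------------------------------------------------
# Layers.  Each layer exposes forward(x, train) / backward(dy) and a params
# list; forward caches whatever backward needs.


class Conv1d:
    """Same-padded 1-D convolution, stride 1, odd kernel."""

    def __init__(self, rng, c_in: int, c_out: int, k: int, name: str):
        assert k % 2 == 1
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.W = Param(f"{name}.W", _glorot(rng, (c_out, c_in * k), c_in * k, c_out))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=_F32))
        self.params = [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, T = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (B, C, T, k) windows -> (B*T, C*k) matmul
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(B * T, C * self.k)
        y = cols @ self.W.v.T + self.b.v
        self._cache = (cols, (B, C, T))
        return y.reshape(B, T, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (B, C, T) = self._cache
        d = dy.transpose(0, 2, 1).reshape(B * T, self.c_out)
        self.W.g += (d.T @ cols).astype(_F32)
        self.b.g += d.sum(axis=0).astype(_F32)
        dcols = (d @ self.W.v).reshape(B, T, C, self.k)
        p = self.k // 2
        dxp = np.zeros((B, C, T + 2 * p), dtype=_F32)
        for j in range(self.k):
            dxp[:, :, j : j + T] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p : p + T] if p else dxp


class BatchNorm:
    """Batch normalization over all axes except ``feature_axis``."""

    def __init__(self, n_features: int, feature_axis: int, ndim: int, name: str,
                 momentum: float = 0.1, eps: float = 1e-5):
        shape = [1] * ndim
        shape[feature_axis] = n_features
        self.shape = tuple(shape)
        self.axes = tuple(a for a in range(ndim) if a != feature_axis)
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(self.shape, dtype=_F32))
        self.beta = Param(f"{name}.beta", np.zeros(self.shape, dtype=_F32))
        self.running_mean = np.zeros(self.shape, dtype=_F32)
        self.running_var = np.ones(self.shape, dtype=_F32)
        self.params = [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=self.axes, keepdims=True)
            var = x.var(axis=self.axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(_F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(_F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(_F32), train)
        return (self.gamma.v * xhat + self.beta.v).astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.gamma.g += (dy * xhat).sum(axis=self.axes, keepdims=True).astype(_F32)
        self.beta.g += dy.sum(axis=self.axes, keepdims=True).astype(_F32)
        dxhat = dy * self.gamma.v
        if not train:
            return (dxhat * inv).astype(_F32)
        m = np.prod([dy.shape[a] for a in self.axes])
        dx = (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=self.axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=self.axes, keepdims=True)
            )
        )
        return dx.astype(_F32)


class ReLU:
    params: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(_F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(_F32)


class MaxPool1d:
    params: list = []

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        B, C, T = x.shape
        To = T // self.size
        xr = x[:, :, : To * self.size].reshape(B, C, To, self.size)
        self._arg = xr.argmax(axis=3)
        self._shape = (B, C, T)
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, T = self._shape
        To = dy.shape[2]
        dx = np.zeros((B, C, To, self.size), dtype=_F32)
        bi, ci, ti = np.meshgrid(
            np.arange(B), np.arange(C), np.arange(To), indexing="ij"
        )
        dx[bi, ci, ti, self._arg] = dy
        out = np.zeros((B, C, T), dtype=_F32)
        out[:, :, : To * self.size] = dx.reshape(B, C, To * self.size)
        return out


class Dropout:
    params: list = []

    def __init__(self, p: float, rng_ref):
        self.p = p
        self._rng_ref = rng_ref  # callable returning the model rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self._rng_ref().random(x.shape) < keep).astype(_F32) / keep
        return (x * self._mask).astype(_F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(_F32)


class LSTM:
    """Single-layer LSTM over (B, T, In); returns the full hidden sequence."""

    def __init__(self, rng, n_in: int, n_hidden: int, name: str):
        H = n_hidden
        self.n_in, self.H = n_in, H
        self.Wx = Param(f"{name}.Wx", _glorot(rng, (n_in, 4 * H), n_in + H, 4 * H))
        self.Wh = Param(f"{name}.Wh", _glorot(rng, (H, 4 * H), n_in + H, 4 * H))
        b = np.zeros(4 * H, dtype=_F32)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.b = Param(f"{name}.b", b)
        self.params = [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        ax = x.reshape(B * T, -1) @ self.Wx.v
        ax = ax.reshape(B, T, 4 * H) + self.b.v
        hs = np.zeros((T + 1, B, H), dtype=_F32)
        cs = np.zeros((T + 1, B, H), dtype=_F32)
        gates = np.zeros((T, B, 4 * H), dtype=_F32)
        tanhc = np.zeros((T, B, H), dtype=_F32)
        for t in range(T):
            a = ax[:, t, :] + hs[t] @ self.Wh.v
            i = 1.0 / (1.0 + np.exp(-a[:, :H]))
            f = 1.0 / (1.0 + np.exp(-a[:, H : 2 * H]))
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-a[:, 3 * H :]))
            cs[t + 1] = f * cs[t] + i * g
            tc = np.tanh(cs[t + 1])
            hs[t + 1] = o * tc
            gates[t, :, :H] = i
            gates[t, :, H : 2 * H] = f
            gates[t, :, 2 * H : 3 * H] = g
            gates[t, :, 3 * H :] = o
            tanhc[t] = tc
        self._cache = (x, hs, cs, gates, tanhc)
        return hs[1:].transpose(1, 0, 2)  # (B, T, H)

    def backward(self, dH: np.ndarray) -> np.ndarray:
        x, hs, cs, gates, tanhc = self._cache
        B, T, _ = x.shape
        H = self.H
        dA = np.zeros((T, B, 4 * H), dtype=_F32)
        dh_next = np.zeros((B, H), dtype=_F32)
        dc_next = np.zeros((B, H), dtype=_F32)
        WhT = self.Wh.v.T
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H : 2 * H]
            g = gates[t, :, 2 * H : 3 * H]
            o = gates[t, :, 3 * H :]
            tc = tanhc[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * cs[t]
            dc_next = dc * f
            da = dA[t]
            da[:, :H] = di * i * (1.0 - i)
            da[:, H : 2 * H] = df * f * (1.0 - f)
            da[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            da[:, 3 * H :] = do * o * (1.0 - o)
            dh_next = da @ WhT
        dA_flat = dA.transpose(1, 0, 2).reshape(B * T, 4 * H)
        x_flat = x.reshape(B * T, -1)
        self.Wx.g += (x_flat.T @ dA_flat).astype(_F32)
        h_prev = hs[:-1].transpose(1, 0, 2).reshape(B * T, H)
        self.Wh.g += (h_prev.T @ dA_flat).astype(_F32)
        self.b.g += dA_flat.sum(axis=0).astype(_F32)
        dx = (dA_flat @ self.Wx.v.T).reshape(B, T, -1)
        return dx.astype(_F32)


class Dense:
    def __init__(self, rng, n_in: int, n_out: int, name: str):
        self.W = Param(f"{name}.W", _glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(f"{name}.b", np.zeros(n_out, dtype=_F32))
        self.params = [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy):
        self.W.g += (self._x.T @ dy).astype(_F32)
        self.b.g += dy.sum(axis=0).astype(_F32)
        return (dy @ self.W.v.T).astype(_F32)


class Bottleneck:
    """Residual bottleneck: trunk and branch each 1x1 -> 3x3 -> 1x1, summed.

    ReLU follows the first two convolutions of each path and the sum;
    temporal length is preserved (stride 1, symmetric padding).
    """

    def __init__(self, rng, channels: int, widths: tuple[int, int, int], name: str):
        reduce_w, inner_w, expand_w = widths
        if expand_w != channels:
            raise ValueError("bottleneck expand width must match input channels")
        self.channels = channels

        def path(tag):
            return [
                Conv1d(rng, channels, reduce_w, 1, f"{name}.{tag}1"),
                ReLU(),
                Conv1d(rng, reduce_w, inner_w, 3, f"{name}.{tag}2"),
                ReLU(),
                Conv1d(rng, inner_w, expand_w, 1, f"{name}.{tag}3"),
            ]

        self.trunk = path("trunk")
        self.branch = path("branch")
        self.out_relu = ReLU()
        self.params = [
            p for layer in self.trunk + self.branch for p in layer.params
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"bottleneck expects {self.channels} channels, got {x.shape[1]}"
            )
        t = x
        for layer in self.trunk:
            t = layer.forward(t, train)
        b = x
        for layer in self.branch:
            b = layer.forward(b, train)
        return self.out_relu.forward(t + b, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.out_relu.backward(dy)
        dt = d
        for layer in reversed(self.trunk):
            dt = layer.backward(dt)
        db = d
        for layer in reversed(self.branch):
            db = layer.backward(db)
        return dt + db


# ---------------------------------------------------------------------------
# The dual-path model.


class CNNLSTM:
    """Dual-path CNN-LSTM classifier over fixed-length force windows."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self._rng = np.random.default_rng(seed)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0FFEE)))
        C = config.cnn_stem_channels
        rngref = lambda: self._rng

        self.stem = Conv1d(rng, 1, C, config.stem_kernel, "stem")
        self.stem_bn = BatchNorm(C, feature_axis=1, ndim=3, name="stem_bn")
        self.stem_relu = ReLU()
        self.block1 = Bottleneck(rng, C, config.bottleneck_channels, "block1")
        self.pool = MaxPool1d(config.pool_size)
        self.block2 = Bottleneck(rng, C, config.bottleneck_channels, "block2")
        self.drop2 = Dropout(config.dropout_cnn, rngref)
        self.block3 = Bottleneck(rng, C, config.bottleneck_channels, "block3")
        self.drop3 = Dropout(config.dropout_cnn, rngref)

        H1, H2 = config.lstm_hidden_1, config.lstm_out
        self.lstm1 = LSTM(rng, 1, H1, "lstm1")
        self.ldrop1 = Dropout(config.dropout_lstm, rngref)
        self.lstm_bn = BatchNorm(H1, feature_axis=2, ndim=3, name="lstm_bn")
        self.lstm_extra = (
            LSTM(rng, H1, H1, "lstm_extra") if config.third_lstm else None
        )
        self.lstm2 = LSTM(rng, H1, H2, "lstm2")
        self.ldrop2 = Dropout(config.dropout_lstm, rngref)

        self.fc = Dense(rng, C + H2, config.n_classes, "fc")

        self._layers = [
            self.stem, self.stem_bn, self.block1, self.block2, self.block3,
            self.lstm1, self.lstm_bn, self.lstm2, self.fc,
        ]
        if self.lstm_extra is not None:
            self._layers.insert(-1, self.lstm_extra)

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[Param]:
        return [p for layer in self._layers for p in layer.params]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.parameters()))

    @property
    def spec(self) -> NetworkSpec:
        c = self.config
        T, C = c.input_length, c.cnn_stem_channels
        Tp = T // c.pool_size
        layers = [
            ("stem_conv+bn+relu", f"(B, {C}, {T})"),
            ("bottleneck1+maxpool", f"(B, {C}, {Tp})"),
            ("bottleneck2+dropout", f"(B, {C}, {Tp})"),
            ("bottleneck3+dropout", f"(B, {C}, {Tp})"),
            ("global_avg_pool", f"(B, {C})"),
            ("lstm1+dropout+bn", f"(B, {T}, {c.lstm_hidden_1})"),
        ]
        if c.third_lstm:
            layers.append(("lstm_extra", f"(B, {T}, {c.lstm_hidden_1})"))
        layers += [
            ("lstm2(last)+dropout", f"(B, {c.lstm_out})"),
            ("concat", f"(B, {C + c.lstm_out})"),
            ("fc+sigmoid", f"(B, {c.n_classes})"),
        ]
        return NetworkSpec(
            layers=tuple(layers),
            n_parameters=self.n_parameters,
            cnn_path_width=C,
            lstm_path_width=c.lstm_out,
            n_classes=c.n_classes,
        )

    # -- forward/backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected batch of shape (B, {self.config.input_length}), "
                f"got {x.shape}"
            )
        B, T = x.shape
        # CNN path
        c = self.stem.forward(x[:, None, :], train)
        c = self.stem_bn.forward(c, train)
        c = self.stem_relu.forward(c, train)
        c = self.block1.forward(c, train)
        c = self.pool.forward(c, train)
        c = self.block2.forward(c, train)
        c = self.drop2.forward(c, train)
        c = self.block3.forward(c, train)
        c = self.drop3.forward(c, train)
        self._gap_T = c.shape[2]
        cnn_feat = c.mean(axis=2)
        # LSTM path
        h = self.lstm1.forward(x[:, :, None], train)
        h = self.ldrop1.forward(h, train)
        h = self.lstm_bn.forward(h, train)
        if self.lstm_extra is not None:
            h = self.lstm_extra.forward(h, train)
        h = self.lstm2.forward(h, train)
        self._lstm_T = h.shape[1]
        lstm_feat = self.ldrop2.forward(h[:, -1, :], train)
        feat = np.concatenate([cnn_feat, lstm_feat], axis=1)
        return self.fc.forward(feat, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-class scores in [0, 1] (sigmoid of the logits)."""
        z = self.forward_logits(x, train)
        return (1.0 / (1.0 + np.exp(-z))).astype(_F32)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.fc.backward(dlogits.astype(_F32))
        C = self.config.cnn_stem_channels
        dcnn, dlstm_last = dfeat[:, :C], dfeat[:, C:]
        # LSTM path
        B = dfeat.shape[0]
        dlast = self.ldrop2.backward(dlstm_last)
        dH2 = np.zeros((B, self._lstm_T, self.config.lstm_out), dtype=_F32)
        dH2[:, -1, :] = dlast
        dh = self.lstm2.backward(dH2)
        if self.lstm_extra is not None:
            dh = self.lstm_extra.backward(dh)
        dh = self.lstm_bn.backward(dh)
        dh = self.ldrop1.backward(dh)
        self.lstm1.backward(dh)
        # CNN path
        dc = (dcnn[:, :, None] / self._gap_T) * np.ones(
            (1, 1, self._gap_T), dtype=_F32
        )
        dc = self.drop3.backward(dc)
        dc = self.block3.backward(dc)
        dc = self.drop2.backward(dc)
        dc = self.block2.backward(dc)
        dc = self.pool.backward(dc)
        dc = self.block1.backward(dc)
        dc = self.stem_relu.backward(dc)
        dc = self.stem_bn.backward(dc)
        self.stem.backward(dc)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.g[...] = 0

    # -- state ------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.v.copy() for p in self.parameters()}
        for name, layer in self._named_bn():
            state[f"{name}.running_mean"] = layer.running_mean.copy()
            state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.v = state[p.name].astype(_F32).reshape(p.v.shape)
        for name, layer in self._named_bn():
            layer.running_mean = state[f"{name}.running_mean"].astype(_F32).reshape(
                layer.running_mean.shape
            )
            layer.running_var = state[f"{name}.running_var"].astype(_F32).reshape(
                layer.running_var.shape
            )

    def _named_bn(self):
        return [("stem_bn", self.stem_bn), ("lstm_bn", self.lstm_bn)]

    def reseed_dropout(self, seed: int) -> None:
        self._rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xD0)))


def build_model(config: ModelConfig, seed: int = 0) -> CNNLSTM:
    """Construct the dual-path network with seeded initialization.

    The static architecture description is available as ``model.spec``;
    identical configs always yield identical parameter counts.
    """
    return CNNLSTM(config, seed=seed)


def bottleneck_forward(x: np.ndarray, block: Bottleneck) -> np.ndarray:
    """Run one bottleneck block in inference mode on (B, C, T) features."""
    return block.forward(np.asarray(x, dtype=_F32), train=False)


def forward(model: CNNLSTM, batch: np.ndarray) -> np.ndarray:
    """Inference-mode class scores in [0, 1] for a batch of sequences."""
    return model.forward(batch, train=False)
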