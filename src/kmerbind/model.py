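"""CNN -> bi-LSTM -> fully-connected binary classifier, in pure numpy.

The network reads an (n_tokens x d) sequence matrix. Three convolution
modules (1-D convolution, ReLU, optional batch normalization, max-pool)
extract and downsample local motif features; a bidirectional LSTM over the
pooled feature sequence captures long-range structure; the final hidden
states of the two directions are concatenated and passed through two
fully-connected layers with one dropout layer and a sigmoid output — the
predicted probability that the input fragment is bound.

The bi-LSTM cell follows the standard gate equations

    f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)
    i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)
    c_t = f_t * c_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
    o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)
    h_t = o_t * tanh(c_t)

Forward and backward passes are written against numpy arrays (float32,
batch-first (N, L, C) layout); gradients flow through every layer
including full backpropagation-through-time in the LSTM. Weights are
Xavier-uniform initialized and biases zero. Ablation variants drop the
recurrent module (``cnn_only``, conv output flattened into the head) or
the convolutional stack (``rnn_only``, LSTM directly over the input).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Literal

import numpy as np

F32 = np.float32


class ShapeError(ValueError):
    """Input shape is incompatible with the built network."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the tuned recommendation)."""

    input_dim: int = 100
    n_conv_modules: int = 3
    conv_channels: int = 16
    kernel_size: int = 3
    pool_window: int = 2
    lstm_units: int = 16  # per direction
    fc_hidden: int = 32
    dropout: float = 0.1
    architecture: Literal["hybrid", "cnn_only", "rnn_only"] = "hybrid"
    batchnorm: bool = True
    # how the recurrent module feeds the head: the full output sequence
    # (every h_t, both directions, flattened) or only the final hidden
    # state of each direction. With pooled sequences ~100 steps long and
    # randomly initialized gates, final-state-only output suppresses
    # signal far from the sequence ends, so "sequence" is the default.
    lstm_output: Literal["sequence", "last"] = "sequence"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "n_conv_modules", "conv_channels",
                     "kernel_size", "pool_window", "lstm_units", "fc_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.architecture not in ("hybrid", "cnn_only", "rnn_only"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


# ---------------------------------------------------------------------------
# standalone bi-LSTM cell (reference form with per-gate parameter matrices)
# ---------------------------------------------------------------------------

@dataclass
class BiLSTMParams:
    """One direction's LSTM cell parameters in per-gate form.

    W_* have shape (H, d_in), U_* shape (H, H), b_* length H.
    """

    W_f: np.ndarray; U_f: np.ndarray; b_f: np.ndarray
    W_i: np.ndarray; U_i: np.ndarray; b_i: np.ndarray
    W_c: np.ndarray; U_c: np.ndarray; b_c: np.ndarray
    W_o: np.ndarray; U_o: np.ndarray; b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @classmethod
    def zeros(cls, hidden: int, d_in: int) -> "BiLSTMParams":
        W = lambda: np.zeros((hidden, d_in))
        U = lambda: np.zeros((hidden, hidden))
        b = lambda: np.zeros(hidden)
        return cls(W(), U(), b(), W(), U(), b(), W(), U(), b(), W(), U(), b())

    @classmethod
    def random(cls, hidden: int, d_in: int, rng: np.random.Generator) -> "BiLSTMParams":
        W = lambda: rng.standard_normal((hidden, d_in))
        U = lambda: rng.standard_normal((hidden, hidden))
        b = lambda: rng.standard_normal(hidden)
        return cls(W(), U(), b(), W(), U(), b(), W(), U(), b(), W(), U(), b())


def bilstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: BiLSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update: gate equations applied to a single time step.

    Inputs are vectors (d_in,) and (H,); returns (h_t, c_t). With all
    parameters zero every gate is sigma(0) = 0.5 and the candidate is
    tanh(0) = 0, so c_t = 0.5 * c_prev and h_t = 0.5 * tanh(0.5 * c_prev).
    """
    H = params.hidden_size
    x_t, h_prev, c_prev = np.asarray(x_t), np.asarray(h_prev), np.asarray(c_prev)
    if x_t.shape[-1] != params.W_f.shape[1]:
        raise ShapeError(
            f"x_t has dim {x_t.shape[-1]}, parameters expect {params.W_f.shape[1]}"
        )
    if h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise ShapeError(f"h_prev/c_prev must have dim {H}")
    f = _sigmoid(params.W_f @ x_t + params.U_f @ h_prev + params.b_f)
    i = _sigmoid(params.W_i @ x_t + params.U_i @ h_prev + params.b_i)
    g = np.tanh(params.W_c @ x_t + params.U_c @ h_prev + params.b_c)
    o = _sigmoid(params.W_o @ x_t + params.U_o @ h_prev + params.b_o)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Minimal trainable-layer protocol: forward caches what backward needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-mode 1-D convolution, stride 1, via patch matrix-multiply."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch
        self.params = {
            "W": _xavier(rng, k * in_ch, out_ch, (k * in_ch, out_ch)),
            "b": np.zeros(out_ch, dtype=F32),
        }

    def forward(self, x, train):
        N, L, C = x.shape
        if L < self.k:
            raise ShapeError(f"input length {L} shorter than kernel {self.k}")
        v = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)  # (N,Lout,C,k)
        patches = np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
            N, L - self.k + 1, self.k * C
        )
        self._patches = patches
        return patches @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        patches = self._patches
        N, Lout, _ = dy.shape
        self.grads["W"] = np.tensordot(patches, dy, axes=([0, 1], [0, 1]))
        self.grads["b"] = dy.sum(axis=(0, 1))
        dpatch = (dy @ self.params["W"].T).reshape(N, Lout, self.k, self.in_ch)
        dx = np.zeros((N, Lout + self.k - 1, self.in_ch), dtype=F32)
        for j in range(self.k):
            dx[:, j : j + Lout] += dpatch[:, :, j]
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm1D(Layer):
    """Per-channel normalization over the batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=F32),
            "beta": np.zeros(channels, dtype=F32),
        }
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(F32))
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[1]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        return (inv / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class MaxPool1D(Layer):
    """Non-overlapping max pooling (stride = window); trailing remainder dropped."""

    def __init__(self, window: int):
        super().__init__()
        self.w = window

    def forward(self, x, train):
        N, L, C = x.shape
        Lout = L // self.w
        if Lout < 1:
            raise ShapeError(f"input length {L} shorter than pool window {self.w}")
        xr = x[:, : Lout * self.w].reshape(N, Lout, self.w, C)
        self._idx = xr.argmax(axis=2)
        self._in_shape = (N, L, C)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        N, L, C = self._in_shape
        Lout = L // self.w
        dxr = np.zeros((N, Lout, self.w, C), dtype=F32)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((N, L, C), dtype=F32)
        dx[:, : Lout * self.w] = dxr.reshape(N, Lout * self.w, C)
        return dx


class BiLSTMLayer(Layer):
    """Bidirectional LSTM; emits concat(final forward h, final backward h).

    Parameters are stored fused per direction: Wx (d_in, 4H), Wh (H, 4H),
    b (4H), gate order (i, f, g, o). Backward implements full BPTT.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        super().__init__()
        self.d_in, self.H = d_in, hidden
        self.return_sequences = return_sequences
        for tag in ("fw", "bw"):
            self.params[f"Wx_{tag}"] = _xavier(rng, d_in, 4 * hidden, (d_in, 4 * hidden))
            self.params[f"Wh_{tag}"] = _xavier(rng, hidden, 4 * hidden, (hidden, 4 * hidden))
            self.params[f"b_{tag}"] = np.zeros(4 * hidden, dtype=F32)

    def _run(self, x: np.ndarray, tag: str) -> tuple[np.ndarray, dict]:
        N, T, _ = x.shape
        H = self.H
        Wx, Wh, b = (self.params[f"Wx_{tag}"], self.params[f"Wh_{tag}"],
                     self.params[f"b_{tag}"])
        xp = x @ Wx + b  # precompute input contribution: (N, T, 4H)
        h = np.zeros((N, H), dtype=F32)
        c = np.zeros((N, H), dtype=F32)
        h_all = np.empty((T, N, H), dtype=F32)
        gates_i = np.empty((T, N, H), dtype=F32)
        gates_f = np.empty((T, N, H), dtype=F32)
        gates_g = np.empty((T, N, H), dtype=F32)
        gates_o = np.empty((T, N, H), dtype=F32)
        h_prev = np.empty((T, N, H), dtype=F32)
        c_prev = np.empty((T, N, H), dtype=F32)
        c_all = np.empty((T, N, H), dtype=F32)
        for t in range(T):
            a = xp[:, t] + h @ Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            h_prev[t], c_prev[t] = h, c
            c = f * c + i * g
            h = o * np.tanh(c)
            gates_i[t], gates_f[t], gates_g[t], gates_o[t] = i, f, g, o
            c_all[t] = c
            h_all[t] = h
        cache = dict(x=x, i=gates_i, f=gates_f, g=gates_g, o=gates_o,
                     h_prev=h_prev, c_prev=c_prev, c=c_all)
        return h, h_all, cache

    def forward(self, x, train):
        if x.shape[2] != self.d_in:
            raise ShapeError(f"LSTM expects input dim {self.d_in}, got {x.shape[2]}")
        h_fw, hs_fw, self._cache_fw = self._run(x, "fw")
        h_bw, hs_bw, self._cache_bw = self._run(x[:, ::-1], "bw")
        if not self.return_sequences:
            return np.concatenate([h_fw, h_bw], axis=1)
        # align both directions to input positions: (N, T, 2H)
        seq_fw = hs_fw.transpose(1, 0, 2)
        seq_bw = hs_bw[::-1].transpose(1, 0, 2)
        return np.concatenate([seq_fw, seq_bw], axis=2)

    def _bptt(self, cache: dict, dh_out: np.ndarray, tag: str) -> np.ndarray:
        """Backprop through time.

        ``dh_out`` is either (N, H) — gradient on the final hidden state
        only — or (T, N, H), per-step output gradients.
        """
        x = cache["x"]
        N, T, _ = x.shape
        H = self.H
        Wx, Wh = self.params[f"Wx_{tag}"], self.params[f"Wh_{tag}"]
        gWx = np.zeros_like(Wx)
        gWh = np.zeros_like(Wh)
        gb = np.zeros(4 * H, dtype=F32)
        dx = np.empty_like(x)
        per_step = dh_out.ndim == 3
        dh = (dh_out[T - 1] if per_step else dh_out).astype(F32)
        dc = np.zeros((N, H), dtype=F32)
        for t in range(T - 1, -1, -1):
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            tc = np.tanh(cache["c"][t])
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            df = dc * cache["c_prev"][t]
            dg = dc * i
            dA = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
                 do * o * (1 - o)], axis=1)  # (N, 4H)
            gWx += x[:, t].T @ dA
            gWh += cache["h_prev"][t].T @ dA
            gb += dA.sum(axis=0)
            dx[:, t] = dA @ Wx.T
            dh = dA @ Wh.T
            if per_step and t > 0:
                dh = dh + dh_out[t - 1]
            dc = dc * f
        self.grads[f"Wx_{tag}"] = gWx
        self.grads[f"Wh_{tag}"] = gWh
        self.grads[f"b_{tag}"] = gb
        return dx

    def backward(self, dy):
        H = self.H
        if not self.return_sequences:
            dx_fw = self._bptt(self._cache_fw, dy[:, :H], "fw")
            dx_bw = self._bptt(self._cache_bw, dy[:, H:], "bw")
            return dx_fw + dx_bw[:, ::-1]
        # dy: (N, T, 2H) aligned to input positions
        d_fw = np.ascontiguousarray(dy[:, :, :H].transpose(1, 0, 2))
        d_bw = np.ascontiguousarray(dy[:, ::-1, H:].transpose(1, 0, 2))
        dx_fw = self._bptt(self._cache_fw, d_fw, "fw")
        dx_bw = self._bptt(self._cache_bw, d_bw, "bw")
        return dx_fw + dx_bw[:, ::-1]

    def direction_params(self, tag: str) -> BiLSTMParams:
        """Export one direction in per-gate (H x d_in) reference form."""
        H = self.H
        Wx, Wh, b = (self.params[f"Wx_{tag}"], self.params[f"Wh_{tag}"],
                     self.params[f"b_{tag}"])
        sl = {"i": slice(0, H), "f": slice(H, 2 * H), "c": slice(2 * H, 3 * H),
              "o": slice(3 * H, 4 * H)}
        kw = {}
        for gate in "fico":
            kw[f"W_{gate}"] = Wx[:, sl[gate]].T.astype(np.float64)
            kw[f"U_{gate}"] = Wh[:, sl[gate]].T.astype(np.float64)
            kw[f"b_{gate}"] = b[sl[gate]].astype(np.float64)
        return BiLSTMParams(**kw)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _xavier(rng, d_in, d_out, (d_in, d_out)),
            "b": np.zeros(d_out, dtype=F32),
        }

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self._rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p).astype(F32) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# full classifier
# ---------------------------------------------------------------------------

def conv_stack_lengths(input_len: int, config: ModelConfig) -> list[int]:
    """Sequence lengths after each conv and pool stage; raises if any drops below 1."""
    lengths = [input_len]
    L = input_len
    for m in range(config.n_conv_modules):
        L = L - config.kernel_size + 1
        if L < 1:
            raise ShapeError(_too_short_msg(input_len, config))
        lengths.append(L)
        L = L // config.pool_window
        if L < 1:
            raise ShapeError(_too_short_msg(input_len, config))
        lengths.append(L)
    return lengths


def minimum_input_length(config: ModelConfig) -> int:
    L = 1
    for _ in range(config.n_conv_modules):
        L = L * config.pool_window  # invert floor-division conservatively
        L = L + config.kernel_size - 1
    return L


def _too_short_msg(input_len: int, config: ModelConfig) -> str:
    return (
        f"input length {input_len} is shorter than the receptive field of the "
        f"convolutional stack; minimum supported length is {minimum_input_length(config)}"
    )


class SequenceClassifier:
    """The assembled network; holds layers, exposes forward/backward/state."""

    def __init__(self, config: ModelConfig, input_len: int):
        self.config = config
        self.input_len = input_len
        rng = np.random.default_rng(config.seed)
        layers: list[Layer] = []
        d = config.input_dim
        if config.architecture in ("hybrid", "cnn_only"):
            lengths = conv_stack_lengths(input_len, config)
            ch = d
            for _ in range(config.n_conv_modules):
                layers.append(Conv1D(ch, config.conv_channels, config.kernel_size, rng))
                layers.append(ReLU())
                if config.batchnorm:
                    layers.append(BatchNorm1D(config.conv_channels))
                layers.append(MaxPool1D(config.pool_window))
                ch = config.conv_channels
            final_len = lengths[-1]
        return_seq = config.lstm_output == "sequence"
        if config.architecture == "hybrid":
            layers.append(BiLSTMLayer(config.conv_channels, config.lstm_units, rng,
                                      return_sequences=return_seq))
            if return_seq:
                layers.append(Flatten())
                head_in = final_len * 2 * config.lstm_units
            else:
                head_in = 2 * config.lstm_units
        elif config.architecture == "rnn_only":
            if input_len < 1:
                raise ShapeError("rnn_only requires input length >= 1")
            layers.append(BiLSTMLayer(d, config.lstm_units, rng,
                                      return_sequences=return_seq))
            if return_seq:
                layers.append(Flatten())
                head_in = input_len * 2 * config.lstm_units
            else:
                head_in = 2 * config.lstm_units
        else:  # cnn_only
            layers.append(Flatten())
            head_in = final_len * config.conv_channels
        layers.append(Dense(head_in, config.fc_hidden, rng))
        layers.append(ReLU())
        layers.append(Dropout(config.dropout, np.random.default_rng(rng.integers(2**31))))
        layers.append(Dense(config.fc_hidden, 1, rng))
        self.layers = layers

    # -- passes ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim != 3 or x.shape[1] != self.input_len or x.shape[2] != self.config.input_dim:
            raise ShapeError(
                f"expected batch of shape (N, {self.input_len}, "
                f"{self.config.input_dim}), got {x.shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits.astype(F32)[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Binding probabilities in (0, 1); deterministic (dropout/BN in eval mode)."""
        return _sigmoid(self.forward_logits(x, train=False))

    # -- parameter access --------------------------------------------------

    def named_params(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                yield f"layer{li}.{name}", arr

    def named_grads(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{li}.{name}", layer.grads.get(name)

    def n_parameters(self) -> int:
        return sum(arr.size for _, arr in self.named_params())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: arr.copy() for name, arr in self.named_params()}
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1D):
                state[f"layer{li}.running_mean"] = layer.running_mean.copy()
                state[f"layer{li}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{li}.{name}"]
            if isinstance(layer, BatchNorm1D):
                layer.running_mean[...] = state[f"layer{li}.running_mean"]
                layer.running_var[...] = state[f"layer{li}.running_var"]

    # -- persistence -------------------------------------------------------

    def config_hash(self) -> str:
        blob = json.dumps({**asdict(self.config), "input_len": self.input_len},
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"config": asdict(self.config),
                           "input_len": self.input_len,
                           "hash": self.config_hash()})
        np.savez_compressed(str(path), __meta__=np.array(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, expected_config: ModelConfig | None = None
             ) -> "SequenceClassifier":
        with np.load(str(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        config = ModelConfig(**meta["config"])
        if expected_config is not None and asdict(expected_config) != asdict(config):
            raise ValueError(
                "checkpoint config does not match the expected config; refusing to load"
            )
        model = cls(config, meta["input_len"])
        if model.config_hash() != meta["hash"]:
            raise ValueError("checkpoint config hash mismatch; refusing to load")
        model.load_state_dict(state)
        return model


def build_model(config: ModelConfig, input_len: int) -> SequenceClassifier:
    """Assemble an untrained classifier, validating input length feasibility."""
    if config.architecture in ("hybrid", "cnn_only"):
        conv_stack_lengths(input_len, config)  # raises with the computed minimum
    return SequenceClassifier(config, input_len)
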