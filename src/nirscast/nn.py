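"""Minimal NumPy recurrent-network engine: stacked LSTM + dense head + Adam.

Implements the standard LSTM cell

    i(t) = sigmoid(W_i x(t) + U_i h(t-1) + b_i)
    f(t) = sigmoid(W_f x(t) + U_f h(t-1) + b_f)
    c~(t) = tanh  (W_c x(t) + U_c h(t-1) + b_c)
    c(t) = f(t) * c(t-1) + i(t) * c~(t)
    o(t) = sigmoid(W_o x(t) + U_o h(t-1) + b_o)
    h(t) = o(t) * tanh(c(t))

with exact backpropagation through time, inverted dropout between stacked
layers (training only), and Adam updates.  Everything is plain NumPy so the
forecaster runs identically on any CPU; gate weights are stored as single
(in, 4H) / (H, 4H) matrices in i, f, c~, o order so each timestep is two
GEMMs.  Gradients are verified against numerical differentiation in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMLayer", "SequenceRegressor", "Adam"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMLayer:
    """One LSTM layer processing (T, B, n_in) -> (T, B, n_hidden)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.n_in = n_in
        self.n_hidden = n_hidden
        self.dtype = dtype
        lim_w = np.sqrt(6.0 / (n_in + n_hidden))
        lim_u = np.sqrt(6.0 / (2 * n_hidden))
        self.W = rng.uniform(-lim_w, lim_w, (n_in, 4 * n_hidden)).astype(dtype)
        self.U = rng.uniform(-lim_u, lim_u, (n_hidden, 4 * n_hidden)).astype(dtype)
        self.b = np.zeros(4 * n_hidden, dtype=dtype)
        self.b[n_hidden:2 * n_hidden] = 1.0     # forget-gate bias

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray, want_cache: bool = True):
        """Run the full sequence; returns hidden sequence (T, B, H) and cache."""
        T, B, _ = x.shape
        H = self.n_hidden
        pre = x @ self.W + self.b                    # (T, B, 4H)
        I = np.empty((T, B, H), dtype=self.dtype)
        F = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        C = np.empty_like(I)
        HC = np.empty_like(I)
        Hs = np.empty_like(I)
        h = np.zeros((B, H), dtype=self.dtype)
        c = np.zeros((B, H), dtype=self.dtype)
        for t in range(T):
            z = pre[t] + h @ self.U
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            hc = np.tanh(c)
            h = o * hc
            I[t], F[t], G[t], O[t], C[t], HC[t], Hs[t] = i, f, g, o, c, hc, h
        cache = (x, I, F, G, O, C, HC, Hs) if want_cache else None
        return Hs, cache

    def backward(self, cache, dh_out: np.ndarray):
        """BPTT given gradient w.r.t. the hidden sequence; returns (dx, grads)."""
        x, I, F, G, O, C, HC, Hs = cache
        T, B, H = I.shape
        dz_all = np.empty((T, B, 4 * H), dtype=self.dtype)
        dh = np.zeros((B, H), dtype=self.dtype)
        dc = np.zeros((B, H), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            dh_t = dh_out[t] + dh
            i, f, g, o, hc = I[t], F[t], G[t], O[t], HC[t]
            do = dh_t * hc
            dc_t = dh_t * o * (1.0 - hc * hc) + dc
            c_prev = C[t - 1] if t > 0 else 0.0
            dz = dz_all[t]
            dz[:, :H] = dc_t * g * i * (1.0 - i)
            dz[:, H:2 * H] = dc_t * c_prev * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dc_t * i * (1.0 - g * g)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            dc = dc_t * f
            dh = dz @ self.U.T
        # dU = sum_t h(t-1)^T dz(t), done as one GEMM over shifted hidden states
        h_prev = np.concatenate(
            [np.zeros((1, B, H), dtype=self.dtype), Hs[:-1]], axis=0)
        dU = h_prev.reshape(T * B, H).T @ dz_all.reshape(T * B, 4 * H)
        db = dz_all.sum(axis=(0, 1))
        dW = x.reshape(T * B, -1).T @ dz_all.reshape(T * B, 4 * H)
        dx = dz_all @ self.W.T
        return dx, [dW, dU, db]


class SequenceRegressor:
    """Stacked LSTM layers + linear head mapping the last hidden state to a scalar.

    Dropout (inverted) is applied to the hidden sequences *between* recurrent
    layers during training only; inference is deterministic.
    """

    def __init__(self, hidden_units=(128, 64, 32), dropout: float = 0.2,
                 seed: int = 0, n_in: int = 1, dtype=np.float32):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.dropout = float(dropout)
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        self.layers: list[LSTMLayer] = []
        sizes = [n_in, *hidden_units]
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.layers.append(LSTMLayer(a, b, self.rng, dtype))
        h_last = hidden_units[-1]
        lim = np.sqrt(6.0 / (h_last + 1))
        self.Wd = self.rng.uniform(-lim, lim, (h_last, 1)).astype(dtype)
        self.bd = np.zeros(1, dtype=dtype)

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend([self.Wd, self.bd])
        return out

    def forward(self, x: np.ndarray, train: bool = False):
        """x: (T, B, n_in) -> predictions (B,); caches kept when training."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        caches, masks = [], []
        h_seq = x
        for k, layer in enumerate(self.layers):
            h_seq, cache = layer.forward(h_seq, want_cache=train)
            caches.append(cache)
            if train and self.dropout > 0.0 and k < len(self.layers) - 1:
                keep = 1.0 - self.dropout
                mask = (self.rng.random(h_seq.shape) < keep).astype(self.dtype) / keep
                h_seq = h_seq * mask
                masks.append(mask)
            else:
                masks.append(None)
        y = h_seq[-1] @ self.Wd + self.bd                 # (B, 1)
        if train:
            self._cache = (caches, masks, h_seq)
        return y[:, 0]

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """Gradient of a scalar loss given d loss / d prediction, shape (B,)."""
        caches, masks, h_top = self._cache
        dy = dy.astype(self.dtype)[:, None]               # (B, 1)
        dWd = h_top[-1].T @ dy
        dbd = dy.sum(axis=0)
        grads_rev: list[np.ndarray] = [dWd, dbd]
        T, B, _ = h_top.shape
        dh_seq = np.zeros((T, B, self.layers[-1].n_hidden), dtype=self.dtype)
        dh_seq[-1] = dy @ self.Wd.T
        layer_grads = []
        for k in range(len(self.layers) - 1, -1, -1):
            dx, g = self.layers[k].backward(caches[k], dh_seq)
            layer_grads.append(g)
            if k > 0:
                mask = masks[k - 1]
                dh_seq = dx if mask is None else dx * mask
        out: list[np.ndarray] = []
        for g in reversed(layer_grads):
            out.extend(g)
        out.extend(grads_rev)
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    # -- flat (de)serialization -------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            state[f"W{i}"], state[f"U{i}"], state[f"b{i}"] = layer.W, layer.U, layer.b
        state["Wd"], state["bd"] = self.Wd, self.bd
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            layer.W = state[f"W{i}"].astype(self.dtype)
            layer.U = state[f"U{i}"].astype(self.dtype)
            layer.b = state[f"b{i}"].astype(self.dtype)
        self.Wd = state["Wd"].astype(self.dtype)
        self.bd = state["bd"].astype(self.dtype)


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
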