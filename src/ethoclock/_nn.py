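"""Self-contained numpy implementation of a 1D-conv + BiLSTM binary classifier.

Architecture (fixed layer order): 1-D convolution over the step axis with
ReLU -> non-overlapping max pooling -> bidirectional LSTM (final hidden
state of each direction, concatenated) -> inverted dropout -> single
sigmoid unit.  Trained with Adam on binary cross-entropy, with manual
backpropagation through time.  Deterministic given the seed.

This module is deliberately minimal: exactly the pieces the classifier
needs, gradient-checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvBiLSTM"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ConvBiLSTM:
    """Conv1D -> maxpool -> BiLSTM -> dropout -> sigmoid head."""

    def __init__(
        self,
        window_len: int,
        n_features: int,
        conv_filters: int = 64,
        conv_kernel: int = 5,
        pool_size: int = 2,
        lstm_units: int = 64,
        dropout: float = 0.3,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if conv_kernel < 2:
            raise ValueError("conv kernel must span at least 2 steps")
        if window_len < conv_kernel * pool_size:
            raise ValueError("window too short for kernel and pooling")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.T = window_len
        self.F = n_features
        self.C = conv_filters
        self.K = conv_kernel
        self.P = pool_size
        self.U = lstm_units
        self.dropout = dropout
        self.dtype = dtype
        self.T1 = self.T - self.K + 1
        self.T2 = self.T1 // self.P
        self.rng = np.random.default_rng(seed)
        self.params = self._init_params()
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- initialization ----------------------------------------------------

    def _glorot(self, fan_in, fan_out, shape):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return self.rng.uniform(-lim, lim, shape).astype(self.dtype)

    def _init_params(self) -> dict:
        K, F, C, U = self.K, self.F, self.C, self.U
        p = {
            "W1": self._glorot(K * F, C, (K * F, C)),
            "b1": np.zeros(C, dtype=self.dtype),
            "wd": self._glorot(2 * U, 1, (2 * U,)),
            "bd": np.zeros(1, dtype=self.dtype),
        }
        for d in ("f", "b"):
            p[f"Wx_{d}"] = self._glorot(C, 4 * U, (C, 4 * U))
            p[f"Wh_{d}"] = self._glorot(U, 4 * U, (U, 4 * U))
            bias = np.zeros(4 * U, dtype=self.dtype)
            bias[U:2 * U] = 1.0  # forget-gate bias
            p[f"bb_{d}"] = bias
        return p

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward -----------------------------------------------------------

    def _conv_pool(self, X):
        K = self.K
        Xcol = np.lib.stride_tricks.sliding_window_view(X, K, axis=1)
        # (B, T1, F, K) -> (B, T1, K*F) matching W1's (K, F) raveling
        Xcol = np.ascontiguousarray(Xcol.transpose(0, 1, 3, 2)).reshape(
            X.shape[0], self.T1, K * self.F
        )
        Z1 = Xcol @ self.params["W1"] + self.params["b1"]
        A1 = np.maximum(Z1, 0.0)
        B = X.shape[0]
        Ap = A1[:, : self.T2 * self.P].reshape(B, self.T2, self.P, self.C)
        pool = Ap.max(axis=2)
        argm = Ap.argmax(axis=2)
        return Xcol, Z1, pool, argm

    def _lstm(self, x, d: str):
        """Run one LSTM direction over x (B, T2, C); returns cache."""
        Wx, Wh, bb = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"bb_{d}"])
        B, T, _ = x.shape
        U = self.U
        pre = x @ Wx + bb  # input contributions for all steps at once
        I = np.empty((B, T, U), dtype=x.dtype)
        Fg = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        Cc = np.empty_like(I)
        H = np.empty_like(I)
        h = np.zeros((B, U), dtype=x.dtype)
        c = np.zeros((B, U), dtype=x.dtype)
        for t in range(T):
            z = pre[:, t] + h @ Wh
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c = f * c + i * g
            h = o * np.tanh(c)
            I[:, t], Fg[:, t], G[:, t], O[:, t], Cc[:, t], H[:, t] = i, f, g, o, c, h
        return {"x": x, "I": I, "F": Fg, "G": G, "O": O, "C": Cc, "H": H}

    def forward(self, X, train: bool = False):
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[1] != self.T or X.shape[2] != self.F:
            raise ValueError(
                f"expected input shaped (n, {self.T}, {self.F}), got {X.shape}"
            )
        Xcol, Z1, pool, argm = self._conv_pool(X)
        cf = self._lstm(pool, "f")
        cb = self._lstm(pool[:, ::-1], "b")
        feat = np.concatenate([cf["H"][:, -1], cb["H"][:, -1]], axis=1)
        if train and self.dropout > 0:
            mask = (self.rng.random(feat.shape) >= self.dropout).astype(self.dtype)
            mask /= (1.0 - self.dropout)
            feat_d = feat * mask
        else:
            mask = None
            feat_d = feat
        logit = feat_d @ self.params["wd"] + self.params["bd"][0]
        prob = _sigmoid(logit)
        cache = {"Xcol": Xcol, "Z1": Z1, "pool": pool, "argm": argm,
                 "cf": cf, "cb": cb, "feat_d": feat_d, "mask": mask, "prob": prob}
        return prob, cache

    def predict_proba(self, X, batch: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        out = np.empty(X.shape[0], dtype=np.float64)
        for lo in range(0, X.shape[0], batch):
            p, _ = self.forward(X[lo:lo + batch], train=False)
            out[lo:lo + batch] = p
        return out

    # -- backward ----------------------------------------------------------

    def _lstm_backward(self, cache, dh_last, d: str, grads):
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        x, I, Fg, G, O, Cc, H = (cache[k] for k in ("x", "I", "F", "G", "O", "C", "H"))
        B, T, U = I.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        dbb = np.zeros(4 * U, dtype=x.dtype)
        dx = np.empty_like(x)
        dh = dh_last.astype(x.dtype)
        dc = np.zeros((B, U), dtype=x.dtype)
        dz = np.empty((B, 4 * U), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c = I[:, t], Fg[:, t], G[:, t], O[:, t], Cc[:, t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            c_prev = Cc[:, t - 1] if t > 0 else np.zeros_like(c)
            h_prev = H[:, t - 1] if t > 0 else np.zeros_like(dh)
            dz[:, :U] = dc * g * i * (1.0 - i)
            dz[:, U:2 * U] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * U:3 * U] = dc * i * (1.0 - g * g)
            dz[:, 3 * U:] = do * o * (1.0 - o)
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            dbb += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        grads[f"Wx_{d}"] = dWx
        grads[f"Wh_{d}"] = dWh
        grads[f"bb_{d}"] = dbb
        return dx

    def backward(self, cache, y) -> dict:
        """Gradients of mean BCE loss w.r.t. all parameters."""
        prob = cache["prob"]
        B = prob.shape[0]
        y = np.asarray(y, dtype=self.dtype)
        dlogit = (prob - y) / B  # BCE + sigmoid shortcut

        grads: dict = {}
        grads["wd"] = cache["feat_d"].T @ dlogit
        grads["bd"] = np.array([dlogit.sum()], dtype=self.dtype)
        dfeat = dlogit[:, None] * self.params["wd"][None, :]
        if cache["mask"] is not None:
            dfeat = dfeat * cache["mask"]
        U = self.U
        dpool = self._lstm_backward(cache["cf"], dfeat[:, :U], "f", grads)
        dpool_b = self._lstm_backward(cache["cb"], dfeat[:, U:], "b", grads)
        dpool = dpool + dpool_b[:, ::-1]

        # unpool: route gradients to argmax positions
        Bn = dpool.shape[0]
        dAp = np.zeros((Bn, self.T2, self.P, self.C), dtype=dpool.dtype)
        bi, ti, ci = np.ogrid[:Bn, :self.T2, :self.C]
        dAp[bi, ti, cache["argm"], ci] = dpool
        dA1 = np.zeros((Bn, self.T1, self.C), dtype=dpool.dtype)
        dA1[:, : self.T2 * self.P] = dAp.reshape(Bn, self.T2 * self.P, self.C)

        dZ1 = dA1 * (cache["Z1"] > 0)
        grads["W1"] = cache["Xcol"].reshape(-1, self.K * self.F).T @ dZ1.reshape(-1, self.C)
        grads["b1"] = dZ1.sum(axis=(0, 1))
        return grads

    # -- optimization ------------------------------------------------------

    def adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999,
                  eps=1e-8, clip: float = 5.0) -> None:
        gnorm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
        scale = 1.0 if gnorm <= clip else clip / (gnorm + 1e-12)
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g * scale
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1; m += (1 - beta1) * g
            v *= beta2; v += (1 - beta2) * (g * g)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(self.dtype)

    @staticmethod
    def bce(prob, y) -> float:
        p = np.clip(np.asarray(prob, dtype=np.float64), 1e-7, 1 - 1e-7)
        y = np.asarray(y, dtype=np.float64)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}
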