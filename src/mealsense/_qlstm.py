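"""LSTM encoder-decoder with per-step quantile heads, in pure numpy.

Forward pass, backpropagation through time and Adam are implemented directly:
the network is small (64 cells, 4-step decoder) and trains on desk-scale data
in minutes on one CPU, so a dedicated deep-learning framework is unnecessary.

Architecture: an encoder LSTM consumes (glucose, insulin, carbs) per step; its
final (h, c) state initialises a decoder LSTM that consumes exogenous
(insulin, carbs) per step; a shared linear layer maps each decoder hidden
state to one output per quantile head.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


#: training dtype; single precision doubles BLAS throughput on one CPU and is
#: ample for pinball-loss optimisation
DTYPE = np.float32


def init_weights(enc_dim: int, dec_dim: int, hidden: int, n_heads: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform initialisation; forget-gate biases start at +1."""
    def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, shape).astype(DTYPE)

    h = hidden
    w = {
        "enc_Wx": glorot(enc_dim, 4 * h, (enc_dim, 4 * h)),
        "enc_Wh": glorot(h, 4 * h, (h, 4 * h)),
        "enc_b": np.zeros(4 * h, dtype=DTYPE),
        "dec_Wx": glorot(dec_dim, 4 * h, (dec_dim, 4 * h)),
        "dec_Wh": glorot(h, 4 * h, (h, 4 * h)),
        "dec_b": np.zeros(4 * h, dtype=DTYPE),
        "head_W": glorot(h, n_heads, (h, n_heads)),
        "head_b": np.zeros(n_heads, dtype=DTYPE),
    }
    w["enc_b"][h:2 * h] = 1.0  # forget gate
    w["dec_b"][h:2 * h] = 1.0
    return w


def _lstm_run(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray,
              h0: np.ndarray, c0: np.ndarray, keep_cache: bool):
    """Run an LSTM over x [B,T,D]; returns hidden states and optional cache."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    zx = x @ Wx + b           # [B,T,4H] input projections, batched once
    hs = np.empty((B, T, H), dtype=x.dtype)
    h, c = h0, c0
    cache = {k: np.empty((B, T, H), dtype=x.dtype) for k in ("i", "f", "g", "o", "c_prev", "tc")} \
        if keep_cache else None
    for t in range(T):
        z = zx[:, t] + h @ Wh
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        if keep_cache:
            cache["i"][:, t] = i
            cache["f"][:, t] = f
            cache["g"][:, t] = g
            cache["o"][:, t] = o
            cache["c_prev"][:, t] = c
            cache["tc"][:, t] = tc
        h = o * tc
        hs[:, t] = h
        c = c_new
    return hs, h, c, cache


def forward(w: dict, xe: np.ndarray, xd: np.ndarray, keep_cache: bool = False):
    """Full forward pass.

    xe: [B, Te, enc_dim] encoder inputs; xd: [B, Td, dec_dim] decoder inputs.
    Returns predictions [B, Td, n_heads] and (if requested) the cache needed
    for :func:`backward`.
    """
    B = xe.shape[0]
    H = w["enc_Wh"].shape[0]
    h0 = np.zeros((B, H), dtype=xe.dtype)
    c0 = np.zeros((B, H), dtype=xe.dtype)
    ehs, h, c, ecache = _lstm_run(xe, w["enc_Wx"], w["enc_Wh"], w["enc_b"], h0, c0, keep_cache)
    dhs, _, _, dcache = _lstm_run(xd, w["dec_Wx"], w["dec_Wh"], w["dec_b"], h, c, keep_cache)
    y = dhs @ w["head_W"] + w["head_b"]
    cache = None
    if keep_cache:
        cache = {"xe": xe, "xd": xd, "ehs": ehs, "dhs": dhs,
                 "ecache": ecache, "dcache": dcache, "h_enc": h, "c_enc": c}
    return y, cache


def _lstm_backward(x: np.ndarray, hs: np.ndarray, h0: np.ndarray,
                   Wx: np.ndarray, Wh: np.ndarray, cache: dict,
                   dH_out: np.ndarray | None,
                   dh_final: np.ndarray, dc_final: np.ndarray):
    """BPTT through one LSTM layer; returns parameter grads and d(h0), d(c0)."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    dZ = np.empty((B, T, 4 * H), dtype=x.dtype)
    dh, dc = dh_final.copy(), dc_final.copy()
    i, f, g, o = cache["i"], cache["f"], cache["g"], cache["o"]
    c_prev, tc = cache["c_prev"], cache["tc"]
    for t in range(T - 1, -1, -1):
        if dH_out is not None:
            dh = dh + dH_out[:, t]
        it, ft, gt, ot = i[:, t], f[:, t], g[:, t], o[:, t]
        tct = tc[:, t]
        do = dh * tct
        dcf = dc + dh * ot * (1.0 - tct * tct)
        di = dcf * gt
        dg = dcf * it
        df = dcf * c_prev[:, t]
        dc = dcf * ft
        dZ[:, t, :H] = di * it * (1.0 - it)
        dZ[:, t, H:2 * H] = df * ft * (1.0 - ft)
        dZ[:, t, 2 * H:3 * H] = dg * (1.0 - gt * gt)
        dZ[:, t, 3 * H:] = do * ot * (1.0 - ot)
        dh = dZ[:, t] @ Wh.T
    h_prev = np.concatenate([h0[:, None, :], hs[:, :-1, :]], axis=1)
    dZf = dZ.reshape(B * T, 4 * H)
    grads = {
        "Wx": x.reshape(B * T, -1).T @ dZf,
        "Wh": h_prev.reshape(B * T, H).T @ dZf,
        "b": dZf.sum(axis=0),
    }
    return grads, dh, dc


def pinball_loss_and_dy(y_true: np.ndarray, y_pred: np.ndarray,
                        taus: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean multitask pinball loss and its gradient w.r.t. predictions.

    y_true: [B, Td]; y_pred: [B, Td, Q]; taus: [Q].  The per-quantile losses
    are averaged over batch and steps, then averaged uniformly over quantiles.
    """
    diff = y_true[:, :, None] - y_pred           # [B,Td,Q]
    tau = taus[None, None, :]
    loss_el = np.where(diff > 0, tau * diff, (tau - 1.0) * diff)
    B, Td, Q = y_pred.shape
    loss = float(loss_el.mean(axis=(0, 1)).mean())
    scale = 1.0 / (B * Td * Q)
    dy = np.where(diff > 0, -tau, (1.0 - tau)) * scale
    return loss, dy


def backward(w: dict, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of the scalar loss w.r.t. every weight, given dL/dy."""
    dhs = cache["dhs"]
    B, Td, H = dhs.shape
    grads: dict[str, np.ndarray] = {}
    grads["head_W"] = dhs.reshape(B * Td, H).T @ dy.reshape(B * Td, -1)
    grads["head_b"] = dy.sum(axis=(0, 1))
    dH_dec = dy @ w["head_W"].T
    zero = np.zeros((B, H), dtype=dhs.dtype)
    g_dec, dh_enc, dc_enc = _lstm_backward(
        cache["xd"], dhs, cache["h_enc"], w["dec_Wx"], w["dec_Wh"],
        cache["dcache"], dH_dec, zero, zero)
    grads["dec_Wx"], grads["dec_Wh"], grads["dec_b"] = g_dec["Wx"], g_dec["Wh"], g_dec["b"]
    h0 = np.zeros((B, H), dtype=dhs.dtype)
    g_enc, _, _ = _lstm_backward(
        cache["xe"], cache["ehs"], h0, w["enc_Wx"], w["enc_Wh"],
        cache["ecache"], None, dh_enc, dc_enc)
    grads["enc_Wx"], grads["enc_Wh"], grads["enc_b"] = g_enc["Wx"], g_enc["Wh"], g_enc["b"]
    return grads


def clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        factor = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= factor


class Adam:
    """Adam optimiser over a dict of weight arrays."""

    def __init__(self, weights: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            weights[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
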