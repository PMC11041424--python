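"""Minimal NumPy neural-network core: masked LSTM, dense layers, Adam.

Implements exactly the pieces the embedding backbone and the fatigue heads
need — a 2-layer masked LSTM with recurrent and inter-layer dropout, dense
layers, the triplet hinge loss with its embedding gradients, softmax
cross-entropy, and the Adam optimizer — with hand-written backward passes.
All forward/backward code is vectorised over the batch; gradients are
verified against finite differences in the test suite.

Conventions: parameters live in plain dicts name -> ndarray; dropout is
"inverted" (activations scaled by 1/(1-p) at train time) so inference needs
no rescaling; masked timesteps carry hidden and cell state through
unchanged, so the final hidden state is the state at the last valid step.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# initialisers


def glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def init_lstm_params(rng: np.random.Generator, d_in: int, d_hidden: int) -> dict:
    """Glorot input weights, orthogonal recurrent weights, forget bias 1."""
    b = np.zeros(4 * d_hidden)
    b[d_hidden : 2 * d_hidden] = 1.0
    U = np.concatenate([orthogonal(rng, d_hidden) for _ in range(4)], axis=1)
    return {"W": glorot(rng, (d_in, 4 * d_hidden)), "U": U, "b": b}


def init_dense_params(rng: np.random.Generator, d_in: int, d_out: int) -> dict:
    return {"W": glorot(rng, (d_in, d_out)), "b": np.zeros(d_out)}


# ---------------------------------------------------------------------------
# masked LSTM layer


def lstm_forward(params: dict, X: np.ndarray, mask: np.ndarray, rdrop_mask=None):
    """Run a masked LSTM over X (B, T, D); returns (H, cache).

    H (B, T, Dh) holds post-mask hidden states; because masked steps carry
    state through, ``H[:, -1]`` is the hidden state at each sequence's last
    valid step.  ``rdrop_mask`` (B, Dh), if given, is a fixed per-sequence
    inverted-dropout mask applied to the recurrent input (Gal-style
    recurrent dropout).
    """
    W, U, b = params["W"], params["U"], params["b"]
    B, T, _ = X.shape
    H_dim = U.shape[0]
    h = np.zeros((B, H_dim))
    c = np.zeros((B, H_dim))
    Hs = np.empty((B, T, H_dim))
    steps = []
    XW = X @ W + b  # (B, T, 4H): input contribution precomputed
    for t in range(T):
        m = mask[:, t][:, None]
        h_prev, c_prev = h, c
        h_drop = h_prev * rdrop_mask if rdrop_mask is not None else h_prev
        a = XW[:, t] + h_drop @ U
        i = sigmoid(a[:, :H_dim])
        f = sigmoid(a[:, H_dim : 2 * H_dim])
        g = np.tanh(a[:, 2 * H_dim : 3 * H_dim])
        o = sigmoid(a[:, 3 * H_dim :])
        c_new = f * c_prev + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        c = m * c_new + (1.0 - m) * c_prev
        h = m * h_new + (1.0 - m) * h_prev
        Hs[:, t] = h
        steps.append((h_prev, c_prev, h_drop, i, f, g, o, c_new, tc, m))
    cache = (X, mask, rdrop_mask, steps, params)
    return Hs, cache


def lstm_backward(cache, dHs: np.ndarray | None = None, dh_last: np.ndarray | None = None):
    """Backprop through `lstm_forward`.

    ``dHs`` (B, T, Dh) are per-step output gradients (may be None);
    ``dh_last`` (B, Dh) is an extra gradient on the final hidden state.
    Returns (dX, grads dict).
    """
    X, mask, rdrop_mask, steps, params = cache
    W, U = params["W"], params["U"]
    B, T, D = X.shape
    H_dim = U.shape[0]
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros_like(params["b"])
    dX = np.zeros_like(X)
    dh = np.zeros((B, H_dim)) if dh_last is None else dh_last.copy()
    dc = np.zeros((B, H_dim))
    for t in range(T - 1, -1, -1):
        if dHs is not None:
            dh = dh + dHs[:, t]
        h_prev, c_prev, h_drop, i, f, g, o, c_new, tc, m = steps[t]
        dh_new = dh * m
        dh_prev = dh * (1.0 - m)
        dc_new = dc * m
        dc_prev = dc * (1.0 - m)
        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
        df = dc_new * c_prev
        di = dc_new * g
        dg = dc_new * i
        dc_prev = dc_prev + dc_new * f
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dW += X[:, t].T @ da
        dU += h_drop.T @ da
        db += da.sum(axis=0)
        dX[:, t] = da @ W.T
        dh_rec = da @ U.T
        if rdrop_mask is not None:
            dh_rec = dh_rec * rdrop_mask
        dh = dh_prev + dh_rec
        dc = dc_prev
    return dX, {"W": dW, "U": dU, "b": db}


# ---------------------------------------------------------------------------
# dense layer


def dense_forward(params: dict, X: np.ndarray, relu: bool = True):
    Z = X @ params["W"] + params["b"]
    A = np.maximum(Z, 0.0) if relu else Z
    return A, (X, Z, relu, params)


def dense_backward(cache, dA: np.ndarray):
    X, Z, relu, params = cache
    dZ = dA * (Z > 0) if relu else dA
    grads = {"W": X.T @ dZ, "b": dZ.sum(axis=0)}
    return dZ @ params["W"].T, grads


# ---------------------------------------------------------------------------
# l2 normalisation (unit-hypersphere embeddings for metric losses)


def l2norm_forward(E: np.ndarray):
    norms = np.maximum(np.linalg.norm(E, axis=1, keepdims=True), _EPS)
    Y = E / norms
    return Y, (Y, norms)


def l2norm_backward(cache, dY: np.ndarray) -> np.ndarray:
    Y, norms = cache
    return (dY - Y * (Y * dY).sum(axis=1, keepdims=True)) / norms


def standardize_forward(E: np.ndarray):
    """Centre the batch and divide by its RMS radius (one scalar scale).

    Used inside metric losses: removes the two degenerate descent
    directions of the raw hinge (global shrinkage and common-mode drift)
    while preserving the cloud's shape, so the loss can only improve by
    rearranging points relative to each other.
    """
    C = E - E.mean(axis=0, keepdims=True)
    s = max(float(np.sqrt((C * C).sum(axis=1).mean())), _EPS)
    return C / s, (C, s)


def standardize_backward(cache, dY: np.ndarray) -> np.ndarray:
    C, s = cache
    n = C.shape[0]
    dC = dY / s - C * (dY * C).sum() / (n * s**3)
    return dC - dC.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# losses


def triplet_hinge(
    E: np.ndarray, margin: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Triplet hinge loss max(0, d_AP - d_AN + margin) on stacked embeddings.

    ``E`` has shape (3B, D), laid out as B anchors, then B positives, then
    B negatives.  Distances are plain (non-squared) Euclidean.  Returns
    (mean loss, dE, per-triplet losses).
    """
    n = E.shape[0] // 3
    A, P, N = E[:n], E[n : 2 * n], E[2 * n :]
    ap = A - P
    an = A - N
    d_ap = np.sqrt(np.maximum((ap * ap).sum(axis=1), 0.0))
    d_an = np.sqrt(np.maximum((an * an).sum(axis=1), 0.0))
    losses = np.maximum(0.0, d_ap - d_an + margin)
    active = (losses > 0).astype(float)[:, None]
    u_ap = ap / np.maximum(d_ap, _EPS)[:, None]
    u_an = an / np.maximum(d_an, _EPS)[:, None]
    dE = np.zeros_like(E)
    dE[:n] = active * (u_ap - u_an) / n
    dE[n : 2 * n] = -active * u_ap / n
    dE[2 * n :] = active * u_an / n
    return float(losses.mean()), dE, losses


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over integer labels; returns (loss, dlogits, probs)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -float(np.log(np.maximum(probs[np.arange(n), y], _EPS)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n, probs


# ---------------------------------------------------------------------------
# optimiser


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, lr: float = 0.005, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def params_checksum(params_tree) -> float:
    """Deterministic scalar fingerprint of a (possibly nested) param dict."""
    total = 0.0
    if isinstance(params_tree, dict):
        for k in sorted(params_tree):
            total += params_checksum(params_tree[k])
    else:
        a = np.asarray(params_tree)
        total = float(a.sum() + (a * a).sum() * 0.5)
    return total
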