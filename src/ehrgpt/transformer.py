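"""Minimal decoder-only transformer in NumPy.

Pre-norm GPT blocks (LayerNorm → causal multi-head self-attention →
residual; LayerNorm → GELU MLP → residual), learned positional
embeddings, untied output head, hand-written backward pass and Adam.
Deliberately small: the corpora this package targets have vocabularies of
a few hundred tokens and sequences of a few hundred positions, where a
2-layer model trains on one CPU core in minutes.

All randomness (init, dropout, batch order) flows through explicit
``numpy.random.Generator`` objects, so identically seeded trainings are
bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np


def gelu(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    c = math.sqrt(2.0 / math.pi)
    x2 = x * x
    t = np.tanh(c * x * (1.0 + 0.044715 * x2))
    return 0.5 * x * (1.0 + t), (x, x2, t)


def gelu_backward(dy: np.ndarray, cache: tuple) -> np.ndarray:
    x, x2, t = cache
    c = math.sqrt(2.0 / math.pi)
    du = 0.5 * x * (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x2)
    return dy * (0.5 * (1.0 + t) + du)


def layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray,
              eps: float = 1e-5) -> tuple[np.ndarray, tuple]:
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def layernorm_backward(dy: np.ndarray, cache: tuple):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class TransformerLM:
    """Causal language model over integer token ids."""

    def __init__(self, vocab_size: int, context_window: int, n_layers: int,
                 n_heads: int, hidden_dim: int, dropout: float = 0.0,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if hidden_dim % n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.context_window = context_window
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.hidden_dim = hidden_dim
        self.dropout = float(dropout)
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)
        D = hidden_dim
        s = 0.02

        def W(*shape):
            return (rng.standard_normal(shape) * s).astype(dtype)

        def zeros(*shape):
            return np.zeros(shape, dtype=dtype)

        def ones(*shape):
            return np.ones(shape, dtype=dtype)

        p: dict[str, np.ndarray] = {
            "wte": W(vocab_size, D),
            "wpe": W(context_window, D),
            "lnf_g": ones(D), "lnf_b": zeros(D),
            "Whead": W(D, vocab_size), "bhead": zeros(vocab_size),
        }
        for l in range(n_layers):
            p[f"ln1_g{l}"] = ones(D)
            p[f"ln1_b{l}"] = zeros(D)
            p[f"Wqkv{l}"] = W(D, 3 * D)
            p[f"bqkv{l}"] = zeros(3 * D)
            p[f"Wo{l}"] = W(D, D)
            p[f"bo{l}"] = zeros(D)
            p[f"ln2_g{l}"] = ones(D)
            p[f"ln2_b{l}"] = zeros(D)
            p[f"W1{l}"] = W(D, 4 * D)
            p[f"b1{l}"] = zeros(4 * D)
            p[f"W2{l}"] = W(4 * D, D)
            p[f"b2{l}"] = zeros(D)
        self.params = p

    # ------------------------------------------------------------------
    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.n_heads
        return x.reshape(B, T, H, D // H).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: np.ndarray) -> np.ndarray:
        B, H, T, Dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * Dh)

    def forward(self, idx: np.ndarray, *, train: bool = False,
                dropout_rng: np.random.Generator | None = None,
                need_cache: bool = False, collect_attention: bool = False):
        """Run the model.

        Returns ``(logits, hidden, attentions, cache)`` where ``hidden``
        is the post-final-LayerNorm states (B,T,D), ``attentions`` the
        per-layer head-resolved attention matrices when requested, and
        ``cache`` the activation record needed for :meth:`backward`.
        """
        idx = np.asarray(idx)
        if idx.ndim == 1:
            idx = idx[None, :]
        B, T = idx.shape
        if T > self.context_window:
            raise ValueError(f"sequence length {T} exceeds context window")
        p = self.params
        H, D = self.n_heads, self.hidden_dim
        Dh = D // H
        drop = self.dropout if train else 0.0

        x = p["wte"][idx] + p["wpe"][:T][None, :, :]
        mask = np.triu(np.full((T, T), -1e9, dtype=self.dtype), k=1)[None, None, :, :]
        cache: dict = {"idx": idx, "T": T, "layers": []}
        attns: list[np.ndarray] = []

        for l in range(self.n_layers):
            lc: dict = {"x_in": x}
            h1, lc["ln1"] = layernorm(x, p[f"ln1_g{l}"], p[f"ln1_b{l}"])
            lc["h1"] = h1
            qkv = h1 @ p[f"Wqkv{l}"] + p[f"bqkv{l}"]
            q, k, v = np.split(qkv, 3, axis=-1)
            q, k, v = map(self._split_heads, (q, k, v))  # (B,H,T,Dh)
            S = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(Dh)) + mask
            A = softmax(S)
            y = A @ v
            ym = self._merge_heads(y)
            att_out = ym @ p[f"Wo{l}"] + p[f"bo{l}"]
            if drop > 0.0:
                m = ((dropout_rng.random(att_out.shape) >= drop) / (1.0 - drop)
                     ).astype(self.dtype)
                att_out = att_out * m
                lc["drop1"] = m
            x = x + att_out
            lc.update(q=q, k=k, v=v, A=A, ym=ym, x_mid=x)
            if collect_attention:
                attns.append(A)

            h2, lc["ln2"] = layernorm(x, p[f"ln2_g{l}"], p[f"ln2_b{l}"])
            lc["h2"] = h2
            z = h2 @ p[f"W1{l}"] + p[f"b1{l}"]
            a, lc["gelu"] = gelu(z)
            lc["a"] = a
            mlp_out = a @ p[f"W2{l}"] + p[f"b2{l}"]
            if drop > 0.0:
                m = ((dropout_rng.random(mlp_out.shape) >= drop) / (1.0 - drop)
                     ).astype(self.dtype)
                mlp_out = mlp_out * m
                lc["drop2"] = m
            x = x + mlp_out
            cache["layers"].append(lc)

        hidden, cache["lnf"] = layernorm(x, p["lnf_g"], p["lnf_b"])
        cache["hidden"] = hidden
        logits = hidden @ p["Whead"] + p["bhead"]
        return logits, hidden, (attns if collect_attention else None), (
            cache if need_cache else None)

    # ------------------------------------------------------------------
    def loss_and_grads(self, idx: np.ndarray, targets: np.ndarray,
                       loss_mask: np.ndarray,
                       dropout_rng: np.random.Generator | None = None):
        """Mean next-token cross-entropy over masked positions + gradients."""
        logits, _, _, cache = self.forward(
            idx, train=self.dropout > 0.0, dropout_rng=dropout_rng,
            need_cache=True)
        B, T, V = logits.shape
        probs = softmax(logits)
        loss_mask = loss_mask.astype(self.dtype)
        n = max(int(loss_mask.sum()), 1)
        rows = np.arange(B)[:, None], np.arange(T)[None, :]
        logp = np.log(probs[rows[0], rows[1], targets] + 1e-12)
        loss = float(-(logp * loss_mask).sum() / n)

        dlogits = probs.copy()
        dlogits[rows[0], rows[1], targets] -= 1.0
        dlogits *= (loss_mask / n)[:, :, None]
        grads = self.backward(dlogits, cache)
        return loss, grads

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        g: dict[str, np.ndarray] = {}
        hidden = cache["hidden"]
        B, T, D = hidden.shape
        Dh = D // self.n_heads

        g["Whead"] = hidden.reshape(-1, D).T @ dlogits.reshape(-1, dlogits.shape[-1])
        g["bhead"] = dlogits.sum((0, 1))
        dhidden = dlogits @ p["Whead"].T
        dx, g["lnf_g"], g["lnf_b"] = layernorm_backward(dhidden, cache["lnf"])

        for l in reversed(range(self.n_layers)):
            lc = cache["layers"][l]
            # MLP branch
            dmlp = dx.copy()
            if "drop2" in lc:
                dmlp = dmlp * lc["drop2"]
            g[f"W2{l}"] = lc["a"].reshape(-1, lc["a"].shape[-1]).T @ dmlp.reshape(-1, D)
            g[f"b2{l}"] = dmlp.sum((0, 1))
            da = dmlp @ p[f"W2{l}"].T
            dz = gelu_backward(da, lc["gelu"])
            g[f"W1{l}"] = lc["h2"].reshape(-1, D).T @ dz.reshape(-1, dz.shape[-1])
            g[f"b1{l}"] = dz.sum((0, 1))
            dh2 = dz @ p[f"W1{l}"].T
            dx_mid, g[f"ln2_g{l}"], g[f"ln2_b{l}"] = layernorm_backward(dh2, lc["ln2"])
            dx = dx + dx_mid  # residual

            # attention branch
            datt = dx.copy()
            if "drop1" in lc:
                datt = datt * lc["drop1"]
            g[f"Wo{l}"] = lc["ym"].reshape(-1, D).T @ datt.reshape(-1, D)
            g[f"bo{l}"] = datt.sum((0, 1))
            dym = datt @ p[f"Wo{l}"].T
            dy = self._split_heads(dym)  # (B,H,T,Dh)
            A, q, k, v = lc["A"], lc["q"], lc["k"], lc["v"]
            dA = dy @ v.transpose(0, 1, 3, 2)
            dv = A.transpose(0, 1, 3, 2) @ dy
            dS = A * (dA - (dA * A).sum(-1, keepdims=True))
            dS *= 1.0 / math.sqrt(Dh)
            dq = dS @ k
            dk = dS.transpose(0, 1, 3, 2) @ q
            dqkv = np.concatenate(
                [self._merge_heads(t) for t in (dq, dk, dv)], axis=-1)
            g[f"Wqkv{l}"] = lc["h1"].reshape(-1, D).T @ dqkv.reshape(-1, dqkv.shape[-1])
            g[f"bqkv{l}"] = dqkv.sum((0, 1))
            dh1 = dqkv @ p[f"Wqkv{l}"].T
            dx_in, g[f"ln1_g{l}"], g[f"ln1_b{l}"] = layernorm_backward(dh1, lc["ln1"])
            dx = dx + dx_in  # residual

        # embeddings
        g["wte"] = np.zeros_like(p["wte"])
        np.add.at(g["wte"], cache["idx"], dx)
        g["wpe"] = np.zeros_like(p["wpe"])
        g["wpe"][:T] = dx.sum(0)
        return g

    # ------------------------------------------------------------------
    def state_bytes(self) -> bytes:
        """Canonical byte serialization of all weights (for hashing)."""
        parts = []
        for k in sorted(self.params):
            parts.append(k.encode())
            parts.append(np.ascontiguousarray(self.params[k]).tobytes())
        return b"".join(parts)


class Adam:
    """Adam with bias correction; state keyed like the parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
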