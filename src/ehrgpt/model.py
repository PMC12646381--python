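"""Training and decoding API around the NumPy transformer.

The model is trained with the standard next-token objective: the mean
negative log-likelihood of each token given its prefix under causal
masking, PAD positions excluded.  Decoding is greedy (ties broken toward
the lowest token id) and visit-bounded: generation stops when the visit
separator is produced or a token cap is hit.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import asdict, dataclass

import numpy as np

from .sequence import TokenSequence
from .transformer import Adam, TransformerLM, softmax

log = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    vocab_size: int
    context_window: int = 512
    n_layers: int = 2
    n_heads: int = 2
    hidden_dim: int = 128
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")


@dataclass
class TrainConfig:
    learning_rate: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 3
    val_fraction: float = 0.1
    seed: int = 0


class DataError(ValueError):
    pass


def _as_id_lists(corpus) -> list[list[int]]:
    out = []
    for s in corpus:
        out.append(list(s.token_ids) if isinstance(s, TokenSequence) else list(s))
    return out


def _make_batches(seqs: list[list[int]], order: np.ndarray, batch_size: int,
                  pad_id: int):
    chunks = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    yield from _batches_from_chunks(seqs, chunks, pad_id)


def _batches_from_chunks(seqs: list[list[int]], chunks, pad_id: int):
    for chunk_idx in chunks:
        chunk = [seqs[j] for j in chunk_idx]
        T = max(len(s) for s in chunk)
        if T < 2:
            continue
        x = np.full((len(chunk), T - 1), pad_id, dtype=np.int64)
        y = np.full((len(chunk), T - 1), pad_id, dtype=np.int64)
        m = np.zeros((len(chunk), T - 1), dtype=np.float64)
        for r, s in enumerate(chunk):
            L = len(s)
            x[r, :L - 1] = s[:-1]
            y[r, :L - 1] = s[1:]
            m[r, :L - 1] = 1.0
        yield x, y, m


class TrainedModel:
    """A trained checkpoint: network, config, and the vocabulary it binds to."""

    def __init__(self, net: TransformerLM, config: ModelConfig,
                 vocab_hash: str, pad_id: int, sep_id: int):
        self.net = net
        self.config = config
        self.vocab_hash = vocab_hash
        self.pad_id = pad_id
        self.sep_id = sep_id
        self._warned_overlong = False

    # ------------------------------------------------------------------
    def _clip_prefix(self, prefix: list[int]) -> list[int]:
        if len(prefix) > self.config.context_window:
            if not self._warned_overlong:
                log.warning("prefix longer than context window; using last %d tokens",
                            self.config.context_window)
                self._warned_overlong = True
            return prefix[-self.config.context_window:]
        return prefix

    def next_token_distribution(self, prefix: list[int]) -> np.ndarray:
        """P(next token | prefix): non-negative, sums to 1."""
        if len(prefix) < 1:
            raise ValueError("prefix must be non-empty")
        prefix = self._clip_prefix(prefix)
        logits, _, _, _ = self.net.forward(np.asarray(prefix, dtype=np.int64))
        return softmax(logits[0, -1])

    def top_n_candidates(self, prefix: list[int], n: int) -> list[int]:
        """The n most probable next tokens, ties broken by ascending id."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if n > self.config.vocab_size:
            raise ValueError(f"n={n} exceeds vocabulary size")
        probs = self.next_token_distribution(prefix)
        order = np.argsort(-probs, kind="stable")  # stable → lowest id on ties
        return [int(i) for i in order[:n]]

    def generate_visit(self, prefix: list[int],
                       max_visit_tokens: int = 64) -> tuple[list[int], bool]:
        """Greedy-decode one visit; stops at SEP or the token cap.

        Returns ``(tokens, capped)`` with SEP excluded from the tokens.
        """
        out: list[int] = []
        cur = list(prefix)
        for _ in range(max_visit_tokens):
            probs = self.next_token_distribution(cur)
            tok = int(np.argmax(probs))  # argmax picks lowest id on ties
            if tok == self.sep_id:
                return out, False
            out.append(tok)
            cur.append(tok)
        log.info("generate_visit hit the %d-token cap", max_visit_tokens)
        return out, True

    # ------------------------------------------------------------------
    def hidden_states(self, token_ids: list[int]) -> np.ndarray:
        """Final-layer (post-LayerNorm) hidden states, shape (T, D)."""
        _, hidden, _, _ = self.net.forward(
            np.asarray(self._clip_prefix(list(token_ids)), dtype=np.int64))
        return hidden[0]

    def final_attention(self, token_ids: list[int]) -> np.ndarray:
        """Final-layer attention averaged over heads, shape (T, T)."""
        _, _, attns, _ = self.net.forward(
            np.asarray(self._clip_prefix(list(token_ids)), dtype=np.int64),
            collect_attention=True)
        return attns[-1][0].mean(axis=0)

    def input_embedding(self, token_id: int) -> np.ndarray:
        return self.net.params["wte"][token_id].copy()

    def weights_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.net.state_bytes()).hexdigest()

    # ------------------------------------------------------------------
    def save(self, path: str | pathlib.Path) -> None:
        """Single-file checkpoint: weights + config + vocabulary hash."""
        path = pathlib.Path(path)
        meta = {"config": asdict(self.config), "vocab_hash": self.vocab_hash,
                "pad_id": self.pad_id, "sep_id": self.sep_id}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.net.params)

    @classmethod
    def load(cls, path: str | pathlib.Path,
             expected_vocab_hash: str | None = None) -> "TrainedModel":
        with np.load(pathlib.Path(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        cfg = ModelConfig(**meta["config"])
        if expected_vocab_hash is not None and meta["vocab_hash"] != expected_vocab_hash:
            raise ValueError("checkpoint was trained against a different vocabulary")
        net = TransformerLM(cfg.vocab_size, cfg.context_window, cfg.n_layers,
                            cfg.n_heads, cfg.hidden_dim, cfg.dropout)
        net.params = params
        return cls(net, cfg, meta["vocab_hash"], meta["pad_id"], meta["sep_id"])


def train(corpus, mcfg: ModelConfig, tcfg: TrainConfig, *, pad_id: int = 0,
          sep_id: int = 1, vocab_hash: str = "",
          verbose: bool = False) -> tuple[TrainedModel, dict[str, list[float]]]:
    """Train on a tokenized corpus; returns the model and loss history.

    The patient-level train/validation split, parameter init, batch order
    and dropout all derive from the two seeds, so two identically seeded
    trainings produce identical loss histories.  Early stopping restores
    the best-validation-loss weights.
    """
    seqs = _as_id_lists(corpus)
    if not seqs:
        raise DataError("corpus is empty")
    for lineno, s in enumerate(seqs):
        bad = [t for t in s if not 0 <= t < mcfg.vocab_size]
        if bad:
            raise DataError(
                f"corpus line {lineno}: token id {bad[0]} >= vocab_size "
                f"{mcfg.vocab_size}")

    rng = np.random.default_rng(tcfg.seed)
    net = TransformerLM(mcfg.vocab_size, mcfg.context_window, mcfg.n_layers,
                        mcfg.n_heads, mcfg.hidden_dim, mcfg.dropout,
                        rng=np.random.default_rng(mcfg.seed))
    opt = Adam(net.params, lr=tcfg.learning_rate)

    perm = rng.permutation(len(seqs))
    n_val = int(round(len(seqs) * tcfg.val_fraction))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = perm, perm[:0]

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = None
    bad_epochs = 0
    drop_rng = np.random.default_rng(tcfg.seed + 1)

    for epoch in range(tcfg.max_epochs):
        # length-bucketed batches (limits padding waste); batch order shuffled
        order = rng.permutation(train_idx)
        order = order[np.argsort([len(seqs[j]) for j in order], kind="stable")]
        chunks = [order[i:i + tcfg.batch_size]
                  for i in range(0, len(order), tcfg.batch_size)]
        chunks = [chunks[i] for i in rng.permutation(len(chunks))]
        tot, cnt = 0.0, 0
        for x, y, m in _batches_from_chunks(seqs, chunks, pad_id):
            loss, grads = net.loss_and_grads(x, y, m, dropout_rng=drop_rng)
            opt.step(net.params, grads)
            tot += loss * m.sum()
            cnt += m.sum()
        train_loss = tot / max(cnt, 1)
        history["train_loss"].append(float(train_loss))

        if len(val_idx):
            val_loss = evaluate_loss(net, seqs, val_idx, tcfg.batch_size, pad_id)
        else:
            val_loss = train_loss
        history["val_loss"].append(float(val_loss))
        if verbose:
            log.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > tcfg.patience:
                break
    if best_params is not None:
        net.params = best_params
    return TrainedModel(net, mcfg, vocab_hash, pad_id, sep_id), history


def evaluate_loss(net: TransformerLM, seqs: list[list[int]], idx, batch_size: int,
                  pad_id: int) -> float:
    """Mean per-token next-token NLL over the given sequences."""
    tot, cnt = 0.0, 0
    order = np.asarray(idx)
    for x, y, m in _make_batches(seqs, order, batch_size, pad_id):
        logits, _, _, _ = net.forward(x)
        probs = softmax(logits)
        r = np.arange(x.shape[0])[:, None], np.arange(x.shape[1])[None, :]
        logp = np.log(probs[r[0], r[1], y] + 1e-12)
        tot += float(-(logp * m).sum())
        cnt += m.sum()
    return tot / max(cnt, 1)
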