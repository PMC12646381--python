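"""Supervised comparator: frozen backbone, mean-pooled linear probe.

The pretrained transformer acts purely as a feature extractor — its
weights never change — and a single linear head (after dropout) is
trained on mean-pooled final-layer embeddings with Adam at learning rate
1e-4 and class balancing via weighted sampling.  Sensitivity is reported
as TP% at a matched FP% so the probe can be compared with the zero-shot
protocol under equal specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class HeadConfig:
    dropout: float = 0.1
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 32
    val_fraction: float = 0.2
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def extract_embedding(model, token_ids: list[int]) -> np.ndarray:
    """Mean of final-layer hidden states over the sequence positions."""
    if len(token_ids) == 0:
        raise ValueError("cannot embed an empty sequence")
    ids = [t for t in token_ids if t != model.pad_id]
    if not ids:
        raise ValueError("sequence contains only PAD tokens")
    return model.hidden_states(ids).mean(axis=0)


@dataclass
class LinearScorer:
    w: np.ndarray
    b: float

    def scores(self, embeddings: np.ndarray) -> np.ndarray:
        z = embeddings @ self.w + self.b
        return 1.0 / (1.0 + np.exp(-z))


def train_linear_head(embeddings: np.ndarray, labels: np.ndarray,
                      cfg: HeadConfig | None = None
                      ) -> tuple[LinearScorer, dict[str, list[float]]]:
    """Train the binary probe on fixed embeddings.

    Batches are drawn by weighted sampling so expected class frequencies
    are balanced; dropout is applied to the embedding inputs during
    training only.  Early stopping monitors held-out log-loss.
    """
    cfg = cfg or HeadConfig()
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")

    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(int(round(n * cfg.val_fraction)), 2)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(np.unique(y[tr_idx])) < 2:  # tiny inputs: fall back to full data
        tr_idx = perm
        val_idx = perm

    # weighted sampling: inverse class frequency on the training part
    freq = {c: max((y[tr_idx] == c).sum(), 1) for c in classes}
    w_sample = np.array([1.0 / freq[c] for c in y[tr_idx]])
    w_sample /= w_sample.sum()

    D = X.shape[1]
    w = np.zeros(D)
    b = 0.0
    m_w = np.zeros(D); v_w = np.zeros(D); m_b = v_b = 0.0
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def val_loss() -> float:
        z = X[val_idx] @ w + b
        p = 1.0 / (1.0 + np.exp(-z))
        yy = y[val_idx]
        return float(-np.mean(yy * np.log(p + 1e-12) + (1 - yy) * np.log(1 - p + 1e-12)))

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best = np.inf
    best_wb = (w.copy(), b)
    bad = 0
    steps_per_epoch = max(len(tr_idx) // cfg.batch_size, 1)
    for _ in range(cfg.epochs):
        ep_loss = 0.0
        for _ in range(steps_per_epoch):
            take = rng.choice(tr_idx, size=cfg.batch_size, p=w_sample)
            xb = X[take]
            if cfg.dropout > 0:
                mask = (rng.random(xb.shape) >= cfg.dropout) / (1 - cfg.dropout)
                xb = xb * mask
            yb = y[take]
            z = xb @ w + b
            p = 1.0 / (1.0 + np.exp(-z))
            ep_loss += float(-np.mean(
                yb * np.log(p + 1e-12) + (1 - yb) * np.log(1 - p + 1e-12)))
            gz = (p - yb) / len(yb)
            gw = xb.T @ gz
            gb = gz.sum()
            t += 1
            m_w = beta1 * m_w + (1 - beta1) * gw
            v_w = beta2 * v_w + (1 - beta2) * gw * gw
            m_b = beta1 * m_b + (1 - beta1) * gb
            v_b = beta2 * v_b + (1 - beta2) * gb * gb
            c1, c2 = 1 - beta1**t, 1 - beta2**t
            w -= cfg.learning_rate * (m_w / c1) / (np.sqrt(v_w / c2) + eps)
            b -= cfg.learning_rate * (m_b / c1) / (np.sqrt(v_b / c2) + eps)
        history["train_loss"].append(ep_loss / steps_per_epoch)
        vl = val_loss()
        history["val_loss"].append(vl)
        if vl < best - 1e-7:
            best = vl
            best_wb = (w.copy(), b)
            bad = 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    w, b = best_wb
    return LinearScorer(w=w, b=float(b)), history


@dataclass
class MatchedFPResult:
    tp_percent: float
    fp_percent: float
    threshold: float
    fp_target_unreachable: bool = False


def tp_at_matched_fp(scores: np.ndarray, labels: np.ndarray,
                     fp_target_percent: float) -> MatchedFPResult:
    """TP% at the smallest threshold whose FP% ≤ the target.

    Predictions are positive when ``score > threshold``; candidate
    thresholds are the distinct scores plus −inf.  The conservative
    "≤ target" matching never overstates sensitivity at the requested
    specificity; if even FP% = 0 requires excluding every positive (all
    scores tied), TP% at FP% = 0 is returned with a flag.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    candidates = np.concatenate(([-np.inf], np.unique(s)))
    best: MatchedFPResult | None = None
    for thr in candidates:  # ascending; FP% is non-increasing in thr
        pred = s > thr
        fp = 100.0 * int((pred & (y == 0)).sum()) / n_neg
        if fp <= fp_target_percent:
            tp = 100.0 * int((pred & (y == 1)).sum()) / n_pos
            best = MatchedFPResult(tp_percent=tp, fp_percent=fp,
                                   threshold=float(thr))
            break
    if best is None:  # cannot happen: thr = max(s) gives FP = 0
        raise AssertionError("threshold sweep failed")
    if fp_target_percent < best.fp_percent:
        best.fp_target_unreachable = True
    return best
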