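import numpy as np
import pytest

from ehrgpt import (
    GeneratorConfig,
    ModelConfig,
    PrecursorRule,
    TrainConfig,
    build_sequence,
    build_vocabulary,
    generate_cohort,
    train,
)


def small_config(seed: int = 7) -> GeneratorConfig:
    """A fast 80-patient cohort with one deterministic-ish rule."""
    cfg = GeneratorConfig(n_patients=80, visit_count_mean=6.0, seed=seed)
    cfg.code_pools = {
        "diagnosis": [f"D{i:02d}" for i in range(12)],
        "medication": ["R00", "R01", "R02"],
        "procedure": ["P00", "P01"],
        "lab": ["L00", "L01"],
    }
    cfg.default_background_rate = 0.15
    cfg.background_rates = {"D00": 0.5, "D11": 0.0}
    cfg.carrier_fractions = {"D00": 0.5}
    cfg.precursor_rules = [
        PrecursorRule("D00", "D11", probability=0.9, min_lag_days=10,
                      max_lag_days=80)
    ]
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    records, truth = generate_cohort(small_config())
    return records, truth


@pytest.fixture(scope="session")
def small_vocab(small_cohort):
    records, _ = small_cohort
    return build_vocabulary(records)


@pytest.fixture(scope="session")
def small_sequences(small_cohort, small_vocab):
    records, _ = small_cohort
    return [build_sequence(r, small_vocab) for r in records]


@pytest.fixture(scope="session")
def tiny_model(small_vocab, small_sequences):
    """A briefly trained model over the small cohort, for interface tests."""
    mcfg = ModelConfig(vocab_size=len(small_vocab), context_window=256,
                       n_layers=2, n_heads=2, hidden_dim=32, seed=0)
    tcfg = TrainConfig(learning_rate=3e-3, batch_size=16, max_epochs=4,
                       patience=2, seed=0)
    model, history = train(small_sequences, mcfg, tcfg,
                           pad_id=small_vocab.pad_id, sep_id=small_vocab.sep_id,
                           vocab_hash=small_vocab.content_hash())
    return model, history


class ScriptedModel:
    """Test double exposing the decoding interface of a trained model.

    ``table`` maps a prefix tuple to a next-token probability vector;
    prefixes not in the table fall back to ``default``.
    """

    def __init__(self, vocab_size: int, sep_id: int, pad_id: int = 0,
                 table: dict | None = None, default: np.ndarray | None = None,
                 attention: np.ndarray | None = None):
        self.vocab_size = vocab_size
        self.sep_id = sep_id
        self.pad_id = pad_id
        self.table = table or {}
        if default is None:
            default = np.full(vocab_size, 1.0 / vocab_size)
        self.default = default
        self.attention = attention

        class _Cfg:
            pass

        self.config = _Cfg()
        self.config.vocab_size = vocab_size
        self.config.context_window = 512

    def next_token_distribution(self, prefix):
        return np.asarray(self.table.get(tuple(prefix), self.default), dtype=float)

    def top_n_candidates(self, prefix, n):
        probs = self.next_token_distribution(prefix)
        return [int(i) for i in np.argsort(-probs, kind="stable")[:n]]

    def generate_visit(self, prefix, max_visit_tokens=64):
        out, cur = [], list(prefix)
        for _ in range(max_visit_tokens):
            tok = int(np.argmax(self.next_token_distribution(cur)))
            if tok == self.sep_id:
                return out, False
            out.append(tok)
            cur.append(tok)
        return out, True

    def final_attention(self, token_ids):
        T = len(token_ids)
        if self.attention is not None:
            return self.attention[:T, :T]
        return np.tril(np.ones((T, T))) / np.arange(1, T + 1)[:, None]
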