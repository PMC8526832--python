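"""BEHRT-style transformer feature extractor for encounter sequences.

Each encounter token is represented as the sum of four embeddings — code, age,
visit-parity segment, and visit-rank position — followed by a stack of
self-attention layers and a first-position pooling layer (affine + tanh).  The
embedding tables may be deterministic point weights or mean-field Gaussian
posteriors; all attention and feed-forward weights are always deterministic,
so in stochastic mode every bit of weight uncertainty enters through the
embedding layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import (Parameter, Tensor, gelu, layer_norm, matmul,
                       softmax_lastaxis, take_rows, where_const)
from .variational import MeanFieldPosterior

TABLE_NAMES = ("code", "age", "segment", "position")


class SequenceLengthError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    max_seq_len: int = 64
    hidden_size: int = 32
    n_layers: int = 2
    n_heads: int = 2
    intermediate_size: int = 64
    dropout: float = 0.1
    pooled_size: int = 32
    embedding_mode: str = "deterministic"   # or "stochastic"
    vocab_size: int = 120
    n_age_buckets: int = 120                # integer years, one bucket each
    n_segments: int = 2
    max_positions: int = 64
    allow_truncation: bool = False

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.pooled_size > self.hidden_size:
            raise ValueError("pooled_size must not exceed hidden_size")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.embedding_mode not in ("deterministic", "stochastic"):
            raise ValueError("embedding_mode must be 'deterministic' or 'stochastic'")

    def to_dict(self) -> dict:
        return asdict(self)


def paper_config(vocab_size: int, pooled_size: int = 24, **over) -> EncoderConfig:
    """The full-scale configuration: max_len 256, hidden 150, 4 layers,
    6 heads, intermediate 108, dropout 0.29; pooled 24 for GP heads, 150 for
    linear heads."""
    base = dict(
        max_seq_len=256, hidden_size=150, n_layers=4, n_heads=6,
        intermediate_size=108, dropout=0.29, pooled_size=pooled_size,
        vocab_size=vocab_size, max_positions=256,
    )
    base.update(over)
    return EncoderConfig(**base)


def desk_config(vocab_size: int = 120, pooled_size: int = 8, **over) -> EncoderConfig:
    """CPU-testable small configuration: hidden 32, 2 layers, 2 heads, max_len 64."""
    base = dict(
        max_seq_len=64, hidden_size=32, n_layers=2, n_heads=2,
        intermediate_size=64, dropout=0.1, pooled_size=pooled_size,
        vocab_size=vocab_size, max_positions=64,
    )
    base.update(over)
    return EncoderConfig(**base)


class EmbeddingBlock:
    """Four embedding tables, point-valued or mean-field variational."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 init_sd: float = 0.05):
        self.config = config
        h = config.hidden_size
        sizes = {
            "code": config.vocab_size,
            "age": config.n_age_buckets,
            "segment": config.n_segments,
            "position": config.max_positions,
        }
        self.stochastic = config.embedding_mode == "stochastic"
        self.tables: dict[str, Parameter | MeanFieldPosterior] = {}
        for name in TABLE_NAMES:
            init = rng.normal(0.0, 0.02, size=(sizes[name], h))
            if self.stochastic:
                self.tables[name] = MeanFieldPosterior(init, init_sd=init_sd)
            else:
                self.tables[name] = Parameter(init)

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for t in self.tables.values():
            out.extend(t.parameters() if isinstance(t, MeanFieldPosterior) else [t])
        return out

    def posteriors(self) -> list[MeanFieldPosterior]:
        return [t for t in self.tables.values() if isinstance(t, MeanFieldPosterior)]

    def clamp_variance(self, clamped: bool = True) -> None:
        for p in self.posteriors():
            p.clamp_variance(clamped)

    def draw_tables(self, rng: np.random.Generator | None, graph: bool = True
                    ) -> dict[str, Tensor]:
        """One weight draw per table.  Deterministic tables return themselves;
        stochastic tables return a reparameterized sample (graph=True keeps the
        draw differentiable, graph=False uses a plain array)."""
        draw: dict[str, Tensor] = {}
        for name, t in self.tables.items():
            if isinstance(t, MeanFieldPosterior):
                if rng is None:
                    raise ValueError("stochastic embeddings require an rng for a draw")
                draw[name] = t.sample(rng) if graph else Tensor(t.sample_array(rng))
            else:
                draw[name] = t
        return draw

    def mean_tables(self) -> dict[str, Tensor]:
        return {
            name: (t.mean if isinstance(t, MeanFieldPosterior) else t)
            for name, t in self.tables.items()
        }


def embed_sequence(batch: dict[str, np.ndarray], block: EmbeddingBlock,
                   draw: dict[str, Tensor]) -> Tensor:
    """Sum of the four embeddings per encounter: (B, T) index arrays -> (B, T, H)."""
    limits = {
        "code": block.config.vocab_size,
        "age": block.config.n_age_buckets,
        "segment": block.config.n_segments,
        "position": block.config.max_positions,
    }
    keys = {"code": "codes", "age": "ages", "segment": "segments",
            "position": "positions"}
    parts = []
    b, t = batch["codes"].shape
    for name in TABLE_NAMES:
        ids = np.asarray(batch[keys[name]])
        if ids.min() < 0 or ids.max() >= limits[name]:
            raise IndexError(
                f"{name} id out of range [0, {limits[name]}) in embedding lookup"
            )
        parts.append(take_rows(draw[name], ids.reshape(-1)))
    total = parts[0] + parts[1] + parts[2] + parts[3]
    return total.reshape(b, t, block.config.hidden_size)


# ------------------------------------------------------------------ transformer

class _LayerNorm:
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)

    def parameters(self):
        return [self.gamma, self.beta]


def _gelu(x: Tensor) -> Tensor:
    return gelu(x)


def _linear_params(rng, n_in, n_out):
    return (Parameter(rng.normal(0.0, 0.02, size=(n_in, n_out))),
            Parameter(np.zeros(n_out)))


class _EncoderLayer:
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        h = config.hidden_size
        self.config = config
        self.wq, self.bq = _linear_params(rng, h, h)
        self.wk, self.bk = _linear_params(rng, h, h)
        self.wv, self.bv = _linear_params(rng, h, h)
        self.wo, self.bo = _linear_params(rng, h, h)
        self.ln1 = _LayerNorm(h)
        self.w1, self.b1 = _linear_params(rng, h, config.intermediate_size)
        self.w2, self.b2 = _linear_params(rng, config.intermediate_size, h)
        self.ln2 = _LayerNorm(h)

    def parameters(self):
        ps = [self.wq, self.bq, self.wk, self.bk, self.wv, self.bv,
              self.wo, self.bo, self.w1, self.b1, self.w2, self.b2]
        return ps + self.ln1.parameters() + self.ln2.parameters()

    def __call__(self, x: Tensor, mask: np.ndarray, dropout_rng) -> Tensor:
        cfg = self.config
        b, t, h = x.shape
        nh, dh = cfg.n_heads, h // cfg.n_heads

        def split_heads(z: Tensor) -> Tensor:
            return z.reshape(b, t, nh, dh).swapaxes(1, 2)

        q = split_heads(x @ self.wq + self.bq)
        k = split_heads(x @ self.wk + self.bk)
        v = split_heads(x @ self.wv + self.bv)
        scores = matmul(q, k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        # keys at PAD positions are excluded from every query's attention
        scores = where_const(mask[:, None, None, :], scores, -1e9)
        attn = softmax_lastaxis(scores)
        ctx = matmul(attn, v).swapaxes(1, 2).reshape(b, t, h)
        out = ctx @ self.wo + self.bo
        out = _dropout(out, cfg.dropout, dropout_rng)
        x = self.ln1(x + out)
        ff = _gelu(x @ self.w1 + self.b1) @ self.w2 + self.b2
        ff = _dropout(ff, cfg.dropout, dropout_rng)
        return self.ln2(x + ff)


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class TransformerEncoder:
    """Self-attention stack over summed encounter embeddings."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.layers = [_EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.ln_emb = _LayerNorm(config.hidden_size)
        self.pool_w, self.pool_b = _linear_params(
            rng, config.hidden_size, config.pooled_size
        )

    def parameters(self):
        ps = list(self.ln_emb.parameters()) + [self.pool_w, self.pool_b]
        for layer in self.layers:
            ps.extend(layer.parameters())
        return ps

    def encode(self, hidden: Tensor, mask: np.ndarray,
               dropout_rng: np.random.Generator | None = None) -> Tensor:
        """Contextualize a (B, T, H) embedded batch; mask marks real tokens.

        `dropout_rng=None` means eval mode (deterministic, dropout off).
        """
        if hidden.shape[1] > self.config.max_seq_len:
            raise SequenceLengthError(
                f"sequence length {hidden.shape[1]} exceeds max_seq_len "
                f"{self.config.max_seq_len}"
            )
        x = self.ln_emb(hidden)
        x = _dropout(x, self.config.dropout, dropout_rng)
        for layer in self.layers:
            x = layer(x, mask, dropout_rng)
        return x

    def pool_first(self, contextual: Tensor) -> Tensor:
        """tanh-affine projection of position 0: (B, T, H) -> (B, pooled)."""
        if contextual.shape[1] < 1:
            raise ValueError("cannot pool an empty sequence")
        first = contextual[:, 0, :]
        return (first @ self.pool_w + self.pool_b).tanh()


def pool_first(contextual: Tensor, pool_w: Tensor, pool_b: Tensor) -> Tensor:
    """Functional form of first-position pooling (affine + tanh)."""
    if contextual.shape[1] < 1:
        raise ValueError("cannot pool an empty sequence")
    return (contextual[:, 0, :] @ pool_w + pool_b).tanh()


# ---------------------------------------------------------------- batch packing

def pack_batch(records, config: EncoderConfig) -> dict[str, np.ndarray]:
    """Pad a list of PatientRecord to a common length and build index arrays.

    Overlength records raise unless ``config.allow_truncation``; truncation
    keeps the leading CLS plus the most recent ``max_seq_len - 1`` tokens.
    """
    seqs = []
    for rec in records:
        codes, ages, segs, poss = rec.codes, rec.ages, rec.segments, rec.positions
        if len(codes) > config.max_seq_len:
            if not config.allow_truncation:
                raise SequenceLengthError(
                    f"record length {len(codes)} exceeds max_seq_len "
                    f"{config.max_seq_len}; enable allow_truncation to clip"
                )
            keep = config.max_seq_len - 1
            codes = [codes[0]] + codes[-keep:]
            ages = [ages[0]] + ages[-keep:]
            segs = [segs[0]] + segs[-keep:]
            poss = [poss[0]] + poss[-keep:]
        seqs.append((codes, ages, segs, poss, rec.label))
    t_max = max(len(s[0]) for s in seqs)
    b = len(seqs)
    out = {
        "codes": np.zeros((b, t_max), dtype=np.int64),
        "ages": np.zeros((b, t_max), dtype=np.int64),
        "segments": np.zeros((b, t_max), dtype=np.int64),
        "positions": np.zeros((b, t_max), dtype=np.int64),
        "mask": np.zeros((b, t_max), dtype=bool),
        "labels": np.zeros(b, dtype=np.int64),
    }
    for i, (codes, ages, segs, poss, label) in enumerate(seqs):
        n = len(codes)
        out["codes"][i, :n] = codes
        out["ages"][i, :n] = np.clip(ages, 0, config.n_age_buckets - 1)
        out["segments"][i, :n] = segs
        out["positions"][i, :n] = np.clip(poss, 0, config.max_positions - 1)
        out["mask"][i, :n] = True
        out["labels"][i] = label
    return out
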