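"""Model variants, joint ELBO training, and Monte-Carlo predictive inference.

Six variants share one architecture (transformer encoder -> first-position
pooling -> classifier) and differ only in which parameter groups are
stochastic and which classifier sits on top:

========== ===================== =======================
variant    stochastic groups     classifier
========== ===================== =======================
DBGP       embeddings            KISS-GP
BE         embeddings            linear (deterministic)
BO         classifier            linear (mean-field)
BE_BO      embeddings+classifier linear (mean-field)
SPARSE_GP  none                  sparse variational GP
KISS_GP    none                  KISS-GP
========== ===================== =======================

The training objective combines the data term (Bernoulli log-likelihood for
linear heads, the GP classification ELBO data term for GP heads, both scaled
to the full dataset size), the GP variational KL (counted once per epoch
sweep), and the weight-space KL with Blundell minibatch weights.  Inference
draws S weight samples; each draw fixes the stochastic weights, runs the
network, and (for GP heads) marginalizes the latent function, yielding a
per-patient predictive sample set summarized by its mean and std.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Adam, Parameter, Tensor, no_grad
from .encoder import (
    EmbeddingBlock,
    EncoderConfig,
    TransformerEncoder,
    embed_sequence,
    pack_batch,
)
from .gp_head import (
    KissGPHead,
    SparseGPHead,
    latent_to_probability,
    predictive_latent,
    sample_latent_conditional,
    svgp_classification_elbo,
)
from .synthetic_ehr import PatientRecord
from .variational import (
    BayesianLinear,
    PriorSpec,
    bayesian_linear_forward,
    kl_to_prior,
    minibatch_kl_weight,
)


class ModelVariant(str, enum.Enum):
    DBGP = "DBGP"
    BE = "BE"
    BO = "BO"
    BE_BO = "BE_BO"
    SPARSE_GP = "SPARSE_GP"
    KISS_GP = "KISS_GP"


_GP_VARIANTS = {ModelVariant.DBGP, ModelVariant.SPARSE_GP, ModelVariant.KISS_GP}
_STOCH_EMB = {ModelVariant.DBGP, ModelVariant.BE, ModelVariant.BE_BO}
_STOCH_CLS = {ModelVariant.BO, ModelVariant.BE_BO}


@dataclass(frozen=True)
class HeadConfig:
    """Classifier-head settings: 40 inducing points / RBF kernels by default."""

    n_inducing: int = 40
    grid_size: int = 64
    grid_bounds: tuple[float, float] = (-1.1, 1.1)
    prior: PriorSpec = field(default_factory=PriorSpec)
    init_sd: float = 0.05
    expected_pooled_size: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior"] = {"mean": self.prior.mean, "sd": self.prior.sd}
        return d


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    learning_rate: float = 3e-5
    weight_decay: float = 0.01
    epochs: int = 5
    mc_train_draws: int = 1
    seed: int = 0
    split: tuple[float, float, float] = (0.5, 0.2, 0.3)  # train / tune / validation
    init_output_bias: bool = True   # start the classifier at the base rate

    def __post_init__(self):
        if min(self.batch_size, self.epochs + 1, self.mc_train_draws) < 1:
            raise ValueError("training config values must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class PredictiveSummary:
    """Per-patient Monte-Carlo predictive sample set and its summary."""

    patient_id: int
    label: int
    mc_probabilities: np.ndarray
    mean_probability: float
    std_probability: float

    @classmethod
    def from_samples(cls, patient_id: int, label: int, samples: np.ndarray
                     ) -> "PredictiveSummary":
        samples = np.asarray(samples, dtype=float)
        if samples.size > 1 and np.ptp(samples) > 0.0:
            std = float(samples.std(ddof=1))
        else:
            std = 0.0
        return cls(patient_id, int(label), samples,
                   float(samples.mean()), std)


class _DeterministicLinear:
    def __init__(self, in_dim: int, rng: np.random.Generator):
        self.w = Parameter(rng.normal(0.0, 0.02, size=(in_dim,)))
        self.b = Parameter(np.zeros(1))

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, pooled: Tensor) -> Tensor:
        return pooled @ self.w + self.b[0]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class SequenceClassifier:
    """Encoder + classifier assembly for one model variant."""

    def __init__(self, variant: ModelVariant, enc_config: EncoderConfig,
                 head_config: HeadConfig, seed: int = 0):
        variant = ModelVariant(variant)
        if (
            head_config.expected_pooled_size is not None
            and enc_config.pooled_size != head_config.expected_pooled_size
        ):
            raise ValueError(
                f"pooled_size {enc_config.pooled_size} inconsistent with head "
                f"expectation {head_config.expected_pooled_size}"
            )
        mode = "stochastic" if variant in _STOCH_EMB else "deterministic"
        if enc_config.embedding_mode != mode:
            enc_config = EncoderConfig(**{**enc_config.to_dict(),
                                          "embedding_mode": mode})
        self.variant = variant
        self.enc_config = enc_config
        self.head_config = head_config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.embedding = EmbeddingBlock(enc_config, rng, init_sd=head_config.init_sd)
        self.transformer = TransformerEncoder(enc_config, rng)
        p = enc_config.pooled_size
        if variant in (ModelVariant.DBGP, ModelVariant.KISS_GP):
            self.head = KissGPHead(p, grid_size=head_config.grid_size,
                                   grid_bounds=head_config.grid_bounds, rng=rng)
        elif variant is ModelVariant.SPARSE_GP:
            self.head = SparseGPHead(p, n_inducing=head_config.n_inducing, rng=rng)
        elif variant in _STOCH_CLS:
            self.head = BayesianLinear(p, rng, init_sd=head_config.init_sd)
        else:
            self.head = _DeterministicLinear(p, rng)

    # ------------------------------------------------------------- structure
    @property
    def is_gp(self) -> bool:
        return self.variant in _GP_VARIANTS

    def stochastic_groups(self) -> set[str]:
        groups = set()
        if self.variant in _STOCH_EMB:
            groups.add("embeddings")
        if self.variant in _STOCH_CLS:
            groups.add("classifier")
        return groups

    def parameter_group_report(self) -> dict[str, dict]:
        def count(params):
            return int(sum(p.size for p in params))
        report = {
            "embeddings": {
                "stochastic": "embeddings" in self.stochastic_groups(),
                "n_params": count(self.embedding.parameters()),
            },
            "encoder": {"stochastic": False,
                        "n_params": count(self.transformer.parameters())},
            "classifier": {
                "stochastic": "classifier" in self.stochastic_groups(),
                "n_params": count(self.head.parameters()),
            },
        }
        if self.is_gp:
            report["classifier"]["kind"] = self.head.kind + "_gp"
        else:
            report["classifier"]["kind"] = "linear"
        return report

    def parameters(self) -> list[Parameter]:
        return (self.embedding.parameters() + self.transformer.parameters()
                + self.head.parameters())

    def decay_parameters(self) -> list[Parameter]:
        """Weight decay applies to deterministic network weights and
        variational means, never to rho parameters or GP hyperparameters."""
        ps = list(self.transformer.parameters())
        for post in self.embedding.posteriors():
            ps.append(post.mean)
        if not self.embedding.stochastic:
            ps.extend(self.embedding.parameters())
        if isinstance(self.head, _DeterministicLinear):
            ps.extend(self.head.parameters())
        elif isinstance(self.head, BayesianLinear):
            ps.extend(p.mean for p in self.head.posteriors())
        return ps

    def weight_posteriors(self):
        posts = []
        if self.variant in _STOCH_EMB:
            posts.extend(self.embedding.posteriors())
        if self.variant in _STOCH_CLS:
            posts.extend(self.head.posteriors())
        return posts

    def clamp_embedding_variance(self, clamped: bool = True) -> None:
        self.embedding.clamp_variance(clamped)

    def initialize_output_bias(self, log_odds: float) -> None:
        """Start the classifier at the cohort base rate (constant GP mean or
        linear-head bias); standard practice for imbalanced outcomes."""
        if self.is_gp:
            self.head.mean_offset.data[:] = log_odds
        elif isinstance(self.head, BayesianLinear):
            self.head.bias.mean.data[:] = log_odds
        else:
            self.head.b.data[:] = log_odds

    # --------------------------------------------------------------- forward
    def pooled_features(self, batch: dict, draw_rng: np.random.Generator | None,
                        dropout_rng: np.random.Generator | None = None,
                        graph: bool = True) -> Tensor:
        if self.embedding.stochastic and draw_rng is not None:
            tables = self.embedding.draw_tables(draw_rng, graph=graph)
        else:
            tables = self.embedding.mean_tables()
        hidden = embed_sequence(batch, self.embedding, tables)
        ctx = self.transformer.encode(hidden, batch["mask"], dropout_rng)
        return self.transformer.pool_first(ctx)

    def predict_probabilities(self, batch: dict,
                              draw_rng: np.random.Generator | None,
                              sample_latent: bool = False) -> np.ndarray:
        """One predictive sample per patient under one weight draw (eval mode).

        For GP heads the default marginalizes the latent function per draw;
        with ``sample_latent`` each call also draws the inducing-value
        posterior, so the sample behaves as one "independent model" for
        epistemic-band analyses.
        """
        with no_grad():
            pooled = self.pooled_features(batch, draw_rng, dropout_rng=None)
            if self.is_gp:
                if sample_latent:
                    if draw_rng is None:
                        raise ValueError("sample_latent requires an rng")
                    mean, var = sample_latent_conditional(pooled, self.head,
                                                          draw_rng)
                    f = mean + np.sqrt(var) * draw_rng.standard_normal(mean.shape)
                    return np.clip(_sigmoid(f), 1e-12, 1 - 1e-12)
                mean, var = predictive_latent(pooled, self.head)
                return latent_to_probability(mean, var)
            if isinstance(self.head, BayesianLinear):
                if draw_rng is not None:
                    w, b = self.head.sample_draw(draw_rng)
                else:
                    w, b = self.head.weight.mean, self.head.bias.mean
                logit = bayesian_linear_forward(pooled, (w, b))
            else:
                logit = self.head(pooled)
            return _sigmoid(logit.data)


def build_model(variant: ModelVariant | str, enc_config: EncoderConfig,
                head_config: HeadConfig | None = None, seed: int = 0
                ) -> SequenceClassifier:
    """Assemble a variant; exactly the variant's named groups are stochastic."""
    return SequenceClassifier(ModelVariant(variant), enc_config,
                              head_config or HeadConfig(), seed=seed)


# ------------------------------------------------------------------- training

def _bernoulli_nll(logit: Tensor, labels: np.ndarray) -> Tensor:
    """-log p(y|logit) = softplus(logit) - y * logit, summed over the batch."""
    y = Tensor(np.asarray(labels, dtype=float))
    return (logit.softplus() - y * logit).sum()


def training_loss(model: SequenceClassifier, batch: dict, dataset_size: int,
                  batch_index: int, n_batches: int,
                  rng: np.random.Generator,
                  train_mode: bool = True) -> Tensor:
    """Per-datapoint negative joint ELBO estimate for one minibatch.

    total = (N/B) * data-NLL + GP-KL / n_batches + pi_i * weight-KL, divided
    by N so the value reads as an average per-sample loss.  The GP KL thereby
    accumulates to one full count per epoch sweep and the weight KL follows
    the Blundell geometric schedule (whose weights sum to one per epoch).
    """
    labels = batch["labels"]
    b = len(labels)
    dropout_rng = rng if train_mode else None
    pooled = model.pooled_features(batch, draw_rng=rng, dropout_rng=dropout_rng)
    if model.is_gp:
        elbo = svgp_classification_elbo(pooled, labels, model.head, dataset_size)
        # elbo = (N/B) data term - full GP KL; re-scale the KL share so one
        # full KL is counted per epoch sweep
        gp_kl = model.head.kl()
        total = -elbo - gp_kl + gp_kl * (1.0 / n_batches)
    else:
        if isinstance(model.head, BayesianLinear):
            draw = model.head.sample_draw(rng)
            logit = bayesian_linear_forward(pooled, draw)
        else:
            logit = model.head(pooled)
        total = _bernoulli_nll(logit, labels) * (dataset_size / b)
    posts = [p for p in model.weight_posteriors() if not p._clamped]
    if posts:
        pi = minibatch_kl_weight(batch_index, n_batches)
        kl = None
        for p in posts:
            term = kl_to_prior(p, model.head_config.prior)
            kl = term if kl is None else kl + term
        total = total + kl * pi
    out = total * (1.0 / dataset_size)
    if not np.isfinite(out.data):
        raise FloatingPointError(_diagnostics(model))
    return out


def _diagnostics(model: SequenceClassifier) -> str:
    parts = ["non-finite training loss"]
    if model.is_gp:
        ls = np.atleast_1d(model.head.raw_lengthscale.data)
        parts.append(f"raw lengthscale range [{ls.min():.3g}, {ls.max():.3g}]")
    for post in model.weight_posteriors():
        parts.append(f"posterior sd range [{post.sd.min():.3g}, {post.sd.max():.3g}]")
    return "; ".join(parts)


def split_cohort(records: list[PatientRecord], ratios: tuple[float, float, float],
                 seed: int) -> tuple[list[int], list[int], list[int]]:
    """Seeded train / tune / validation index split."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(ratios[0] * len(records)))
    n_tune = int(round(ratios[1] * len(records)))
    return (
        order[:n_train].tolist(),
        order[n_train:n_train + n_tune].tolist(),
        order[n_train + n_tune:].tolist(),
    )


def train(model: SequenceClassifier, records: list[PatientRecord],
          config: TrainingConfig) -> list[float]:
    """Train in place; returns the per-epoch mean loss trace.

    Reproducible under a fixed seed: batch order, weight draws, and dropout
    masks all derive from one seeded generator.  Training aborts if the loss
    diverges past ten times its initial value.
    """
    rng = np.random.default_rng(config.seed)
    if config.init_output_bias and config.epochs > 0:
        current = (model.head.mean_offset.data if model.is_gp else
                   (model.head.bias.mean.data if isinstance(model.head, BayesianLinear)
                    else model.head.b.data))
        if not current.any():   # only if still untouched
            rate = float(np.clip(np.mean([r.label for r in records]),
                                 1e-3, 1 - 1e-3))
            model.initialize_output_bias(float(np.log(rate / (1 - rate))))
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate,
               weight_decay=config.weight_decay,
               decay_params=model.decay_parameters())
    n = len(records)
    trace: list[float] = []
    initial_loss: float | None = None
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        batches = [order[i:i + config.batch_size]
                   for i in range(0, n, config.batch_size)]
        epoch_losses = []
        for bi, idx in enumerate(batches, start=1):
            batch = pack_batch([records[j] for j in idx], model.enc_config)
            loss_val = 0.0
            opt.zero_grad()
            for _draw in range(config.mc_train_draws):
                loss = training_loss(model, batch, n, bi, len(batches), rng)
                loss.backward(np.array(1.0 / config.mc_train_draws))
                loss_val += loss.item() / config.mc_train_draws
            opt.step()
            epoch_losses.append(loss_val)
            if initial_loss is None:
                initial_loss = loss_val
            elif loss_val > 10.0 * abs(initial_loss) + 10.0:
                raise FloatingPointError(
                    f"training diverged: loss {loss_val:.3g} vs initial "
                    f"{initial_loss:.3g}; " + _diagnostics(model)
                )
        trace.append(float(np.mean(epoch_losses)))
    return trace


def train_two_stage(model: SequenceClassifier, records: list[PatientRecord],
                    warm_config: TrainingConfig,
                    fine_config: TrainingConfig | None = None) -> list[float]:
    """Warm-started training for stochastic-embedding variants.

    Stage one trains the deterministic special case (embedding variances
    clamped to zero, no weight KL), which plays the role of pretraining a
    point-weight model; stage two unclamps the variances so the variational
    means start from the trained weights and fine-tunes the full objective,
    typically at the reference learning rate 3e-5.  For variants without
    stochastic embeddings only stage one applies.
    """
    if model.embedding.stochastic:
        model.clamp_embedding_variance(True)
        trace = train(model, records, warm_config)
        model.clamp_embedding_variance(False)
        if fine_config is not None and fine_config.epochs > 0:
            trace += train(model, records, fine_config)
        return trace
    return train(model, records, warm_config)


def desk_training_config(seed: int = 0, epochs: int = 15
                         ) -> tuple[TrainingConfig, TrainingConfig]:
    """CPU-scale optimization recipe used throughout the examples and tests:
    batch 256 at learning rate 3e-3 for the deterministic/warm stage, then a
    short variational fine-tune at the reference rate 3e-5.
    Returns (warm_config, fine_config)."""
    warm = TrainingConfig(batch_size=256, learning_rate=3e-3, epochs=epochs,
                          seed=seed)
    fine = TrainingConfig(batch_size=256, learning_rate=3e-5, epochs=4,
                          seed=seed + 50)
    return warm, fine


# ------------------------------------------------------------------ inference

def mc_predict(model: SequenceClassifier, records: list[PatientRecord],
               n_draws: int = 30, seed: int = 0,
               batch_size: int = 256,
               sample_latent: bool = False) -> list[PredictiveSummary]:
    """Monte-Carlo predictive distributions: one forward pass per weight draw.

    Stochastic variants draw embedding/classifier weights each round;
    deterministic variants produce identical samples (zero predictive std).
    For GP heads each sample is already latent-marginalized via the
    logistic-Gaussian integral.
    """
    if n_draws < 1:
        raise ValueError("need at least one Monte-Carlo draw")
    rng = np.random.default_rng(seed)
    n = len(records)
    samples = np.zeros((n, n_draws))
    sample_latent = sample_latent and model.is_gp
    stochastic = bool(model.stochastic_groups()) or sample_latent
    for s in range(n_draws):
        draw_rng = rng if stochastic else None
        for start in range(0, n, batch_size):
            chunk = records[start:start + batch_size]
            batch = pack_batch(chunk, model.enc_config)
            samples[start:start + len(chunk), s] = model.predict_probabilities(
                batch, draw_rng, sample_latent=sample_latent
            )
    return [
        PredictiveSummary.from_samples(i, records[i].label, samples[i])
        for i in range(n)
    ]


def summaries_to_frame(summaries: list[PredictiveSummary]):
    """Predictions table: patient_id, label, mean_prob, std_prob, sample_*."""
    import pandas as pd

    n_draws = len(summaries[0].mc_probabilities) if summaries else 0
    rows = {
        "patient_id": [s.patient_id for s in summaries],
        "label": [s.label for s in summaries],
        "mean_prob": [s.mean_probability for s in summaries],
        "std_prob": [s.std_probability for s in summaries],
    }
    for k in range(n_draws):
        rows[f"sample_{k:02d}"] = [s.mc_probabilities[k] for s in summaries]
    return pd.DataFrame(rows)


def summaries_from_frame(frame) -> list[PredictiveSummary]:
    for col in ("patient_id", "label", "mean_prob", "std_prob"):
        if col not in frame.columns:
            raise ValueError(f"predictions table is missing column {col!r}")
    sample_cols = sorted(c for c in frame.columns if c.startswith("sample_"))
    out = []
    for _, row in frame.iterrows():
        samples = np.array([row[c] for c in sample_cols]) if sample_cols else \
            np.array([row["mean_prob"]])
        out.append(PredictiveSummary(
            int(row["patient_id"]), int(row["label"]), samples,
            float(row["mean_prob"]), float(row["std_prob"]),
        ))
    return out


# ----------------------------------------------------------------- checkpoint

def _named_arrays(model: SequenceClassifier) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, table in model.embedding.tables.items():
        if model.embedding.stochastic:
            out[f"variational/embedding/{name}/mean"] = table.mean.data
            out[f"variational/embedding/{name}/rho"] = table.rho.data
        else:
            out[f"embedding/{name}"] = table.data
    for i, p in enumerate(model.transformer.parameters()):
        out[f"encoder/param{i:03d}"] = p.data
    head = model.head
    if isinstance(head, (SparseGPHead, KissGPHead)):
        for i, p in enumerate(head.parameters()):
            out[f"gp/param{i:03d}"] = p.data
    elif isinstance(head, BayesianLinear):
        out["variational/classifier/w/mean"] = head.weight.mean.data
        out["variational/classifier/w/rho"] = head.weight.rho.data
        out["variational/classifier/b/mean"] = head.bias.mean.data
        out["variational/classifier/b/rho"] = head.bias.rho.data
    else:
        out["classifier/w"] = head.w.data
        out["classifier/b"] = head.b.data
    return out


def save_checkpoint(model: SequenceClassifier, path: str | Path) -> None:
    """Single .npz archive: config JSON + every weight/posterior array."""
    meta = json.dumps({
        "variant": model.variant.value,
        "encoder": model.enc_config.to_dict(),
        "head": model.head_config.to_dict(),
        "seed": model.seed,
    })
    arrays = _named_arrays(model)
    np.savez(Path(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> SequenceClassifier:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    head_d = meta["head"]
    head = HeadConfig(
        n_inducing=head_d["n_inducing"], grid_size=head_d["grid_size"],
        grid_bounds=tuple(head_d["grid_bounds"]),
        prior=PriorSpec(**head_d["prior"]), init_sd=head_d["init_sd"],
        expected_pooled_size=head_d.get("expected_pooled_size"),
    )
    model = build_model(meta["variant"], EncoderConfig(**meta["encoder"]), head,
                        seed=meta["seed"])
    restored = _named_arrays(model)
    for key, arr in arrays.items():
        restored[key][...] = arr
    return model


def deterministic_twin(model: SequenceClassifier) -> SequenceClassifier:
    """The deterministic-kernel-learning special case of a DBGP model.

    Returns a KISS_GP-variant model whose embedding tables equal the DBGP
    variational means and whose transformer and GP-head weights are copied,
    so it predicts exactly what the DBGP predicts with embedding variances
    clamped to zero.
    """
    if model.variant is not ModelVariant.DBGP:
        raise ValueError("deterministic_twin is defined for the DBGP variant")
    twin = build_model(ModelVariant.KISS_GP, model.enc_config,
                       model.head_config, seed=model.seed)
    for name, table in model.embedding.tables.items():
        twin.embedding.tables[name].data[...] = table.mean.data
    for p_dst, p_src in zip(twin.transformer.parameters(),
                            model.transformer.parameters()):
        p_dst.data[...] = p_src.data
    for p_dst, p_src in zip(twin.head.parameters(), model.head.parameters()):
        p_dst.data[...] = p_src.data
    return twin


def load_pretrained_means(model: SequenceClassifier,
                          checkpoint_path: str | Path) -> None:
    """Transfer hook: initialize embedding means from a saved checkpoint.

    Mirrors the fine-tuning convention of centering variational posteriors at
    pretrained point weights.  Exposed for workflows with a separate
    pretraining stage; not exercised at scale here.
    """
    with np.load(Path(checkpoint_path)) as data:
        for name, table in model.embedding.tables.items():
            for key in (f"embedding/{name}",
                        f"variational/embedding/{name}/mean"):
                if key in data.files:
                    target = table.mean if model.embedding.stochastic else table
                    target.data[...] = data[key]
                    break
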