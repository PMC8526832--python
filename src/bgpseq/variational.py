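"""Mean-field Gaussian variational machinery (Bayes by Backprop).

Each stochastic weight carries an independent Gaussian posterior
q(w) = N(mu, sigma^2) with sigma = softplus(rho), trained against a zero-mean
Gaussian prior by the closed-form KL.  Sampling uses the reparameterization
trick so gradients flow to both mu and rho.  The Blundell minibatch weighting
distributes the KL penalty geometrically across the batches of an epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def inv_softplus(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    return y + np.log(-np.expm1(-y))


@dataclass(frozen=True)
class PriorSpec:
    """Isotropic Gaussian weight prior; the default sd follows the reference
    configuration for this model family (zero mean, 0.374 sd)."""

    mean: float = 0.0
    sd: float = 0.374

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")


class MeanFieldPosterior:
    """Per-weight Gaussian variational parameters for one weight array.

    ``mean`` and ``rho`` are trainable; sd = softplus(rho) > 0 always.  The
    variance can be clamped to zero (``clamp_variance``) to recover the
    deterministic special case exactly, e.g. for deterministic-limit checks.
    """

    def __init__(self, mean: np.ndarray, init_sd: float = 0.05):
        mean = np.asarray(mean, dtype=np.float64)
        self.mean = Parameter(mean.copy())
        self.rho = Parameter(np.full(mean.shape, inv_softplus(init_sd)))
        self._clamped = False

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mean.shape

    @property
    def sd(self) -> np.ndarray:
        if self._clamped:
            return np.zeros(self.shape)
        return softplus(self.rho.data)

    def clamp_variance(self, clamped: bool = True) -> None:
        self._clamped = clamped

    def parameters(self) -> list[Parameter]:
        return [self.mean, self.rho]

    def sample(self, rng: np.random.Generator) -> Tensor:
        """Reparameterized draw mean + softplus(rho) * eps as a graph node."""
        if self._clamped:
            return self.mean + Tensor(np.zeros(self.shape)) * self.rho
        eps = Tensor(rng.standard_normal(self.shape))
        return self.mean + self.rho.softplus() * eps

    def sample_array(self, rng: np.random.Generator) -> np.ndarray:
        """Plain ndarray draw (no graph), for inference-time weight sampling."""
        if self._clamped:
            return self.mean.data.copy()
        return self.mean.data + self.sd * rng.standard_normal(self.shape)


def sample_weights(posterior: MeanFieldPosterior, rng: np.random.Generator) -> Tensor:
    return posterior.sample(rng)


def kl_to_prior(posterior: MeanFieldPosterior, prior: PriorSpec) -> Tensor:
    """Closed-form KL( q || p ) summed over all weights, as a graph scalar.

    KL(N(mu,s^2) || N(m0,s0^2)) = log(s0/s) + (s^2 + (mu-m0)^2)/(2 s0^2) - 1/2.
    """
    if prior.sd <= 0:
        raise ValueError("prior sd must be positive")
    sd = posterior.rho.softplus()
    var = sd * sd
    dmu = posterior.mean - prior.mean
    term = (
        Tensor(np.log(prior.sd)) - sd.log()
        + (var + dmu * dmu) / (2.0 * prior.sd**2)
        - 0.5
    )
    return term.sum()


def gaussian_kl(mu_f: float, sd_f: float, mu_t: float, sd_t: float) -> float:
    """Closed-form KL(N(mu_f, sd_f^2) || N(mu_t, sd_t^2)) in nats."""
    if sd_f <= 0 or sd_t <= 0:
        raise ValueError("standard deviations must be positive")
    return float(
        np.log(sd_t / sd_f) + (sd_f**2 + (mu_f - mu_t) ** 2) / (2.0 * sd_t**2) - 0.5
    )


def minibatch_kl_weight(batch_index: int, n_batches: int) -> float:
    """Blundell geometric KL weight pi_i = 2^(M-i) / (2^M - 1), 1-based index.

    The weights over one epoch sum to one, front-loading the complexity cost
    on early batches.  Computed in log-space so large M does not overflow.
    """
    if not 1 <= batch_index <= n_batches:
        raise ValueError(f"batch_index {batch_index} outside [1, {n_batches}]")
    # 2^(M-i) / (2^M - 1) = 2^(-i) / (1 - 2^-M)
    return float(2.0 ** (-batch_index) / (1.0 - 2.0 ** (-n_batches)))


class BayesianLinear:
    """Linear classifier head with a mean-field posterior over weights and bias."""

    def __init__(self, in_dim: int, rng: np.random.Generator, init_sd: float = 0.05):
        w0 = rng.normal(0.0, 0.02, size=(in_dim,))
        self.weight = MeanFieldPosterior(w0, init_sd=init_sd)
        self.bias = MeanFieldPosterior(np.zeros(1), init_sd=init_sd)

    def posteriors(self) -> list[MeanFieldPosterior]:
        return [self.weight, self.bias]

    def parameters(self) -> list[Parameter]:
        return self.weight.parameters() + self.bias.parameters()

    def sample_draw(self, rng: np.random.Generator) -> tuple[Tensor, Tensor]:
        return self.weight.sample(rng), self.bias.sample(rng)


def bayesian_linear_forward(
    pooled: Tensor, draw: tuple[Tensor, Tensor]
) -> Tensor:
    """Affine map with a drawn weight vector: logit_i = pooled_i . w + b."""
    w, b = draw
    if pooled.shape[-1] != w.shape[0]:
        raise ValueError(
            f"pooled dimension {pooled.shape[-1]} != weight dimension {w.shape[0]}"
        )
    return pooled @ w + b[0]
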