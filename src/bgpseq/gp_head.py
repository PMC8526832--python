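"""Gaussian-process classification heads and their regression-mode oracles.

Four layers of machinery live here:

* plain-NumPy kernel and marginal-likelihood routines (`rbf_kernel`,
  `exact_gp_log_marginal`, `sparse_free_energy`) used as regression-mode
  objectives and as exact oracles for the variational approximations;
* structured kernel interpolation (`kiss_interpolation`, `kiss_q_ff`):
  inducing points on a grid, cross-covariances by local linear interpolation;
* trainable classification heads (`SparseGPHead`, `KissGPHead`) with a
  whitened variational Gaussian over inducing values (prior N(0, I)), a
  Bernoulli likelihood through a logistic transfer, and Gauss-Hermite
  quadrature for the expected log-likelihood;
* `latent_to_probability`, the logistic-Gaussian integral used at inference.

The KISS head in a d-dimensional pooled space uses an additive kernel — one
1-D grid per latent dimension, with the per-dimension latent GPs summed —
because a tensor-product grid is infeasible beyond a few dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .autodiff import Parameter, Tensor, cholesky, take_rows, tri_solve
from .variational import inv_softplus

JITTER = 1e-6
GH_ORDER = 20

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(GH_ORDER)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(np.pi)


# ----------------------------------------------------------------- kernel math

@dataclass(frozen=True)
class KernelParams:
    """RBF kernel hyperparameters; `noise_sd` only enters regression mode."""

    lengthscale: float | np.ndarray = 1.0
    outputscale: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if np.any(np.asarray(self.lengthscale) <= 0):
            raise ValueError("lengthscale must be strictly positive")
        if self.outputscale <= 0 or self.noise_sd <= 0:
            raise ValueError("outputscale and noise_sd must be strictly positive")


@dataclass(frozen=True)
class InducingPointSet:
    """Free inducing locations (sparse-GP) — an M x d array."""

    points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "points", np.atleast_2d(np.asarray(self.points, dtype=float)))
        if self.points.shape[0] < 1:
            raise ValueError("need at least one inducing point")

    @property
    def m(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class InterpolationWeights:
    """Sparse interpolation rows: two adjacent grid indices + convex weights."""

    indices: np.ndarray   # (n, 2) int
    weights: np.ndarray   # (n, 2), rows sum to 1, non-negative

    def dense(self, n_grid: int) -> np.ndarray:
        w = np.zeros((self.indices.shape[0], n_grid))
        rows = np.arange(self.indices.shape[0])[:, None]
        np.add.at(w, (rows, self.indices), self.weights)
        return w


def rbf_kernel(x: np.ndarray, z: np.ndarray, params: KernelParams) -> np.ndarray:
    """K[i, j] = outputscale * exp(-0.5 ||x_i - z_j||^2 / lengthscale^2)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if x.shape[1] != z.shape[1]:
        raise ValueError("x and z must share dimensionality")
    ls = np.broadcast_to(np.asarray(params.lengthscale, dtype=float), (x.shape[1],))
    xs, zs = x / ls, z / ls
    d2 = (
        (xs**2).sum(axis=1)[:, None]
        + (zs**2).sum(axis=1)[None, :]
        - 2.0 * xs @ zs.T
    )
    return params.outputscale * np.exp(-0.5 * np.maximum(d2, 0.0))


def exact_gp_log_marginal(x: np.ndarray, y: np.ndarray, params: KernelParams) -> float:
    """Dense GP-regression log marginal likelihood (small-n oracle).

    log p(y) = -1/2 y^T K_n^-1 y - 1/2 log|K_n| - N/2 log(2 pi),
    K_n = K_ff + noise_sd^2 I.
    """
    y = np.asarray(y, dtype=float).ravel()
    k_n = rbf_kernel(x, x, params) + params.noise_sd**2 * np.eye(len(y))
    try:
        cf = sla.cho_factor(k_n, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "K_n is singular; consider adding jitter to the diagonal"
        ) from exc
    alpha = sla.cho_solve(cf, y)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * len(y) * np.log(2.0 * np.pi))


def sparse_free_energy(
    x: np.ndarray, y: np.ndarray, inducing: InducingPointSet, params: KernelParams
) -> float:
    """Variational free energy (Titsias bound) for sparse GP regression.

    F = -1/2 y^T Q_n^-1 y - 1/2 log|Q_n| - N/2 log(2 pi) - t / (2 noise^2),
    Q_n = Q_ff + noise^2 I, Q_ff = K_uf^T K_uu^-1 K_uf,
    t = Tr(K_ff - Q_ff) >= 0.  Always a lower bound on the exact log marginal.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    k_uu = rbf_kernel(inducing.points, inducing.points, params)
    k_uf = rbf_kernel(inducing.points, x, params)
    # adaptive jitter: start tiny so that U == X reproduces the exact bound
    l_uu = None
    for jitter in (1e-12, 1e-9, 1e-6, 1e-4):
        try:
            l_uu = np.linalg.cholesky(k_uu + jitter * np.eye(inducing.m))
            break
        except np.linalg.LinAlgError:
            continue
    if l_uu is None:
        warnings.warn("K_uu ill-conditioned even with jitter", RuntimeWarning)
        raise np.linalg.LinAlgError("K_uu not positive definite")
    a = sla.solve_triangular(l_uu, k_uf, lower=True)       # M x n
    q_n = a.T @ a + params.noise_sd**2 * np.eye(n)
    cf = sla.cho_factor(q_n, lower=True)
    alpha = sla.cho_solve(cf, y)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    trace_resid = float(n * params.outputscale - (a**2).sum())
    return float(
        -0.5 * y @ alpha
        - 0.5 * logdet
        - 0.5 * n * np.log(2.0 * np.pi)
        - trace_resid / (2.0 * params.noise_sd**2)
    )


# ----------------------------------------------------- structured interpolation

def kiss_interpolation(x: np.ndarray, grid: np.ndarray) -> InterpolationWeights:
    """Local linear interpolation of 1-D inputs onto adjacent grid points.

    The weight on the nearer grid point is proportional to the distance to the
    farther one, so k(x, u_j) ~ w k(u_a, u_j) + (1-w) k(u_b, u_j).  Inputs
    outside the grid are clamped to the boundary with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must contain >= 2 strictly increasing points")
    if np.any(x < grid[0]) or np.any(x > grid[-1]):
        warnings.warn("inputs outside the inducing grid were clamped", RuntimeWarning)
        x = np.clip(x, grid[0], grid[-1])
    idx = np.clip(np.searchsorted(grid, x, side="right") - 1, 0, grid.size - 2)
    left, right = grid[idx], grid[idx + 1]
    t = (x - left) / (right - left)
    indices = np.stack([idx, idx + 1], axis=1)
    weights = np.stack([1.0 - t, t], axis=1)
    return InterpolationWeights(indices=indices, weights=weights)


def kiss_q_ff(x: np.ndarray, grid: np.ndarray, params: KernelParams) -> np.ndarray:
    """Structured-kernel-interpolation covariance Q_ff ~ W^T K_uu W.

    Built from the sparse interpolation rows and the small grid Gram matrix;
    the dense n x n data kernel is never formed.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    interp = kiss_interpolation(x, grid)
    w = interp.dense(grid.size)                       # n x G
    k_uu = rbf_kernel(grid[:, None], grid[:, None], params)
    return w @ k_uu @ w.T


def latent_to_probability(mean, variance):
    """E[logistic(f)] under N(mean, variance), by Gauss-Hermite quadrature."""
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < 0):
        raise ValueError("latent variance must be non-negative")
    z = mean[..., None] + np.sqrt(2.0 * variance)[..., None] * _GH_NODES
    p = (_GH_WEIGHTS * _sigmoid_np(z)).sum(axis=-1)
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def _sigmoid_np(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ----------------------------------------------------------- trainable heads

def _expected_bernoulli_loglik(mean_t: Tensor, var_t: Tensor, labels: np.ndarray) -> Tensor:
    """Per-point E_q[log Bernoulli(y | logistic(f))] by Gauss-Hermite quadrature.

    log p(y|f) = y f - softplus(f); the expectation is a weighted sum over
    quadrature nodes f_k = mu + sqrt(2 v) t_k, differentiable in mu and v.
    """
    y = Tensor(np.asarray(labels, dtype=float).reshape(-1, 1))
    scale = (var_t.clip_min(1e-12) * 2.0).sqrt()
    z = mean_t.reshape(-1, 1) + scale.reshape(-1, 1) * Tensor(_GH_NODES[None, :])
    ll = y * z - z.softplus()
    return (ll * Tensor(_GH_WEIGHTS[None, :])).sum(axis=1)


class _WhitenedVariational:
    """Whitened variational Gaussian q(v) = N(m, C C^T) with N(0, I) prior."""

    def __init__(self, m: int, rng: np.random.Generator):
        self.mean = Parameter(np.zeros(m))
        # raw lower-triangular factor; diagonal passed through softplus
        self.raw_factor = Parameter(
            np.diag(np.full(m, inv_softplus(1.0))) + 0.0 * rng.standard_normal((m, m))
        )
        self._tril_mask = np.tril(np.ones((m, m)), k=-1)
        self._diag_mask = np.eye(m)

    def factor(self) -> Tensor:
        raw = self.raw_factor
        return raw * Tensor(self._tril_mask) + raw.softplus() * Tensor(self._diag_mask)

    def kl(self) -> Tensor:
        """KL(N(m, CC^T) || N(0, I)) = (|m|^2 + |C|_F^2 - M - 2 sum log diag C)/2."""
        c = self.factor()
        m = self.mean
        n = m.shape[0]
        didx = (np.arange(n), np.arange(n))
        logdiag = self.raw_factor[didx].softplus().log()
        return 0.5 * (
            (m * m).sum() + (c * c).sum() - float(n) - 2.0 * logdiag.sum()
        )

    def parameters(self) -> list[Parameter]:
        return [self.mean, self.raw_factor]


class SparseGPHead:
    """Sparse variational GP classifier with free inducing points.

    Whitened parameterization: with L = chol(K_uu) and A = K_fu L^-T, the
    latent marginal at x has mean A m and variance
    k(x,x) - |A|^2_row + |A C|^2_row.
    """

    kind = "sparse"

    def __init__(self, in_dim: int, n_inducing: int = 40,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.n_inducing = n_inducing
        self.inducing = Parameter(rng.uniform(-0.8, 0.8, size=(n_inducing, in_dim)))
        self.raw_lengthscale = Parameter(np.array(inv_softplus(1.0)))
        self.raw_outputscale = Parameter(np.array(inv_softplus(1.0)))
        self.mean_offset = Parameter(np.zeros(1))   # constant mean function
        self.variational = _WhitenedVariational(n_inducing, rng)

    def parameters(self) -> list[Parameter]:
        return [self.inducing, self.raw_lengthscale, self.raw_outputscale,
                self.mean_offset] + self.variational.parameters()

    def hyper_parameters(self) -> list[Parameter]:
        return self.parameters()

    def _kernel(self, x: Tensor, z: Tensor) -> Tensor:
        ls = self.raw_lengthscale.softplus()
        os_ = self.raw_outputscale.softplus()
        xs = x / ls
        zs = z / ls
        d2 = (
            (xs * xs).sum(axis=1).reshape(-1, 1)
            + (zs * zs).sum(axis=1).reshape(1, -1)
            - 2.0 * (xs @ zs.T)
        )
        return os_ * (d2.clip_min(0.0) * -0.5).exp()

    def latent(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        """Per-point latent marginal (mean, variance) of q(f)."""
        k_uu = self._kernel(self.inducing, self.inducing)
        l_uu = cholesky(k_uu, jitter=JITTER)
        k_uf = self._kernel(self.inducing, pooled)     # M x B
        a_t = tri_solve(l_uu, k_uf)                    # M x B == A^T
        a = a_t.T                                      # B x M
        mean = a @ self.variational.mean + self.mean_offset[0]
        c = self.variational.factor()
        ac = a @ c
        prior_var = self.raw_outputscale.softplus()
        var = prior_var - (a * a).sum(axis=1) + (ac * ac).sum(axis=1)
        return mean, var.clip_min(1e-10)

    def kl(self) -> Tensor:
        return self.variational.kl()


class KissGPHead:
    """KISS-GP classifier: additive 1-D grid kernels across pooled dimensions.

    Each latent dimension d carries its own 1-D inducing grid, RBF kernel, and
    whitened variational Gaussian; the per-dimension latent GPs are summed.
    Because the cross-covariance K_fu ~ W K_uu under local linear
    interpolation, the whitened projector is simply A_d = W_d L_d, where W_d
    has two non-zeros per row.  Pooled features come from a tanh layer, so a
    fixed grid over [-1.1, 1.1] always covers the inputs.
    """

    kind = "kiss"

    def __init__(self, in_dim: int, grid_size: int = 64,
                 grid_bounds: tuple[float, float] = (-1.1, 1.1),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.grid = np.linspace(grid_bounds[0], grid_bounds[1], grid_size)
        self.h = self.grid[1] - self.grid[0]
        self.raw_lengthscale = Parameter(np.full(in_dim, inv_softplus(0.4)))
        self.raw_outputscale = Parameter(np.full(in_dim, inv_softplus(1.0 / in_dim)))
        self.mean_offset = Parameter(np.zeros(1))   # constant mean function
        self.variational = [_WhitenedVariational(grid_size, rng) for _ in range(in_dim)]
        g = self.grid
        self._grid_d2 = (g[:, None] - g[None, :]) ** 2

    def parameters(self) -> list[Parameter]:
        ps = [self.raw_lengthscale, self.raw_outputscale, self.mean_offset]
        for v in self.variational:
            ps.extend(v.parameters())
        return ps

    def hyper_parameters(self) -> list[Parameter]:
        return self.parameters()

    def _grid_chol(self, dim: int) -> Tensor:
        ls = self.raw_lengthscale[dim].softplus()
        os_ = self.raw_outputscale[dim].softplus()
        k_uu = os_ * (Tensor(self._grid_d2) * (-0.5) / (ls * ls)).exp()
        return cholesky(k_uu, jitter=JITTER)

    def _interp(self, x_d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.grid[0], self.grid[-1]
        if np.any(x_d < lo) or np.any(x_d > hi):
            warnings.warn("pooled features outside KISS grid were clamped",
                          RuntimeWarning)
        xc = np.clip(x_d, lo, hi)
        idx = np.clip(((xc - lo) / self.h).astype(int), 0, self.grid.size - 2)
        return idx, xc

    def latent(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        mean_total: Tensor | None = None
        var_total: Tensor | None = None
        for d in range(self.in_dim):
            x_d = pooled[:, d]
            idx, _ = self._interp(x_d.data)
            left = Tensor(self.grid[idx])
            t = (x_d - left) * (1.0 / self.h)
            l_d = self._grid_chol(d)
            a = (
                (1.0 - t).reshape(-1, 1) * take_rows(l_d, idx)
                + t.reshape(-1, 1) * take_rows(l_d, idx + 1)
            )
            v = self.variational[d]
            mean_d = a @ v.mean
            ac = a @ v.factor()
            var_d = (
                self.raw_outputscale[d].softplus()
                - (a * a).sum(axis=1)
                + (ac * ac).sum(axis=1)
            )
            mean_total = mean_d if mean_total is None else mean_total + mean_d
            var_total = var_d if var_total is None else var_total + var_d
        return mean_total + self.mean_offset[0], var_total.clip_min(1e-10)

    def kl(self) -> Tensor:
        total = self.variational[0].kl()
        for v in self.variational[1:]:
            total = total + v.kl()
        return total


def svgp_classification_elbo(
    pooled: Tensor,
    labels: np.ndarray,
    head,
    dataset_size: int,
) -> Tensor:
    """Stochastic variational classification ELBO for a minibatch.

    (N / B) * sum_i E_q[log Bernoulli(y_i | logistic(f_i))] - KL(q(u) || N(0, I)),
    with the expectation by Gauss-Hermite quadrature over each latent marginal.
    """
    labels = np.asarray(labels)
    if not set(np.unique(labels)).issubset({0, 1}):
        raise ValueError("labels must be binary")
    mean, var = head.latent(pooled)
    ell = _expected_bernoulli_loglik(mean, var, labels)
    scale = dataset_size / float(labels.shape[0])
    return ell.sum() * scale - head.kl()


def predictive_latent(pooled: Tensor | np.ndarray, head) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode latent marginal (mean, variance) arrays for a pooled batch."""
    x = pooled if isinstance(pooled, Tensor) else Tensor(np.atleast_2d(pooled))
    mean, var = head.latent(x.detach())
    return mean.data.copy(), var.data.copy()


def sample_latent_conditional(pooled: Tensor | np.ndarray, head,
                              rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Latent conditional (mean, variance) under one inducing-posterior draw.

    Samples the whitened inducing values v ~ N(m, CC^T) — the GP head's
    "weights" — and returns the conditional latent marginal given that draw:
    mean A v + offset and the residual conditional variance.  Each call thus
    yields one "independent model" whose own predictive distribution is still
    marginalized downstream; spread across calls isolates the epistemic
    (inducing-posterior) component.
    """
    x = pooled if isinstance(pooled, Tensor) else Tensor(np.atleast_2d(pooled))
    x = x.detach()

    if isinstance(head, SparseGPHead):
        k_uu = head._kernel(head.inducing, head.inducing)
        l_uu = cholesky(k_uu, jitter=JITTER)
        k_uf = head._kernel(head.inducing, x)
        a = tri_solve(l_uu, k_uf).data.T                # B x M
        c = head.variational.factor().data
        m = head.variational.mean.data
        v = m + c @ rng.standard_normal(m.shape[0])
        mean = a @ v + head.mean_offset.data[0]
        resid = np.maximum(
            np.logaddexp(0, head.raw_outputscale.data) - (a**2).sum(axis=1), 0.0
        )
        return mean, resid

    if isinstance(head, KissGPHead):
        mean = np.zeros(x.shape[0])
        var = np.zeros(x.shape[0])
        for d in range(head.in_dim):
            x_d = x.data[:, d]
            idx, xc = head._interp(x_d)
            t = (xc - head.grid[idx]) / head.h
            l_d = head._grid_chol(d).data
            a = (1.0 - t)[:, None] * l_d[idx] + t[:, None] * l_d[idx + 1]
            v_state = head.variational[d]
            c = v_state.factor().data
            m = v_state.mean.data
            v = m + c @ rng.standard_normal(m.shape[0])
            mean += a @ v
            os_d = np.logaddexp(0, head.raw_outputscale.data[d])
            var += np.maximum(os_d - (a**2).sum(axis=1), 0.0)
        return mean + head.mean_offset.data[0], var

    raise TypeError(f"not a GP head: {type(head).__name__}")
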