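"""Model and prior types, and the complete-data log posterior.

The model has two hidden layers.  Observed expression decomposes as

    y_bi = L f_bi + gamma_b + eps_bi,      eps_bi ~ N_p(0, T_b^{-1})

with a p × d loading matrix L shared across batches, additive batch effects
gamma_b, and diagonal batch precisions T_b (multiplicative batch effects).
The latent factors follow a Gaussian mixture with a spot-specific precision
scale,

    f_bi | c_bi = k, omega_bi ~ N_d(mu_k, omega_bi^{-1} Lambda^{-1}),
    omega_bi ~ Gamma(nu_omega/2, nu_omega/2),

so that marginally f_bi | c_bi = k is multivariate Student-t with nu_omega
degrees of freedom — robust to expression outliers.  The labels c follow a
Potts prior on the combined neighborhood graph, and sparsity of L is induced
by a spike-and-slab prior whose slab is the nonlocal pMOM density (vanishing
at zero, so retained loadings are bounded away from 0).

``log_joint`` evaluates the complete-data log posterior up to the (fixed)
Potts normalizing constant; it is the objective tracked by inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .graph import NeighborGraph

_LOG_2PI = np.log(2.0 * np.pi)


class NumericalError(RuntimeError):
    """A quantity that must be finite or positive-definite is not."""


@dataclass
class Hyperparams:
    """Fixed hyperparameters.

    ``eta`` is the per-batch Potts smoothness; ``lambda0``/``lambda1`` are
    the spike/slab variances of the loading prior; the remaining entries are
    the weak conjugate priors on cluster means (mu_mu, Sigma_mu), the shared
    factor precision (n_Lambda, Sigma_Lambda), the factor scale mixing
    (nu_omega) and noise precision (nu_t) Gamma priors, and the Beta prior
    (alpha_p, beta_p) on per-factor inclusion probabilities.
    """

    d: int
    q: int
    eta: np.ndarray | float = 1.0
    mu_mu: np.ndarray | None = None
    sigma_mu: float = 100.0
    n_Lambda: float | None = None
    sigma_Lambda: float = 100.0
    nu_omega: float = 2.0
    nu_t: float = 1.0
    lambda0: float = 0.015
    lambda1: float = 0.871
    alpha_p: float = 1.0
    beta_p: float = 1.0

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.n_Lambda is None:
            self.n_Lambda = float(self.d)  # least informative Wishart df
        if self.n_Lambda <= self.d - 1:
            raise ValueError("n_Lambda must exceed d - 1")
        if self.mu_mu is None:
            self.mu_mu = np.zeros(self.d)  # data are centered
        for name in ("sigma_mu", "sigma_Lambda", "nu_omega", "nu_t", "lambda0", "lambda1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def eta_vector(self, n_batches: int) -> np.ndarray:
        eta = np.asarray(self.eta, dtype=float)
        if eta.ndim == 0:
            eta = np.full(n_batches, float(eta))
        if eta.shape != (n_batches,):
            raise ValueError(f"eta must be scalar or length {n_batches}")
        if np.any(eta < 0):
            raise ValueError("eta must be non-negative")
        return eta


@dataclass
class ModelParams:
    """Point estimates of all model parameters."""

    L: np.ndarray          # p × d loadings
    gamma: np.ndarray      # p × B additive batch effects
    T: np.ndarray          # p × B diagonal noise precisions (positive)
    mu: np.ndarray         # d × q cluster means
    Lambda: np.ndarray     # d × d shared factor precision (SPD)
    incl: np.ndarray       # p × d posterior slab-inclusion probabilities
    p_slab: np.ndarray     # length-d per-factor slab probabilities

    def validate(self) -> None:
        if np.any(self.T <= 0):
            raise ValueError("T must be strictly positive")
        if np.any((self.incl < 0) | (self.incl > 1)):
            raise ValueError("incl must lie in [0, 1]")
        if np.any((self.p_slab < 0) | (self.p_slab > 1)):
            raise ValueError("p_slab must lie in [0, 1]")
        chol_spd(self.Lambda)  # raises if not SPD

    def copy(self) -> "ModelParams":
        return ModelParams(
            L=self.L.copy(), gamma=self.gamma.copy(), T=self.T.copy(),
            mu=self.mu.copy(), Lambda=self.Lambda.copy(),
            incl=self.incl.copy(), p_slab=self.p_slab.copy(),
        )


@dataclass
class LatentState:
    """Per-spot latent variables, rows aligned to the global spot index."""

    f: np.ndarray          # n × d factor scores
    omega: np.ndarray      # n positive precision scales
    c: np.ndarray          # n labels in 0..q-1
    f_precisions: np.ndarray | None = field(default=None, repr=False)

    def validate(self, q: int) -> None:
        if np.any(self.omega <= 0):
            raise ValueError("omega must be positive")
        if np.any((self.c < 0) | (self.c >= q)):
            raise ValueError("labels out of range")

    def copy(self) -> "LatentState":
        return LatentState(
            f=self.f.copy(), omega=self.omega.copy(), c=self.c.copy(),
            f_precisions=None if self.f_precisions is None else self.f_precisions.copy(),
        )


def chol_spd(M: np.ndarray, jitter: float = 1e-8):
    """Cholesky factor of M, adding ``jitter * I`` once on failure."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise NumericalError("matrix not positive definite after jitter") from exc


def logdet_spd(M: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(chol_spd(M)))))


# ---------------------------------------------------------------------------
# Potts prior


def potts_log_prior_unnorm(
    c: np.ndarray, graph: NeighborGraph, eta: np.ndarray, batch: np.ndarray
) -> float:
    """Unnormalized Potts log prior: sum over spots i of
    eta_{b(i)} * #{neighbors j of i with c_j = c_i}.

    Written per spot, each unordered edge is counted from both endpoints —
    a concordant intra-batch edge contributes 2 * eta_b, a concordant
    cross-batch edge eta_{b(i)} + eta_{b(j)}.  The normalizing constant
    (fixed, since eta is fixed) is omitted.
    """
    c = np.asarray(c)
    if np.any(c < 0):
        raise ValueError("labels must be non-negative")
    indptr, indices = graph.neighbor_lists()
    total = 0.0
    # vectorized over the CSR structure
    src = np.repeat(np.arange(graph.n), np.diff(indptr))
    same = c[src] == c[indices]
    total = float(np.sum(eta[batch[src]] * same))
    return total


# ---------------------------------------------------------------------------
# loading prior densities


def pmom_slab_logpdf(l, lambda1: float):
    """Log density of the nonlocal product-moment (pMOM) slab:
    (l^2 / lambda1) * N(l; 0, lambda1).  Integrates to one; vanishes at 0."""
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    l = np.asarray(l, dtype=float)
    with np.errstate(divide="ignore"):
        out = (
            2.0 * np.log(np.abs(l))
            - np.log(lambda1)
            - 0.5 * (np.log(2.0 * np.pi * lambda1) + l**2 / lambda1)
        )
    return out if out.ndim else float(out)


def loading_prior_logpdf(l, incl_prob, lambda0: float, lambda1: float):
    """Log of the spike-and-slab mixture (1-pi) N(0, lambda0) + pi pMOM(lambda1)."""
    l = np.asarray(l, dtype=float)
    pi = np.asarray(incl_prob, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("incl_prob must lie in [0, 1]")
    log_spike = -0.5 * (np.log(2.0 * np.pi * lambda0) + l**2 / lambda0)
    log_slab = pmom_slab_logpdf(l, lambda1)
    with np.errstate(divide="ignore"):
        a = np.log1p(-pi) + log_spike
        b = np.log(pi) + np.asarray(log_slab)
    out = np.logaddexp(a, b)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# complete-data log posterior


def _gamma_logpdf(x, shape: float, rate: float):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def log_joint(
    Y: np.ndarray,
    batch: np.ndarray,
    graph: NeighborGraph,
    params: ModelParams,
    latent: LatentState,
    hyper: Hyperparams,
) -> float:
    """Complete-data log posterior, up to the Potts normalizing constant.

    Terms: Gaussian observation model, Gaussian mixture over factors with
    Gamma-distributed precision scales, the Potts label prior, and all
    parameter priors (gamma, T, mu, Lambda, the spike-and-slab loading
    mixture with per-factor slab weight p_slab, and the Beta prior on
    p_slab).  Raises ``NumericalError`` naming the offending component if
    any term is non-finite.
    """
    n, p = Y.shape
    d, q = hyper.d, hyper.q
    B = params.gamma.shape[1]
    eta = hyper.eta_vector(B)

    terms: dict[str, float] = {}

    # (i) observation: y ~ N(L f + gamma_b, T_b^{-1}), T_b diagonal
    resid = Y - latent.f @ params.L.T - params.gamma[:, batch].T
    logT = np.log(params.T)  # p × B
    counts = np.bincount(batch, minlength=B).astype(float)
    terms["observation"] = float(
        -0.5 * n * p * _LOG_2PI
        + 0.5 * float(logT.sum(axis=0) @ counts)
        - 0.5 * float(np.sum(params.T[:, batch].T * resid**2))
    )

    # (ii) factors: f | c=k, omega ~ N(mu_k, omega^{-1} Lambda^{-1})
    ld_Lambda = logdet_spd(params.Lambda)
    dev = latent.f - params.mu[:, latent.c].T
    maha = np.einsum("ij,jk,ik->i", dev, params.Lambda, dev)
    if np.any(maha < -1e-9):
        raise NumericalError("factor term: Lambda produced negative Mahalanobis distance")
    maha = np.maximum(maha, 0.0)
    terms["factors"] = float(
        -0.5 * n * d * _LOG_2PI
        + 0.5 * n * ld_Lambda
        + 0.5 * d * np.sum(np.log(latent.omega))
        - 0.5 * np.sum(latent.omega * maha)
    )

    # (iii) omega ~ Gamma(nu_omega/2, nu_omega/2)
    a = hyper.nu_omega / 2.0
    terms["omega_prior"] = float(np.sum(_gamma_logpdf(latent.omega, a, a)))

    # (iv) Potts prior on labels
    terms["potts"] = potts_log_prior_unnorm(latent.c, graph, eta, batch)

    # (v) parameter priors
    terms["gamma_prior"] = float(
        -0.5 * params.gamma.size * _LOG_2PI - 0.5 * np.sum(params.gamma**2)
    )
    at = hyper.nu_t / 2.0
    terms["T_prior"] = float(np.sum(_gamma_logpdf(params.T, at, at)))
    dev_mu = params.mu - hyper.mu_mu[:, None]
    terms["mu_prior"] = float(
        -0.5 * q * d * _LOG_2PI
        - 0.5 * q * d * np.log(hyper.sigma_mu)
        - 0.5 * np.sum(dev_mu**2) / hyper.sigma_mu
    )
    terms["Lambda_prior"] = float(
        stats.wishart.logpdf(
            params.Lambda, df=hyper.n_Lambda, scale=hyper.sigma_Lambda * np.eye(d)
        )
    )
    terms["loading_prior"] = float(
        np.sum(loading_prior_logpdf(params.L, params.p_slab[None, :], hyper.lambda0, hyper.lambda1))
    )
    # Beta(alpha_p, beta_p) on p_slab; zero under the default uniform prior
    ps = np.clip(params.p_slab, 1e-12, 1.0 - 1e-12)
    terms["p_slab_prior"] = float(
        np.sum(stats.beta.logpdf(ps, hyper.alpha_p, hyper.beta_p))
    )

    for name, val in terms.items():
        if not np.isfinite(val):
            raise NumericalError(f"log_joint component {name!r} is not finite ({val})")
    return float(sum(terms.values()))
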