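"""EM inference with iterated-conditional-modes label updates.

The fit alternates conditional updates of the latent variables (factor
scores f, precision scales omega, labels c) with conditional-mode updates
of the parameters (loadings L with spike/slab inclusion, batch effects
gamma and T, cluster means mu and shared precision Lambda), tracking the
complete-data log posterior of :func:`stadia.model_core.log_joint`.

All latent and parameter updates are point-valued (hard EM / ICM): each
step maximizes — or, for omega, takes the conjugate posterior mean of — its
slice of the tracked objective, which keeps the coordinate-ascent contract
checkable step by step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .data_io import MultiSliceDataset, ValidationError
from .graph import NeighborGraph
from .model_core import (
    Hyperparams,
    LatentState,
    ModelParams,
    NumericalError,
    chol_spd,
    loading_prior_logpdf,
    log_joint,
)

logger = logging.getLogger(__name__)

T_INIT_CLIP = (1e-4, 1e4)
T_FLOOR = 1e-6


@dataclass
class FitResult:
    """Outcome of an EM fit."""

    params: ModelParams
    latent: LatentState
    objective_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def domains(self) -> np.ndarray:
        """Per-spot spatial-domain labels (0-based)."""
        return self.latent.c

    @property
    def embedding(self) -> np.ndarray:
        """Batch-corrected low-dimensional representation (n × d)."""
        return self.latent.f


# ---------------------------------------------------------------------------
# initialization


def _deterministic_svd(Y: np.ndarray):
    """SVD with the sign of each right singular vector fixed (largest-
    magnitude element positive) so initialization is reproducible."""
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    for j in range(Vt.shape[0]):
        m = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, m] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U, s, Vt


def _solve_factors_ls(Y: np.ndarray, L: np.ndarray) -> np.ndarray:
    G = L.T @ L
    return np.linalg.solve(G, L.T @ Y.T).T


def init_state(
    Y: np.ndarray,
    batch: np.ndarray,
    hyper: Hyperparams,
    seed: int,
    fixed_L: np.ndarray | None = None,
) -> tuple[ModelParams, LatentState]:
    """Deterministic (given ``seed``) moment-based initialization.

    Loadings and scores come from the pooled PCA of the centered data (or a
    least-squares projection when ``fixed_L`` is supplied), labels from
    k-means on the scores, batch effects and noise precisions from the
    residual moments, and the cluster moments from the labeled scores.
    """
    n, p = Y.shape
    d, q = hyper.d, hyper.q
    if q > n:
        raise ValidationError(f"q={q} exceeds the number of spots n={n}")
    if d >= p:
        raise ValidationError(f"d={d} must be smaller than p={p}")

    if fixed_L is not None:
        L = np.asarray(fixed_L, dtype=float)
        f = _solve_factors_ls(Y, L)
    else:
        U, s, Vt = _deterministic_svd(Y)
        L = Vt[:d].T.copy()
        f = U[:, :d] * s[:d]

    # the factor marginals are heavy-tailed (Student-t with few df), and
    # k-means is not outlier-robust: cluster on winsorized scores so stray
    # extreme spots cannot capture whole centroids.  Labels only; the
    # scores themselves stay untouched.
    lo = np.percentile(f, 1, axis=0)
    hi = np.percentile(f, 99, axis=0)
    km = KMeans(n_clusters=q, random_state=int(seed), n_init=10)
    c = km.fit_predict(np.clip(f, lo, hi)).astype(np.int64)

    B = int(batch.max()) + 1
    resid = Y - f @ L.T
    gamma = np.zeros((p, B))
    T = np.ones((p, B))
    for b in range(B):
        rows = batch == b
        gamma[:, b] = resid[rows].mean(axis=0)
        var = resid[rows].var(axis=0)
        T[:, b] = np.clip(1.0 / np.maximum(var, 1e-12), *T_INIT_CLIP)

    mu = np.zeros((d, q))
    for k in range(q):
        members = c == k
        if members.any():
            mu[:, k] = f[members].mean(axis=0)
    dev = f - mu[:, c].T
    S = dev.T @ dev / n + 1e-6 * np.eye(d)
    Lambda = np.linalg.inv(S)
    Lambda = 0.5 * (Lambda + Lambda.T)

    params = ModelParams(
        L=L,
        gamma=gamma,
        T=T,
        mu=mu,
        Lambda=Lambda,
        incl=np.full((p, d), 0.5),
        p_slab=np.full(d, 0.5),
    )
    latent = LatentState(f=f, omega=np.ones(n), c=c)
    return params, latent


# ---------------------------------------------------------------------------
# E-steps


def e_step_factors(
    Y: np.ndarray,
    batch: np.ndarray,
    params: ModelParams,
    latent: LatentState,
    hyper: Hyperparams,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional posterior mean (= mode) of every factor score.

    Solves (omega_i Lambda + L' T_b L) f_i = L' T_b (y_i - gamma_b)
    + omega_i Lambda mu_{c_i} per spot.  Returns (f, per-spot precision
    matrices); the precisions are retained on the latent state.
    """
    n, p = Y.shape
    d = hyper.d
    B = params.gamma.shape[1]
    L, T = params.L, params.T
    M = np.empty((B, d, d))
    for b in range(B):
        M[b] = (L * T[:, b][:, None]).T @ L
    rhs = ((Y - params.gamma[:, batch].T) * T[:, batch].T) @ L
    Lam_mu = (params.Lambda @ params.mu).T[latent.c]  # n × d
    rhs = rhs + latent.omega[:, None] * Lam_mu
    A = latent.omega[:, None, None] * params.Lambda[None] + M[batch]
    try:
        f = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.eye(d)[None]
        try:
            f = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular factor-score precision") from exc
    return f, A


def e_step_omega(
    params: ModelParams, latent: LatentState, hyper: Hyperparams
) -> np.ndarray:
    """Conjugate Gamma posterior mean of each precision scale:
    omega_i = (nu_omega + d) / (nu_omega + delta_i^2) with delta^2 the
    Lambda-Mahalanobis distance of f_i from its cluster mean."""
    dev = latent.f - params.mu[:, latent.c].T
    delta2 = np.einsum("ij,jk,ik->i", dev, params.Lambda, dev)
    if np.any(delta2 < -1e-9):
        raise NumericalError("negative Mahalanobis distance; Lambda is not SPD")
    delta2 = np.maximum(delta2, 0.0)
    d = params.mu.shape[0]
    return (hyper.nu_omega + d) / (hyper.nu_omega + delta2)


def e_step_labels_icm(
    graph: NeighborGraph,
    params: ModelParams,
    latent: LatentState,
    hyper: Hyperparams,
    batch: np.ndarray,
    n_sweeps: int = 10,
) -> np.ndarray:
    """Iterated conditional modes over the Potts-regularized labels.

    Spots are swept in global-index order; each spot takes the label
    maximizing its Gaussian factor log density plus the local Potts field
    sum_{j ~ i, c_j = k} (eta_{b(i)} + eta_{b(j)}).  Ties go to the
    smallest label.  Stops early once a sweep changes nothing.
    """
    n, d = latent.f.shape
    q = hyper.q
    B = int(batch.max()) + 1
    eta = hyper.eta_vector(B)
    eta_spot = eta[batch]

    # n × q Gaussian log densities (terms constant across labels dropped)
    loglik = np.empty((n, q))
    for k in range(q):
        dev = latent.f - params.mu[:, k][None, :]
        maha = np.einsum("ij,jk,ik->i", dev, params.Lambda, dev)
        loglik[:, k] = -0.5 * latent.omega * maha

    indptr, indices = graph.neighbor_lists()
    c = latent.c.copy()
    for _ in range(max(1, n_sweeps)):
        changed = 0
        for i in range(n):
            nb = indices[indptr[i]: indptr[i + 1]]
            score = loglik[i].copy()
            if nb.size:
                w = eta_spot[i] + eta_spot[nb]
                np.add.at(score, c[nb], w)
            k_new = int(np.argmax(score))
            if k_new != c[i]:
                c[i] = k_new
                changed += 1
        if changed == 0:
            break
    return c


# ---------------------------------------------------------------------------
# M-steps


def m_step_batch(
    Y: np.ndarray,
    batch: np.ndarray,
    params: ModelParams,
    latent: LatentState,
    hyper: Hyperparams,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional modes of the additive and multiplicative batch effects.

    gamma_bj maximizes its Gaussian slice under the N(0, 1) prior given the
    current t_bj; t_bj is then the mode of its Gamma full conditional given
    the new gamma_bj, floored at a small positive value.
    """
    p, B = params.gamma.shape
    gamma = params.gamma.copy()
    T = params.T.copy()
    resid = Y - latent.f @ params.L.T
    for b in range(B):
        rows = batch == b
        n_b = int(rows.sum())
        if n_b == 0:
            logger.warning("batch %d has no spots; skipped", b)
            continue
        R = resid[rows]
        t = T[:, b]
        gamma[:, b] = t * R.sum(axis=0) / (1.0 + n_b * t)
        ss = np.sum((R - gamma[:, b][None, :]) ** 2, axis=0)
        T[:, b] = np.maximum((hyper.nu_t + n_b - 2.0) / (hyper.nu_t + ss), T_FLOOR)
    return gamma, T


def _slab_argmax(a: np.ndarray, b: np.ndarray, lambda1: float) -> np.ndarray:
    """Maximizer of -a l^2/2 + b l + log pMOM(l; lambda1): the sign(b) root
    of (a + 1/lambda1) l^2 - b l - 2 = 0 (the pMOM slab repels zero)."""
    A = a + 1.0 / lambda1
    s = np.where(b >= 0, 1.0, -1.0)
    return (b + s * np.sqrt(b**2 + 8.0 * A)) / (2.0 * A)


def _spike_argmax(a: np.ndarray, b: np.ndarray, lambda0: float) -> np.ndarray:
    """Ridge solution of the spike branch: l = b / (a + 1/lambda0)."""
    return b / (a + 1.0 / lambda0)


def _slab_spike_log_evidence(a, b, lambda0: float, lambda1: float):
    """Log marginal evidences of the two prior components against the
    coordinate Gaussian likelihood exp(-a l^2/2 + b l) (shared constant
    dropped)."""
    A0 = a + 1.0 / lambda0
    A1 = a + 1.0 / lambda1
    log_spike = -0.5 * np.log(lambda0 * A0) + b**2 / (2.0 * A0)
    log_slab = (
        -1.5 * np.log(lambda1)
        - 0.5 * np.log(A1)
        + b**2 / (2.0 * A1)
        + np.log(1.0 / A1 + (b / A1) ** 2)
    )
    return log_slab, log_spike


def m_step_loadings(
    Y: np.ndarray,
    batch: np.ndarray,
    params: ModelParams,
    latent: LatentState,
    hyper: Hyperparams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinate-wise update of loadings, inclusion probabilities, and
    per-factor slab weights.

    For each factor column, the coordinate quadratic statistics
    a_j = sum_i t_{b(i)j} f_ik^2 and b_j = sum_i t_{b(i)j} f_ik r_ij (with
    r the partial residual) give (i) the posterior slab probability from
    the marginalized component evidences, (ii) the loading as the
    stationary point of the responsibility-weighted mixture objective
    (which reduces to the pure slab/spike closed forms at incl 1/0), and
    (iii) the Beta-posterior mode of p_slab.
    """
    n, p = Y.shape
    d = hyper.d
    lam0, lam1 = hyper.lambda0, hyper.lambda1
    F = latent.f
    t_rows = params.T[:, batch].T  # n × p
    L = params.L.copy()
    incl = params.incl.copy()
    p_slab = params.p_slab.copy()
    R = Y - params.gamma[:, batch].T - F @ L.T

    for k in range(d):
        fk = F[:, k]
        Rk = R + np.outer(fk, L[:, k])
        tf = t_rows * fk[:, None]
        a = (tf * fk[:, None]).sum(axis=0)
        b = (tf * Rk).sum(axis=0)
        if np.any(a <= 0):
            j = int(np.argmax(a <= 0))
            raise NumericalError(
                f"loading update: non-positive curvature for gene index {j}, factor {k}"
            )
        log_slab, log_spike = _slab_spike_log_evidence(a, b, lam0, lam1)
        pk = np.clip(p_slab[k], 1e-12, 1.0 - 1e-12)
        logit = np.log(pk) - np.log1p(-pk) + log_slab - log_spike
        r = 1.0 / (1.0 + np.exp(-logit))
        C = a + r / lam1 + (1.0 - r) / lam0
        s = np.where(b >= 0, 1.0, -1.0)
        with np.errstate(invalid="ignore"):
            l_mixed = (b + s * np.sqrt(b**2 + 8.0 * r * C)) / (2.0 * C)
        l_new = np.where(r > 0, l_mixed, b / C)
        L[:, k] = l_new
        incl[:, k] = r
        R = Rk - np.outer(fk, l_new)

    denom = hyper.alpha_p + hyper.beta_p - 2.0 + p
    p_slab = np.clip((hyper.alpha_p - 1.0 + incl.sum(axis=0)) / denom, 0.0, 1.0)
    return L, incl, p_slab


def m_step_clusters(
    params: ModelParams, latent: LatentState, hyper: Hyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional modes of the cluster means and shared factor precision.

    mu_k combines the omega-weighted member scores with the N(mu_mu,
    sigma_mu I) prior; Lambda is the Wishart posterior mode from the
    omega-weighted scatter.  Empty clusters keep their mean (flagged)."""
    f, omega, c = latent.f, latent.omega, latent.c
    n, d = f.shape
    q = hyper.q
    mu = params.mu.copy()
    for k in range(q):
        members = c == k
        if not members.any():
            logger.info("cluster %d is empty; mean retained", k)
            continue
        w = omega[members]
        prec = np.eye(d) / hyper.sigma_mu + params.Lambda * w.sum()
        rhs = hyper.mu_mu / hyper.sigma_mu + params.Lambda @ (w[:, None] * f[members]).sum(axis=0)
        mu[:, k] = np.linalg.solve(prec, rhs)
    dev = f - mu[:, c].T
    S = (omega[:, None] * dev).T @ dev
    V_inv = np.eye(d) / hyper.sigma_Lambda + S
    V_inv = 0.5 * (V_inv + V_inv.T)
    chol_spd(V_inv)
    df_post = hyper.n_Lambda + n
    Lambda = (df_post - d - 1.0) * np.linalg.inv(V_inv)
    Lambda = 0.5 * (Lambda + Lambda.T)
    chol_spd(Lambda)
    return mu, Lambda


def _gauge_step(
    Y: np.ndarray,
    batch: np.ndarray,
    params: ModelParams,
    latent: LatentState,
    B: int,
) -> None:
    """Rebalance the batch-shift reparameterization in place.

    The likelihood is invariant under f_i -> f_i + delta_b (all spots of
    batch b) with gamma_b -> gamma_b - L delta_b, so the split between a
    per-batch factor shift and the additive batch effect is decided only by
    the factor-mixture and gamma priors — a nearly flat valley that plain
    coordinate updates drain extremely slowly.  This step maximizes the
    objective exactly along those B directions (a convex d-dimensional
    quadratic per batch), which is a parameter-expansion (PX-EM) move: it
    never decreases the objective and resolves the additive effects into
    the gauge the priors select.
    """
    LtL = params.L.T @ params.L
    for b in range(B):
        rows = batch == b
        if not rows.any():
            continue
        w = latent.omega[rows]
        dev = latent.f[rows] - params.mu[:, latent.c[rows]].T
        A = params.Lambda * w.sum() + LtL
        rhs = params.L.T @ params.gamma[:, b] - params.Lambda @ (w[:, None] * dev).sum(axis=0)
        delta = np.linalg.solve(A, rhs)
        latent.f[rows] += delta
        params.gamma[:, b] -= params.L @ delta


def _scale_step(
    params: ModelParams, latent: LatentState, hyper: Hyperparams, n: int
) -> None:
    """Rebalance the per-factor scale reparameterization in place.

    The likelihood is also invariant under L_k -> s L_k, f_k -> f_k / s
    (with mu and Lambda rescaled accordingly); the objective's preference
    along this direction comes from the factor-density determinant and the
    loading/Lambda/mu priors, and plain coordinate updates drift toward it
    very slowly.  Each factor's slice objective is one-dimensional and
    separable, so it is maximized by a bounded line search on log s; the
    move is accepted only when it improves the slice, preserving the
    ascent contract.
    """
    from scipy.optimize import minimize_scalar

    d = hyper.d
    for k in range(d):
        Lk = params.L[:, k]
        muk = params.mu[k, :]
        Lkk = params.Lambda[k, k]
        pk = params.p_slab[k]
        mu_ss = float(np.sum(muk**2))

        def slice_obj(log_s: float) -> float:
            s = np.exp(log_s)
            val = (n + hyper.n_Lambda - d - 1.0) * log_s
            val -= 0.5 * s**2 * Lkk / hyper.sigma_Lambda
            val -= 0.5 * mu_ss / (hyper.sigma_mu * s**2)
            val += float(
                np.sum(loading_prior_logpdf(Lk * s, pk, hyper.lambda0, hyper.lambda1))
            )
            return val

        res = minimize_scalar(
            lambda x: -slice_obj(x), bounds=(-8.0, 8.0), method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > slice_obj(0.0) + 1e-10:
            s = float(np.exp(res.x))
            params.L[:, k] *= s
            latent.f[:, k] /= s
            params.mu[k, :] /= s
            params.Lambda[k, :] *= s
            params.Lambda[:, k] *= s


# ---------------------------------------------------------------------------
# driver


def fit_em(
    dataset: MultiSliceDataset | None,
    graph: NeighborGraph,
    hyper: Hyperparams,
    max_iter: int = 30,
    tol: float = 1e-5,
    icm_sweeps: int = 10,
    seed: int = 0,
    Y: np.ndarray | None = None,
    batch: np.ndarray | None = None,
    fixed_L: np.ndarray | None = None,
    fixed_gamma: np.ndarray | None = None,
    fixed_T: np.ndarray | None = None,
    callback=None,
) -> FitResult:
    """Run the EM/ICM loop to convergence.

    Either ``dataset`` (assembled and centered) or the raw ``Y``/``batch``
    arrays may be supplied.  ``fixed_*`` pin the corresponding parameters
    (useful for reductions and diagnostics).  Stops when the relative
    change of the tracked objective falls below ``tol`` or after
    ``max_iter`` iterations.  Fully deterministic given ``seed``.
    """
    if Y is None:
        if dataset is None:
            raise ValidationError("fit_em needs a dataset or Y/batch arrays")
        Y = dataset.stacked_expr()
        batch = dataset.batch_of_spot()
    batch = np.asarray(batch)
    params, latent = init_state(Y, batch, hyper, seed=seed, fixed_L=fixed_L)
    if fixed_gamma is not None:
        params.gamma = np.array(fixed_gamma, dtype=float)
    if fixed_T is not None:
        params.T = np.array(fixed_T, dtype=float)

    obj_prev = log_joint(Y, batch, graph, params, latent, hyper)
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        latent.f, latent.f_precisions = e_step_factors(Y, batch, params, latent, hyper)
        latent.omega = e_step_omega(params, latent, hyper)
        latent.c = e_step_labels_icm(graph, params, latent, hyper, batch, icm_sweeps)
        if fixed_L is None:
            params.L, params.incl, params.p_slab = m_step_loadings(
                Y, batch, params, latent, hyper
            )
            _scale_step(params, latent, hyper, Y.shape[0])
        if fixed_gamma is None or fixed_T is None:
            gamma_new, T_new = m_step_batch(Y, batch, params, latent, hyper)
            if fixed_gamma is None:
                params.gamma = gamma_new
            if fixed_T is None:
                params.T = T_new
        if fixed_gamma is None:
            _gauge_step(Y, batch, params, latent, int(batch.max()) + 1)
        params.mu, params.Lambda = m_step_clusters(params, latent, hyper)

        obj = log_joint(Y, batch, graph, params, latent, hyper)
        if not np.isfinite(obj):
            raise NumericalError(f"objective became non-finite at iteration {it}")
        trace.append(obj)
        if callback is not None:
            callback(it, params, latent, obj)
        if abs(obj - obj_prev) < tol * abs(obj_prev):
            converged = True
            obj_prev = obj
            break
        obj_prev = obj

    return FitResult(
        params=params,
        latent=latent,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
    )


def corrected_expression(params: ModelParams, latent: LatentState) -> np.ndarray:
    """Batch-free reconstruction x_bi = L f_bi (n × p, rank <= d).

    Adding gamma_b back gives the model's fitted per-batch mean."""
    return latent.f @ params.L.T
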