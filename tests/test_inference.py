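import numpy as np
import pytest
from scipy import integrate, optimize

from stadia import data_io, graph as graph_mod, inference, simulate
from stadia.graph import NeighborGraph, _edges_to_adjacency
from stadia.inference import (
    _slab_argmax,
    _spike_argmax,
    e_step_factors,
    e_step_labels_icm,
    e_step_omega,
    fit_em,
    init_state,
    m_step_batch,
    m_step_clusters,
    m_step_loadings,
)
from stadia.model import STADIA
from stadia.model_core import Hyperparams, LatentState, ModelParams, pmom_slab_logpdf
from stadia.metrics import ari


def make_graph(n, edges):
    edges = {(min(i, j), max(i, j)) for i, j in edges}
    return NeighborGraph(
        n=n, intra_edges=edges, inter_edges=set(), adjacency=_edges_to_adjacency(n, edges)
    )


def random_state(rng, n=7, p=4, d=2, q=3, B=2):
    params = ModelParams(
        L=rng.standard_normal((p, d)) * 0.5,
        gamma=rng.standard_normal((p, B)) * 0.2,
        T=rng.uniform(0.5, 3.0, (p, B)),
        mu=rng.standard_normal((d, q)),
        Lambda=np.eye(d) * rng.uniform(0.5, 2.0),
        incl=np.full((p, d), 0.5),
        p_slab=np.full(d, 0.5),
    )
    latent = LatentState(
        f=rng.standard_normal((n, d)),
        omega=rng.uniform(0.5, 2.0, n),
        c=rng.integers(0, q, n),
    )
    Y = rng.standard_normal((n, p))
    batch = rng.integers(0, B, n)
    hyper = Hyperparams(d=d, q=q, eta=1.0)
    return Y, batch, params, latent, hyper


# ---------------------------------------------------------------------------
# initialization


class TestInit:
    def test_same_seed_identical(self, rng):
        Y = rng.standard_normal((40, 10))
        batch = np.repeat([0, 1], 20)
        hyper = Hyperparams(d=3, q=2)
        p1, l1 = init_state(Y, batch, hyper, seed=5)
        p2, l2 = init_state(Y, batch, hyper, seed=5)
        np.testing.assert_array_equal(p1.L, p2.L)
        np.testing.assert_array_equal(l1.c, l2.c)
        np.testing.assert_array_equal(p1.gamma, p2.gamma)

    def test_rank_d_noiseless_recovery(self, rng):
        d = 3
        f = rng.standard_normal((50, d))
        L = np.linalg.qr(rng.standard_normal((12, d)))[0]
        Y = f @ L.T
        params, latent = init_state(Y, np.zeros(50, dtype=int), Hyperparams(d=d, q=2), seed=0)
        recon = latent.f @ params.L.T
        assert np.linalg.norm(Y - recon) < 1e-8 * np.linalg.norm(Y)

    def test_omega_starts_at_one(self, rng):
        Y = rng.standard_normal((20, 6))
        _, latent = init_state(Y, np.zeros(20, dtype=int), Hyperparams(d=2, q=2), seed=0)
        np.testing.assert_array_equal(latent.omega, np.ones(20))

    def test_too_many_clusters_rejected(self, rng):
        Y = rng.standard_normal((5, 6))
        with pytest.raises(data_io.ValidationError):
            init_state(Y, np.zeros(5, dtype=int), Hyperparams(d=2, q=9), seed=0)


# ---------------------------------------------------------------------------
# E-steps


class TestFactorStep:
    def test_zero_loadings_collapse_to_cluster_mean(self, rng):
        Y, batch, params, latent, hyper = random_state(rng)
        params.L = np.zeros_like(params.L)
        f, _ = e_step_factors(Y, batch, params, latent, hyper)
        np.testing.assert_allclose(f, params.mu[:, latent.c].T, atol=1e-10)

    def test_no_noise_identity_loadings_recover_data(self, rng):
        n, d = 5, 3
        Y = rng.standard_normal((n, d))
        params = ModelParams(
            L=np.eye(d),
            gamma=np.zeros((d, 1)),
            T=np.full((d, 1), 1e12),
            mu=np.zeros((d, 1)),
            Lambda=np.eye(d),
            incl=np.full((d, d), 0.5),
            p_slab=np.full(d, 0.5),
        )
        latent = LatentState(f=np.zeros((n, d)), omega=np.ones(n), c=np.zeros(n, dtype=int))
        f, _ = e_step_factors(Y, np.zeros(n, dtype=int), params, latent, Hyperparams(d=d, q=1))
        np.testing.assert_allclose(f, Y, atol=1e-6)

    def test_matches_numeric_optimum_of_spot_slice(self, rng):
        """The factor update must maximize the per-spot objective slice."""
        Y, batch, params, latent, hyper = random_state(rng, n=1, p=3, d=2, q=2, B=1)
        f, _ = e_step_factors(Y, batch, params, latent, hyper)

        t = params.T[:, batch[0]]
        om, k = latent.omega[0], latent.c[0]

        def neg_slice(fv):
            r = Y[0] - params.L @ fv - params.gamma[:, batch[0]]
            dev = fv - params.mu[:, k]
            return 0.5 * np.sum(t * r**2) + 0.5 * om * dev @ params.Lambda @ dev

        res = optimize.minimize(neg_slice, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14})
        np.testing.assert_allclose(f[0], res.x, rtol=1e-4, atol=1e-6)


class TestOmegaStep:
    def test_at_cluster_mean_closed_form(self):
        hyper = Hyperparams(d=10, q=1, nu_omega=2.0)
        params = ModelParams(
            L=np.zeros((11, 10)), gamma=np.zeros((11, 1)), T=np.ones((11, 1)),
            mu=np.zeros((10, 1)), Lambda=np.eye(10),
            incl=np.full((11, 10), 0.5), p_slab=np.full(10, 0.5),
        )
        latent = LatentState(f=np.zeros((1, 10)), omega=np.ones(1), c=np.zeros(1, dtype=int))
        om = e_step_omega(params, latent, hyper)
        assert om[0] == pytest.approx(6.0)  # (nu + d) / nu at zero distance

    def test_default_nu_omega_is_two(self):
        assert Hyperparams(d=2, q=2).nu_omega == 2.0

    def test_matches_quadrature_posterior_mean(self, rng):
        Y, batch, params, latent, hyper = random_state(rng, n=4)
        om = e_step_omega(params, latent, hyper)
        i = 2
        dev = latent.f[i] - params.mu[:, latent.c[i]]
        d2 = dev @ params.Lambda @ dev
        nu, d = hyper.nu_omega, hyper.d

        def unnorm(w):
            return w ** ((nu + d) / 2 - 1) * np.exp(-(nu + d2) * w / 2)

        num, _ = integrate.quad(lambda w: w * unnorm(w), 0, np.inf)
        den, _ = integrate.quad(unnorm, 0, np.inf)
        assert om[i] == pytest.approx(num / den, rel=1e-8)


class TestICMLabels:
    def test_eta_zero_is_density_argmax(self, rng):
        Y, batch, params, latent, hyper = random_state(rng, n=10)
        hyper = Hyperparams(d=hyper.d, q=hyper.q, eta=0.0)
        g = make_graph(10, {(i, i + 1) for i in range(9)})
        c = e_step_labels_icm(g, params, latent, hyper, batch)
        for i in range(10):
            scores = []
            for k in range(hyper.q):
                dev = latent.f[i] - params.mu[:, k]
                scores.append(-0.5 * latent.omega[i] * dev @ params.Lambda @ dev)
            assert c[i] == int(np.argmax(scores))

    def test_large_eta_freezes_connected_graph(self, rng):
        n, d, q = 12, 2, 3
        f = rng.standard_normal((n, d)) * 0.01
        params = ModelParams(
            L=np.zeros((3, d)), gamma=np.zeros((3, 1)), T=np.ones((3, 1)),
            mu=rng.standard_normal((d, q)), Lambda=np.eye(d),
            incl=np.full((3, d), 0.5), p_slab=np.full(d, 0.5),
        )
        latent = LatentState(f=f, omega=np.ones(n), c=rng.integers(0, q, n))
        g = make_graph(n, {(i, i + 1) for i in range(n - 1)})
        hyper = Hyperparams(d=d, q=q, eta=200.0)
        c = e_step_labels_icm(g, params, latent, hyper, np.zeros(n, dtype=int), n_sweeps=50)
        assert len(np.unique(c)) == 1

    def test_path_graph_matches_exhaustive_search(self):
        """4-spot path, 2 clusters: ICM fixed point equals the global MAP
        labeling found by brute force over all 2^4 assignments."""
        import itertools

        n, d, q = 4, 1, 2
        f = np.array([[-1.0], [-0.8], [0.9], [1.1]])
        params = ModelParams(
            L=np.zeros((2, d)), gamma=np.zeros((2, 1)), T=np.ones((2, 1)),
            mu=np.array([[-1.0, 1.0]]), Lambda=np.eye(1),
            incl=np.full((2, d), 0.5), p_slab=np.full(d, 0.5),
        )
        latent = LatentState(f=f, omega=np.ones(n), c=np.zeros(n, dtype=int))
        edges = {(0, 1), (1, 2), (2, 3)}
        g = make_graph(n, edges)
        eta = 0.4
        hyper = Hyperparams(d=d, q=q, eta=eta)
        c = e_step_labels_icm(g, params, latent, hyper, np.zeros(n, dtype=int), n_sweeps=20)

        def score(labels):
            s = 0.0
            for i in range(n):
                dev = f[i, 0] - params.mu[0, labels[i]]
                s -= 0.5 * dev**2
            for i, j in edges:
                if labels[i] == labels[j]:
                    s += 2 * eta
            return s

        best = max(itertools.product(range(q), repeat=n), key=score)
        np.testing.assert_array_equal(c, np.array(best))


# ---------------------------------------------------------------------------
# M-steps


class TestBatchStep:
    def test_zero_residuals_give_zero_gamma(self, rng):
        Y, batch, params, latent, hyper = random_state(rng)
        Y = latent.f @ params.L.T  # residual-free data
        gamma, T = m_step_batch(Y, batch, params, latent, hyper)
        np.testing.assert_allclose(gamma, 0.0, atol=1e-12)

    def test_default_nu_t_is_one(self):
        assert Hyperparams(d=2, q=2).nu_t == 1.0

    def test_matches_numeric_conditional_optima(self, rng):
        """gamma maximizes its slice at the old t; t maximizes its slice at
        the new gamma (single gene, single batch)."""
        n = 6
        Y, batch, params, latent, hyper = random_state(rng, n=n, p=1, B=1)
        batch = np.zeros(n, dtype=int)
        gamma, T = m_step_batch(Y, batch, params, latent, hyper)
        r = (Y - latent.f @ params.L.T)[:, 0]
        t_old = params.T[0, 0]

        def neg_gamma_slice(g):
            return 0.5 * t_old * np.sum((r - g) ** 2) + 0.5 * g**2

        res = optimize.minimize_scalar(neg_gamma_slice, bounds=(-10, 10), method="bounded",
                                       options={"xatol": 1e-12})
        assert gamma[0, 0] == pytest.approx(res.x, rel=1e-4, abs=1e-8)

        ss = np.sum((r - gamma[0, 0]) ** 2)

        def neg_t_slice(t):
            return -(0.5 * n * np.log(t) - 0.5 * t * ss
                     + (hyper.nu_t / 2 - 1) * np.log(t) - hyper.nu_t * t / 2)

        res = optimize.minimize_scalar(neg_t_slice, bounds=(1e-8, 1e4), method="bounded",
                                       options={"xatol": 1e-12})
        assert T[0, 0] == pytest.approx(res.x, rel=1e-4)


class TestLoadingStep:
    def test_slab_branch_repels_zero(self):
        a = np.array([2.0])
        l = _slab_argmax(a, np.array([0.0]), 0.871)
        assert abs(l[0]) == pytest.approx(np.sqrt(2.0 / (2.0 + 1 / 0.871)))
        assert l[0] != 0.0

    def test_slab_branch_matches_numeric_optimum(self, rng):
        a = float(rng.uniform(0.5, 5.0))
        b = float(rng.normal())
        l = _slab_argmax(np.array([a]), np.array([b]), 0.871)[0]

        def neg(x):
            return 0.5 * a * x**2 - b * x - pmom_slab_logpdf(x, 0.871)

        lo, hi = (1e-9, 10.0) if l > 0 else (-10.0, -1e-9)
        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-12})
        assert l == pytest.approx(res.x, rel=1e-4)

    def test_spike_branch_matches_ridge(self, rng):
        a, b = 3.0, -1.2
        l = _spike_argmax(np.array([a]), np.array([b]), 0.015)[0]

        def neg(x):
            return 0.5 * a * x**2 - b * x + 0.5 * x**2 / 0.015

        res = optimize.minimize_scalar(neg, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-12})
        assert l == pytest.approx(res.x, rel=1e-4, abs=1e-8)

    def test_defaults_are_printed_spike_slab_variances(self):
        h = Hyperparams(d=2, q=2)
        assert h.lambda0 == 0.015
        assert h.lambda1 == 0.871

    def test_full_update_is_stationary_for_weighted_objective(self, rng):
        """Each updated coordinate maximizes the responsibility-weighted
        quadratic-plus-mixture slice it was solved for."""
        Y, batch, params, latent, hyper = random_state(rng, n=30, p=5, d=2)
        L_new, incl_new, _ = m_step_loadings(Y, batch, params, latent, hyper)
        # recompute the coordinate statistics of the FIRST factor at the
        # solution (partial residual uses new k=0, old k=1 as in the sweep)
        k = 0
        Lmix = params.L.copy()
        Lmix[:, 0] = L_new[:, 0]
        R = Y - params.gamma[:, batch].T - latent.f @ Lmix.T
        fk = latent.f[:, k]
        t_rows = params.T[:, batch].T
        Rk = R + np.outer(fk, Lmix[:, k])
        a = (t_rows * fk[:, None] ** 2).sum(axis=0)
        b = ((t_rows * fk[:, None]) * Rk).sum(axis=0)
        j = 3
        r = incl_new[j, k]

        def neg(x):
            pen = r * pmom_slab_logpdf(x, hyper.lambda1) - (1 - r) * 0.5 * x**2 / hyper.lambda0
            return 0.5 * a[j] * x**2 - b[j] * x - pen

        side = (1e-9, 5.0) if L_new[j, k] > 0 else (-5.0, -1e-9)
        res = optimize.minimize_scalar(neg, bounds=side, method="bounded",
                                       options={"xatol": 1e-12})
        assert L_new[j, k] == pytest.approx(res.x, rel=1e-4)


class TestClusterStep:
    def test_flat_prior_limit_gives_cluster_means(self, rng):
        Y, batch, params, latent, hyper = random_state(rng, n=20)
        hyper = Hyperparams(d=hyper.d, q=hyper.q, sigma_mu=1e12)
        latent.omega = np.ones(20)
        mu, _ = m_step_clusters(params, latent, hyper)
        for k in range(hyper.q):
            members = latent.c == k
            if members.any():
                np.testing.assert_allclose(mu[:, k], latent.f[members].mean(axis=0),
                                           atol=1e-6)

    def test_default_sigma_mu_is_100(self):
        assert Hyperparams(d=2, q=2).sigma_mu == 100.0

    def test_matches_numeric_conditional_optima(self, rng):
        Y, batch, params, latent, hyper = random_state(rng, n=5, d=2, q=2)
        mu, Lambda = m_step_clusters(params, latent, hyper)

        k = 0
        members = latent.c == k
        w = latent.omega[members]
        fk = latent.f[members]

        def neg_mu_slice(m):
            dev = fk - m
            quad = np.sum(w * np.einsum("ij,jk,ik->i", dev, params.Lambda, dev))
            return 0.5 * quad + 0.5 * np.sum(m**2) / hyper.sigma_mu

        res = optimize.minimize(neg_mu_slice, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14})
        np.testing.assert_allclose(mu[:, k], res.x, rtol=1e-4, atol=1e-8)

        dev = latent.f - mu[:, latent.c].T
        n = len(dev)

        def neg_Lambda_slice(chol_params):
            C = np.array([[np.exp(chol_params[0]), 0.0],
                          [chol_params[1], np.exp(chol_params[2])]])
            Lam = C @ C.T
            ld = 2 * (chol_params[0] + chol_params[2])
            quad = np.sum(latent.omega * np.einsum("ij,jk,ik->i", dev, Lam, dev))
            from scipy.stats import wishart
            prior = wishart.logpdf(Lam, df=hyper.n_Lambda, scale=hyper.sigma_Lambda * np.eye(2))
            return -(0.5 * n * ld - 0.5 * quad + prior)

        res = optimize.minimize(neg_Lambda_slice, np.array([0.0, 0.0, 0.0]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000})
        C = np.array([[np.exp(res.x[0]), 0.0], [res.x[1], np.exp(res.x[2])]])
        np.testing.assert_allclose(Lambda, C @ C.T, rtol=1e-3)


# ---------------------------------------------------------------------------
# full EM


class TestFitEM:
    def test_tol_inf_runs_single_iteration(self, tiny_sim):
        dsc, _, g = tiny_sim
        model = STADIA(dsc, n_domains=3, n_factors=4, eta=1.0, graph=g)
        res = model.fit(max_iter=10, tol=np.inf, seed=0)
        assert res.n_iter == 1
        assert len(res.objective_trace) == 1

    def test_same_seed_identical_results(self, tiny_sim):
        dsc, _, g = tiny_sim
        model = STADIA(dsc, n_domains=3, n_factors=4, eta=1.0, graph=g)
        r1 = model.fit(max_iter=4, seed=7)
        r2 = model.fit(max_iter=4, seed=7)
        np.testing.assert_array_equal(r1.domains, r2.domains)
        np.testing.assert_array_equal(r1.params.L, r2.params.L)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_objective_never_decreases(self, tiny_sim):
        dsc, _, g = tiny_sim
        model = STADIA(dsc, n_domains=3, n_factors=4, eta=1.0, graph=g)
        res = model.fit(max_iter=12, tol=1e-12, seed=1)
        tr = res.objective_trace
        assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[:-1]))

    def test_recovers_labels_on_separated_data(self, tiny_sim):
        dsc, truth, g = tiny_sim
        model = STADIA(dsc, n_domains=3, n_factors=4, eta=1.0, graph=g)
        res = model.fit(max_iter=20, seed=0)
        assert ari(res.domains, truth.labels_true) >= 0.9

    def test_raising_eta_never_reduces_neighbor_concordance(self):
        for seed in range(5):
            ds, _ = simulate.simulate_dataset(
                seed=seed, B=1, width=10, height=10, p=30, d=3, q=3,
                eta=1.0, potts_sweeps=20,
            )
            dsc = data_io.center_genes(ds)
            g = graph_mod.assemble_adjacency(dsc)
            indptr, indices = g.neighbor_lists()
            src = np.repeat(np.arange(g.n), np.diff(indptr))

            def concord(labels):
                return float(np.mean(labels[src] == labels[indices]))

            frac = []
            for eta in (0.0, 2.0):
                model = STADIA(dsc, n_domains=3, n_factors=3, eta=eta, graph=g)
                res = model.fit(max_iter=8, seed=seed)
                frac.append(concord(res.domains))
            assert frac[1] >= frac[0] - 1e-12


class TestCorrectedExpression:
    def test_zero_factors_give_zero_matrix(self, rng):
        Y, batch, params, latent, hyper = random_state(rng)
        latent.f = np.zeros_like(latent.f)
        out = inference.corrected_expression(params, latent)
        np.testing.assert_array_equal(out, 0.0)

    def test_rank_at_most_d(self, rng):
        Y, batch, params, latent, hyper = random_state(rng, n=10, p=6, d=2)
        out = inference.corrected_expression(params, latent)
        assert np.linalg.matrix_rank(out) <= 2

    def test_noiseless_simulation_recovery(self):
        ds, truth = simulate.simulate_dataset(
            seed=4, B=2, width=12, height=12, p=40, d=4, q=3, eta=1.0,
            noise_level=0.0, potts_sweeps=30,
        )
        x_true = np.vstack([
            s.expr - truth.gamma_true[:, b][None, :] for b, s in enumerate(ds.slices)
        ])
        dsc = data_io.center_genes(ds)
        g = graph_mod.assemble_adjacency(dsc)
        model = STADIA(dsc, n_domains=3, n_factors=4, eta=1.0, graph=g)
        res = model.fit(max_iter=15, seed=0)
        x_hat = res.corrected_expression()
        xt = x_true - x_true.mean(axis=0)
        corr = [np.corrcoef(x_hat[i], xt[i])[0, 1] for i in range(0, len(xt), 7)]
        assert np.median(corr) >= 0.99


# ---------------------------------------------------------------------------
# reduction to a plain scale-mixture mixture model


def _oracle_hard_em_t_mixture(z, q, tau, hyper, seed, n_iter):
    """Independent hard-EM for the d-dimensional model z = f + noise(tau^-1 I),
    f | c=k ~ N(mu_k, omega^-1 Lambda^-1), omega ~ G(nu/2, nu/2)."""
    from sklearn.cluster import KMeans

    n, d = z.shape
    f = z.copy()
    lo, hi = np.percentile(f, 1, axis=0), np.percentile(f, 99, axis=0)
    c = KMeans(n_clusters=q, random_state=seed, n_init=10).fit_predict(
        np.clip(f, lo, hi)
    ).astype(np.int64)
    omega = np.ones(n)
    mu = np.zeros((d, q))
    for k in range(q):
        if (c == k).any():
            mu[:, k] = f[c == k].mean(axis=0)
    dev = f - mu[:, c].T
    Lambda = np.linalg.inv(dev.T @ dev / n + 1e-6 * np.eye(d))
    Lambda = 0.5 * (Lambda + Lambda.T)

    for _ in range(n_iter):
        # factor update
        A = omega[:, None, None] * Lambda[None] + tau * np.eye(d)[None]
        rhs = tau * z + omega[:, None] * (Lambda @ mu).T[c]
        f = np.linalg.solve(A, rhs[..., None])[..., 0]
        # omega update
        dev = f - mu[:, c].T
        d2 = np.einsum("ij,jk,ik->i", dev, Lambda, dev)
        omega = (hyper.nu_omega + d) / (hyper.nu_omega + d2)
        # labels: independent density argmax
        scores = np.empty((n, q))
        for k in range(q):
            dv = f - mu[:, k][None]
            scores[:, k] = -0.5 * omega * np.einsum("ij,jk,ik->i", dv, Lambda, dv)
        c = np.argmax(scores, axis=1)
        # cluster moments
        for k in range(q):
            members = c == k
            if not members.any():
                continue
            w = omega[members]
            prec = np.eye(d) / hyper.sigma_mu + Lambda * w.sum()
            rhs_k = Lambda @ (w[:, None] * f[members]).sum(axis=0)
            mu[:, k] = np.linalg.solve(prec, rhs_k)
        dev = f - mu[:, c].T
        S = (omega[:, None] * dev).T @ dev
        Vinv = np.eye(d) / hyper.sigma_Lambda + S
        Vinv = 0.5 * (Vinv + Vinv.T)
        Lambda = (hyper.n_Lambda + n - d - 1.0) * np.linalg.inv(Vinv)
        Lambda = 0.5 * (Lambda + Lambda.T)
    return c


def test_reduction_to_hard_em_mixture():
    """B=1, eta=0, fixed orthonormal loadings, fixed unit batch terms: the
    full fit's labels equal an independently coded hard-EM scale-mixture
    clustering of the projected data."""
    rng = np.random.default_rng(123)
    n, p, d, q = 200, 20, 3, 3
    mu_true = rng.normal(0, 3, (d, q))
    c_true = rng.integers(0, q, n)
    f_true = mu_true[:, c_true].T + rng.standard_normal((n, d))
    V = np.linalg.qr(rng.standard_normal((p, d)))[0]
    tau = 4.0
    Y = f_true @ V.T + rng.standard_normal((n, p)) / np.sqrt(tau)

    hyper = Hyperparams(d=d, q=q, eta=0.0)
    g = make_graph(n, set())
    seed = 9
    n_iter = 6
    res = fit_em(
        None, g, hyper, max_iter=n_iter, tol=1e-15, seed=seed,
        Y=Y, batch=np.zeros(n, dtype=int),
        fixed_L=V, fixed_gamma=np.zeros((p, 1)), fixed_T=np.full((p, 1), tau),
    )
    z = Y @ V
    c_oracle = _oracle_hard_em_t_mixture(z, q, tau, hyper, seed, n_iter)
    np.testing.assert_array_equal(res.domains, c_oracle)
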