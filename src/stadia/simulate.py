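"""Generative simulator: Potts-correlated domains on lattice geometries,
Student-t latent factors, sparse pMOM loadings, and per-slice batch effects.

The simulator draws from the model's own forward process and emits
continuous (already normalized-scale) expression together with the full
ground truth, so inference can be scored on label and parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import MultiSliceDataset, SliceData, ValidationError

#: Additive / multiplicative batch-effect presets.  ``gamma_sd`` is the
#: standard deviation of the per-gene additive shifts; ``noise_scales``
#: multiplies each batch's noise standard deviation (so batches differ in
#: their per-gene precisions).  Values are the package's own calibration.
BATCH_SCALE_PRESETS = {
    "small": {"gamma_sd": 0.2, "noise_scales": (1.0, 1.1)},
    "medium": {"gamma_sd": 0.5, "noise_scales": (1.0, 1.5)},
    "large": {"gamma_sd": 1.0, "noise_scales": (1.0, 2.0)},
}


@dataclass
class SimulationConfig:
    """Study conditions for the default recovery scenario: two 40 x 40
    lattice slices, p=200 genes, d=10 factors, q=5 Potts-correlated
    domains with smoothness eta=1.5, Student-t factors with nu_omega=2,
    and medium batch effects."""

    B: int = 2
    width: int = 40
    height: int = 40
    p: int = 200
    d: int = 10
    q: int = 5
    eta: float = 1.5
    nu_omega: float = 2.0
    noise_level: float = 0.3
    batch_scales: str | dict = "medium"
    sparsity: float = 0.8
    lambda1: float = 0.871
    mu_scale: float = 3.0
    potts_sweeps: int = 60

    def scales(self) -> dict:
        if isinstance(self.batch_scales, str):
            try:
                return BATCH_SCALE_PRESETS[self.batch_scales]
            except KeyError:
                raise ValidationError(
                    f"unknown batch_scales preset {self.batch_scales!r}"
                ) from None
        return dict(self.batch_scales)


@dataclass
class SimulationTruth:
    """Ground-truth parameters and labels of a simulated dataset."""

    L_true: np.ndarray
    gamma_true: np.ndarray
    T_true: np.ndarray
    mu_true: np.ndarray
    Lambda_true: np.ndarray
    labels_true: np.ndarray
    omega_true: np.ndarray
    geometry: list[tuple[int, int]] = field(default_factory=list)


def sample_potts(
    width: int,
    height: int,
    q: int,
    eta: float,
    n_sweeps: int,
    seed: int,
) -> np.ndarray:
    """Gibbs sampling of the q-state Potts model on a 4-neighbor lattice.

    The target is P(c) proportional to exp(eta * sum_i sum_{j~i}
    1(c_i = c_j)); written per spot, each lattice edge carries coupling
    2 * eta.  Starts from an i.i.d. uniform configuration and performs
    ``n_sweeps`` full raster-order sweeps.  Returns a (height, width)
    integer grid of labels in 0..q-1.
    """
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    grid = rng.integers(0, q, size=(height, width))
    if q == 1:
        return grid
    coupling = 2.0 * eta
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    color = (rr + cc) % 2
    for _ in range(n_sweeps):
        # two-color (checkerboard) sweep: sites of one color are mutually
        # non-adjacent on the 4-neighbor lattice, so their conditionals are
        # independent and may be resampled as one Gibbs block
        for col_id in (0, 1):
            mask = color == col_id
            counts = np.zeros((height, width, q))
            for k in range(q):
                is_k = (grid == k).astype(float)
                nb = np.zeros_like(is_k)
                nb[1:, :] += is_k[:-1, :]
                nb[:-1, :] += is_k[1:, :]
                nb[:, 1:] += is_k[:, :-1]
                nb[:, :-1] += is_k[:, 1:]
                counts[:, :, k] = nb
            logits = coupling * counts[mask]
            gumbel = rng.gumbel(size=logits.shape)
            grid[mask] = np.argmax(logits + gumbel, axis=-1)
    return grid


def neighbor_concordance(grid: np.ndarray) -> float:
    """Fraction of 4-neighbor lattice edges whose endpoints share a label."""
    same = 0
    total = 0
    same += int(np.sum(grid[:-1, :] == grid[1:, :]))
    total += grid[:-1, :].size
    same += int(np.sum(grid[:, :-1] == grid[:, 1:]))
    total += grid[:, :-1].size
    return same / total


def sample_pmom(n: int, lambda1: float, rng: np.random.Generator) -> np.ndarray:
    """Exact rejection sampling of the pMOM slab (l^2/lambda1) N(0, lambda1)
    with a N(0, 3*lambda1) proposal; the density ratio is bounded by 2."""
    out = np.empty(n)
    filled = 0
    bound = 2.0
    while filled < n:
        m = max(2 * (n - filled), 16)
        x = rng.normal(0.0, np.sqrt(3.0 * lambda1), size=m)
        u = x**2 / lambda1
        ratio = np.sqrt(3.0) * u * np.exp(-u / 3.0)
        accept = rng.random(m) < ratio / bound
        take = x[accept][: n - filled]
        out[filled: filled + len(take)] = take
        filled += len(take)
    return out


def _sample_loadings(p: int, d: int, sparsity: float, lambda1: float, rng) -> np.ndarray:
    """Sparse loading matrix: a (1 - sparsity) fraction of entries drawn
    from the pMOM slab, at least one nonzero per factor column."""
    L = np.zeros((p, d))
    mask = rng.random((p, d)) >= sparsity
    for k in range(d):
        if not mask[:, k].any():
            mask[rng.integers(0, p), k] = True
    n_nz = int(mask.sum())
    L[mask] = sample_pmom(n_nz, lambda1, rng)
    return L


def simulate_dataset(
    cfg: SimulationConfig | None = None, seed: int = 0, **overrides
) -> tuple[MultiSliceDataset, SimulationTruth]:
    """Draw a multi-slice dataset from the forward model with full truth.

    Per slice: Potts labels on the lattice, omega ~ Gamma(nu/2, nu/2),
    f | c=k ~ N(mu_k, omega^{-1} Lambda^{-1}), then
    y = L f + gamma_b + eps with eps ~ N(0, T_b^{-1}).  The emitted
    expression is continuous (normalized scale); counts are not simulated.
    Bit-identical for a fixed seed.
    """
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        raise ValidationError("pass either cfg or keyword overrides, not both")
    if cfg.d >= cfg.p:
        raise ValidationError(f"d={cfg.d} must be smaller than p={cfg.p}")
    if cfg.q < 1 or cfg.B < 1:
        raise ValidationError("q and B must be >= 1")
    scales = cfg.scales()
    noise_scales = list(scales["noise_scales"])
    if len(noise_scales) < cfg.B:
        noise_scales = [
            noise_scales[b % len(noise_scales)] for b in range(cfg.B)
        ]
    rng = np.random.default_rng(seed)

    L = _sample_loadings(cfg.p, cfg.d, cfg.sparsity, cfg.lambda1, rng)
    mu = rng.normal(0.0, cfg.mu_scale, size=(cfg.d, cfg.q))
    Lambda = np.eye(cfg.d)
    Lambda_chol_inv = np.eye(cfg.d)  # Lambda = I, so Lambda^{-1/2} = I

    gamma_sd = float(scales["gamma_sd"])
    gamma = rng.normal(0.0, gamma_sd, size=(cfg.p, cfg.B)) if gamma_sd > 0 else np.zeros(
        (cfg.p, cfg.B)
    )
    # identifiability convention for location effects: the additive shifts
    # sum to zero over batches (spot-weighted); the removed shared component
    # is indistinguishable from a global expression offset
    if cfg.B > 1:
        w_b = np.full(cfg.B, 1.0 / cfg.B)  # equal lattice sizes per slice
        gamma = gamma - (gamma @ w_b)[:, None]
    # per-gene noise sd jittered around noise_level * batch scale
    T = np.empty((cfg.p, cfg.B))
    for b in range(cfg.B):
        sd = cfg.noise_level * noise_scales[b] * rng.uniform(0.8, 1.2, size=cfg.p)
        if cfg.noise_level == 0:
            T[:, b] = np.inf
        else:
            T[:, b] = 1.0 / sd**2

    slices = []
    labels_all = []
    omega_all = []
    geometry = []
    for b in range(cfg.B):
        grid = sample_potts(
            cfg.width, cfg.height, cfg.q, cfg.eta, cfg.potts_sweeps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        labels = grid.ravel()
        n_b = labels.size
        omega = rng.gamma(cfg.nu_omega / 2.0, 2.0 / cfg.nu_omega, size=n_b)
        z = rng.standard_normal((n_b, cfg.d))
        f = mu[:, labels].T + (z @ Lambda_chol_inv) / np.sqrt(omega)[:, None]
        signal = f @ L.T + gamma[:, b][None, :]
        if cfg.noise_level == 0:
            y = signal
        else:
            eps = rng.standard_normal((n_b, cfg.p)) / np.sqrt(T[:, b])[None, :]
            y = signal + eps
        rows, cols = np.divmod(np.arange(n_b), cfg.width)
        coords = np.column_stack([cols, rows]).astype(float)
        slices.append(
            SliceData(
                counts=None,
                coords=coords,
                platform="ST",
                batch_id=f"sim{b}",
                barcodes=[f"sim{b}_spot{i}" for i in range(n_b)],
                genes=[f"gene{j}" for j in range(cfg.p)],
                expr=y,
            )
        )
        labels_all.append(labels)
        omega_all.append(omega)
        geometry.append((cfg.width, cfg.height))

    dataset = MultiSliceDataset(slices=slices, genes=[f"gene{j}" for j in range(cfg.p)])
    truth = SimulationTruth(
        L_true=L,
        gamma_true=gamma,
        T_true=T,
        mu_true=mu,
        Lambda_true=Lambda,
        labels_true=np.concatenate(labels_all),
        omega_true=np.concatenate(omega_all),
        geometry=geometry,
    )
    return dataset, truth


def write_truth(truth: SimulationTruth, out_dir) -> None:
    """Write the truth bundle as CSV files alongside a data bundle."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.L_true).to_csv(out / "L_true.csv", index=False)
    pd.DataFrame(truth.gamma_true).to_csv(out / "gamma_true.csv", index=False)
    pd.DataFrame(truth.T_true).to_csv(out / "T_true.csv", index=False)
    pd.DataFrame(truth.mu_true).to_csv(out / "mu_true.csv", index=False)
    pd.DataFrame(truth.Lambda_true).to_csv(out / "Lambda_true.csv", index=False)
    pd.DataFrame(
        {"label": truth.labels_true, "omega": truth.omega_true}
    ).to_csv(out / "latent_true.csv", index=False)
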