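"""Model / Results front end.

:class:`STADIA` bundles an assembled multi-slice dataset, its neighborhood
graph, and the hyperparameters; ``fit()`` runs the EM/ICM engine and
returns a :class:`STADIAResults` carrying estimates, the objective trace,
diagnostics, and serialization/plotting helpers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, graph as graph_mod, inference
from .data_io import MultiSliceDataset, SliceData, ValidationError
from .graph import NeighborGraph
from .inference import FitResult
from .model_core import Hyperparams


class STADIA:
    """Hierarchical hidden Markov random field model for multi-slice
    spatial transcriptomics.

    Parameters
    ----------
    dataset
        Assembled, normalized, gene-centered multi-slice dataset.
    n_domains
        Number of spatial domains q (required; no automatic selection).
    n_factors
        Latent dimension d of the shared factor space.
    eta
        Potts smoothness, scalar or per-batch.
    graph
        Precomputed :class:`NeighborGraph`; built from the dataset with
        platform defaults when omitted.
    **hyper_kwargs
        Remaining prior hyperparameters, forwarded to :class:`Hyperparams`.
    """

    def __init__(
        self,
        dataset: MultiSliceDataset,
        n_domains: int,
        n_factors: int = 15,
        eta: float | np.ndarray = 1.0,
        graph: NeighborGraph | None = None,
        **hyper_kwargs,
    ):
        self.dataset = dataset
        self.hyper = Hyperparams(d=n_factors, q=n_domains, eta=eta, **hyper_kwargs)
        self.graph = graph if graph is not None else graph_mod.assemble_adjacency(dataset)

    @classmethod
    def from_slices(
        cls,
        slices: list[SliceData],
        n_domains: int,
        n_hvgs: int | None = 2000,
        scale: float = 1e4,
        **kwargs,
    ) -> "STADIA":
        """Build the model from raw slices: normalize, select highly
        variable genes on the shared panel, and center."""
        normalized = [data_io.normalize_log(s, scale=scale) for s in slices]
        ds = data_io.assemble_dataset(normalized)
        if n_hvgs is not None and n_hvgs < len(ds.genes):
            panel = data_io.select_hvgs(ds, n_hvgs)
            ds = data_io.restrict_dataset(ds, panel)
        ds = data_io.center_genes(ds)
        return cls(ds, n_domains=n_domains, **kwargs)

    def fit(
        self,
        max_iter: int = 30,
        tol: float = 1e-5,
        icm_sweeps: int = 10,
        seed: int = 0,
        **fit_kwargs,
    ) -> "STADIAResults":
        res = inference.fit_em(
            self.dataset,
            self.graph,
            self.hyper,
            max_iter=max_iter,
            tol=tol,
            icm_sweeps=icm_sweeps,
            seed=seed,
            **fit_kwargs,
        )
        return STADIAResults(self, res, seed=seed)


class STADIAResults:
    """Fitted-model container.

    Attributes
    ----------
    params, latent
        Final parameter and latent-state estimates.
    domains
        Per-spot spatial-domain labels (0-based).
    embedding
        Batch-corrected n × d factor scores.
    objective_trace
        Tracked complete-data log posterior per EM iteration.
    """

    def __init__(self, model: STADIA, fit: FitResult, seed: int = 0):
        self.model = model
        self._fit = fit
        self.seed = seed
        self.params = fit.params
        self.latent = fit.latent
        self.converged = fit.converged
        self.n_iter = fit.n_iter
        self.objective_trace = fit.objective_trace

    @property
    def domains(self) -> np.ndarray:
        return self._fit.domains

    @property
    def embedding(self) -> np.ndarray:
        return self._fit.embedding

    def corrected_expression(self) -> np.ndarray:
        """Batch-free reconstruction L f (n × p)."""
        return inference.corrected_expression(self.params, self.latent)

    def domain_sizes(self) -> pd.Series:
        return pd.Series(self.domains).value_counts().sort_index()

    def summary(self) -> str:
        h = self.model.hyper
        n = self.model.dataset.n_total
        lines = [
            "STADIA fit summary",
            "=" * 58,
            f"spots: {n}   genes: {len(self.model.dataset.genes)}   "
            f"batches: {self.model.dataset.n_batches}",
            f"factors d: {h.d}   domains q: {h.q}   "
            f"eta: {np.atleast_1d(np.asarray(h.eta, float)).tolist()}",
            f"iterations: {self.n_iter}   converged: {self.converged}",
            f"final objective: {self.objective_trace[-1]:.4f}"
            if len(self.objective_trace)
            else "final objective: n/a",
            "-" * 58,
            "domain sizes:",
        ]
        for k, v in self.domain_sizes().items():
            lines.append(f"  domain {k:>3d}: {v:>8d} spots")
        nonzero = float(np.mean(self.params.incl > 0.5))
        lines.append("-" * 58)
        lines.append(f"loading entries with inclusion prob > 0.5: {nonzero:.1%}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, out_dir) -> None:
        """Write spots (with domains), embedding, parameters, and the
        objective trace as open-format CSV files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tab = self.model.dataset.spot_table()
        tab["domain"] = self.domains
        tab.to_csv(out / "domains.csv", index=False)
        pd.DataFrame(
            self.embedding, columns=[f"factor_{j}" for j in range(self.embedding.shape[1])]
        ).to_csv(out / "embedding.csv", index=False)
        genes = self.model.dataset.genes
        pd.DataFrame(self.params.L, index=genes).to_csv(out / "loadings.csv")
        pd.DataFrame(self.params.incl, index=genes).to_csv(out / "inclusion.csv")
        batches = self.model.dataset.batch_ids
        pd.DataFrame(self.params.gamma, index=genes, columns=batches).to_csv(
            out / "gamma.csv"
        )
        pd.DataFrame(self.params.T, index=genes, columns=batches).to_csv(out / "T.csv")
        pd.DataFrame(self.params.mu).to_csv(out / "mu.csv", index=False)
        pd.DataFrame(self.params.Lambda).to_csv(out / "Lambda.csv", index=False)
        pd.Series(self.objective_trace, name="log_joint").to_csv(
            out / "objective_trace.csv", index=False
        )
        manifest = {
            "seed": self.seed,
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "d": self.model.hyper.d,
            "q": self.model.hyper.q,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # -- plotting -----------------------------------------------------------

    def plot_domains(self, ax=None):
        """Scatter the spots of all slices colored by domain (one panel per
        slice side by side, offset on x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4 * self.model.dataset.n_batches, 4))
        coords = self.model.dataset.stacked_coords().astype(float).copy()
        batch = self.model.dataset.batch_of_spot()
        offset = 0.0
        for b in range(self.model.dataset.n_batches):
            rows = batch == b
            span = coords[rows, 0].max() - coords[rows, 0].min()
            coords[rows, 0] += offset - coords[rows, 0].min()
            offset += span * 1.15 + 1.0
        ax.scatter(coords[:, 0], coords[:, 1], c=self.domains, s=6, cmap="tab20")
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
        return ax

    def plot_objective(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, self.n_iter + 1), self.objective_trace, marker="o")
        ax.set_xlabel("EM iteration")
        ax.set_ylabel("complete-data log posterior")
        return ax


def load_results_domains(run_dir) -> pd.DataFrame:
    """Read the per-spot table written by :meth:`STADIAResults.save`."""
    path = Path(run_dir) / "domains.csv"
    if not path.exists():
        raise ValidationError(f"no domains.csv under {run_dir}")
    return pd.read_csv(path, dtype={"barcode": str, "batch": str})
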