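"""Model/Results front end over the factorization solvers.

``MLMF`` holds the aligned dataset and hyperparameters; ``fit`` runs the
linear (coordinate-descent) or nonlinear (projected-gradient) solver and
returns an :class:`MLMFResults` carrying the per-view factor stacks, the
consensus embedding, the loss trace and convergence status.  Subtype
assignment and diagnostics hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MultiOmicsDataset, OmicsView, align_views, zscore_standardize
from .errors import ConfigurationError
from .linear import SolverConfig, default_layer_dims, fit_linear
from .nonlinear import GradState, fit_nonlinear, get_activation
from .subtyping import cluster_consensus, estimate_num_clusters

__all__ = ["MLMF", "MLMFResults"]


class MLMF:
    """Multi-layer matrix factorization of a multi-omics dataset.

    Parameters
    ----------
    dataset : MultiOmicsDataset
        Aligned views; build one with :func:`mlmf.align_views` or use
        :meth:`from_dataframes`.
    layer_dims : sequence of int, optional
        Layer sizes ``[d_1, ..., d_m]``.  Default: a wide hidden layer of
        ``min(100, smallest view dim / 2)`` then ``n_clusters`` (or 20).
    mode : {"linear", "nonlinear"}
    activation : {"relu", "sigmoid", "tanh", "identity"}
        Used only in nonlinear mode.
    lambda1, lambda2 : float
        Sparsity and consensus-coupling weights (default 1, 1).
    max_iter, tol : solver stopping rule (default 50 sweeps, 1e-4 relative).
    n_clusters : int, optional
        Expected subtype count; informs the default latent dimension.
    """

    def __init__(self, dataset: MultiOmicsDataset, layer_dims=None,
                 mode: str = "linear", activation: str = "relu",
                 lambda1: float = 1.0, lambda2: float = 1.0,
                 max_iter: int = 50, tol: float = 1e-4, seed: int = 0,
                 n_clusters: int | None = None):
        if mode not in ("linear", "nonlinear"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        self.dataset = dataset
        self.mode = mode
        self.activation = get_activation(activation)
        self.n_clusters = n_clusters
        if layer_dims is None:
            layer_dims = default_layer_dims(dataset, n_clusters)
        self.config = SolverConfig(layer_dims=list(layer_dims), lambda1=lambda1,
                                   lambda2=lambda2, max_iter=max_iter, tol=tol,
                                   seed=seed)
        self.config.validate_against(dataset)

    @classmethod
    def from_dataframes(cls, frames: dict, standardize: bool = True, **kwargs):
        """Build from ``{view_name: DataFrame}`` (features x samples).

        Views are z-scored per feature by default, matching the usual
        preprocessing of omics matrices before factorization.
        """
        views = []
        for name, frame in frames.items():
            view = OmicsView(name=name,
                             features=tuple(str(f) for f in frame.index),
                             samples=tuple(str(s) for s in frame.columns),
                             values=frame.to_numpy(dtype=float))
            if standardize:
                view = zscore_standardize(view)
            views.append(view)
        return cls(align_views(views), **kwargs)

    def fit(self) -> "MLMFResults":
        if self.mode == "linear":
            fit = fit_linear(self.dataset, self.config)
        else:
            fit = fit_nonlinear(self.dataset, self.config, act=self.activation)
        return MLMFResults(self, fit)


class MLMFResults:
    """Fitted factors, consensus embedding and diagnostics."""

    def __init__(self, model: MLMF, fit):
        self.model = model
        self.stacks = fit.stacks
        self.consensus = fit.consensus
        self.loss_trace = fit.loss_trace
        self.converged = fit.converged

    @property
    def n_sweeps(self) -> int:
        return len(self.loss_trace)

    def consensus_frame(self) -> pd.DataFrame:
        """Consensus embedding as samples x latent-dims DataFrame."""
        h = self.consensus.values
        cols = [f"dim{i}" for i in range(h.shape[0])]
        return pd.DataFrame(h.T, index=list(self.model.dataset.intact_samples),
                            columns=cols)

    def view_representation(self, v: int) -> pd.DataFrame:
        """Deepest representation of view ``v`` (samples x latent dims)."""
        view = self.model.dataset.views[v]
        hm = self.stacks[v].H[-1]
        cols = [f"dim{i}" for i in range(hm.shape[0])]
        return pd.DataFrame(hm.T, index=list(view.samples), columns=cols)

    def reconstruction_error(self, v: int) -> float:
        """Relative Frobenius reconstruction error of view ``v``."""
        view = self.model.dataset.views[v]
        resid = view.values - self.stacks[v].reconstruction()
        return float(np.linalg.norm(resid) / np.linalg.norm(view.values))

    def cluster(self, k: int | None = None, neighbor_k: int | None = None,
                t="auto", seed: int | None = None, restarts: int = 50):
        """Assign subtypes by spectral clustering of the consensus embedding."""
        if k is None:
            k = self.model.n_clusters
        if k is None:
            k = self.estimate_num_clusters()
        if seed is None:
            seed = self.model.config.seed
        return cluster_consensus(self.consensus, k, neighbor_k=neighbor_k,
                                 t=t, seed=seed, restarts=restarts)

    def estimate_num_clusters(self, k_max: int = 10,
                              neighbor_k: int | None = None, t="auto") -> int:
        return estimate_num_clusters(self.consensus, k_max=k_max,
                                     neighbor_k=neighbor_k, t=t)

    def plot_loss(self, ax=None):
        """Objective value per sweep (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, self.n_sweeps + 1), self.loss_trace, marker="o")
        ax.set_xlabel("sweep")
        ax.set_ylabel("objective")
        ax.set_yscale("log")
        ax.set_title(f"{self.model.mode} MLMF loss trace")
        return ax

    def summary(self) -> str:
        ds = self.model.dataset
        cfg = self.model.config
        lines = [
            "Multi-Layer Matrix Factorization Results",
            "=" * 48,
            f"mode:             {self.model.mode}"
            + (f" ({self.model.activation.name})"
               if self.model.mode == "nonlinear" else ""),
            f"views:            {ds.n_views}",
            f"intact samples:   {ds.n_samples}",
            f"layer dims:       {cfg.layer_dims}",
            f"lambda1/lambda2:  {cfg.lambda1:g} / {cfg.lambda2:g}",
            f"sweeps run:       {self.n_sweeps} (max {cfg.max_iter})",
            f"converged:        {self.converged} (tol {cfg.tol:g})",
            f"final objective:  {self.loss_trace[-1]:.6g}",
            "-" * 48,
            "view      D_v    N_v   rel. recon. error",
        ]
        for v, view in enumerate(ds.views):
            lines.append(f"{view.name:<8} {view.n_features:>5} {view.n_samples:>6}"
                         f"   {self.reconstruction_error(v):.4f}")
        return "\n".join(lines)
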