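"""Linear multi-layer semi-NMF with consensus fusion.

Each view ``X^(v)`` (D_v x N_v) is factorized through ``m`` layers,

    X^(v) ~= Z_1^(v) Z_2^(v) ... Z_m^(v) H_m^(v),   H_m^(v) >= 0,

with only the deepest representation constrained nonnegative (semi-NMF:
bases and data may be mixed-sign).  The per-view deep representations are
coupled to one consensus embedding ``H`` (d x N over the intact samples)
through indicator matrices ``G^(v)``, giving the objective

    sum_v ||X - Z_1..Z_m H_m||_F^2
        + lambda1 * sum_j ||(H_m)_.j||_1^2
        + lambda2 * ||H_m - H G||_F^2.

Coordinate descent alternates exact pseudoinverse updates for the bases,
a sign-safe multiplicative update for ``H_m``, and the closed-form
consensus update; each step is individually non-increasing, so the sweep
loss trace descends monotonically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment

from .data import IndicatorMatrix, MultiOmicsDataset, OmicsView, pos_neg_split
from .errors import ConfigurationError, NumericalError, SingularityError

__all__ = [
    "FactorStack",
    "ConsensusRepresentation",
    "SolverConfig",
    "LinearFit",
    "initialize_stack",
    "align_factor_frames",
    "update_basis_Z",
    "update_deep_H",
    "update_intermediate_H",
    "update_consensus",
    "sparsity_trace",
    "sparsity_l1",
    "linear_objective",
    "fit_linear",
    "default_layer_dims",
]


@dataclass
class FactorStack:
    """Per-view factor hierarchy: bases ``Z_1..Z_m`` and representations
    ``H_1..H_m`` with ``H_m >= 0``.

    Shapes chain-conform: ``Z_i`` is ``d_{i-1} x d_i`` (``d_0 = D_v``) and
    ``H_i`` is ``d_i x N_v``, so ``Z_1...Z_m H_m`` reconstructs ``D_v x N_v``.
    Intermediate representations may be mixed-sign; only the deepest layer
    carries the nonnegativity constraint.
    """

    Z: list
    H: list

    def __post_init__(self):
        if len(self.Z) != len(self.H) or not self.Z:
            raise ConfigurationError("stack needs matching, non-empty Z and H lists")
        for i in range(len(self.Z)):
            if self.Z[i].shape[1] != self.H[i].shape[0]:
                raise ConfigurationError(f"layer {i + 1}: Z/H inner dims disagree")
            if i > 0 and self.Z[i].shape[0] != self.Z[i - 1].shape[1]:
                raise ConfigurationError(f"layer {i + 1}: basis chain broken")
        if (self.H[-1] < 0).any():
            raise ConfigurationError("deepest representation must be nonnegative")

    @property
    def n_layers(self) -> int:
        return len(self.Z)

    @property
    def layer_dims(self):
        return [z.shape[1] for z in self.Z]

    def basis_product(self, upto: int | None = None) -> np.ndarray:
        """Psi_i = Z_1 ... Z_i (all layers when ``upto`` is None)."""
        upto = self.n_layers if upto is None else upto
        out = self.Z[0]
        for z in self.Z[1:upto]:
            out = out @ z
        return out if upto >= 1 else np.eye(self.Z[0].shape[0])

    def reconstruction(self) -> np.ndarray:
        return self.basis_product() @ self.H[-1]


@dataclass(frozen=True)
class ConsensusRepresentation:
    """Shared latent embedding, ``d x N`` over the intact samples."""

    values: np.ndarray
    samples: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "samples", tuple(self.samples))
        if v.ndim != 2 or not np.isfinite(v).all():
            raise NumericalError("consensus representation must be a finite 2-D matrix")

    @property
    def latent_dim(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SolverConfig:
    """Hyperparameters shared by both solvers.

    ``lambda1`` weighs the column-sparsity penalty sum_j ||(H_m)_.j||_1^2,
    ``lambda2`` the consensus coupling; both default to 1.  ``max_iter=50``
    sweeps and relative tolerance ``tol=1e-4`` on the objective stop the
    outer loop.  ``eps`` guards multiplicative-update denominators.
    """

    layer_dims: list
    lambda1: float = 1.0
    lambda2: float = 1.0
    max_iter: int = 50
    tol: float = 1e-4
    seed: int = 0
    eps: float = 1e-12

    def __post_init__(self):
        self.layer_dims = [int(d) for d in self.layer_dims]
        if not self.layer_dims or any(d <= 0 for d in self.layer_dims):
            raise ConfigurationError("layer_dims must be positive integers")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ConfigurationError("lambda1, lambda2 must be nonnegative")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.tol <= 0 or self.eps <= 0:
            raise ConfigurationError("tol and eps must be positive")

    @property
    def latent_dim(self) -> int:
        return self.layer_dims[-1]

    def validate_against(self, dataset: MultiOmicsDataset):
        cap = min(min(v.n_features, v.n_samples) for v in dataset.views)
        if self.latent_dim > cap:
            raise ConfigurationError(
                f"deepest layer dim {self.latent_dim} exceeds the smallest "
                f"view dimension {cap}"
            )


@dataclass
class LinearFit:
    """Outcome of :func:`fit_linear`: per-view stacks, consensus, trace."""

    stacks: list
    consensus: ConsensusRepresentation
    loss_trace: np.ndarray
    converged: bool

    def __iter__(self):  # allow (stacks, H, trace) unpacking
        return iter((self.stacks, self.consensus, self.loss_trace))


def default_layer_dims(dataset: MultiOmicsDataset, n_clusters: int | None = None):
    """Two-layer default: a wide hidden layer then the latent dimension.

    The latent dimension equals the cluster count when known, else 20,
    capped by the smallest view dimension.
    """
    cap = min(min(v.n_features, v.n_samples) for v in dataset.views)
    d = n_clusters if n_clusters is not None else 20
    d = min(d, cap)
    hidden = min(100, cap // 2)
    if hidden <= d:
        return [d]
    return [hidden, d]


def _svd_nonneg_factor(x: np.ndarray, d: int, eps: float):
    """Rank-d truncated SVD of ``x`` with deterministic signs; the
    representation is made nonnegative by a per-row shift to its minimum.

    Shifting (rather than clipping) keeps the sample geometry intact — a
    translation per latent coordinate — and leaves no hard zeros for the
    multiplicative updates to lock in place.
    """
    u, s, vt = scipy.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :d], s[:d], vt[:d]
    # fix signs so each left singular vector's largest-|.| entry is positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    u = u * flip
    vt = vt * flip[:, None]
    h = s[:, None] * vt
    h = h - np.minimum(h.min(axis=1, keepdims=True), 0.0) + eps
    return u, h


def initialize_stack(view: OmicsView, layer_dims, seed: int = 0,
                     eps: float = 1e-12) -> FactorStack:
    """Layer-wise SVD pretraining.

    Factorize ``X ~= Z_1 H_1`` by truncated SVD (signs fixed so the leading
    entry of each singular vector is positive), shift each row of ``H_1``
    into the nonnegative orthant, then recurse on ``H_1`` for the next
    layer.  Deterministic: the seed exists for interface symmetry with the
    stochastic parts of the pipeline but SVD needs no randomness.
    """
    x = view.values
    zs, hs = [], []
    for d in layer_dims:
        d = int(d)
        if d > min(x.shape):
            raise ConfigurationError(
                f"layer dim {d} exceeds current matrix shape {x.shape}"
            )
        z, h = _svd_nonneg_factor(x, d, eps)
        zs.append(z)
        hs.append(h)
        x = h
    return FactorStack(Z=zs, H=hs)


def align_factor_frames(stacks, views) -> list:
    """Align per-view latent frames by a signed row permutation of the
    deepest representation.

    Each view's SVD pretraining orders and orients latent components by its
    own spectrum, so the same biological axis can appear as a different
    (possibly flipped) coordinate in every view; fusing unaligned frames
    cancels structure.  The view observing the most samples serves as the
    reference.  For every other view the row permutation and signs of
    ``H_m`` that best correlate (on shared samples, after centering) with
    the reference's rows are found by linear assignment; the inverse
    transform is absorbed into ``Z_m`` so the reconstruction is unchanged,
    and flipped rows are re-shifted into the nonnegative orthant.
    Views sharing fewer than 3 samples with the reference are left as-is.
    """
    views = list(views)
    ref = max(range(len(views)), key=lambda v: (views[v].n_samples, -v))
    ref_view, ref_stack = views[ref], stacks[ref]
    ref_pos = {s: j for j, s in enumerate(ref_view.samples)}
    for v in range(len(stacks)):
        if v == ref:
            continue
        view, stack = views[v], stacks[v]
        own_pos = {s: j for j, s in enumerate(view.samples)}
        shared = [s for s in view.samples if s in ref_pos]
        if len(shared) < 3:
            continue
        a = stack.H[-1][:, [own_pos[s] for s in shared]]
        b = ref_stack.H[-1][:, [ref_pos[s] for s in shared]]
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        corr = bc @ ac.T
        rows, cols = linear_sum_assignment(-np.abs(corr))
        perm = np.empty(len(rows), dtype=int)
        sign = np.empty(len(rows))
        for i, j in zip(rows, cols):
            perm[i] = j
            sign[i] = 1.0 if corr[i, j] >= 0 else -1.0
        h = sign[:, None] * stack.H[-1][perm]
        stack.Z[-1] = stack.Z[-1][:, perm] * sign[None, :]
        stack.H[-1] = h - np.minimum(h.min(axis=1, keepdims=True), 0.0) + 1e-12
    return stacks


def update_basis_Z(stack: FactorStack, view: OmicsView, i: int) -> FactorStack:
    """Exact least-squares update of the i-th basis (1-based layer index):

        Z_i <- phi^+ X H~_i^+ ,  phi = Z_1..Z_{i-1},  H~_i = Z_{i+1}..Z_m H_m,

    the minimum-norm minimizer of ||X - phi Z_i H~_i||_F^2 with all other
    factors fixed, so the reconstruction term never increases.
    """
    m = stack.n_layers
    if not 1 <= i <= m:
        raise ConfigurationError(f"layer index {i} outside 1..{m}")
    phi = stack.basis_product(i - 1) if i > 1 else None
    h_tilde = stack.H[-1]
    for z in reversed(stack.Z[i:]):
        h_tilde = z @ h_tilde
    x = view.values
    left = np.linalg.pinv(phi) @ x if phi is not None else x
    z_new = left @ np.linalg.pinv(h_tilde)
    if not np.isfinite(z_new).all():
        raise NumericalError(f"basis update produced non-finite values at layer {i}")
    stack.Z[i - 1] = z_new
    return stack


def update_deep_H(stack: FactorStack, view: OmicsView, G: IndicatorMatrix,
                  H: ConsensusRepresentation, cfg: SolverConfig) -> FactorStack:
    """Sign-safe multiplicative update of the deepest representation.

    With ``A = H_m``, ``Psi = Z_1..Z_m``, ``B = Psi' X + lambda2 H G`` and
    ``C = Psi' Psi + lambda1 E + lambda2 I`` (E all-ones), the rule

        A <- A * sqrt( (B+ + C- A) / (B- + C+ A + eps) )

    is the standard auxiliary-function-monotone semi-NMF step for the
    quadratic ``tr(A'CA) - 2 tr(B'A)``; zeros of ``A`` are preserved.
    """
    a = stack.H[-1]
    psi = stack.basis_product()
    d = a.shape[0]
    b = psi.T @ view.values + cfg.lambda2 * (H.values @ G.values)
    c = psi.T @ psi + cfg.lambda1 * np.ones((d, d)) + cfg.lambda2 * np.eye(d)
    bp, bm = pos_neg_split(b)
    cp, cm = pos_neg_split(c)
    a_new = a * np.sqrt((bp + cm @ a) / (bm + cp @ a + cfg.eps))
    if not np.isfinite(a_new).all():
        raise NumericalError("deep representation update produced non-finite values")
    stack.H[-1] = a_new
    return stack


def update_intermediate_H(stack: FactorStack, view: OmicsView, i: int,
                          eps: float = 1e-12) -> FactorStack:
    """Multiplicative refresh of an intermediate representation (i < m):

        H_i <- H_i * sqrt( ((Psi_i'X)+ + (Psi_i'Psi_i)- H_i)
                         / ((Psi_i'X)- + (Psi_i'Psi_i)+ H_i + eps) )

    with ``Psi_i = Z_1..Z_i`` — the canonical deep semi-NMF step driving
    ``H_i`` toward the least-squares fit of ``X ~= Psi_i H_i``.  The stored
    intermediate layers expose the per-depth feature hierarchy; the global
    objective depends only on the bases and the deepest layer.
    """
    m = stack.n_layers
    if not 1 <= i < m:
        raise ConfigurationError(f"intermediate layer index {i} outside 1..{m - 1}")
    psi = stack.basis_product(i)
    p = psi.T @ view.values
    q = psi.T @ psi
    pp, pm = pos_neg_split(p)
    qp, qm = pos_neg_split(q)
    h = stack.H[i - 1]
    h_new = h * np.sqrt((pp + qm @ h) / (pm + qp @ h + eps))
    if not np.isfinite(h_new).all():
        raise NumericalError(f"intermediate update produced non-finite values, layer {i}")
    stack.H[i - 1] = h_new
    return stack


def update_consensus(stacks, Gs) -> ConsensusRepresentation:
    """Closed-form consensus update

        H = [ sum_v H_m^(v) G^(v)' ] [ sum_v G^(v) G^(v)' ]^{-1},

    the exact minimizer of sum_v ||H_m^(v) - H G^(v)||_F^2.  The Gram sum is
    diagonal (entry j = number of views observing intact sample j) and is
    invertible iff every intact sample is observed at least once.
    """
    num = None
    den = None
    for stack, g in zip(stacks, Gs):
        hm = stack.H[-1]
        gv = g.values
        num = hm @ gv.T if num is None else num + hm @ gv.T
        den = gv @ gv.T if den is None else den + gv @ gv.T
    diag = np.diag(den)
    if (diag < 1).any():
        j = int(np.argmin(diag))
        raise SingularityError(
            f"intact sample at position {j} is observed in zero views"
        )
    h = np.linalg.solve(den.T, num.T).T
    return ConsensusRepresentation(values=h)


def sparsity_trace(hm: np.ndarray) -> float:
    """Sparsity penalty in trace form, ``Tr(H_m H_m' E)`` with E all-ones."""
    d = hm.shape[0]
    e = np.ones((d, d))
    return float(np.trace(hm @ hm.T @ e))


def sparsity_l1(hm: np.ndarray) -> float:
    """Sparsity penalty as squared column l1 norms, ``sum_j ||(H_m)_.j||_1^2``."""
    return float((np.abs(hm).sum(axis=0) ** 2).sum())


def linear_objective(stacks, Gs, H: ConsensusRepresentation,
                     cfg: SolverConfig, views) -> float:
    """Full objective: reconstruction + lambda1 sparsity + lambda2 coupling."""
    total = 0.0
    for stack, g, view in zip(stacks, Gs, views):
        resid = view.values - stack.reconstruction()
        total += float((resid ** 2).sum())
        total += cfg.lambda1 * sparsity_trace(stack.H[-1])
        coupling = stack.H[-1] - H.values @ g.values
        total += cfg.lambda2 * float((coupling ** 2).sum())
    return total


def fit_linear(dataset: MultiOmicsDataset, cfg: SolverConfig) -> LinearFit:
    """Coordinate-descent fit of the linear model.

    One sweep updates, per view, the bases ``Z_1..Z_m`` (ascending),
    the intermediate representations, then the deepest ``H_m``; the
    consensus ``H`` closes the sweep.  Stops when the relative objective
    change drops below ``cfg.tol`` or after ``cfg.max_iter`` sweeps.
    """
    cfg.validate_against(dataset)
    stacks = [initialize_stack(v, cfg.layer_dims, seed=cfg.seed, eps=cfg.eps)
              for v in dataset.views]
    align_factor_frames(stacks, dataset.views)
    Gs = dataset.indicators()
    H = update_consensus(stacks, Gs)
    loss_prev = linear_objective(stacks, Gs, H, cfg, dataset.views)
    trace = []
    converged = False
    m = len(cfg.layer_dims)
    for sweep in range(cfg.max_iter):
        try:
            for stack, g, view in zip(stacks, Gs, dataset.views):
                for i in range(1, m + 1):
                    update_basis_Z(stack, view, i)
                for i in range(1, m):
                    update_intermediate_H(stack, view, i, eps=cfg.eps)
                update_deep_H(stack, view, g, H, cfg)
            H = update_consensus(stacks, Gs)
        except NumericalError as exc:
            raise NumericalError(f"sweep {sweep + 1}: {exc}") from exc
        loss = linear_objective(stacks, Gs, H, cfg, dataset.views)
        trace.append(loss)
        rel = abs(loss_prev - loss) / max(abs(loss_prev), cfg.eps)
        loss_prev = loss
        if rel < cfg.tol:
            converged = True
            break
    return LinearFit(stacks=stacks,
                     consensus=ConsensusRepresentation(
                         values=H.values, samples=dataset.intact_samples),
                     loss_trace=np.asarray(trace), converged=converged)
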