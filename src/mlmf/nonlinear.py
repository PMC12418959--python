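"""Nonlinear multi-layer factorization fitted by projected gradient descent.

The nonlinear model composes the layers through an elementwise activation,

    X^(v) ~= Z_1 f( Z_2 f( ... f( Z_m H_m ) ) ),   H_m >= 0,

(the outermost layer stays linear), with the same sparsity and consensus
penalties as the linear model.  Hidden representations are the cached
post-activation values ``f(Z_i H_i)`` — implicit functions of the deeper
factors — so the free parameters are ``H_m``, the bases ``Z_i``, and the
consensus ``H``.  Each is updated by a gradient step with monotone
backtracking line search (the "adaptive step size"), and ``H_m`` is
projected back onto the nonnegative orthant, so the loss trace is
non-increasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import IndicatorMatrix, MultiOmicsDataset, OmicsView
from .errors import ConfigurationError, NumericalError
from .linear import (ConsensusRepresentation, FactorStack, LinearFit,
                     SolverConfig, align_factor_frames, initialize_stack,
                     sparsity_trace, update_consensus)

__all__ = [
    "Activation",
    "GradState",
    "get_activation",
    "forward_reconstruct",
    "nonlinear_objective",
    "grad_intermediate_H",
    "grad_Z",
    "grad_consensus",
    "fit_nonlinear",
]


@dataclass(frozen=True)
class Activation:
    """Elementwise nonlinearity with its derivative."""

    name: str
    f: callable
    grad_f: callable


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    # subgradient at 0 taken as 0
    return (x > 0).astype(float)


def _sigmoid_grad(x):
    s = expit(x)
    return s * (1.0 - s)


_ACTIVATIONS = {
    "relu": Activation("relu", _relu, _relu_grad),
    "sigmoid": Activation("sigmoid", expit, _sigmoid_grad),
    "tanh": Activation("tanh", np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "identity": Activation("identity", lambda x: x, lambda x: np.ones_like(x)),
}


def get_activation(name) -> Activation:
    if isinstance(name, Activation):
        return name
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


@dataclass
class GradState:
    """Backtracking line-search state for one parameter block."""

    step_size: float = 1e-2
    backtrack_factor: float = 0.5
    grow_factor: float = 1.2
    max_backtracks: int = 30

    def __post_init__(self):
        if self.step_size <= 0:
            raise ConfigurationError("step size must be positive")
        if not 0 < self.backtrack_factor < 1:
            raise ConfigurationError("backtrack_factor must be in (0, 1)")
        if self.grow_factor <= 1:
            raise ConfigurationError("grow_factor must exceed 1")


@dataclass
class ForwardCache:
    """Per-layer intermediates of one forward pass.

    ``hidden[i-1]`` is the post-activation input to layer ``i`` (so
    ``hidden[m-1]`` is ``H_m`` itself) and ``pre[i-1]`` the pre-activation
    ``Z_i H_i`` for ``i >= 2`` (``None`` for the linear outermost layer).
    """

    hidden: list
    pre: list


def forward_reconstruct(stack: FactorStack, act: Activation):
    """Compute ``X^ = Z_1 f(Z_2 f(...f(Z_m H_m)))`` and cache intermediates."""
    m = stack.n_layers
    hidden = [None] * m
    pre = [None] * m
    hidden[m - 1] = stack.H[-1]
    for i in range(m, 1, -1):  # layers m..2 pass through the activation
        p = stack.Z[i - 1] @ hidden[i - 1]
        if not np.isfinite(p).all():
            raise NumericalError(f"overflow in activation argument at layer {i}")
        pre[i - 1] = p
        hidden[i - 2] = act.f(p)
    xhat = stack.Z[0] @ hidden[0]
    if not np.isfinite(xhat).all():
        raise NumericalError("overflow in reconstruction")
    return xhat, ForwardCache(hidden=hidden, pre=pre)


def nonlinear_objective(stacks, Gs, H: ConsensusRepresentation,
                        cfg: SolverConfig, views, act: Activation) -> float:
    """Reconstruction + lambda1 sparsity + lambda2 consensus coupling."""
    act = get_activation(act)
    total = 0.0
    for stack, g, view in zip(stacks, Gs, views):
        xhat, _ = forward_reconstruct(stack, act)
        total += float(((view.values - xhat) ** 2).sum())
        total += cfg.lambda1 * sparsity_trace(stack.H[-1])
        coupling = stack.H[-1] - H.values @ g.values
        total += cfg.lambda2 * float((coupling ** 2).sum())
    return total


def _backprop(stack: FactorStack, view: OmicsView, act: Activation,
              cache: ForwardCache):
    """Gradients of the reconstruction term w.r.t. every hidden input and
    basis.  Returns (d_hidden, d_Z) lists, 0-indexed by layer."""
    m = stack.n_layers
    xhat = stack.Z[0] @ cache.hidden[0]
    r = 2.0 * (xhat - view.values)
    d_hidden = [None] * m
    d_z = [None] * m
    d_z[0] = r @ cache.hidden[0].T
    d_hidden[0] = stack.Z[0].T @ r
    for i in range(2, m + 1):
        dp = d_hidden[i - 2] * act.grad_f(cache.pre[i - 1])
        d_z[i - 1] = dp @ cache.hidden[i - 1].T
        d_hidden[i - 1] = stack.Z[i - 1].T @ dp
    return d_hidden, d_z


def grad_intermediate_H(stack: FactorStack, view: OmicsView, i: int,
                        act: Activation, cache: ForwardCache | None = None,
                        G: IndicatorMatrix | None = None,
                        H: ConsensusRepresentation | None = None,
                        cfg: SolverConfig | None = None) -> np.ndarray:
    """Gradient of the loss w.r.t. the hidden input of layer ``i`` (1-based).

    For ``i = m`` this is the gradient w.r.t. the free variable ``H_m`` and
    includes the penalty terms ``2 lambda1 E H_m + 2 lambda2 (H_m - H G)``
    when ``G``, ``H`` and ``cfg`` are supplied.
    """
    act = get_activation(act)
    m = stack.n_layers
    if not 1 <= i <= m:
        raise ConfigurationError(f"layer index {i} outside 1..{m}")
    if cache is None:
        _, cache = forward_reconstruct(stack, act)
    d_hidden, _ = _backprop(stack, view, act, cache)
    grad = d_hidden[i - 1]
    if i == m and cfg is not None and G is not None and H is not None:
        hm = stack.H[-1]
        d = hm.shape[0]
        grad = grad + 2.0 * cfg.lambda1 * np.ones((d, d)) @ hm
        grad = grad + 2.0 * cfg.lambda2 * (hm - H.values @ G.values)
    return grad


def grad_Z(stack: FactorStack, view: OmicsView, i: int, act: Activation,
           cache: ForwardCache | None = None) -> np.ndarray:
    """Gradient of the reconstruction term w.r.t. basis ``Z_i`` (1-based)."""
    act = get_activation(act)
    if not 1 <= i <= stack.n_layers:
        raise ConfigurationError(f"layer index {i} outside 1..{stack.n_layers}")
    if cache is None:
        _, cache = forward_reconstruct(stack, act)
    _, d_z = _backprop(stack, view, act, cache)
    return d_z[i - 1]


def grad_consensus(stacks, Gs, H: ConsensusRepresentation,
                   cfg: SolverConfig) -> np.ndarray:
    """Gradient of the coupling term w.r.t. the consensus ``H``:

        2 lambda2 sum_v ( H G^(v) G^(v)' - H_m^(v) G^(v)' );

    vanishes exactly at the closed-form consensus of the linear solver.
    """
    grad = np.zeros_like(H.values)
    for stack, g in zip(stacks, Gs):
        gv = g.values
        grad += H.values @ gv @ gv.T - stack.H[-1] @ gv.T
    return 2.0 * cfg.lambda2 * grad


def _line_search(current_loss, param, grad, state: GradState, set_param,
                 evaluate, project=None):
    """Monotone backtracking step on one block.

    Accepts the largest step (starting at ``state.step_size``, halving) for
    which the objective does not increase; grows the step after a full
    accepted step; reverts the block if ``max_backtracks`` is exhausted.
    Returns (new_loss, accepted).
    """
    alpha = state.step_size
    for attempt in range(state.max_backtracks + 1):
        candidate = param - alpha * grad
        if project is not None:
            candidate = project(candidate)
        set_param(candidate)
        loss = evaluate()
        if loss <= current_loss:
            if attempt == 0:
                state.step_size = alpha * state.grow_factor
            else:
                state.step_size = alpha
            return loss, True
        alpha *= state.backtrack_factor
    set_param(param)  # revert
    state.step_size = alpha
    return current_loss, False


def fit_nonlinear(dataset: MultiOmicsDataset, cfg: SolverConfig,
                  act="relu", grad_state: GradState | None = None) -> LinearFit:
    """Projected-gradient fit of the nonlinear model.

    Factors are pretrained with the linear layer-wise SVD initialization;
    each sweep takes one line-searched gradient step on ``H_m`` (projected
    onto the nonnegative orthant) and on every basis ``Z_i`` per view, then
    on the consensus ``H``.  Because a step is only accepted when the full
    objective does not increase, the per-sweep loss trace is non-increasing
    exactly.  If every block of a sweep exhausts its backtracks the fit
    stops with a warning rather than an error.
    """
    act = get_activation(act)
    cfg.validate_against(dataset)
    proto = grad_state if grad_state is not None else GradState()
    stacks = [initialize_stack(v, cfg.layer_dims, seed=cfg.seed, eps=cfg.eps)
              for v in dataset.views]
    align_factor_frames(stacks, dataset.views)
    Gs = dataset.indicators()
    H = update_consensus(stacks, Gs)
    views = dataset.views
    m = len(cfg.layer_dims)

    def objective():
        return nonlinear_objective(stacks, Gs, H, cfg, views, act)

    # independent step-size state per parameter block
    states = {}
    for v in range(len(views)):
        states[("hm", v)] = GradState(proto.step_size, proto.backtrack_factor,
                                      proto.grow_factor, proto.max_backtracks)
        for i in range(1, m + 1):
            states[("z", v, i)] = GradState(proto.step_size, proto.backtrack_factor,
                                            proto.grow_factor, proto.max_backtracks)
    states["consensus"] = GradState(proto.step_size, proto.backtrack_factor,
                                    proto.grow_factor, proto.max_backtracks)

    loss = objective()
    trace = []
    converged = False
    for sweep in range(cfg.max_iter):
        loss_start = loss
        any_accepted = False
        for v, (stack, g, view) in enumerate(zip(stacks, Gs, views)):
            _, cache = forward_reconstruct(stack, act)
            g_hm = grad_intermediate_H(stack, view, m, act, cache,
                                       G=g, H=H, cfg=cfg)

            def set_hm(val, stack=stack):
                stack.H[-1] = val

            loss, ok = _line_search(loss, stack.H[-1], g_hm, states[("hm", v)],
                                    set_hm, objective,
                                    project=lambda x: np.clip(x, 0.0, None))
            any_accepted |= ok
            for i in range(1, m + 1):
                _, cache = forward_reconstruct(stack, act)
                g_z = grad_Z(stack, view, i, act, cache)

                def set_z(val, stack=stack, i=i):
                    stack.Z[i - 1] = val

                loss, ok = _line_search(loss, stack.Z[i - 1], g_z,
                                        states[("z", v, i)], set_z, objective)
                any_accepted |= ok
        g_h = grad_consensus(stacks, Gs, H, cfg)

        def set_h(val):
            nonlocal H
            H = ConsensusRepresentation(values=val)

        loss, ok = _line_search(loss, H.values, g_h, states["consensus"],
                                set_h, objective)
        any_accepted |= ok
        trace.append(loss)
        if not any_accepted:
            warnings.warn(
                f"line search stalled at sweep {sweep + 1}; treating as converged",
                stacklevel=2,
            )
            converged = True
            break
        rel = abs(loss_start - loss) / max(abs(loss_start), cfg.eps)
        if rel < cfg.tol:
            converged = True
            break
    return LinearFit(stacks=stacks,
                     consensus=ConsensusRepresentation(
                         values=H.values, samples=dataset.intact_samples),
                     loss_trace=np.asarray(trace), converged=converged)
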