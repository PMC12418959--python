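"""Linear solver: initialization, updates, objective, full fits."""

import numpy as np
import pytest

from mlmf.data import align_views, build_indicator_matrix
from mlmf.errors import ConfigurationError, SingularityError
from mlmf.linear import (ConsensusRepresentation, FactorStack, SolverConfig,
                         fit_linear, initialize_stack, linear_objective,
                         sparsity_l1, sparsity_trace, update_basis_Z,
                         update_consensus, update_deep_H,
                         update_intermediate_H)
from mlmf.simulate import SimulationConfig, generate_dataset
from tests.conftest import make_single_view_dataset, make_view


def scalar_loop_objective(stacks, Gs, H, cfg, views):
    """Independent elementwise re-summation of the objective."""
    total = 0.0
    for stack, g, view in zip(stacks, Gs, views):
        recon = stack.Z[0]
        for z in stack.Z[1:]:
            recon = recon @ z
        recon = recon @ stack.H[-1]
        for a in range(view.n_features):
            for b in range(view.n_samples):
                total += (view.values[a, b] - recon[a, b]) ** 2
        hm = stack.H[-1]
        for j in range(hm.shape[1]):
            total += cfg.lambda1 * sum(abs(hm[i, j]) for i in range(hm.shape[0])) ** 2
        hg = H.values @ g.values
        for i in range(hm.shape[0]):
            for j in range(hm.shape[1]):
                total += cfg.lambda2 * (hm[i, j] - hg[i, j]) ** 2
    return total


class TestInitializeStack:
    def test_exact_recovery_when_svd_frame_is_nonnegative(self, rng):
        # X built from an SVD whose representation rows each touch zero:
        # the nonnegativity shift is then a no-op and the init must match
        # the best rank-2 truncation exactly (zero error here).
        u, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(2)])
        u *= flip
        # orthogonal rows (so they are the SVD frame) whose minima are 0:
        # the nonnegativity shift is then the identity
        h = np.array([[3.0, 0.0, 1.0, 0.0], [0.0, 2.0, 0.0, 0.5]])
        x = u @ h
        stack = initialize_stack(make_view(x), [2])
        err = np.linalg.norm(x - stack.Z[0] @ stack.H[0])
        assert err <= 1e-8

    def test_deterministic(self, rng):
        view = make_view(rng.normal(size=(12, 9)))
        a = initialize_stack(view, [5, 3], seed=0)
        b = initialize_stack(view, [5, 3], seed=0)
        for za, zb in zip(a.Z, b.Z):
            np.testing.assert_array_equal(za, zb)
        for ha, hb in zip(a.H, b.H):
            np.testing.assert_array_equal(ha, hb)

    def test_oversized_layer_rejected(self, rng):
        view = make_view(rng.normal(size=(50, 30)))
        with pytest.raises(ConfigurationError):
            initialize_stack(view, [200])

    def test_shapes_chain_and_nonnegative_layers(self, rng):
        view = make_view(rng.normal(size=(20, 15)))
        stack = initialize_stack(view, [8, 4])
        assert stack.layer_dims == [8, 4]
        assert stack.reconstruction().shape == (20, 15)
        assert (stack.H[-1] >= 0).all()


class TestUpdateBasisZ:
    def test_single_layer_least_squares_recovers_exact_basis(self, rng):
        z_true = rng.normal(size=(10, 3))
        h = rng.uniform(0.1, 1, size=(3, 8))  # full row rank
        view = make_view(z_true @ h)
        stack = FactorStack(Z=[rng.normal(size=(10, 3))], H=[h.copy()])
        update_basis_Z(stack, view, 1)
        np.testing.assert_allclose(stack.Z[0], z_true, atol=1e-8)

    def test_rank_deficient_gives_minimum_norm_solution(self, rng):
        h = np.vstack([rng.uniform(0.1, 1, size=(2, 8)),
                       np.zeros((1, 8))])  # rank 2 < d=3
        view = make_view(rng.normal(size=(6, 8)))
        stack = FactorStack(Z=[rng.normal(size=(6, 3))], H=[h])
        update_basis_Z(stack, view, 1)
        expect = view.values @ np.linalg.pinv(h)
        np.testing.assert_allclose(stack.Z[0], expect, atol=1e-10)

    def test_reconstruction_term_never_increases(self, rng):
        view = make_view(rng.normal(size=(12, 10)))
        stack = initialize_stack(view, [5, 3])
        for i in (1, 2):
            before = np.linalg.norm(view.values - stack.reconstruction()) ** 2
            update_basis_Z(stack, view, i)
            after = np.linalg.norm(view.values - stack.reconstruction()) ** 2
            assert after <= before + 1e-9 * before


class TestUpdateDeepH:
    def _setup(self, rng, d=2, D=6, n=5):
        view = make_view(rng.normal(size=(D, n)))
        ds = align_views([view])
        g = ds.indicators()[0]
        stack = initialize_stack(view, [d])
        h = ConsensusRepresentation(values=rng.normal(size=(d, n)))
        cfg = SolverConfig(layer_dims=[d], lambda1=1, lambda2=1)
        return ds, view, g, stack, h, cfg

    def test_objective_non_increasing(self, rng):
        ds, view, g, stack, h, cfg = self._setup(rng)
        for _ in range(5):
            before = linear_objective([stack], [g], h, cfg, [view])
            update_deep_H(stack, view, g, h, cfg)
            after = linear_objective([stack], [g], h, cfg, [view])
            assert after <= before + 1e-9 * abs(before)

    def test_result_nonnegative_and_zeros_preserved(self, rng):
        ds, view, g, stack, h, cfg = self._setup(rng)
        stack.H[-1][0, 0] = 0.0
        update_deep_H(stack, view, g, h, cfg)
        assert (stack.H[-1] >= 0).all()
        assert stack.H[-1][0, 0] == 0.0

    def test_stationary_point_unchanged(self, rng):
        # construct B = C A with all parts consistent: nonnegative Psi and
        # consensus chosen so that the multiplicative ratio is exactly 1
        d, n = 2, 4
        a = rng.uniform(0.5, 1.5, size=(d, n))
        psi = rng.uniform(0.1, 1.0, size=(6, d))
        c = psi.T @ psi + np.ones((d, d)) + np.eye(d)
        b = c @ a  # entrywise positive
        # choose X and H consistent with B = Psi'X + lambda2 H G, G = I
        x = np.linalg.lstsq(psi.T, b - a, rcond=None)[0]
        h = ConsensusRepresentation(values=a.copy())
        b_check = psi.T @ x + a
        np.testing.assert_allclose(b_check, b, atol=1e-9)
        view = make_view(x)
        ds = align_views([view])
        g = ds.indicators()[0]
        stack = FactorStack(Z=[psi], H=[a.copy()])
        cfg = SolverConfig(layer_dims=[d], lambda1=1, lambda2=1)
        update_deep_H(stack, view, g, h, cfg)
        np.testing.assert_allclose(stack.H[-1], a, atol=1e-8)


class TestUpdateIntermediateH:
    def test_reconstruction_of_first_layer_non_increasing(self, rng):
        view = make_view(rng.normal(size=(12, 10)))
        stack = initialize_stack(view, [5, 3])
        stack.H[0] = rng.uniform(0.1, 1.0, size=stack.H[0].shape)
        psi1 = stack.Z[0]
        before = np.linalg.norm(view.values - psi1 @ stack.H[0]) ** 2
        update_intermediate_H(stack, view, 1)
        after = np.linalg.norm(view.values - psi1 @ stack.H[0]) ** 2
        assert after <= before + 1e-9 * before

    def test_zeros_preserved(self, rng):
        view = make_view(rng.normal(size=(8, 6)))
        stack = initialize_stack(view, [4, 2])
        stack.H[0][1, 1] = 0.0
        update_intermediate_H(stack, view, 1)
        assert stack.H[0][1, 1] == 0.0

    def test_reduces_to_classical_nmf_form_on_nonnegative_system(self, rng):
        # when Psi'Psi >= 0 and Psi'X >= 0 the negative parts vanish and the
        # update is H * sqrt(P / (Q H))
        psi = rng.uniform(0.1, 1.0, size=(8, 3))
        h0 = rng.uniform(0.1, 1.0, size=(3, 6))
        x = psi @ h0
        view = make_view(x)
        z2 = rng.uniform(0.1, 1.0, size=(3, 2))
        h2 = rng.uniform(0.1, 1.0, size=(2, 6))
        stack = FactorStack(Z=[psi, z2], H=[h0.copy(), h2])
        update_intermediate_H(stack, view, 1)
        p = psi.T @ x
        q = psi.T @ psi
        expect = h0 * np.sqrt(p / (q @ h0 + 1e-12))
        np.testing.assert_allclose(stack.H[0], expect, atol=1e-12)


class TestUpdateConsensus:
    def test_single_complete_view_is_identity(self, rng):
        view = make_view(rng.normal(size=(6, 5)))
        ds = align_views([view])
        stack = initialize_stack(view, [2])
        h = update_consensus([stack], ds.indicators())
        np.testing.assert_allclose(h.values, stack.H[-1], atol=1e-12)

    def test_two_complete_views_average(self, rng):
        v1 = make_view(rng.normal(size=(6, 5)), name="a")
        v2 = make_view(rng.normal(size=(4, 5)), name="b")
        ds = align_views([v1, v2])
        s1 = initialize_stack(v1, [2])
        s2 = initialize_stack(v2, [2])
        h = update_consensus([s1, s2], ds.indicators())
        np.testing.assert_allclose(h.values, (s1.H[-1] + s2.H[-1]) / 2, atol=1e-12)

    def test_partial_view_matches_generic_least_squares(self, rng):
        # view 2 misses the last sample: its column of H comes from view 1 alone
        v1 = make_view(rng.normal(size=(5, 3)), name="a")
        from mlmf.data import OmicsView
        v2 = OmicsView("b", ("f0", "f1"), v1.samples[:2], rng.normal(size=(2, 2)))
        ds = align_views([v1, v2])
        s1 = initialize_stack(v1, [2])
        s2 = initialize_stack(v2, [2])
        gs = ds.indicators()
        h = update_consensus([s1, s2], gs)
        np.testing.assert_allclose(h.values[:, 2], s1.H[-1][:, 2], atol=1e-12)
        a = np.vstack([g.values.T for g in gs])
        b = np.vstack([s1.H[-1].T, s2.H[-1].T])
        expect = np.linalg.lstsq(a, b, rcond=None)[0].T
        np.testing.assert_allclose(h.values, expect, atol=1e-10)

    def test_uncovered_sample_raises(self, rng):
        view = make_view(rng.normal(size=(4, 3)))
        ds = align_views([view])
        stack = initialize_stack(view, [2])
        g = ds.indicators()[0]
        bad = type(g)(g.values[:, :2])  # drop a column: sample 2 uncovered

        class Fake:
            H = [stack.H[-1][:, :2]]

        with pytest.raises(SingularityError):
            update_consensus([Fake()], [bad])

    def test_consensus_gradient_vanishes(self, rng):
        """After the closed-form update the coupling gradient is ~0."""
        v1 = make_view(rng.normal(size=(6, 5)), name="a")
        v2 = make_view(rng.normal(size=(7, 5)), name="b")
        ds = align_views([v1, v2])
        stacks = [initialize_stack(v, [3]) for v in ds.views]
        gs = ds.indicators()
        h = update_consensus(stacks, gs)
        grad = sum((h.values @ g.values - s.H[-1]) @ g.values.T
                   for s, g in zip(stacks, gs))
        assert np.abs(2 * grad).max() < 1e-8


class TestObjective:
    def test_zero_loss_at_exact_factorization(self, rng):
        z = rng.normal(size=(6, 2))
        hm = rng.uniform(0.1, 1, size=(2, 5))
        view = make_view(z @ hm)
        ds = align_views([view])
        stack = FactorStack(Z=[z], H=[hm])
        h = ConsensusRepresentation(values=hm.copy())
        cfg = SolverConfig(layer_dims=[2], lambda1=0, lambda2=1)
        assert linear_objective([stack], ds.indicators(), h, cfg, [view]) < 1e-18

    def test_matches_scalar_loop_oracle(self, rng):
        view = make_view(rng.normal(size=(4, 3)))
        ds = align_views([view])
        stack = initialize_stack(view, [2])
        h = ConsensusRepresentation(values=rng.normal(size=(2, 3)))
        cfg = SolverConfig(layer_dims=[2], lambda1=1.0, lambda2=1.0)
        got = linear_objective([stack], ds.indicators(), h, cfg, [view])
        expect = scalar_loop_objective([stack], ds.indicators(), h, cfg, [view])
        np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_sparsity_trace_equals_column_l1_squares(self, rng):
        for _ in range(20):
            hm = rng.uniform(0, 1, size=(rng.integers(1, 8), rng.integers(1, 9)))
            assert abs(sparsity_trace(hm) - sparsity_l1(hm)) < 1e-10


class TestFitLinear:
    def test_loss_trace_non_increasing_and_hm_nonnegative(self):
        ds, _ = generate_dataset(SimulationConfig(
            n_samples=40, n_views=2, n_clusters=3, n_features=(25, 20), seed=7))
        res = fit_linear(ds, SolverConfig(layer_dims=[8, 3], seed=7))
        trace = res.loss_trace
        assert len(trace) >= 1
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]))
        for stack in res.stacks:
            assert (stack.H[-1] >= 0).all()

    def test_infinite_tolerance_runs_exactly_one_sweep(self):
        ds, _ = generate_dataset(SimulationConfig(
            n_samples=20, n_views=1, n_clusters=2, n_features=12, seed=1))
        res = fit_linear(ds, SolverConfig(layer_dims=[3], tol=np.inf, seed=1))
        assert len(res.loss_trace) == 1 and res.converged

    def test_noiseless_low_rank_reconstruction_halves(self):
        ds, _ = generate_dataset(SimulationConfig(
            n_samples=30, n_views=2, n_clusters=3, n_features=(20, 15),
            noise_sd=0.0, seed=3))
        cfg = SolverConfig(layer_dims=[4], lambda1=0, lambda2=1,
                           max_iter=100, tol=1e-10, seed=3)
        stacks0 = [initialize_stack(v, [4]) for v in ds.views]
        init_err = sum(np.linalg.norm(v.values - s.reconstruction()) ** 2
                       for v, s in zip(ds.views, stacks0))
        res = fit_linear(ds, cfg)
        final_err = sum(np.linalg.norm(v.values - s.reconstruction()) ** 2
                        for v, s in zip(ds.views, res.stacks))
        assert final_err <= init_err
        assert final_err <= 0.5 * init_err

    def test_deterministic_given_seed(self):
        ds, _ = generate_dataset(SimulationConfig(
            n_samples=24, n_views=2, n_clusters=2, n_features=(15, 12), seed=5))
        a = fit_linear(ds, SolverConfig(layer_dims=[4, 2], seed=5))
        b = fit_linear(ds, SolverConfig(layer_dims=[4, 2], seed=5))
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)
        np.testing.assert_array_equal(a.consensus.values, b.consensus.values)
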