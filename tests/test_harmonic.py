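"""The harmonic-extension solver against independent oracles and its
structural guarantees (maximum principle, linearity, optimality)."""

import numpy as np
import pytest
from scipy.optimize import minimize

from trajfuse.harmonic import (CompletedTrajectory, DisconnectedGraphError,
                               ModalityLabels, complete_study,
                               dirichlet_energy, harmonic_extension,
                               label_propagation)
from conftest import random_connected_graph


def qp_oracle(W, labeled_idx, Y):
    """Minimise the Dirichlet energy directly with a generic optimiser
    (conjugate gradients on the free variables, analytic gradient)."""
    n = W.shape[0]
    unl = np.setdiff1d(np.arange(n), labeled_idx)
    f = np.zeros(n)
    f[labeled_idx] = Y

    def fun(z):
        g = f.copy()
        g[unl] = z
        return dirichlet_energy(W, g)

    def grad(z):
        g = f.copy()
        g[unl] = z
        d = W.sum(axis=1)
        full = 4.0 * (d * g - W @ g)
        return full[unl]

    def hessp(_z, p):
        d = W.sum(axis=1)[unl]
        return 4.0 * (d * p - W[np.ix_(unl, unl)] @ p)

    z0 = np.full(unl.size, Y.mean())
    res = minimize(fun, z0, jac=grad, hessp=hessp, method="Newton-CG",
                   options={"xtol": 1e-14, "maxiter": 20000})
    f[unl] = res.x
    return f


class TestClosedForm:
    def test_path_graph_midpoint(self):
        W = np.array([[1.0, 1.0, 0.0],
                      [1.0, 1.0, 1.0],
                      [0.0, 1.0, 1.0]])
        traj = harmonic_extension(
            W, ModalityLabels("y", np.array([0, 2]), np.array([0.0, 1.0])))
        assert traj.values[1] == pytest.approx(0.5)

    def test_constant_labels_extend_to_constant(self):
        rng = np.random.default_rng(0)
        W, lab, _ = random_connected_graph(rng, 15, 4)
        traj = harmonic_extension(W, ModalityLabels("y", lab, np.full(4, 3.3)))
        np.testing.assert_allclose(traj.values, 3.3, atol=1e-10)

    def test_matches_direct_quadratic_minimisation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(8, 16))
            W, lab, Y = random_connected_graph(rng, n, int(rng.integers(2, 5)))
            traj = harmonic_extension(W, ModalityLabels("y", lab, Y))
            oracle = qp_oracle(W, lab, Y)
            np.testing.assert_allclose(traj.values, oracle, atol=1e-8)

    def test_labels_clamped_exactly(self):
        rng = np.random.default_rng(2)
        W, lab, Y = random_connected_graph(rng, 12, 4)
        traj = harmonic_extension(W, ModalityLabels("y", lab, Y))
        assert np.array_equal(traj.values[lab], Y)

    def test_single_unlabeled_point_is_weighted_average(self):
        rng = np.random.default_rng(3)
        W, _, _ = random_connected_graph(rng, 8, 2)
        lab = np.arange(1, 8)
        Y = rng.normal(size=7)
        traj = harmonic_extension(W, ModalityLabels("y", lab, Y))
        expect = np.sum(W[0, 1:] * Y) / np.sum(W[0, 1:])
        assert traj.values[0] == pytest.approx(expect, abs=1e-12)


class TestProperties:
    def test_maximum_principle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(6, 20))
            W, lab, Y = random_connected_graph(rng, n, int(rng.integers(1, 5)))
            traj = harmonic_extension(W, ModalityLabels("y", lab, Y))
            assert traj.values.min() >= Y.min() - 1e-10
            assert traj.values.max() <= Y.max() + 1e-10

    def test_linearity(self):
        rng = np.random.default_rng(5)
        W, lab, _ = random_connected_graph(rng, 14, 4)
        Y1, Y2 = rng.normal(size=4), rng.normal(size=4)
        a, b = 2.5, -1.3
        lhs = harmonic_extension(W, ModalityLabels("y", lab, a * Y1 + b * Y2)).values
        rhs = (a * harmonic_extension(W, ModalityLabels("y", lab, Y1)).values
               + b * harmonic_extension(W, ModalityLabels("y", lab, Y2)).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_perturbing_any_estimate_increases_energy(self):
        rng = np.random.default_rng(6)
        W, lab, Y = random_connected_graph(rng, 10, 3)
        traj = harmonic_extension(W, ModalityLabels("y", lab, Y))
        e0 = dirichlet_energy(W, traj.values)
        for i in np.setdiff1d(np.arange(10), lab):
            for eps in (1e-3, -1e-3):
                f = traj.values.copy()
                f[i] += eps
                assert dirichlet_energy(W, f) > e0

    def test_fixed_point_of_clamped_averaging(self):
        rng = np.random.default_rng(7)
        W, lab, Y = random_connected_graph(rng, 12, 4)
        closed = harmonic_extension(W, ModalityLabels("y", lab, Y)).values
        iterated = label_propagation(W, ModalityLabels("y", lab, Y),
                                     tol=1e-12).values
        rel = np.linalg.norm(iterated - closed) / np.linalg.norm(closed)
        assert rel < 1e-6


class TestBatched:
    def test_multicolumn_matches_looped_single_columns(self):
        rng = np.random.default_rng(8)
        W, lab, Y = random_connected_graph(rng, 12, 5, p_cols=7)
        batched = harmonic_extension(W, ModalityLabels("m", lab, Y)).values
        for c in range(7):
            single = harmonic_extension(
                W, ModalityLabels("m", lab, Y[:, c])).values
            np.testing.assert_allclose(batched[:, c], single, atol=1e-10)

    def test_all_points_labeled_returns_labels(self):
        rng = np.random.default_rng(9)
        W, _, _ = random_connected_graph(rng, 6, 2)
        Y = rng.normal(size=(6, 3))
        traj = harmonic_extension(W, ModalityLabels("m", np.arange(6), Y))
        assert np.array_equal(traj.values, Y)

    def test_complete_study_runs_all_modalities(self):
        rng = np.random.default_rng(10)
        W, lab, Y = random_connected_graph(rng, 10, 3)
        trajs = complete_study(W, [ModalityLabels("a", lab, Y),
                                   ModalityLabels("b", np.arange(10), rng.normal(size=10))])
        assert [t.name for t in trajs] == ["a", "b"]


class TestErrors:
    def test_disconnected_graph_names_components(self):
        W = np.eye(4)
        W[0, 1] = W[1, 0] = 0.8
        with pytest.raises(DisconnectedGraphError) as exc:
            harmonic_extension(W, ModalityLabels("y", np.array([0]), np.array([1.0])))
        assert any(2 in c or 3 in c for c in exc.value.components)

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            ModalityLabels("y", np.array([], dtype=int), np.array([]))

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            ModalityLabels("y", np.array([1, 1]), np.array([0.0, 1.0]))
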