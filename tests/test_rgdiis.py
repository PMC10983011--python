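"""C2-DIIS solver, GDIIS extrapolation and the three resetting rules."""

import numpy as np
import pytest

from orbopt.implicit_hessian import ImplicitHessian
from orbopt.orbital_space import KappaVector, OrbitalPoint, SpinBlock
from orbopt.rgdiis import (
    DegenerateDIISError,
    DIISHistory,
    ResetAction,
    apply_reset_rules,
    error_vector,
    gdiis_solve_vanilla,
    gdiis_step,
    solve_c2diis,
)

BLOCKS = (SpinBlock(1, 4),)


def _point(x, e, g):
    return OrbitalPoint(KappaVector(np.asarray(x, float), BLOCKS), e, np.asarray(g, float))


def _history(points_errors):
    h = DIISHistory()
    for p, e in points_errors:
        h.push(p, e)
    return h


class TestErrorVector:
    def test_zero_gradient(self):
        h = ImplicitHessian(np.ones(4))
        np.testing.assert_array_equal(error_vector(np.zeros(4), h), np.zeros(4))

    def test_seed_only_is_scaled_gradient(self, rng):
        seed = rng.uniform(0.5, 2.0, 4)
        g = rng.standard_normal(4)
        np.testing.assert_allclose(error_vector(g, ImplicitHessian(seed)), -g / seed, atol=1e-14)

    def test_dense_solve_agreement(self, rng):
        seed = rng.uniform(0.5, 2.0, 6)
        h = ImplicitHessian(seed)
        for _ in range(3):
            dk = rng.standard_normal(6)
            h.push_pair(dk, 2.0 * dk + 0.1 * rng.standard_normal(6))
        g = rng.standard_normal(6)
        np.testing.assert_allclose(error_vector(g, h), -np.linalg.solve(h.dense(), g), atol=1e-10)


class TestC2DIIS:
    def test_single_point(self):
        sol = solve_c2diis(np.array([[2.0]]))
        np.testing.assert_array_equal(sol.coefficients, [1.0])

    def test_closed_form_two_by_two(self):
        # min c.T B c with sum(c)=1 for B=diag(4,1): c = (0.2, 0.8), cBc = 0.8
        sol = solve_c2diis(np.diag([4.0, 1.0]))
        np.testing.assert_allclose(sol.coefficients, [0.2, 0.8], atol=1e-12)
        assert sol.predicted_error_sq == pytest.approx(0.8, abs=1e-12)

    def test_coefficients_sum_to_one(self, rng):
        for _ in range(10):
            E = rng.standard_normal((4, 6))
            B = E @ E.T
            sol = solve_c2diis(B)
            assert np.sum(sol.coefficients) == pytest.approx(1.0, abs=1e-12)

    def test_returns_minimal_error_candidate(self, rng):
        E = rng.standard_normal((3, 8))
        B = E @ E.T
        sol = solve_c2diis(B)
        # brute force on the constraint plane
        best = min(
            float(c @ B @ c)
            for c in (
                np.array([a, b, 1 - a - b])
                for a in np.linspace(-2, 2, 81)
                for b in np.linspace(-2, 2, 81)
            )
        )
        assert sol.predicted_error_sq <= best + 1e-6

    def test_near_singular_candidate_rejected(self):
        # two nearly identical error vectors: one eigenvector has a huge
        # renormalized norm and a tiny predicted error -> rejected
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = e1 + 1e-12 * np.array([0.0, 1.0, 0.0])
        e3 = np.array([0.0, 2.0, 0.0])
        E = np.vstack([e1, e2, e3])
        B = E @ E.T
        sol = solve_c2diis(B)
        assert sol.rejected_count >= 1
        assert float(sol.coefficients @ sol.coefficients) <= 100.0 or (
            sol.predicted_error_sq >= 1e-5
        )

    def test_all_rejected_signals_degeneracy(self):
        # rank-deficient B whose every usable candidate is corrupt
        e = np.array([1.0, 0.0])
        E = np.vstack([e, e + 1e-13, e - 1e-13])
        B = E @ E.T
        try:
            sol = solve_c2diis(B)
            assert sol.coefficients.size == 3
        except DegenerateDIISError:
            pass  # acceptable signalled outcome for this pathological input

    def test_vanilla_solver_agrees_on_well_conditioned_input(self, rng):
        E = rng.standard_normal((3, 10))
        B = E @ E.T
        c2 = solve_c2diis(B).coefficients
        lin = gdiis_solve_vanilla(B).coefficients
        np.testing.assert_allclose(c2, lin, atol=1e-8)


class TestGDIISStep:
    def test_single_point_is_quasi_newton(self, rng):
        h = ImplicitHessian(np.full(4, 2.0))
        g = rng.standard_normal(4)
        hist = _history([(_point(np.zeros(4), 1.0, g), error_vector(g, h))])
        x_new, sol = gdiis_step(hist, h)
        np.testing.assert_allclose(x_new, -g / 2.0, atol=1e-14)

    def test_exact_quadratic_one_step(self, rng):
        spec = np.array([1.0, 2.0, 3.0, 4.0])
        h = ImplicitHessian(spec)  # exact Hessian of E = x.T diag(spec) x / 2
        x0 = rng.standard_normal(4)
        g0 = spec * x0
        hist = _history([(_point(x0, 0.5 * x0 @ g0, g0), error_vector(g0, h))])
        x_new, _ = gdiis_step(hist, h)
        np.testing.assert_allclose(spec * x_new, 0.0, atol=1e-12)

    def test_predicted_error_bounded_by_best_single_point(self, rng):
        h = ImplicitHessian(np.ones(4))
        entries = []
        for k in range(4):
            g = rng.standard_normal(4) * (0.5**k)
            entries.append((_point(rng.standard_normal(4), -float(k), g), error_vector(g, h)))
        hist = _history(entries)
        _, sol = gdiis_step(hist, h)
        assert sol.predicted_error_sq <= np.min(np.diag(hist.b_matrix())) + 1e-12

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            gdiis_step(DIISHistory(), ImplicitHessian(np.ones(2)))


class TestResetRules:
    def _energies_descending(self, errors, energies):
        return _history(
            [
                (_point(np.zeros(4), E, e), np.asarray(e, float))
                for E, e in zip(energies, errors)
            ]
        )

    def test_well_scaled_history_no_action(self):
        errs = [np.full(4, s) for s in (0.4, 0.3, 0.2, 0.1)]
        hist = self._energies_descending(errs, [-1.0, -1.1, -1.2, -1.3])
        assert apply_reset_rules(hist, -1.3) == [ResetAction.NONE]

    def test_rule1_disparity_shrinks_depth(self):
        # smallest error on the latest point so rule 2 stays silent
        errs = [np.full(4, 1.0), np.full(4, 2e-6), np.full(4, 1e-6)]
        hist = self._energies_descending(errs, [-1.0, -1.1, -1.2])
        actions = apply_reset_rules(hist, -1.2)
        assert ResetAction.SHRINK_M in actions
        assert hist.m == 2  # oldest (largest) error dropped

    def test_rule2_shoulder_energy_resets_depth(self):
        # lowest-error point has *higher* energy than now: shoulder signature
        errs = [np.full(4, 0.5), np.full(4, 1e-3), np.full(4, 0.4)]
        hist = self._energies_descending(errs, [-1.0, -0.5, -1.05])
        actions = apply_reset_rules(hist, -1.05)
        assert ResetAction.RESET_M_1 in actions
        assert hist.m == 1
        assert len(hist.points) == 1  # discarded points dropped permanently

    def test_rule2_descending_order_violation(self):
        errs = [np.full(4, 0.01), np.full(4, 0.5)]  # B_11*15 < B_22
        hist = self._energies_descending(errs, [-1.0, -1.01])
        actions = apply_reset_rules(hist, -1.01)
        assert ResetAction.RESET_M_1 in actions

    def test_rule3_signalled_for_long_step(self):
        errs = [np.full(4, 0.2)]
        hist = self._energies_descending(errs, [-1.0])
        actions = apply_reset_rules(hist, -1.0, proposed_step_norm=4.0)
        assert ResetAction.REDUCE_BFGS_DEPTH in actions

    def test_long_step_reduced_below_pi_by_depth_reduction(self, rng):
        # an ill-conditioned update pair produces a step far beyond pi;
        # depth reduction restores the (bounded) seed step
        dim = 6
        seed = np.ones(dim)
        h = ImplicitHessian(seed)
        dk = 1e-4 * rng.standard_normal(dim)
        dg = 1e-8 * dk / np.linalg.norm(dk)  # near-zero curvature pair
        h.push_pair(dk, dg)
        g = rng.standard_normal(dim)
        g *= 2.9 / np.linalg.norm(g)  # seed step just below pi
        step = -h.invhessvec(g)
        assert np.linalg.norm(step) > np.pi
        h.reduce_depth(0)
        assert np.linalg.norm(-h.invhessvec(g)) <= np.pi


class TestHistory:
    def test_fifo_eviction_at_m_max(self, rng):
        hist = DIISHistory(m_max=3)
        for k in range(5):
            g = rng.standard_normal(4)
            hist.push(_point(np.zeros(4), -float(k), g), g)
        assert len(hist.points) == 3
        assert hist.m == 3
        assert hist.points[-1].energy == -4.0

    def test_b_matrix_matches_errors(self, rng):
        errs = [rng.standard_normal(5) for _ in range(3)]
        hist = _history([(_point(np.zeros(4), 0.0, np.zeros(4)), e) for e in errs])
        B = hist.b_matrix()
        for i in range(3):
            for j in range(3):
                assert B[i, j] == pytest.approx(float(errs[i] @ errs[j]), abs=1e-14)
        assert np.min(np.linalg.eigvalsh(B)) >= -1e-12
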