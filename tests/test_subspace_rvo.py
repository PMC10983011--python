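"""Subspace construction, projections and restricted-variance steps."""

import numpy as np
import pytest

from orbopt import model_surface, optimize, RunConfig
from orbopt.gek import build_model, characteristic_lengths
from orbopt.implicit_hessian import ImplicitHessian
from orbopt.orbital_space import KappaVector, OrbitalPoint, SpinBlock
from orbopt.subspace_rvo import (
    build_subspace,
    expand,
    project,
    project_hessian,
    rvo_step,
)

K_FULL = 50
BLOCKS = (SpinBlock(1, K_FULL),)


def _pt(rng, x=None, g=None, e=0.0):
    x = rng.standard_normal(K_FULL) if x is None else x
    g = rng.standard_normal(K_FULL) if g is None else g
    return OrbitalPoint(KappaVector(x, BLOCKS), e, g)


@pytest.fixture
def history(rng):
    return [_pt(rng, e=-float(k)) for k in range(5)]


class TestBuildSubspace:
    def test_m1_spans_gradient_and_prediction(self, rng):
        g = rng.standard_normal(K_FULL)
        p = rng.standard_normal(K_FULL)
        basis = build_subspace([_pt(rng)], g, p)
        assert basis.dim_reduced <= 2
        assert set(basis.provenance) <= {"latest-gradient", "rfo-prediction"}

    def test_duplicates_dropped(self, rng):
        g = rng.standard_normal(K_FULL)
        basis = build_subspace([_pt(rng)], g, g.copy())  # prediction == gradient
        assert basis.dim_reduced == 1
        V = basis.vectors
        np.testing.assert_allclose(V.T @ V, np.eye(1), atol=1e-12)

    def test_orthonormal(self, history, rng):
        basis = build_subspace(history, rng.standard_normal(K_FULL),
                               rng.standard_normal(K_FULL))
        V = basis.vectors
        assert basis.dim_reduced <= 2 * len(history)
        np.testing.assert_allclose(V.T @ V, np.eye(basis.dim_reduced), atol=1e-12)

    def test_candidates_reproduced_by_span(self, history, rng):
        g = rng.standard_normal(K_FULL)
        p = rng.standard_normal(K_FULL)
        basis = build_subspace(history, g, p)
        cands = [g, p]
        for a, b in zip(history[:-1], history[1:]):
            cands.append(b.kappa.values - a.kappa.values)
            cands.append(b.gradient - a.gradient)
        for v in cands:
            np.testing.assert_allclose(expand(basis, project(basis, v)), v,
                                       atol=1e-10 * np.linalg.norm(v))

    def test_null_candidates_give_empty_basis(self):
        pt = OrbitalPoint(KappaVector(np.zeros(K_FULL), BLOCKS), 0.0, np.zeros(K_FULL))
        basis = build_subspace([pt], np.zeros(K_FULL), np.zeros(K_FULL))
        assert basis.dim_reduced == 0


class TestProjections:
    def test_orthogonal_vector_projects_to_zero(self, history, rng):
        basis = build_subspace(history[:2], rng.standard_normal(K_FULL),
                               rng.standard_normal(K_FULL))
        v = rng.standard_normal(K_FULL)
        v -= basis.vectors @ (basis.vectors.T @ v)
        np.testing.assert_allclose(project(basis, v), 0.0, atol=1e-10)

    def test_project_expand_is_identity_on_reduced(self, history, rng):
        basis = build_subspace(history, rng.standard_normal(K_FULL),
                               rng.standard_normal(K_FULL))
        r = rng.standard_normal(basis.dim_reduced)
        np.testing.assert_allclose(project(basis, expand(basis, r)), r, atol=1e-12)

    def test_contraction(self, history, rng):
        basis = build_subspace(history, rng.standard_normal(K_FULL),
                               rng.standard_normal(K_FULL))
        for _ in range(10):
            v = rng.standard_normal(K_FULL)
            assert np.linalg.norm(expand(basis, project(basis, v))) <= np.linalg.norm(v) + 1e-12

    def test_dimension_mismatch(self, history, rng):
        basis = build_subspace(history, rng.standard_normal(K_FULL),
                               rng.standard_normal(K_FULL))
        with pytest.raises(ValueError):
            project(basis, np.zeros(K_FULL + 1))
        with pytest.raises(ValueError):
            expand(basis, np.zeros(basis.dim_reduced + 1))


class TestProjectHessian:
    def test_diagonal_seed_canonical_axes(self):
        from orbopt.subspace_rvo import SubspaceBasis

        seed = np.arange(1.0, 7.0)
        h = ImplicitHessian(seed)
        V = np.zeros((6, 2))
        V[1, 0] = V[4, 1] = 1.0
        basis = SubspaceBasis(V, ("a", "b"))
        Hr = project_hessian(basis, h)
        np.testing.assert_allclose(Hr, np.diag([2.0, 5.0]), atol=1e-14)

    def test_dense_projection_oracle(self, rng):
        dim = 30
        seed = rng.uniform(0.5, 2.0, dim)
        h = ImplicitHessian(seed)
        for _ in range(4):
            dk = rng.standard_normal(dim)
            h.push_pair(dk, 1.5 * dk + 0.1 * rng.standard_normal(dim))
        V, _ = np.linalg.qr(rng.standard_normal((dim, 8)))
        from orbopt.subspace_rvo import SubspaceBasis

        basis = SubspaceBasis(V, tuple("x" * 8))
        Hr = project_hessian(basis, h)
        Hd = h.dense()
        np.testing.assert_allclose(Hr, V.T @ Hd @ V, atol=1e-12)
        # Cauchy interlacing: reduced spectrum inside the full spectrum range
        full = np.linalg.eigvalsh(Hd)
        red = np.linalg.eigvalsh(Hr)
        assert red[0] >= full[0] - 1e-10 and red[-1] <= full[-1] + 1e-10


class TestRVOStep:
    def test_zero_gradient_single_point(self):
        lengths = characteristic_lengths(np.ones(2))
        m = build_model(np.zeros((1, 2)), [-1.0], np.zeros((1, 2)), lengths)
        res = rvo_step(m, np.zeros(2), variance_limit=1.0, step_limit=10.0)
        np.testing.assert_array_equal(res.dz, 0.0)

    def test_quadratic_exact_lengths_newton_step(self):
        # single point on a quadratic with exact-Hessian lengths and a huge
        # variance limit: the step is the dense RFO step for (g, H), which
        # approaches the Newton step for a small gradient
        h_eig = np.array([1.0, 2.0])
        g = np.array([1e-5, -2e-5])
        lengths = characteristic_lengths(h_eig)
        m = build_model(np.zeros((1, 2)), [-1.0], g[None, :], lengths)
        res = rvo_step(m, np.zeros(2), variance_limit=1e6, step_limit=10.0)
        np.testing.assert_allclose(res.dz, -g / h_eig, atol=1e-8)

    def test_step_norm_monotone_in_variance_limit(self, rng):
        h_eig = np.array([1.0, 1.5, 3.0])
        g = np.array([0.4, -0.3, 0.2])
        lengths = characteristic_lengths(h_eig)
        m = build_model(np.zeros((1, 3)), [-1.0], g[None, :], lengths)
        norms = []
        for lim in (1e-6, 1e-4, 1e-2, 1.0, 100.0):
            res = rvo_step(m, np.zeros(3), variance_limit=lim, step_limit=10.0)
            norms.append(np.linalg.norm(res.dz))
        assert all(np.diff(norms) >= -1e-12)
        assert norms[0] < norms[-1]

    def test_variance_limit_respected(self):
        h_eig = np.array([1.0, 1.0])
        g = np.array([2.0, -1.0])
        lengths = characteristic_lengths(h_eig)
        m = build_model(np.zeros((1, 2)), [-1.0], g[None, :], lengths)
        res = rvo_step(m, np.zeros(2), variance_limit=1e-3, step_limit=10.0)
        assert res.restricted
        assert res.predicted_std <= 1e-3 * (1 + 1e-8)

    def test_fallback_on_degenerate_model(self):
        g = np.array([1.0, 0.5])
        H = np.diag([2.0, 4.0])
        res = rvo_step(None, np.zeros(2), variance_limit=1.0, step_limit=10.0,
                       fallback=(g, H))
        assert res.used_fallback
        assert np.linalg.norm(res.dz) > 0

    def test_degenerate_without_fallback(self):
        with pytest.raises(ValueError):
            rvo_step(None, np.zeros(2), 1.0, 1.0)


class TestSGEKIterate:
    def test_quadratic_matches_rsrfo_energy(self):
        surf = model_surface("quadratic", 8, {"spectrum": np.linspace(0.5, 3.0, 8)})
        e_rfo = optimize(surf, RunConfig(method="rs-rfo")).final_energy
        tr = optimize(surf, RunConfig(method="s-gek-rvo"))
        assert tr.converged
        assert abs(tr.final_energy - e_rfo) <= 1e-10

    def test_system_dimension_bound_every_iteration(self):
        # the linear system never exceeds m (1 + 2m)
        surf = model_surface("anharmonic_well", 12, {"start": 2.0})
        cfg = RunConfig(method="s-gek-rvo")
        tr = optimize(surf, cfg)
        assert tr.converged
        bound = cfg.sgek_m * (1 + 2 * cfg.sgek_m)
        dims = [r["method_internals"].get("gek_system_dim", 0) for r in tr.rows]
        assert max(dims) <= bound
        assert max(dims) > 0

    def test_first_step_equals_rsrfo_with_unbounded_variance(self):
        # the RFO prediction is in the subspace and the single-point surrogate
        # is locally exact, so the steps coincide
        from orbopt.driver import _RSRFOStepper, _SGEKStepper, _SurfaceAdapter

        surf = model_surface("quadratic", 6, {"spectrum": np.linspace(0.5, 3.0, 6),
                                              "start": 0.5})
        cfg = RunConfig(method="s-gek-rvo", rvo_floor=1e6)
        ad = _SurfaceAdapter(surf, cfg)
        ev = ad.evaluate(ad.start)
        h1 = ImplicitHessian(ad.hess_seed())
        h2 = ImplicitHessian(ad.hess_seed())
        x_rfo, _, _ = _RSRFOStepper(ad, h1, cfg).propose(ad.start, ev)
        x_gek, _, _ = _SGEKStepper(ad, h2, cfg).propose(ad.start, ev)
        np.testing.assert_allclose(x_gek, x_rfo, atol=1e-8)

    def test_expanded_step_lies_in_span(self, rng):
        history = [_pt(rng, e=-float(k)) for k in range(4)]
        g = rng.standard_normal(K_FULL)
        p = rng.standard_normal(K_FULL)
        basis = build_subspace(history, g, p)
        r = rng.standard_normal(basis.dim_reduced)
        full = expand(basis, r)
        residual = full - basis.vectors @ (basis.vectors.T @ full)
        assert np.linalg.norm(residual) <= 1e-12 * max(1.0, np.linalg.norm(full))
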