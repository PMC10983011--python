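"""Gradient-enhanced Kriging: kernel calculus, interpolation, variance, lengths."""

import numpy as np
import pytest

from orbopt.gek import (
    CoincidentPointsError,
    Matern52,
    build_model,
    characteristic_lengths,
    matern52,
    scaled_distance,
)


class TestDistanceAndKernel:
    def test_unit_lengths_is_euclidean(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        assert scaled_distance(a, b, np.ones(5)) == pytest.approx(np.linalg.norm(a - b))

    def test_zero_at_coincidence(self, rng):
        a = rng.standard_normal(4)
        assert scaled_distance(a, a, np.full(4, 2.0)) == 0.0

    def test_direct_formula_1d(self):
        assert scaled_distance(np.array([2.0]), np.array([0.0]), np.array([2.0])) == 1.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            scaled_distance(np.zeros(2), np.ones(2), np.array([1.0, 0.0]))

    def test_matern_maximal_at_zero_and_monotone(self):
        r = np.linspace(0, 10, 200)
        f = matern52(r)
        assert f[0] == pytest.approx(1.0)
        assert np.all(np.diff(f) < 0)

    def test_kernel_symmetry(self, rng):
        kern = Matern52(rng.uniform(0.5, 2.0, 4))
        d = rng.standard_normal(4)
        assert kern.value(d) == pytest.approx(kern.value(-d), abs=1e-15)

    def test_first_derivative_zero_at_origin(self):
        kern = Matern52(np.ones(3))
        np.testing.assert_allclose(kern.grad_d(np.zeros(3)), 0.0, atol=0)

    def test_derivatives_match_finite_differences(self, rng):
        kern = Matern52(np.array([1.5, 0.7, 2.0]))
        h = 1e-6
        eye = np.eye(3)
        for _ in range(20):
            d = rng.standard_normal(3) * rng.uniform(0.1, 3.0)
            fd_g = np.array(
                [(kern.value(d + h * eye[i]) - kern.value(d - h * eye[i])) / (2 * h)
                 for i in range(3)]
            )
            np.testing.assert_allclose(fd_g, kern.grad_d(d), atol=1e-8)
            fd_h = np.array(
                [[(kern.grad_d(d + h * eye[j])[i] - kern.grad_d(d - h * eye[j])[i]) / (2 * h)
                  for j in range(3)] for i in range(3)]
            )
            np.testing.assert_allclose(fd_h, kern.hess_d(d), atol=1e-7)
            fd_t = np.array(
                [[[(kern.hess_d(d + h * eye[p])[k, m] - kern.hess_d(d - h * eye[p])[k, m])
                   / (2 * h) for p in range(3)] for m in range(3)] for k in range(3)]
            )
            np.testing.assert_allclose(fd_t, kern.third_d(d), atol=1e-6)


class TestCharacteristicLengths:
    def test_equal_eigenvalues_equal_lengths(self):
        ls = characteristic_lengths(np.full(4, 2.0))
        assert np.ptp(ls) == 0.0

    def test_stiff_directions_get_short_lengths(self):
        h = np.array([0.1, 1.0, 10.0])
        ls = characteristic_lengths(h)
        assert np.all(np.diff(ls) < 0)

    def test_flooring_handles_nonpositive(self):
        ls = characteristic_lengths(np.array([-1.0, 0.0, 1.0]), floor=0.025)
        assert np.isfinite(ls).all()
        assert ls[0] == ls[1] == pytest.approx(np.sqrt((5 / 3) * 10.0 / 0.025))

    @pytest.mark.parametrize("hk", [0.1, 1.0, 10.0])
    def test_single_point_surrogate_reproduces_hessian(self, hk):
        # central-difference Hessian of the predictor at its only data point
        # (FD step scaled to the characteristic length to stay clear of both
        # truncation and cancellation error)
        K = 3
        lengths = characteristic_lengths(np.full(K, hk))
        model = build_model(np.zeros((1, K)), [-2.0], np.zeros((1, K)), lengths)
        for i in range(K):
            step = 5e-4 * lengths[i]
            zp, zm = np.zeros(K), np.zeros(K)
            zp[i] += step
            zm[i] -= step
            fd = (model.predict(zp) - 2 * model.predict(np.zeros(K)) + model.predict(zm)) / step**2
            assert abs(fd - hk) / hk <= 1e-6
        # and the analytic Hessian agrees even tighter
        np.testing.assert_allclose(np.diag(model.predict_hessian(np.zeros(K))), hk, rtol=1e-9)


@pytest.fixture
def random_model(rng):
    n, K = 6, 5
    pts = rng.standard_normal((n, K))
    Es = -75.0 + 0.1 * rng.standard_normal(n)
    Gs = rng.standard_normal((n, K))
    return build_model(pts, Es, Gs, np.full(K, 2.0)), pts, Es, Gs


class TestModel:
    def test_single_point_zero_gradient(self):
        # interpolation holds to the nugget scale (~1e-9 of the trend offset)
        m = build_model(np.zeros((1, 2)), [-1.5], np.zeros((1, 2)), np.full(2, 2.0))
        assert m.predict(np.zeros(2)) == pytest.approx(-1.5, abs=1e-8)
        assert m.predict_variance(np.zeros(2)) <= 1e-10 * m.kernel.sigma2
        np.testing.assert_allclose(m.predict_gradient(np.zeros(2)), 0.0, atol=1e-8)

    def test_two_point_quadratic_1d(self):
        # data on E(x) = x^2: energies and slopes reproduced at both points
        pts = np.array([[0.5], [1.5]])
        Es = (pts**2).ravel()
        Gs = 2.0 * pts
        m = build_model(pts, Es, Gs, np.array([3.0]))
        for p, e, g in zip(pts, Es, Gs):
            assert m.predict(p) == pytest.approx(e, abs=1e-8)
            assert m.predict_gradient(p)[0] == pytest.approx(g[0], abs=1e-8)

    def test_exact_interpolation(self, random_model):
        m, pts, Es, Gs = random_model
        scale = max(1.0, np.max(np.abs(Es)))
        for p, e, g in zip(pts, Es, Gs):
            assert abs(m.predict(p) - e) <= 1e-9 * scale
            np.testing.assert_allclose(m.predict_gradient(p), g, atol=1e-8)

    def test_variance_nonnegative_and_zero_at_data(self, random_model, rng):
        m, pts, _, _ = random_model
        for p in pts:
            assert 0.0 <= m.predict_variance(p) <= 1e-10 * m.kernel.sigma2
        for _ in range(20):
            assert m.predict_variance(rng.standard_normal(5) * 3) >= 0.0

    def test_prior_reversion_far_from_data(self, random_model):
        m, pts, _, _ = random_model
        far = pts[0] + 500.0
        assert m.predict(far) == pytest.approx(m.mu, abs=1e-8)
        assert m.predict_variance(far) == pytest.approx(m.kernel.sigma2, rel=1e-10)

    def test_predict_gradient_matches_fd(self, random_model, rng):
        m, _, _, _ = random_model
        h = 1e-6
        for _ in range(5):
            z = rng.standard_normal(5)
            fd = np.array(
                [(m.predict(z + h * np.eye(5)[i]) - m.predict(z - h * np.eye(5)[i])) / (2 * h)
                 for i in range(5)]
            )
            np.testing.assert_allclose(fd, m.predict_gradient(z), atol=1e-7)

    def test_permutation_invariance(self, random_model, rng):
        m, pts, Es, Gs = random_model
        perm = rng.permutation(len(Es))
        m2 = build_model(pts[perm], np.asarray(Es)[perm], Gs[perm], np.full(5, 2.0))
        z = rng.standard_normal(5)
        assert m.predict(z) == pytest.approx(m2.predict(z), abs=1e-10)

    def test_trend_is_emax_plus_offset(self, random_model):
        m, _, Es, _ = random_model
        assert m.mu == pytest.approx(np.max(Es) + 10.0)

    def test_coincident_points_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(CoincidentPointsError):
            build_model(pts, [0.0, 1.0], np.zeros((2, 2)), np.ones(2))

    def test_system_dimension(self, random_model):
        m, _, _, _ = random_model
        assert m.system_dimension == 6 * (1 + 5)
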