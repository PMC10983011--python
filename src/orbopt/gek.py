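"""Gradient-enhanced Kriging (GEK) surrogate with a Matern 5/2 kernel.

The surrogate regresses energies *and* full gradient vectors of the data
points and interpolates both exactly.  Distances use per-dimension
characteristic lengths,

    r(a, b) = sqrt( sum_k ((a_k - b_k) / l_k)^2 ),

and the correlation is the Matern 5/2 function
``phi(r) = (1 + sqrt5 r + 5 r^2 / 3) exp(-sqrt5 r)`` scaled by a signal
variance.  The kernel is C^4 at r = 0 (the cubic term of its expansion
cancels), so all the first/second/third coordinate derivatives needed for the
generalized covariance system and for the predictor's analytic gradient and
Hessian are smooth where they are used.

Characteristic lengths are not fitted: they are fixed by the requirement that
a surrogate built from a *single* data point with zero gradient reproduces a
prescribed diagonal Hessian ``h_k`` -- which yields
``l_k = sqrt((5/3) (mu - E_max) / h_k)`` with the trend offset
``mu - E_max = 10 E_h``.  Stiff directions get short lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

__all__ = [
    "CoincidentPointsError",
    "GEKModel",
    "Matern52",
    "scaled_distance",
    "matern52",
    "characteristic_lengths",
    "build_model",
]

SQRT5 = math.sqrt(5.0)
#: trend offset above the highest sampled energy (E_h)
MU_MINUS_EMAX = 10.0
#: prior standard deviation; one documented constant consistent with the trend offset
SIGNAL_SIGMA = MU_MINUS_EMAX
NUGGET_RELATIVE = 1e-10
NUGGET_MAX_RELATIVE = 1e-6
DEFAULT_MODEL_DEPTH = 10


class CoincidentPointsError(ValueError):
    """Data points closer than the resolvable scaled distance."""


def scaled_distance(a: np.ndarray, b: np.ndarray, lengths: np.ndarray) -> float:
    a, b, lengths = (np.asarray(x, dtype=float) for x in (a, b, lengths))
    if a.shape != b.shape or a.shape != lengths.shape:
        raise ValueError("dimension mismatch")
    if np.min(lengths) <= 0:
        raise ValueError("characteristic lengths must be positive")
    return float(np.linalg.norm((a - b) / lengths))


def matern52(r):
    """Matern 5/2 correlation (unit signal variance); vectorized in ``r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    return (1.0 + SQRT5 * r + (5.0 / 3.0) * r * r) * np.exp(-SQRT5 * r)


def characteristic_lengths(
    hessian_eigenvalues: np.ndarray,
    mu_minus_emax: float = MU_MINUS_EMAX,
    floor: float = 0.025,
) -> np.ndarray:
    """Per-dimension lengths reproducing ``h_k`` from a single-point surrogate."""
    h = np.maximum(np.asarray(hessian_eigenvalues, dtype=float), floor)
    if np.min(h) <= 0:
        raise ValueError("Hessian eigenvalues must be positive after flooring")
    return np.sqrt((5.0 / 3.0) * mu_minus_emax / h)


class Matern52:
    """Matern 5/2 covariance with per-dimension lengths and analytic derivatives.

    Derivatives are taken with respect to the separation ``d = a - b``; the
    caller maps them onto first/second-argument derivatives with the
    appropriate signs.
    """

    def __init__(self, lengths: np.ndarray, sigma2: float = SIGNAL_SIGMA**2):
        self.lengths = np.asarray(lengths, dtype=float)
        if np.min(self.lengths) <= 0:
            raise ValueError("characteristic lengths must be positive")
        self.sigma2 = float(sigma2)
        self._il2 = 1.0 / self.lengths**2

    def _r(self, d):
        return float(np.linalg.norm(d / self.lengths))

    def value(self, d: np.ndarray) -> float:
        return self.sigma2 * float(matern52(self._r(d)))

    def grad_d(self, d: np.ndarray) -> np.ndarray:
        """d f / d d_k  (smooth through r=0)."""
        r = self._r(d)
        psi = (5.0 / 3.0) * (1.0 + SQRT5 * r) * math.exp(-SQRT5 * r)
        return -self.sigma2 * psi * d * self._il2

    def hess_d(self, d: np.ndarray) -> np.ndarray:
        """d^2 f / d d_k d d_m."""
        r = self._r(d)
        e = math.exp(-SQRT5 * r)
        C = (25.0 / 3.0) * e
        psi = (5.0 / 3.0) * (1.0 + SQRT5 * r) * e
        t = d * self._il2
        return self.sigma2 * (C * np.outer(t, t) - psi * np.diag(self._il2))

    def third_d(self, d: np.ndarray) -> np.ndarray:
        """d^3 f / d d_k d d_m d d_p (finite limit 0-tensor terms at r=0)."""
        r = self._r(d)
        e = math.exp(-SQRT5 * r)
        C = (25.0 / 3.0) * e
        t = d * self._il2
        K = t.size
        T = np.zeros((K, K, K))
        il2 = self._il2
        for p in range(K):
            T[:, :, p] += C * (np.outer(il2 * (np.arange(K) == p), t)
                               + np.outer(t, il2 * (np.arange(K) == p)))
            T[:, :, p] += C * t[p] * np.diag(il2)
        if r > 0:
            ttt = np.einsum("k,m,p->kmp", t, t, t)
            T -= C * SQRT5 * ttt / r
        return self.sigma2 * T


@dataclass
class GEKModel:
    """Solved GEK system: data, kernel, trend and weights."""

    points: np.ndarray = field(repr=False)  # (n, K)
    energies: np.ndarray = field(repr=False)  # (n,)
    gradients: np.ndarray = field(repr=False)  # (n, K)
    kernel: Matern52 = field(repr=False)
    mu: float = 0.0
    weights: np.ndarray = field(repr=False, default=None)
    cho: tuple = field(repr=False, default=None)
    nugget: float = 0.0

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def K(self) -> int:
        return self.points.shape[1]

    @property
    def system_dimension(self) -> int:
        return self.n * (1 + self.K)

    # -- generalized covariance vector and its derivatives ------------------

    def _v(self, z: np.ndarray) -> np.ndarray:
        n, K = self.n, self.K
        v = np.empty(n * (1 + K))
        for j in range(n):
            d = z - self.points[j]
            v[j] = self.kernel.value(d)
            v[n + j * K : n + (j + 1) * K] = -self.kernel.grad_d(d)
        return v

    def _v_jac(self, z: np.ndarray) -> np.ndarray:
        """d v / d z_k, shape (K, len(v))."""
        n, K = self.n, self.K
        J = np.empty((K, n * (1 + K)))
        for j in range(n):
            d = z - self.points[j]
            J[:, j] = self.kernel.grad_d(d)
            J[:, n + j * K : n + (j + 1) * K] = -self.kernel.hess_d(d)
        return J

    def _v_hess(self, z: np.ndarray) -> np.ndarray:
        """d^2 v / d z_k d z_l, shape (K, K, len(v))."""
        n, K = self.n, self.K
        H = np.empty((K, K, n * (1 + K)))
        for j in range(n):
            d = z - self.points[j]
            H[:, :, j] = self.kernel.hess_d(d)
            H[:, :, n + j * K : n + (j + 1) * K] = -self.kernel.third_d(d)
        return H

    # -- prediction ----------------------------------------------------------

    def predict(self, z: np.ndarray) -> float:
        return self.mu + float(self._v(np.asarray(z, dtype=float)) @ self.weights)

    def predict_gradient(self, z: np.ndarray) -> np.ndarray:
        return self._v_jac(np.asarray(z, dtype=float)) @ self.weights

    def predict_hessian(self, z: np.ndarray) -> np.ndarray:
        H = self._v_hess(np.asarray(z, dtype=float)) @ self.weights
        return 0.5 * (H + H.T)

    def predict_variance(self, z: np.ndarray) -> float:
        v = self._v(np.asarray(z, dtype=float))
        s2 = self.kernel.sigma2 - float(v @ sla.cho_solve(self.cho, v))
        return max(s2, 0.0)

    def predict_std(self, z: np.ndarray) -> float:
        return math.sqrt(self.predict_variance(z))


def build_model(
    points: np.ndarray,
    energies: np.ndarray,
    gradients: np.ndarray,
    lengths: np.ndarray,
    mu: float | None = None,
    sigma2: float = SIGNAL_SIGMA**2,
    nugget_relative: float = NUGGET_RELATIVE,
) -> GEKModel:
    """Assemble and solve the generalized covariance system.

    Ordering of the value vector ``y``: all energies first, then the gradient
    block of each data point.  The trend defaults to
    ``mu = max(E_i) + MU_MINUS_EMAX``.  The symmetric factorization carries a
    small diagonal nugget, escalated tenfold on factorization failure up to
    ``NUGGET_MAX_RELATIVE`` of the mean diagonal.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    gradients = np.atleast_2d(np.asarray(gradients, dtype=float))
    n, K = points.shape
    if energies.shape != (n,) or gradients.shape != (n, K):
        raise ValueError("inconsistent data shapes")
    kernel = Matern52(lengths, sigma2=sigma2)
    for i in range(n):
        for j in range(i):
            if scaled_distance(points[i], points[j], kernel.lengths) <= 1e-10:
                raise CoincidentPointsError(f"points {i} and {j} coincide")
    if mu is None:
        mu = float(np.max(energies)) + MU_MINUS_EMAX

    dim = n * (1 + K)
    M = np.empty((dim, dim))
    for i in range(n):
        for j in range(n):
            d = points[i] - points[j]
            M[i, j] = kernel.value(d)
            gd = kernel.grad_d(d)
            M[i, n + j * K : n + (j + 1) * K] = -gd
            M[n + i * K : n + (i + 1) * K, j] = gd
            M[n + i * K : n + (i + 1) * K, n + j * K : n + (j + 1) * K] = -kernel.hess_d(d)
    M = 0.5 * (M + M.T)

    y = np.concatenate([energies - mu, gradients.ravel()])
    mean_diag = float(np.mean(np.diag(M)))
    rel = nugget_relative
    last_err = None
    while rel <= NUGGET_MAX_RELATIVE * 1.0001:
        nugget = rel * mean_diag
        try:
            cho = sla.cho_factor(M + nugget * np.eye(dim), lower=True)
            weights = sla.cho_solve(cho, y)
            return GEKModel(points, energies, gradients, kernel, mu, weights, cho, nugget)
        except np.linalg.LinAlgError as exc:
            last_err = exc
            rel *= 10.0
    raise np.linalg.LinAlgError(
        f"GEK covariance factorization failed up to nugget {NUGGET_MAX_RELATIVE}: {last_err}"
    )
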