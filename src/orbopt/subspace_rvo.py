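"""Subspace GEK with restricted-variance steps (S-GEK/RVO).

Each macro-iteration builds a small subspace from the recent optimization
record -- the displacement vectors and gradient-difference vectors of the
last ``m - 1`` iterations, the latest gradient and the RS-RFO predicted
displacement (2m candidate vectors, orthonormalized) -- projects coordinates,
gradients and the implicit Hessian into it, and runs a restricted-variance
GEK step there.  All GEK linear algebra then lives in at most ``2m``
dimensions: the linear system solved per iteration is ``m (1 + 2m)`` instead
of ``m (1 + N_scf)``.

The variance restriction replaces the fixed step-length restriction: the RFO
step-scale parameter ``alpha`` is raised until the surrogate's predicted
standard deviation at the step endpoint falls inside ``[0.9, 1.0]`` of the
allowed limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np


from .gek import GEKModel
from .implicit_hessian import ImplicitHessian
from .orbital_space import OrbitalPoint

__all__ = [
    "SubspaceBasis",
    "RVOResult",
    "RVOPolicy",
    "build_subspace",
    "project",
    "expand",
    "project_hessian",
    "rvo_step",
    "sgek_iterate",
]

GRAM_SCHMIDT_DROP_TOL = 1e-10
DEFAULT_M = 5
VARIANCE_BAND = (0.9, 1.0)
MAX_MICRO_ITERATIONS = 100


@dataclass(frozen=True)
class SubspaceBasis:
    """Orthonormal full-space vectors spanning the reduced space (columns)."""

    vectors: np.ndarray = field(repr=False)  # (K_full, dim_reduced)
    provenance: tuple[str, ...] = ()

    @property
    def dim_full(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim_reduced(self) -> int:
        return self.vectors.shape[1]


def build_subspace(
    history: list[OrbitalPoint],
    latest_gradient: np.ndarray,
    rfo_prediction: np.ndarray,
) -> SubspaceBasis:
    """Orthonormalize the 2m candidate vectors of the last m iterations.

    Candidates: (m-1) displacements, (m-1) gradient differences, the latest
    gradient, and the RS-RFO predicted displacement.  Modified Gram-Schmidt
    with a relative drop tolerance removes near-dependent candidates.
    """
    if not history:
        raise ValueError("empty history")
    candidates: list[tuple[str, np.ndarray]] = []
    for prev, cur in zip(history[:-1], history[1:]):
        candidates.append(("displacement", cur.kappa.values - prev.kappa.values))
        candidates.append(("gradient-difference", cur.gradient - prev.gradient))
    candidates.append(("latest-gradient", np.asarray(latest_gradient, dtype=float)))
    candidates.append(("rfo-prediction", np.asarray(rfo_prediction, dtype=float)))

    kept: list[np.ndarray] = []
    tags: list[str] = []
    for tag, vec in candidates:
        v = vec.astype(float).copy()
        norm0 = np.linalg.norm(v)
        if norm0 <= GRAM_SCHMIDT_DROP_TOL:
            continue
        for _pass in range(2):  # MGS twice for orthogonality to ~1e-14
            for u in kept:
                v -= np.dot(u, v) * u
        norm = np.linalg.norm(v)
        if norm <= GRAM_SCHMIDT_DROP_TOL * norm0:
            continue
        kept.append(v / norm)
        tags.append(tag)
    V = np.column_stack(kept) if kept else np.zeros((latest_gradient.size, 0))
    return SubspaceBasis(V, tuple(tags))


def project(basis: SubspaceBasis, full_vector: np.ndarray) -> np.ndarray:
    full_vector = np.asarray(full_vector, dtype=float)
    if full_vector.shape != (basis.dim_full,):
        raise ValueError("dimension mismatch")
    return basis.vectors.T @ full_vector


def expand(basis: SubspaceBasis, reduced_vector: np.ndarray) -> np.ndarray:
    reduced_vector = np.asarray(reduced_vector, dtype=float)
    if reduced_vector.shape != (basis.dim_reduced,):
        raise ValueError("dimension mismatch")
    return basis.vectors @ reduced_vector


def project_hessian(basis: SubspaceBasis, h: ImplicitHessian) -> np.ndarray:
    """``H_r = V.T (H V)`` using one hessvec per basis vector."""
    if basis.dim_reduced == 0:
        raise ValueError("empty basis")
    HV = np.column_stack([h.hessvec(basis.vectors[:, j]) for j in range(basis.dim_reduced)])
    Hr = basis.vectors.T @ HV
    return 0.5 * (Hr + Hr.T)


def _dense_rfo_step(g: np.ndarray, H: np.ndarray, alpha: float) -> np.ndarray:
    """Lowest-eigenvector RFO displacement in a (small) dense space."""
    k = g.size
    sqa = np.sqrt(alpha)
    A = np.empty((k + 1, k + 1))
    A[:k, :k] = H / alpha
    A[:k, k] = A[k, :k] = g / sqa
    A[k, k] = 0.0
    _, vecs = np.linalg.eigh(A)
    v = vecs[:, 0]
    if abs(v[k]) < 1e-12:
        raise np.linalg.LinAlgError("degenerate RFO eigenvector")
    return v[:k] / (sqa * v[k])


@dataclass(frozen=True)
class RVOResult:
    dz: np.ndarray = field(repr=False)
    alpha: float = 1.0
    predicted_std: float = 0.0
    micro_iterations: int = 0
    restricted: bool = False
    used_fallback: bool = False


def rvo_step(
    model: GEKModel | None,
    z0: np.ndarray,
    variance_limit: float,
    step_limit: float,
    fallback: tuple[np.ndarray, np.ndarray] | None = None,
) -> RVOResult:
    """Restricted-variance RFO step on the GEK surrogate.

    The step is the rational-function displacement for the surrogate's
    analytic gradient and Hessian at ``z0``; ``alpha``-microiterations raise
    the step-scale until both the predicted standard deviation at the
    endpoint and the step norm are within their limits.  A degenerate model
    (``model=None``) falls back to the projected quadratic model
    ``fallback = (gradient, dense Hessian)``.
    """
    if variance_limit <= 0 or step_limit <= 0:
        raise ValueError("limits must be positive")
    if model is None:
        if fallback is None:
            raise ValueError("degenerate model and no fallback supplied")
        g_r, H_r = fallback

        def step_at(alpha):
            return _dense_rfo_step(g_r, H_r, alpha)

        def std_at(dz):
            return 0.0

        used_fallback = True
    else:
        g_hat = model.predict_gradient(z0)
        H_hat = model.predict_hessian(z0)

        def step_at(alpha):
            return _dense_rfo_step(g_hat, H_hat, alpha)

        # restrict the *additional* predicted uncertainty of the move: the
        # nugget leaves an irreducible residual variance at the expansion
        # point itself, which is numerical noise, not model uncertainty
        var0 = model.predict_variance(z0)

        def std_at(dz):
            return math.sqrt(max(model.predict_variance(z0 + dz) - var0, 0.0))

        used_fallback = False
        if float(np.linalg.norm(g_hat)) == 0.0:
            return RVOResult(np.zeros_like(z0), 1.0, 0.0, 0, False, False)

    def feasible(dz):
        return (
            float(np.linalg.norm(dz)) <= step_limit
            and std_at(dz) <= variance_limit
        )

    dz = step_at(1.0)
    if feasible(dz):
        return RVOResult(dz, 1.0, std_at(dz), 0, False, used_fallback)

    lo, hi = 1.0, 2.0
    micro = 0
    while micro < MAX_MICRO_ITERATIONS:
        micro += 1
        dz_hi = step_at(hi)
        if feasible(dz_hi):
            break
        lo, hi = hi, hi * 4.0
    else:
        raise RuntimeError("failed to bracket the variance restriction in alpha")

    def within_band(dz):
        # at least one restriction close to active, neither violated
        return feasible(dz) and (
            std_at(dz) >= VARIANCE_BAND[0] * variance_limit
            or float(np.linalg.norm(dz)) >= VARIANCE_BAND[0] * step_limit
        )

    if within_band(dz_hi):
        return RVOResult(dz_hi, hi, std_at(dz_hi), micro, True, used_fallback)
    best = (hi, dz_hi)
    while micro < MAX_MICRO_ITERATIONS:
        micro += 1
        mid = 0.5 * (lo + hi)
        dz_mid = step_at(mid)
        if not feasible(dz_mid):
            lo = mid
        elif within_band(dz_mid):
            return RVOResult(dz_mid, mid, std_at(dz_mid), micro, True, used_fallback)
        else:
            hi, best = mid, (mid, dz_mid)
    alpha, dz = best
    return RVOResult(dz, alpha, std_at(dz), micro, True, used_fallback)


@dataclass
class RVOPolicy:
    """Adaptive variance limit: shrink on uphill steps, grow on downhill ones.

    The limit starts at ``init_factor * |last energy change|`` (floored), is
    halved whenever a step increased the energy and doubled (capped at
    ``cap_factor`` times the initial value) whenever it decreased it.
    """

    init_factor: float = 0.3
    floor: float = 1e-6
    cap_factor: float = 10.0
    _limit: float | None = None
    _initial: float | None = None

    def limit(self, last_energy_change: float) -> float:
        if self._limit is None:
            self._initial = max(self.init_factor * abs(last_energy_change), self.floor)
            self._limit = self._initial
        return self._limit

    def update(self, energy_decreased: bool) -> None:
        if self._limit is None:
            return
        if energy_decreased:
            self._limit = min(2.0 * self._limit, self.cap_factor * self._initial)
        else:
            self._limit = max(0.5 * self._limit, self.floor)


def sgek_iterate(oracle, config=None):
    """Drive a full S-GEK/RVO optimization; see :func:`orbopt.driver.optimize`."""
    from .driver import RunConfig, optimize

    config = config or RunConfig(method="s-gek-rvo")
    if config.method != "s-gek-rvo":
        raise ValueError("config.method must be 's-gek-rvo'")
    return optimize(oracle, config)
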