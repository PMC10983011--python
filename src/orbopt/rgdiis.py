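"""GDIIS with the C2-DIIS eigenvalue solver and three resetting rules.

The extrapolation works on quasi-Newton error vectors ``e_i = -H^-1 g_i``.
Coefficients minimizing the norm of the extrapolated error under the
affine constraint ``sum c = 1`` are obtained from the eigenvectors of the
``B_{ij} = e_i.T e_j`` matrix (C2-DIIS): each eigenvector ``q_j`` is
renormalized by the sum of its components, numerically corrupted candidates
(huge coefficient norm together with a tiny predicted error) are rejected, and
the surviving candidate with the smallest extrapolated error norm wins.

Three resetting rules guard the extrapolation (the "r" of r-GDIIS):

1. if the active error norms disagree by many orders of magnitude the depth
   is decreased one step at a time;
2. if the lowest-error history point lies *above* the current energy, or the
   error norms are far from descending order, the depth is reset to 1 (the
   shoulder/inflection defense) and the discarded points are dropped;
3. if the proposed step implies a rotation larger than 180 degrees, the BFGS
   update depth is reduced until the step is acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .implicit_hessian import ImplicitHessian
from .orbital_space import OrbitalPoint

__all__ = [
    "DIISHistory",
    "DIISSolution",
    "DegenerateDIISError",
    "ResetAction",
    "error_vector",
    "solve_c2diis",
    "gdiis_solve_vanilla",
    "gdiis_step",
    "apply_reset_rules",
]

M_MAX = 5
#: rule-1 disparity bound on min(B_ii)/max(B_ii)
RULE1_DELTA = 1e-8
#: rule-2 energy margin (E_h) and descending-order factor
RULE2_DELTA = 1e-4
RULE2_SIGMA = 15.0
#: C2-DIIS candidate rejection thresholds
REJECT_DELTA = 100.0
REJECT_SIGMA = 1e-5
#: rule-3 / step-length bound: a rotation of 180 degrees
MAX_ROTATION = np.pi


class DegenerateDIISError(RuntimeError):
    """All C2-DIIS candidates rejected; caller must reset the depth."""


class ResetAction(Enum):
    NONE = "none"
    SHRINK_M = "shrink_m"
    RESET_M_1 = "reset_m_1"
    REDUCE_BFGS_DEPTH = "reduce_bfgs_depth"


def error_vector(g: np.ndarray, h: ImplicitHessian) -> np.ndarray:
    """Quasi-Newton error vector ``e = -H^-1 g`` (zero iff the gradient is)."""
    return -h.invhessvec(g)


@dataclass
class DIISHistory:
    """Ring buffer of iterates, error vectors and their Gram matrix."""

    m_max: int = M_MAX
    points: list[OrbitalPoint] = field(default_factory=list)
    errors: list[np.ndarray] = field(default_factory=list)
    m: int = 0  # active depth (most recent m entries)

    def push(self, point: OrbitalPoint, error: np.ndarray) -> None:
        self.points.append(point)
        self.errors.append(np.asarray(error, dtype=float))
        if len(self.points) > self.m_max:
            self.points.pop(0)
            self.errors.pop(0)
        self.m = min(self.m + 1, self.m_max, len(self.points))

    def set_depth(self, m: int, drop: bool = False) -> None:
        m = max(1, min(m, len(self.points)))
        if drop:
            # discarded points are eliminated permanently
            self.points = self.points[len(self.points) - m :]
            self.errors = self.errors[len(self.errors) - m :]
        self.m = m

    @property
    def active_points(self) -> list[OrbitalPoint]:
        return self.points[len(self.points) - self.m :]

    @property
    def active_errors(self) -> list[np.ndarray]:
        return self.errors[len(self.errors) - self.m :]

    def b_matrix(self) -> np.ndarray:
        errs = self.active_errors
        m = len(errs)
        B = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                B[i, j] = B[j, i] = float(np.dot(errs[i], errs[j]))
        return B


@dataclass(frozen=True)
class DIISSolution:
    coefficients: np.ndarray
    predicted_error_sq: float  # c.T B c
    eigenvalue: float
    rejected_count: int


def solve_c2diis(B: np.ndarray) -> DIISSolution:
    """DIIS coefficients through the eigenvalue formulation of the B matrix.

    The constrained minimizer of ``c.T B c`` under ``sum c = 1`` expands in
    the eigenpairs of ``B`` as ``c ~ sum_j (u_j / lambda_j) q_j`` with
    ``u_j = q_j.T 1``; small eigenvalues amplify numerical noise through the
    ``1/lambda`` weights.  Candidates are therefore the partial sums of this
    expansion truncated at each eigenvalue (largest kept first), each
    renormalized by the sum of its components ``c_j = q_j / N_j``: the full
    sum is the exact Lagrangian solution, the truncations are its
    noise-filtered variants.  Candidates with a vanishing normalization are
    skipped; candidates with ``c.T c > 100`` *and* ``c.T B c < 1e-5`` carry
    the signature of instability (large oscillating coefficients, spuriously
    small predicted error) and are rejected.  Among the survivors the
    smallest extrapolated error norm ``c.T B c`` wins.
    """
    B = np.asarray(B, dtype=float)
    m = B.shape[0]
    if m == 1:
        return DIISSolution(np.array([1.0]), float(B[0, 0]), float(B[0, 0]), 0)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]  # keep dominant (stable) terms first
    candidates = []
    rejected = 0
    partial = np.zeros(m)
    for k, j in enumerate(order):
        lam_j = float(evals[j])
        q = evecs[:, j]
        u = float(np.sum(q))
        if lam_j != 0.0:
            partial = partial + (u / lam_j) * q
        N = float(np.sum(partial))
        if abs(N) < 1e-12:
            continue
        c = partial / N
        cc = float(np.dot(c, c))
        cBc = float(c @ B @ c)
        if cc > REJECT_DELTA and cBc < REJECT_SIGMA:
            rejected += 1
            continue
        candidates.append((cBc, lam_j, c.copy()))
    if not candidates:
        raise DegenerateDIISError("all C2-DIIS candidates rejected; reset the DIIS depth")
    candidates.sort(key=lambda t: t[0])
    cBc, lam, c = candidates[0]
    return DIISSolution(c, cBc, lam, rejected)


def gdiis_solve_vanilla(B: np.ndarray) -> DIISSolution:
    """Baseline solver: the augmented linear system of the original GDIIS."""
    B = np.asarray(B, dtype=float)
    m = B.shape[0]
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = B
    A[m, :m] = A[:m, m] = 1.0
    rhs = np.zeros(m + 1)
    rhs[m] = 1.0
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
    c = sol[:m]
    s = float(np.sum(c))
    if abs(s) > 1e-12:
        c = c / s
    return DIISSolution(c, float(c @ B @ c), float(sol[m]), 0)


def gdiis_step(
    history: DIISHistory,
    h: ImplicitHessian,
    solution: DIISSolution | None = None,
    solver=solve_c2diis,
) -> tuple[np.ndarray, DIISSolution]:
    """Extrapolate and take the full-space quasi-Newton update.

    ``kappa_{n+1} = sum_i c_i kappa_i - H^-1 (sum_i c_i g_i)``.  With a
    single-point history this is a pure variable-metric (quasi-Newton) step.
    """
    if not history.points:
        raise ValueError("empty DIIS history")
    if solution is None:
        solution = solver(history.b_matrix())
    pts = history.active_points
    c = solution.coefficients
    kappa_bar = sum(ci * p.kappa.values for ci, p in zip(c, pts))
    g_bar = sum(ci * p.gradient for ci, p in zip(c, pts))
    return kappa_bar - h.invhessvec(g_bar), solution


def apply_reset_rules(
    history: DIISHistory,
    current_energy: float,
    proposed_step_norm: float | None = None,
) -> list[ResetAction]:
    """Evaluate the r-GDIIS resetting rules (in order 1, 2, 3).

    Rules 1 and 2 mutate the history depth; rule 3 is only *signalled* here --
    the caller owns the BFGS depth reduction and re-stepping loop.
    """
    actions: list[ResetAction] = []

    # rule 1: error norms spanning more than RULE1_DELTA^-1 orders of magnitude
    while history.m > 1:
        d = np.diag(history.b_matrix())
        if float(np.min(d)) / float(np.max(d)) < RULE1_DELTA:
            history.set_depth(history.m - 1)
            if ResetAction.SHRINK_M not in actions:
                actions.append(ResetAction.SHRINK_M)
        else:
            break

    # rule 2: shoulder detection + descending-order check
    if history.m > 1:
        d = np.diag(history.b_matrix())
        pts = history.active_points
        i_min = int(np.argmin(d))
        fire = current_energy + RULE2_DELTA < pts[i_min].energy
        if not fire:
            for i in range(len(d) - 1):
                if d[i] * RULE2_SIGMA < d[i + 1]:
                    fire = True
                    break
        if fire:
            history.set_depth(1, drop=True)
            actions.append(ResetAction.RESET_M_1)

    # rule 3: rotation larger than 180 degrees
    if proposed_step_norm is not None and proposed_step_norm > MAX_ROTATION:
        actions.append(ResetAction.REDUCE_BFGS_DEPTH)

    if not actions:
        actions.append(ResetAction.NONE)
    return actions
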