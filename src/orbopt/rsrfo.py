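"""Restricted-step rational-function optimization (RS-RFO).

The step is recovered from the lowest eigenpair of the gradient-augmented
Hessian.  With the step-scale parameter ``alpha`` the (N+1)-dimensional
symmetric operator is::

    M(alpha) = [[ H / alpha,  g / sqrt(alpha) ],
                [ g.T / sqrt(alpha),        0 ]]

and the displacement is ``dkappa = v_kappa / (sqrt(alpha) * v_0)`` for the
lowest eigenvector ``(v_kappa, v_0)``.  ``alpha = 1`` is the plain RFO step;
increasing ``alpha`` shrinks the step monotonically, which is how the step
restriction is enforced (bracketing + bisection "alpha-microiterations").
The eigenpair is found with a Davidson solver using only Hessian-vector
products, so the Hessian is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .implicit_hessian import ImplicitHessian

__all__ = [
    "DavidsonError",
    "DegenerateStepError",
    "RFOStep",
    "davidson_lowest",
    "rfo_step",
    "restrict_step",
    "rsrfo_iterate",
]

#: default step-length limit; tightened to pi after a BFGS depth reset
DEFAULT_STEP_LIMIT = 10.0
RESET_STEP_LIMIT = np.pi
#: accepted band for the restricted step norm, as fractions of the limit
STEP_BAND = (0.9, 1.0)
MAX_MICRO_ITERATIONS = 100


class DavidsonError(RuntimeError):
    def __init__(self, message, best_residual=None):
        super().__init__(message)
        self.best_residual = best_residual


class DegenerateStepError(RuntimeError):
    """Augmentation component of the RFO eigenvector vanished."""


def davidson_lowest(
    matvec,
    dimension: int,
    diag_preconditioner: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    v0: np.ndarray | None = None,
    max_subspace: int = 30,
):
    """Lowest eigenpair of a symmetric operator from matrix-vector products.

    Classic Davidson: expand an orthonormal subspace with diagonally
    preconditioned residuals, restart when the subspace grows past
    ``max_subspace``.  Returns ``(eigenvalue, unit eigenvector)`` with
    residual norm below ``tol``.
    """
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    diag = (
        np.zeros(dimension)
        if diag_preconditioner is None
        else np.asarray(diag_preconditioner, dtype=float)
    )
    if v0 is None:
        v0 = np.zeros(dimension)
        v0[int(np.argmin(diag))] = 1.0
    b = v0 / np.linalg.norm(v0)
    V = [b]
    AV = [matvec(b)]
    best_residual = np.inf
    for _ in range(max_iter):
        k = len(V)
        Vm = np.column_stack(V)
        AVm = np.column_stack(AV)
        T = Vm.T @ AVm
        T = 0.5 * (T + T.T)
        evals, evecs = np.linalg.eigh(T)
        theta = float(evals[0])
        y = evecs[:, 0]
        x = Vm @ y
        r = AVm @ y - theta * x
        rnorm = float(np.linalg.norm(r))
        best_residual = min(best_residual, rnorm)
        if rnorm <= tol:
            return theta, x / np.linalg.norm(x)
        if k == dimension:
            # subspace is the full space; the Ritz pair is exact up to roundoff
            return theta, x / np.linalg.norm(x)
        if k >= max_subspace:
            V, AV = [x / np.linalg.norm(x)], [matvec(x / np.linalg.norm(x))]
            continue
        denom = diag - theta
        denom = np.where(np.abs(denom) < 1e-10, np.copysign(1e-10, denom + 1e-30), denom)
        t = r / denom
        # orthogonalize against the current subspace (twice, for stability)
        for _pass in range(2):
            for v in V:
                t -= np.dot(v, t) * v
        tn = np.linalg.norm(t)
        if tn < 1e-14:
            t = np.random.default_rng(k).standard_normal(dimension)
            for v in V:
                t -= np.dot(v, t) * v
            tn = np.linalg.norm(t)
        t /= tn
        V.append(t)
        AV.append(matvec(t))
    raise DavidsonError(
        f"Davidson did not reach tol={tol} in {max_iter} iterations",
        best_residual=best_residual,
    )


@dataclass(frozen=True)
class RFOStep:
    dkappa: np.ndarray = field(repr=False)
    eigenvalue: float = 0.0
    alpha_final: float = 1.0
    restricted: bool = False
    micro_iterations: int = 0

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.dkappa))


def _augmented_matvec(g: np.ndarray, hessvec, alpha: float):
    sqa = np.sqrt(alpha)

    def mv(v):
        vk, v0 = v[:-1], v[-1]
        out = np.empty_like(v)
        out[:-1] = hessvec(vk) / alpha + g * (v0 / sqa)
        out[-1] = float(np.dot(g, vk)) / sqa
        return out

    return mv


def rfo_step(
    g: np.ndarray,
    h: ImplicitHessian,
    alpha: float = 1.0,
    tol: float = 1e-10,
) -> RFOStep:
    """One rational-function step at fixed ``alpha`` (Davidson on the augmented system)."""
    g = np.asarray(g, dtype=float)
    n = g.size
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient must be finite")
    gnorm = float(np.linalg.norm(g))
    if gnorm == 0.0:
        return RFOStep(np.zeros(n), 0.0, alpha, False, 0)
    diag = np.concatenate([h.seed / alpha, [0.0]])
    v0 = np.concatenate([-g / gnorm * 0.1, [1.0]])
    theta, v = davidson_lowest(
        _augmented_matvec(g, h.hessvec, alpha),
        n + 1,
        diag_preconditioner=diag,
        tol=max(tol, 1e-12 * max(1.0, gnorm)),
        v0=v0,
    )
    v_kappa, v_aug = v[:-1], float(v[-1])
    if abs(v_aug) < 1e-12:
        raise DegenerateStepError("augmentation component below 1e-12")
    dkappa = v_kappa / (np.sqrt(alpha) * v_aug)
    return RFOStep(dkappa, theta, alpha, False, 0)


def restrict_step(
    g: np.ndarray,
    h: ImplicitHessian,
    step_limit: float = DEFAULT_STEP_LIMIT,
) -> RFOStep:
    """RFO step with its norm restricted to ``[0.9, 1.0] * step_limit``.

    ``|dkappa(alpha)|`` decreases monotonically with ``alpha``, so a bracket
    on ``alpha >= 1`` followed by bisection terminates quickly; each trial is
    one alpha-microiteration.
    """
    if step_limit <= 0:
        raise ValueError("step_limit must be positive")
    step = rfo_step(g, h, alpha=1.0)
    if step.norm <= step_limit:
        return step
    lo, hi = 1.0, 2.0
    micro = 0
    step_hi = None
    while micro < MAX_MICRO_ITERATIONS:
        micro += 1
        step_hi = rfo_step(g, h, alpha=hi)
        if step_hi.norm <= step_limit:
            break
        lo, hi = hi, hi * 4.0
    else:
        raise RuntimeError("failed to bracket the step restriction in alpha")
    if step_hi.norm >= STEP_BAND[0] * step_limit:
        return RFOStep(step_hi.dkappa, step_hi.eigenvalue, hi, True, micro)
    while micro < MAX_MICRO_ITERATIONS:
        micro += 1
        mid = 0.5 * (lo + hi)
        trial = rfo_step(g, h, alpha=mid)
        if trial.norm > step_limit:
            lo = mid
        elif trial.norm < STEP_BAND[0] * step_limit:
            hi = mid
        else:
            return RFOStep(trial.dkappa, trial.eigenvalue, mid, True, micro)
    # band not hit exactly; return the last feasible endpoint
    final = rfo_step(g, h, alpha=hi)
    return RFOStep(final.dkappa, final.eigenvalue, hi, True, micro)


def rsrfo_iterate(oracle, config=None):
    """Drive a full RS-RFO optimization; see :func:`orbopt.driver.optimize`."""
    from .driver import RunConfig, optimize

    config = config or RunConfig(method="rs-rfo")
    if config.method != "rs-rfo":
        raise ValueError("config.method must be 'rs-rfo'")
    return optimize(oracle, config)
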