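"""On-the-fly BFGS: Hessian (and inverse) action without forming the matrix.

The approximate Hessian is a positive diagonal seed plus a sequence of BFGS
rank-2 updates defined by (displacement, gradient-difference) pairs.  Products
``H v`` apply the updates in chronological order; inverse products use the
standard two-loop recursion, which is the exact inverse of the same update
sequence.  Pairs that violate the curvature condition ``dk.T dg > 0`` are
stored but never applied, so the operator stays symmetric positive definite.

The number of most-recent active pairs (the *depth*) can be reduced and later
restored -- the resetting rules of the optimizers rely on this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImplicitHessian", "UpdatePair"]

CURVATURE_TOL = 1e-12
DEFAULT_MAX_DEPTH = 20


@dataclass(frozen=True)
class UpdatePair:
    dk: np.ndarray
    dg: np.ndarray
    active: bool  # curvature condition satisfied


class ImplicitHessian:
    """BFGS-updated Hessian applied matrix-free.

    Parameters
    ----------
    seed:
        Positive diagonal of the zeroth-order Hessian model.
    max_depth:
        Ring-buffer capacity for update pairs; the oldest pair is evicted
        beyond it.
    """

    def __init__(self, seed: np.ndarray, max_depth: int = DEFAULT_MAX_DEPTH):
        seed = np.asarray(seed, dtype=float)
        if seed.ndim != 1 or np.min(seed) <= 0:
            raise ValueError("seed must be a positive diagonal vector")
        self.seed = seed
        self.max_depth = int(max_depth)
        self._pairs: list[UpdatePair] = []
        self._depth: int | None = None  # None -> all pairs

    # -- bookkeeping --------------------------------------------------------

    @property
    def dimension(self) -> int:
        return self.seed.size

    @property
    def pairs(self) -> list[UpdatePair]:
        return list(self._pairs)

    @property
    def depth(self) -> int:
        """Number of most-recent pairs currently applied."""
        if self._depth is None:
            return len(self._pairs)
        return min(self._depth, len(self._pairs))

    def _window(self) -> list[UpdatePair]:
        pairs = self._pairs if self._depth is None else self._pairs[len(self._pairs) - self.depth :]
        return [p for p in pairs if p.active]

    def push_pair(self, dk: np.ndarray, dg: np.ndarray) -> None:
        dk = np.asarray(dk, dtype=float)
        dg = np.asarray(dg, dtype=float)
        if dk.shape != self.seed.shape or dg.shape != self.seed.shape:
            raise ValueError("update pair dimension mismatch")
        curv = float(np.dot(dk, dg))
        active = curv > CURVATURE_TOL * np.linalg.norm(dk) * np.linalg.norm(dg)
        self._pairs.append(UpdatePair(dk, dg, active))
        if len(self._pairs) > self.max_depth:
            self._pairs.pop(0)
        self._depth = None  # a fresh pair restores full depth

    def reduce_depth(self, new_depth: int) -> None:
        """Keep only the `new_depth` most recent pairs active (pairs are retained)."""
        if new_depth < 0:
            raise ValueError("depth must be nonnegative")
        self._depth = min(new_depth, self.depth)

    def restore_depth(self) -> None:
        self._depth = None

    def clear_pairs(self) -> None:
        self._pairs = []
        self._depth = None

    # -- operator action ----------------------------------------------------

    def hessvec(self, v: np.ndarray) -> np.ndarray:
        """Product of the BFGS-updated matrix with ``v`` (chronological updates)."""
        v = np.asarray(v, dtype=float)
        if v.shape != self.seed.shape:
            raise ValueError("vector dimension mismatch")
        window = self._window()
        # H_k s_k needed per pair; build incrementally (O(depth^2) vector work)
        hs: list[np.ndarray] = []
        shs: list[float] = []
        sy: list[float] = []

        def apply_upto(k: int, x: np.ndarray) -> np.ndarray:
            out = self.seed * x
            for j in range(k):
                p = window[j]
                out += (
                    -hs[j] * (np.dot(hs[j], x) / shs[j])
                    + p.dg * (np.dot(p.dg, x) / sy[j])
                )
            return out

        for k, p in enumerate(window):
            h_s = apply_upto(k, p.dk)
            hs.append(h_s)
            shs.append(float(np.dot(p.dk, h_s)))
            sy.append(float(np.dot(p.dk, p.dg)))
        return apply_upto(len(window), v)

    def invhessvec(self, v: np.ndarray) -> np.ndarray:
        """Inverse product via the two-loop recursion (exact inverse of hessvec)."""
        v = np.asarray(v, dtype=float)
        if v.shape != self.seed.shape:
            raise ValueError("vector dimension mismatch")
        window = self._window()
        q = v.copy()
        alphas = []
        rhos = [1.0 / float(np.dot(p.dk, p.dg)) for p in window]
        for p, rho in zip(reversed(window), reversed(rhos)):
            a = rho * float(np.dot(p.dk, q))
            alphas.append(a)
            q = q - a * p.dg
        r = q / self.seed
        for p, rho, a in zip(window, rhos, reversed(alphas)):
            b = rho * float(np.dot(p.dg, r))
            r = r + (a - b) * p.dk
        return r

    # -- dense oracle (testing / tiny reduced spaces) -----------------------

    def dense(self) -> np.ndarray:
        """Explicit matrix; for oracles and dim-independent checks only."""
        H = np.diag(self.seed)
        for p in self._window():
            Hs = H @ p.dk
            H = (
                H
                - np.outer(Hs, Hs) / float(p.dk @ Hs)
                + np.outer(p.dg, p.dg) / float(p.dk @ p.dg)
            )
        return H
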