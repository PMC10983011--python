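"""Synthetic model objectives exercising optimizer edge cases.

Three families:

* ``quadratic`` -- convex with a prescribed SPD spectrum; closed-form tests.
* ``anharmonic_well`` -- quartic perturbation of a quadratic; mild anharmonicity.
* ``shoulder`` -- one coordinate follows a confined sigmoid profile with an
  inflection-point plateau ("shoulder") before a steep drop toward the
  minimum; all other coordinates are quadratic.  This reproduces the failure
  mode where extrapolation over small-gradient history points pulls the
  iterate back onto the plateau after it has crossed the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

__all__ = ["ModelSurface", "model_surface"]


@dataclass(frozen=True)
class ModelSurface:
    name: str
    dimension: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    description: str
    hessian_diag: np.ndarray = field(repr=False)  # quadratic-region curvature model
    start: np.ndarray = field(repr=False)
    minimizer: np.ndarray | None = field(default=None, repr=False)
    inflection: float | None = None  # shoulder coordinate of sign change of d2E/dx0^2

    def __call__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        return self.energy(x), self.gradient(x)


def _as_spectrum(dimension: int, params: dict) -> np.ndarray:
    spec = np.asarray(params.get("spectrum", np.ones(dimension)), dtype=float)
    if spec.size == 1:
        spec = np.full(dimension, float(spec))
    if spec.size != dimension:
        raise ValueError("spectrum length does not match dimension")
    if np.min(spec) <= 0:
        raise ValueError("quadratic spectrum must be positive definite")
    return spec


def model_surface(name: str, dimension: int, params: dict | None = None) -> ModelSurface:
    """Factory for the synthetic objectives (`quadratic`, `anharmonic_well`, `shoulder`)."""
    params = dict(params or {})
    if name == "quadratic":
        h = _as_spectrum(dimension, params)
        x0 = np.asarray(params.get("start", np.ones(dimension)), dtype=float)
        return ModelSurface(
            name="quadratic",
            dimension=dimension,
            energy=lambda x: 0.5 * float(np.dot(h, x * x)),
            gradient=lambda x: h * x,
            description="convex quadratic with prescribed SPD spectrum",
            hessian_diag=h,
            start=np.broadcast_to(x0, (dimension,)).copy(),
            minimizer=np.zeros(dimension),
        )
    if name == "anharmonic_well":
        h = _as_spectrum(dimension, params)
        a = float(params.get("quartic", 0.1))
        x0 = np.asarray(params.get("start", np.full(dimension, 1.5)), dtype=float)
        return ModelSurface(
            name="anharmonic_well",
            dimension=dimension,
            energy=lambda x: 0.5 * float(np.dot(h, x * x)) + a * float(np.sum(x**4)),
            gradient=lambda x: h * x + 4.0 * a * x**3,
            description="quartic-perturbed quadratic well",
            hessian_diag=h,
            start=np.broadcast_to(x0, (dimension,)).copy(),
            minimizer=np.zeros(dimension),
        )
    if name == "shoulder":
        if dimension < 1:
            raise ValueError("shoulder surface needs at least one coordinate")
        # sigmoid-plus-linear profile along x0: a long near-flat plateau with a
        # tiny constant slope, a steep sigmoid drop at the edge, and a stiff
        # cubic-hinge far wall confining a narrow basin.  E'' changes sign
        # exactly at the edge: concave on the plateau flank, convex beyond.
        slope = float(params.get("slope", 0.01))
        A = float(params.get("amplitude", 1.0))
        w = float(params.get("width", 0.2))
        xs = float(params.get("edge", 2.0))
        xm = float(params.get("basin", 2.8))
        wall = float(params.get("wall", 50.0))
        # curvature model along the shoulder coordinate: deliberately stiff
        # (the flat direction is exactly what a diagonal guess cannot see)
        h0 = float(params.get("model_curvature", 1.0))
        h_rest = _as_spectrum(dimension - 1, {"spectrum": params.get("spectrum", 1.0)}) if dimension > 1 else np.zeros(0)

        def _sech2(z):
            e = np.exp(-np.abs(z))
            return (2.0 * e / (1.0 + e * e)) ** 2

        def energy(x):
            z = (x[0] - xs) / w
            r = max(float(x[0]) - xm, 0.0)
            e0 = -slope * x[0] - A * np.tanh(z) + (wall / 6.0) * r**3
            return float(e0 + 0.5 * np.dot(h_rest, x[1:] * x[1:]))

        def gradient(x):
            z = (x[0] - xs) / w
            r = max(float(x[0]) - xm, 0.0)
            g = np.array(x, dtype=float).copy()
            g[0] = -slope - (A / w) * _sech2(z) + 0.5 * wall * r**2
            g[1:] = h_rest * x[1:]
            return g

        x_min = brentq(
            lambda x0: -slope - (A / w) * _sech2((x0 - xs) / w)
            + 0.5 * wall * max(x0 - xm, 0.0) ** 2,
            xm, xm + 5.0,
        )
        minimizer = np.zeros(dimension)
        minimizer[0] = x_min
        start = np.ones(dimension)
        start[0] = float(params.get("start", 1.0))
        hess = np.concatenate([[h0], h_rest])
        return ModelSurface(
            name="shoulder",
            dimension=dimension,
            energy=energy,
            gradient=gradient,
            description="linear-plus-sigmoid shoulder with a cubic-hinge far wall; "
            f"inflection at x0 = {xs:.6f}, minimum at x0 = {x_min:.6f}",
            hessian_diag=hess,
            start=start,
            minimizer=minimizer,
            inflection=float(xs),
        )
    raise ValueError(f"unknown model surface {name!r}")
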