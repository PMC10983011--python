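"""Orbital-rotation parameterization of an SCF determinant.

The occupied orbitals of a Slater determinant are varied through a unitary
rotation ``C' = C exp(-K)`` where ``K`` is the antisymmetric matrix whose only
nonzero entries couple occupied and virtual orbitals.  The free parameters --
the occupied-virtual block of ``K`` -- are collected in a :class:`KappaVector`
(radians).  The SCF energy is invariant under occ-occ and vir-vir rotations,
so this block is the complete parameter space of the problem, of size
``N_scf = sum_spins n_occ * n_vir``.

Conventions (fixed once, validated by the finite-difference tests):

* ``K[i, a] = +kappa_(i,a)``, ``K[a, i] = -kappa_(i,a)``; new orbitals are
  ``C' = C @ expm(-K)``.
* kappa components are stored row-major with the occupied index outer, one
  contiguous block per spin channel (restricted: a single block).
* the energy derivative with respect to a kappa component is ``2 F_ai`` per
  spin channel, hence ``4 F_ai`` for a doubly-occupied restricted block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "KappaVector",
    "OrbitalPoint",
    "SpinBlock",
    "antisymmetric_embedding",
    "expm_antisymmetric",
    "gradient_from_fock",
    "fock_ov_max_from_gradient",
    "diagonal_hessian_guess",
]

#: Restricted occ-vir rotations move two electrons, unrestricted ones move one.
RESTRICTED_GRADIENT_FACTOR = 4.0
UNRESTRICTED_GRADIENT_FACTOR = 2.0

#: Default floor for the diagonal Hessian model (E_h / rad^2).
DEFAULT_HESSIAN_FLOOR = 0.025


@dataclass(frozen=True)
class SpinBlock:
    """Occupied/virtual partition of one spin channel."""

    n_occ: int
    n_vir: int

    @property
    def n_mo(self) -> int:
        return self.n_occ + self.n_vir

    @property
    def n_rot(self) -> int:
        return self.n_occ * self.n_vir


@dataclass(frozen=True)
class KappaVector:
    """Orbital-rotation parameters, one contiguous occ x vir block per spin."""

    values: np.ndarray
    blocks: tuple[SpinBlock, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        expected = sum(b.n_rot for b in self.blocks)
        if values.ndim != 1 or values.size != expected:
            raise ValueError(
                f"kappa length {values.size} does not match rotation space size {expected}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("kappa entries must be finite")

    @classmethod
    def zeros(cls, blocks: Sequence[SpinBlock]) -> "KappaVector":
        blocks = tuple(blocks)
        return cls(np.zeros(sum(b.n_rot for b in blocks)), blocks)

    @property
    def restricted(self) -> bool:
        return len(self.blocks) == 1

    def split(self) -> list[np.ndarray]:
        """Per-spin (n_occ, n_vir) matrices of rotation parameters."""
        out, offset = [], 0
        for b in self.blocks:
            out.append(self.values[offset : offset + b.n_rot].reshape(b.n_occ, b.n_vir))
            offset += b.n_rot
        return out

    def with_values(self, values: np.ndarray) -> "KappaVector":
        return KappaVector(np.asarray(values, dtype=float), self.blocks)


@dataclass(frozen=True)
class OrbitalPoint:
    """One iterate: parameters, total energy (E_h) and gradient (E_h/rad)."""

    kappa: KappaVector
    energy: float
    gradient: np.ndarray = field(repr=False)

    def __post_init__(self):
        gradient = np.asarray(self.gradient, dtype=float)
        object.__setattr__(self, "gradient", gradient)
        if gradient.shape != self.kappa.values.shape:
            raise ValueError("gradient and kappa live in different spaces")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")


def antisymmetric_embedding(kappa_block: np.ndarray, block: SpinBlock) -> np.ndarray:
    """Embed an (n_occ, n_vir) parameter matrix into the full antisymmetric K."""
    if kappa_block.shape != (block.n_occ, block.n_vir):
        raise ValueError(
            f"kappa block shape {kappa_block.shape} does not match "
            f"({block.n_occ}, {block.n_vir})"
        )
    n = block.n_mo
    K = np.zeros((n, n))
    K[: block.n_occ, block.n_occ :] = kappa_block
    K[block.n_occ :, : block.n_occ] = -kappa_block.T
    return K


def expm_antisymmetric(kappa: KappaVector) -> list[np.ndarray]:
    """Per-spin orthogonal rotation matrices ``U = exp(-K)``.

    ``U`` is special orthogonal (``U^T U = I``, ``det U = +1``); the identity
    for ``kappa = 0``.  Spaces here are tiny, so the exact scaling-and-squaring
    exponential is used rather than any truncation.
    """
    out = []
    for kb, block in zip(kappa.split(), kappa.blocks):
        K = antisymmetric_embedding(kb, block)
        out.append(expm(-K))
    return out


def _spin_factors(blocks: Sequence[SpinBlock]) -> list[float]:
    if len(blocks) == 1:
        return [RESTRICTED_GRADIENT_FACTOR]
    return [UNRESTRICTED_GRADIENT_FACTOR] * len(blocks)


def gradient_from_fock(
    fock_mo: Sequence[np.ndarray] | np.ndarray,
    blocks: Sequence[SpinBlock],
) -> np.ndarray:
    """Orbital-rotation gradient from the MO-basis Fock matrix (one per spin).

    The derivative of the energy along kappa component (i, a) equals the
    occupied-virtual Fock element times the spin-channel occupancy factor:
    2 per singly-occupied (unrestricted) channel, 4 for the restricted
    doubly-occupied channel.  Exact at the expansion point of the rotation.
    """
    focks = [fock_mo] if isinstance(fock_mo, np.ndarray) else list(fock_mo)
    if len(focks) != len(blocks):
        raise ValueError("one Fock matrix per spin block required")
    parts = []
    for F, block, factor in zip(focks, blocks, _spin_factors(blocks)):
        if F.shape != (block.n_mo, block.n_mo):
            raise ValueError("Fock matrix does not match orbital counts")
        if not 0 <= block.n_occ <= block.n_mo:
            raise ValueError("n_occ out of range")
        parts.append(factor * F[: block.n_occ, block.n_occ :].ravel())
    return np.concatenate(parts) if parts else np.zeros(0)


def fock_ov_max_from_gradient(gradient: np.ndarray, blocks: Sequence[SpinBlock]) -> float:
    """Largest |F_ov| implied by a gradient vector (convergence measure)."""
    out, offset = 0.0, 0
    for block, factor in zip(blocks, _spin_factors(blocks)):
        seg = gradient[offset : offset + block.n_rot]
        if seg.size:
            out = max(out, float(np.max(np.abs(seg))) / factor)
        offset += block.n_rot
    return out


def diagonal_hessian_guess(
    orbital_energies: Sequence[np.ndarray] | np.ndarray,
    blocks: Sequence[SpinBlock],
    floor: float = DEFAULT_HESSIAN_FLOOR,
) -> np.ndarray:
    """Diagonal second-derivative model from orbital-energy gaps.

    Element (i -> a) is ``factor * (eps_a - eps_i)`` with the same occupancy
    factor as the gradient, so that at a converged canonical solution it is the
    leading (one-electron) part of the true Hessian diagonal.  Entries are
    floored at ``floor`` so degenerate or inverted gaps never produce an
    indefinite seed.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    eps_list = (
        [orbital_energies] if isinstance(orbital_energies, np.ndarray) else list(orbital_energies)
    )
    parts = []
    for eps, block, factor in zip(eps_list, blocks, _spin_factors(blocks)):
        eps = np.asarray(eps, dtype=float)
        gaps = eps[block.n_occ :][None, :] - eps[: block.n_occ][:, None]
        parts.append(np.maximum(factor * gaps, floor).ravel())
    return np.concatenate(parts) if parts else np.zeros(0)
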