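"""Hartree-Fock energy/gradient oracle over molecular fixtures.

The oracle is a smooth function of the orbital-rotation parameters: for a
fixed set of reference orbitals ``C`` (orthonormal with respect to the fixture
overlap), ``E(kappa)`` is the HF expectation value of the determinant built
from the occupied columns of ``C' = C exp(-K)``.  The gradient is the *exact*
derivative of this function, obtained through the adjoint Frechet derivative
of the matrix exponential, so finite differences of the energy match the
gradient everywhere, not only at the expansion point.

A tightly converged Roothaan fixed-point solver (`roothaan_reference`) serves
as the independent brute-force oracle for the converged energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .fixtures import MoleculeFixture
from .orbital_space import (
    KappaVector,
    SpinBlock,
    antisymmetric_embedding,
    diagonal_hessian_guess,
)

__all__ = ["ScfEvaluation", "ScfOracle", "scf_oracle", "core_guess", "roothaan_reference"]


def _fock_restricted(fix: MoleculeFixture, P: np.ndarray) -> np.ndarray:
    J = np.einsum("pqrs,rs->pq", fix.eri, P)
    K = np.einsum("prqs,rs->pq", fix.eri, P)
    return fix.hcore + J - 0.5 * K


def _fock_unrestricted(fix: MoleculeFixture, Pa: np.ndarray, Pb: np.ndarray):
    Jt = np.einsum("pqrs,rs->pq", fix.eri, Pa + Pb)
    Ka = np.einsum("prqs,rs->pq", fix.eri, Pa)
    Kb = np.einsum("prqs,rs->pq", fix.eri, Pb)
    return fix.hcore + Jt - Ka, fix.hcore + Jt - Kb


@dataclass(frozen=True)
class ScfEvaluation:
    """One oracle evaluation at a kappa point."""

    energy: float
    gradient: np.ndarray = field(repr=False)
    fock_mo: list = field(repr=False)  # per-spin MO-basis Fock matrices
    orbital_energies: list = field(repr=False)  # per-spin Fock diagonals
    fock_ov_max: float = 0.0


class ScfOracle:
    """Callable ``kappa -> ScfEvaluation`` bound to a fixture and reference orbitals."""

    def __init__(self, fixture: MoleculeFixture, reference_orbitals, unrestricted: bool | None = None):
        fixture.validate()
        self.fixture = fixture
        self.unrestricted = (not fixture.restricted) if unrestricted is None else bool(unrestricted)
        if not self.unrestricted and not fixture.restricted:
            raise ValueError("open-shell fixtures require the unrestricted formulation")
        if not self.unrestricted:
            self._C = [np.asarray(reference_orbitals, dtype=float)]
            n_occ = [fixture.n_alpha]
        else:
            if isinstance(reference_orbitals, np.ndarray):
                reference_orbitals = (reference_orbitals, reference_orbitals)
            Ca, Cb = reference_orbitals
            self._C = [np.asarray(Ca, dtype=float), np.asarray(Cb, dtype=float)]
            n_occ = [fixture.n_alpha, fixture.n_beta]
        if max(n_occ) > fixture.n_ao:
            raise ValueError("electron count exceeds basis size")
        for C in self._C:
            dev = np.max(np.abs(C.T @ fixture.overlap @ C - np.eye(fixture.n_ao)))
            if dev > 1e-8:
                raise ValueError(f"reference orbitals not S-orthonormal (deviation {dev:.2e})")
        self.blocks = tuple(
            SpinBlock(n, fixture.n_ao - n) for n in n_occ
        )
        self.dimension = sum(b.n_rot for b in self.blocks)

    # -- helpers ------------------------------------------------------------

    def kappa(self, values=None) -> KappaVector:
        if values is None:
            return KappaVector.zeros(self.blocks)
        return KappaVector(np.asarray(values, dtype=float), self.blocks)

    def rotated_orbitals(self, kappa: KappaVector) -> list[np.ndarray]:
        Us = [
            sla.expm(-antisymmetric_embedding(kb, b))
            for kb, b in zip(kappa.split(), kappa.blocks)
        ]
        return [C @ U for C, U in zip(self._C, Us)]

    def _exact_gradient_block(self, kb, block, F_ao, C_ref, Cp, factor) -> np.ndarray:
        """d E / d kappa for one spin via the adjoint Frechet derivative of expm."""
        K = antisymmetric_embedding(kb, block)
        # dE/dC' has columns `factor * F C'_i` for occupied i, zero for virtuals
        Gc = np.zeros_like(Cp)
        Gc[:, : block.n_occ] = factor * (F_ao @ Cp[:, : block.n_occ])
        Lam = C_ref.T @ Gc
        M = sla.expm_frechet(K, Lam, compute_expm=False)
        A = M - M.T  # g_(i,a) = -(M_ia - M_ai)
        return -A[: block.n_occ, block.n_occ :].ravel()

    # -- evaluation ---------------------------------------------------------

    def __call__(self, kappa) -> ScfEvaluation:
        if not isinstance(kappa, KappaVector):
            kappa = self.kappa(kappa)
        fix = self.fixture
        Cp = self.rotated_orbitals(kappa)
        if not self.unrestricted:
            Cocc = Cp[0][:, : self.blocks[0].n_occ]
            P = 2.0 * Cocc @ Cocc.T
            F = _fock_restricted(fix, P)
            energy = 0.5 * np.sum(P * (fix.hcore + F)) + fix.enuc
            focks_ao = [F]
            factors = [4.0]
        else:
            Pa = Cp[0][:, : self.blocks[0].n_occ] @ Cp[0][:, : self.blocks[0].n_occ].T
            Pb = Cp[1][:, : self.blocks[1].n_occ] @ Cp[1][:, : self.blocks[1].n_occ].T
            Fa, Fb = _fock_unrestricted(fix, Pa, Pb)
            energy = (
                0.5 * np.sum(Pa * (fix.hcore + Fa))
                + 0.5 * np.sum(Pb * (fix.hcore + Fb))
                + fix.enuc
            )
            focks_ao = [Fa, Fb]
            factors = [2.0, 2.0]

        grads, focks_mo, eps, ov_max = [], [], [], 0.0
        for kb, block, F_ao, C_ref, C_rot, factor in zip(
            kappa.split(), self.blocks, focks_ao, self._C, Cp, factors
        ):
            F_mo = C_rot.T @ F_ao @ C_rot
            focks_mo.append(F_mo)
            eps.append(np.diag(F_mo).copy())
            if block.n_occ and block.n_vir:
                ov_max = max(ov_max, float(np.max(np.abs(F_mo[: block.n_occ, block.n_occ:]))))
            grads.append(self._exact_gradient_block(kb, block, F_ao, C_ref, C_rot, factor))

        return ScfEvaluation(
            energy=float(energy),
            gradient=np.concatenate(grads) if grads else np.zeros(0),
            fock_mo=focks_mo,
            orbital_energies=eps,
            fock_ov_max=ov_max,
        )

    def hessian_diag_guess(self, evaluation: ScfEvaluation, floor: float = 0.025) -> np.ndarray:
        return diagonal_hessian_guess(evaluation.orbital_energies, self.blocks, floor=floor)


def scf_oracle(
    fixture: MoleculeFixture, reference_orbitals, unrestricted: bool | None = None
) -> ScfOracle:
    """Bind a fixture and reference orbitals into an energy/gradient oracle."""
    return ScfOracle(fixture, reference_orbitals, unrestricted=unrestricted)


def core_guess(fixture: MoleculeFixture):
    """Orbitals from diagonalizing the core Hamiltonian (no electron repulsion)."""
    _, C = sla.eigh(fixture.hcore, fixture.overlap)
    return C if fixture.restricted else (C.copy(), C.copy())


def roothaan_steps(fixture: MoleculeFixture, orbitals, n_steps: int):
    """Plain Roothaan fixed-point iterations (diagonalize the current Fock).

    Used by the driver's simplified SCF startup.  Returns the new orbitals and
    the energy of each step.
    """
    fix = fixture
    energies = []
    if fix.restricted:
        C = np.asarray(orbitals, dtype=float)
        for _ in range(n_steps):
            Cocc = C[:, : fix.n_alpha]
            P = 2.0 * Cocc @ Cocc.T
            F = _fock_restricted(fix, P)
            energies.append(float(0.5 * np.sum(P * (fix.hcore + F)) + fix.enuc))
            _, C = sla.eigh(F, fix.overlap)
        return C, energies
    Ca, Cb = (np.asarray(c, dtype=float) for c in orbitals)
    for _ in range(n_steps):
        Pa = Ca[:, : fix.n_alpha] @ Ca[:, : fix.n_alpha].T
        Pb = Cb[:, : fix.n_beta] @ Cb[:, : fix.n_beta].T
        Fa, Fb = _fock_unrestricted(fix, Pa, Pb)
        energies.append(
            float(
                0.5 * np.sum(Pa * (fix.hcore + Fa))
                + 0.5 * np.sum(Pb * (fix.hcore + Fb))
                + fix.enuc
            )
        )
        _, Ca = sla.eigh(Fa, fix.overlap)
        _, Cb = sla.eigh(Fb, fix.overlap)
    return (Ca, Cb), energies


def _diis_extrapolate(focks, errors):
    m = len(focks)
    B = np.empty((m + 1, m + 1))
    B[-1, :] = B[:, -1] = -1.0
    B[-1, -1] = 0.0
    for i in range(m):
        for j in range(m):
            B[i, j] = np.vdot(errors[i], errors[j])
    rhs = np.zeros(m + 1)
    rhs[-1] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:m]
    except np.linalg.LinAlgError:
        c = np.linalg.lstsq(B, rhs, rcond=None)[0][:m]
    return sum(ci * F for ci, F in zip(c, focks))


def roothaan_reference(
    fixture: MoleculeFixture,
    tol: float = 1e-12,
    max_iter: int = 1000,
    diis: bool = True,
):
    """Tight Roothaan fixed-point SCF (with Fock-matrix DIIS).

    Independent of the rotation-based optimizers; used as the brute-force
    reference for converged energies.  Returns ``(energy, orbitals,
    orbital_energies)`` with per-spin tuples in the unrestricted case.
    """
    fix = fixture
    S = fix.overlap
    X = sla.fractional_matrix_power(S, -0.5)
    if fix.restricted:
        C = core_guess(fix)
        nocc = fix.n_alpha
        E_old, focks, errs = 0.0, [], []
        for _ in range(max_iter):
            Cocc = C[:, :nocc]
            P = 2.0 * Cocc @ Cocc.T
            F = _fock_restricted(fix, P)
            E = 0.5 * np.sum(P * (fix.hcore + F)) + fix.enuc
            err = X.T @ (F @ P @ S - S @ P @ F) @ X
            focks.append(F)
            errs.append(err)
            if len(focks) > 8:
                focks.pop(0), errs.pop(0)
            if abs(E - E_old) < tol and np.max(np.abs(err)) < 1e-9:
                return float(E), C, sla.eigh(F, S)[0]
            E_old = E
            Fuse = _diis_extrapolate(focks, errs) if (diis and len(focks) > 1) else F
            _, C = sla.eigh(Fuse, S)
        raise RuntimeError("Roothaan reference did not converge")
    Ca, Cb = core_guess(fix)
    na, nb = fix.n_alpha, fix.n_beta
    E_old, focks, errs = 0.0, [], []
    for _ in range(max_iter):
        Pa = Ca[:, :na] @ Ca[:, :na].T
        Pb = Cb[:, :nb] @ Cb[:, :nb].T
        Fa, Fb = _fock_unrestricted(fix, Pa, Pb)
        E = (
            0.5 * np.sum(Pa * (fix.hcore + Fa))
            + 0.5 * np.sum(Pb * (fix.hcore + Fb))
            + fix.enuc
        )
        err = np.concatenate(
            [
                (X.T @ (Fa @ Pa @ S - S @ Pa @ Fa) @ X).ravel(),
                (X.T @ (Fb @ Pb @ S - S @ Pb @ Fb) @ X).ravel(),
            ]
        )
        focks.append((Fa, Fb))
        errs.append(err)
        if len(focks) > 8:
            focks.pop(0), errs.pop(0)
        if abs(E - E_old) < tol and np.max(np.abs(err)) < 1e-9:
            return float(E), (Ca, Cb), (sla.eigh(Fa, S)[0], sla.eigh(Fb, S)[0])
        E_old = E
        if diis and len(focks) > 1:
            m = len(focks)
            B = np.empty((m + 1, m + 1))
            B[-1, :] = B[:, -1] = -1.0
            B[-1, -1] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.vdot(errs[i], errs[j])
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:m]
            except np.linalg.LinAlgError:
                c = np.linalg.lstsq(B, rhs, rcond=None)[0][:m]
            Fa = sum(ci * F[0] for ci, F in zip(c, focks))
            Fb = sum(ci * F[1] for ci, F in zip(c, focks))
        _, Ca = sla.eigh(Fa, S)
        _, Cb = sla.eigh(Fb, S)
    raise RuntimeError("Roothaan reference did not converge")
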