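"""Minimal-basis Gaussian integral engine (McMurchie-Davidson scheme).

Computes overlap, kinetic, nuclear-attraction and two-electron repulsion
integrals over contracted Cartesian Gaussians for the elements needed by the
bundled molecular fixtures (H, He, O in an STO-3G basis).  Everything is exact
closed-form Gaussian algebra: Hermite expansion coefficients ``E`` couple
Cartesian to Hermite Gaussians, and the Hermite Coulomb tensor ``R`` carries
the Boys-function kernel.  Spaces are tiny (<= 10 AOs), so clarity wins over
vectorization throughout.

All returned integrals are in atomic units; geometries enter in Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import hyp1f1

__all__ = ["BasisShell", "build_basis", "compute_integrals", "ANGSTROM_TO_BOHR", "SUPPORTED_ELEMENTS"]

ANGSTROM_TO_BOHR = 1.0 / 0.529177210903

ELEMENT_Z = {"H": 1, "He": 2, "O": 8}
SUPPORTED_ELEMENTS = tuple(ELEMENT_Z)

# STO-3G exponents / contraction coefficients (coefficients refer to
# normalized primitives; contracted functions are renormalized below).
_STO3G = {
    "H": [("S", [3.425250914, 0.6239137298, 0.1688554040],
           [0.1543289673, 0.5353281423, 0.4446345422])],
    "He": [("S", [6.362421394, 1.158922999, 0.3136497915],
            [0.1543289673, 0.5353281423, 0.4446345422])],
    "O": [
        ("S", [130.7093214, 23.80886605, 6.443608313],
         [0.1543289673, 0.5353281423, 0.4446345422]),
        ("S", [5.033151319, 1.169596125, 0.3803889600],
         [-0.09996722919, 0.3995128261, 0.7001154689]),
        ("P", [5.033151319, 1.169596125, 0.3803889600],
         [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
}

_CARTESIAN_POWERS = {"S": [(0, 0, 0)], "P": [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}


def _double_factorial(n: int) -> int:
    return 1 if n <= 1 else n * _double_factorial(n - 2)


def _primitive_norm(alpha: float, lmn: tuple[int, int, int]) -> float:
    l, m, n = lmn
    L = l + m + n
    pref = (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    return pref / math.sqrt(
        _double_factorial(2 * l - 1) * _double_factorial(2 * m - 1) * _double_factorial(2 * n - 1)
    )


@dataclass(frozen=True)
class BasisShell:
    """One contracted Cartesian Gaussian function."""

    center: tuple[float, float, float]
    lmn: tuple[int, int, int]
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]  # include primitive + contraction norms
    label: str


def build_basis(symbols, coords_bohr) -> list[BasisShell]:
    """STO-3G Cartesian basis functions for a geometry (coordinates in bohr)."""
    basis: list[BasisShell] = []
    for sym, xyz in zip(symbols, coords_bohr):
        if sym not in _STO3G:
            raise ValueError(f"unsupported element {sym!r}; supported: {SUPPORTED_ELEMENTS}")
        for shell_type, exps, coefs in _STO3G[sym]:
            for lmn in _CARTESIAN_POWERS[shell_type]:
                c = np.array([cf * _primitive_norm(a, lmn) for a, cf in zip(exps, coefs)])
                # contraction self-overlap -> unit norm
                norm2 = 0.0
                for ci, ai in zip(c, exps):
                    for cj, aj in zip(c, exps):
                        norm2 += ci * cj * _overlap_prim(ai, lmn, (0.0, 0.0, 0.0),
                                                         aj, lmn, (0.0, 0.0, 0.0))
                c /= math.sqrt(norm2)
                basis.append(BasisShell(tuple(map(float, xyz)), lmn, tuple(exps),
                                        tuple(c), f"{sym}_{shell_type}{lmn}"))
    return basis


def boys(n: int, x: float) -> float:
    return hyp1f1(n + 0.5, n + 1.5, -x) / (2.0 * n + 1.0)


def _e_coeff(i: int, j: int, t: int, Qx: float, a: float, b: float) -> float:
    """Hermite expansion coefficient E_t^{ij} for a 1-D Gaussian product."""
    p = a + b
    q = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == j == t == 0:
        return math.exp(-q * Qx * Qx)
    if j == 0:
        return (
            (1.0 / (2.0 * p)) * _e_coeff(i - 1, j, t - 1, Qx, a, b)
            - (q * Qx / a) * _e_coeff(i - 1, j, t, Qx, a, b)
            + (t + 1) * _e_coeff(i - 1, j, t + 1, Qx, a, b)
        )
    return (
        (1.0 / (2.0 * p)) * _e_coeff(i, j - 1, t - 1, Qx, a, b)
        + (q * Qx / b) * _e_coeff(i, j - 1, t, Qx, a, b)
        + (t + 1) * _e_coeff(i, j - 1, t + 1, Qx, a, b)
    )


def _overlap_prim(a, lmn1, A, b, lmn2, B) -> float:
    p = a + b
    s = (math.pi / p) ** 1.5
    for l1, l2, Ax, Bx in zip(lmn1, lmn2, A, B):
        s *= _e_coeff(l1, l2, 0, Ax - Bx, a, b)
    return s


def _kinetic_prim(a, lmn1, A, b, lmn2, B) -> float:
    l2, m2, n2 = lmn2
    term0 = b * (2 * (l2 + m2 + n2) + 3) * _overlap_prim(a, lmn1, A, b, lmn2, B)
    term1 = -2.0 * b * b * (
        _overlap_prim(a, lmn1, A, b, (l2 + 2, m2, n2), B)
        + _overlap_prim(a, lmn1, A, b, (l2, m2 + 2, n2), B)
        + _overlap_prim(a, lmn1, A, b, (l2, m2, n2 + 2), B)
    )
    term2 = -0.5 * (
        l2 * (l2 - 1) * _overlap_prim(a, lmn1, A, b, (l2 - 2, m2, n2), B)
        + m2 * (m2 - 1) * _overlap_prim(a, lmn1, A, b, (l2, m2 - 2, n2), B)
        + n2 * (n2 - 1) * _overlap_prim(a, lmn1, A, b, (l2, m2, n2 - 2), B)
    )
    return term0 + term1 + term2


def _hermite_coulomb(t: int, u: int, v: int, n: int, p: float, PC, memo) -> float:
    key = (t, u, v, n)
    if key in memo:
        return memo[key]
    if t < 0 or u < 0 or v < 0:
        return 0.0
    if t == u == v == 0:
        val = (-2.0 * p) ** n * boys(n, p * (PC[0] ** 2 + PC[1] ** 2 + PC[2] ** 2))
    elif t > 0:
        val = (t - 1) * _hermite_coulomb(t - 2, u, v, n + 1, p, PC, memo) + PC[0] * _hermite_coulomb(
            t - 1, u, v, n + 1, p, PC, memo
        )
    elif u > 0:
        val = (u - 1) * _hermite_coulomb(t, u - 2, v, n + 1, p, PC, memo) + PC[1] * _hermite_coulomb(
            t, u - 1, v, n + 1, p, PC, memo
        )
    else:
        val = (v - 1) * _hermite_coulomb(t, u, v - 2, n + 1, p, PC, memo) + PC[2] * _hermite_coulomb(
            t, u, v - 1, n + 1, p, PC, memo
        )
    memo[key] = val
    return val


def _nuclear_prim(a, lmn1, A, b, lmn2, B, C) -> float:
    p = a + b
    P = tuple((a * Ax + b * Bx) / p for Ax, Bx in zip(A, B))
    PC = tuple(Px - Cx for Px, Cx in zip(P, C))
    memo: dict = {}
    val = 0.0
    for t in range(lmn1[0] + lmn2[0] + 1):
        Ex = _e_coeff(lmn1[0], lmn2[0], t, A[0] - B[0], a, b)
        for u in range(lmn1[1] + lmn2[1] + 1):
            Ey = _e_coeff(lmn1[1], lmn2[1], u, A[1] - B[1], a, b)
            for v in range(lmn1[2] + lmn2[2] + 1):
                Ez = _e_coeff(lmn1[2], lmn2[2], v, A[2] - B[2], a, b)
                val += Ex * Ey * Ez * _hermite_coulomb(t, u, v, 0, p, PC, memo)
    return 2.0 * math.pi / p * val


def _eri_prim(a, lmn1, A, b, lmn2, B, c, lmn3, C, d, lmn4, D) -> float:
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = tuple((a * Ax + b * Bx) / p for Ax, Bx in zip(A, B))
    Q = tuple((c * Cx + d * Dx) / q for Cx, Dx in zip(C, D))
    PQ = tuple(Px - Qx for Px, Qx in zip(P, Q))
    memo: dict = {}
    E1 = [
        [_e_coeff(lmn1[k], lmn2[k], t, A[k] - B[k], a, b)
         for t in range(lmn1[k] + lmn2[k] + 1)]
        for k in range(3)
    ]
    E2 = [
        [_e_coeff(lmn3[k], lmn4[k], t, C[k] - D[k], c, d)
         for t in range(lmn3[k] + lmn4[k] + 1)]
        for k in range(3)
    ]
    val = 0.0
    for t, Ex in enumerate(E1[0]):
        for u, Ey in enumerate(E1[1]):
            for v, Ez in enumerate(E1[2]):
                w1 = Ex * Ey * Ez
                if w1 == 0.0:
                    continue
                for tau, Fx in enumerate(E2[0]):
                    for nu, Fy in enumerate(E2[1]):
                        for phi, Fz in enumerate(E2[2]):
                            w2 = Fx * Fy * Fz
                            if w2 == 0.0:
                                continue
                            sign = -1.0 if (tau + nu + phi) % 2 else 1.0
                            val += w1 * w2 * sign * _hermite_coulomb(
                                t + tau, u + nu, v + phi, 0, alpha, PQ, memo
                            )
    return val * 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))


def _contracted(prim_fn, sh1: BasisShell, sh2: BasisShell, *more) -> float:
    shells = (sh1, sh2) + more
    total = 0.0

    def rec(idx, coef, args):
        nonlocal total
        if idx == len(shells):
            total += coef * prim_fn(*args)
            return
        sh = shells[idx]
        for a, c in zip(sh.exponents, sh.coefficients):
            rec(idx + 1, coef * c, args + [a, sh.lmn, sh.center])

    rec(0, 1.0, [])
    return total


def compute_integrals(symbols, coords_angstrom):
    """All one- and two-electron integrals for a geometry.

    Returns ``(S, hcore, eri, enuc)`` with ``eri`` in chemists' notation
    ``(ij|kl)`` carrying the full 8-fold permutational symmetry.
    """
    coords = np.asarray(coords_angstrom, dtype=float) * ANGSTROM_TO_BOHR
    basis = build_basis(symbols, coords)
    n = len(basis)
    charges = [ELEMENT_Z[s] for s in symbols]

    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            S[i, j] = S[j, i] = _contracted(_overlap_prim, basis[i], basis[j])
            T[i, j] = T[j, i] = _contracted(_kinetic_prim, basis[i], basis[j])
            v = 0.0
            for Z, R in zip(charges, coords):
                v -= Z * _contracted(
                    lambda a, l1, A, b, l2, B, R=tuple(R): _nuclear_prim(a, l1, A, b, l2, B, R),
                    basis[i], basis[j],
                )
            V[i, j] = V[j, i] = v

    eri = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    val = _contracted(_eri_prim, basis[i], basis[j], basis[k], basis[l])
                    for (p, q, r, s) in (
                        (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
                        (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
                    ):
                        eri[p, q, r, s] = val

    enuc = 0.0
    for i in range(len(charges)):
        for j in range(i):
            enuc += charges[i] * charges[j] / np.linalg.norm(coords[i] - coords[j])

    return S, T + V, eri, float(enuc)
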