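"""Bundled molecular fixtures: integral tables for small test systems.

Each fixture carries everything an SCF oracle needs -- overlap, core
Hamiltonian, two-electron integrals (chemists' notation), nuclear repulsion --
for a small molecule in the STO-3G basis.  The suite mirrors a production
benchmark's design at desk scale: equilibrium vs stretched geometries,
closed- and open-shell (singlet/doublet/triplet) systems.

Tables are generated deterministically by the in-repo integral engine on
first access and cached for the session.  ``save_fixture`` / ``load_fixture``
provide an HDF5 container round-trip; loading re-validates the integrity
invariants (overlap SPD, 8-fold permutational symmetry, electron-count
parity), so a corrupted container fails loudly with the violated invariant.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .integrals import SUPPORTED_ELEMENTS, compute_integrals

__all__ = [
    "MoleculeFixture",
    "FixtureIntegrityError",
    "make_fixture",
    "list_fixtures",
    "save_fixture",
    "load_fixture",
    "read_xyz",
]

BASIS_LABEL = "STO-3G"

#: name -> (symbols, coordinates in Angstrom, charge, spin multiplicity)
_REGISTRY: dict[str, tuple[tuple[str, ...], tuple[tuple[float, float, float], ...], int, int]] = {
    # equilibrium H2 and the 2.5x stretched analog of a strained wave function
    "H2": (("H", "H"), ((0.0, 0.0, 0.0), (0.0, 0.0, 0.7414)), 0, 1),
    "H2_stretched": (("H", "H"), ((0.0, 0.0, 0.0), (0.0, 0.0, 1.8535)), 0, 1),
    "HeH+": (("He", "H"), ((0.0, 0.0, 0.0), (0.0, 0.0, 0.7743)), 1, 1),
    "H2O": (
        ("O", "H", "H"),
        ((0.0, 0.0, 0.1173), (0.0, 0.7572, -0.4692), (0.0, -0.7572, -0.4692)),
        0,
        1,
    ),
    # linear symmetric H3, the classic doublet radical
    "H3": (("H", "H", "H"), ((0.0, 0.0, -0.93), (0.0, 0.0, 0.0), (0.0, 0.0, 0.93)), 0, 2),
    # O2 near equilibrium, ground-state triplet
    "O2": (("O", "O"), ((0.0, 0.0, 0.0), (0.0, 0.0, 1.2075)), 0, 3),
}


class FixtureIntegrityError(ValueError):
    """An integral table violates one of the fixture invariants."""


@dataclass(frozen=True)
class MoleculeFixture:
    name: str
    symbols: tuple[str, ...]
    coordinates: np.ndarray  # Angstrom, shape (n_atoms, 3)
    n_electrons: int
    spin_multiplicity: int
    overlap: np.ndarray = field(repr=False)
    hcore: np.ndarray = field(repr=False)
    eri: np.ndarray = field(repr=False)
    enuc: float = 0.0
    basis: str = BASIS_LABEL

    @property
    def n_ao(self) -> int:
        return self.overlap.shape[0]

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.spin_multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    @property
    def restricted(self) -> bool:
        return self.spin_multiplicity == 1

    def validate(self) -> None:
        S, eri = self.overlap, self.eri
        if not np.allclose(S, S.T, atol=1e-12):
            raise FixtureIntegrityError("overlap matrix is not symmetric")
        if np.min(np.linalg.eigvalsh(S)) <= 0:
            raise FixtureIntegrityError("overlap matrix is not positive definite")
        for perm, tag in (
            ((1, 0, 2, 3), "(ij|kl)=(ji|kl)"),
            ((0, 1, 3, 2), "(ij|kl)=(ij|lk)"),
            ((2, 3, 0, 1), "(ij|kl)=(kl|ij)"),
        ):
            if not np.allclose(eri, eri.transpose(perm), atol=1e-10):
                raise FixtureIntegrityError(f"two-electron tensor violates {tag} symmetry")
        if (self.n_electrons - (self.spin_multiplicity - 1)) % 2 != 0:
            raise FixtureIntegrityError("electron count inconsistent with spin multiplicity")
        if self.n_alpha > self.n_ao or self.n_beta < 0:
            raise FixtureIntegrityError("electron count exceeds basis size")


def _build(name, symbols, coords, charge, multiplicity) -> MoleculeFixture:
    S, hcore, eri, enuc = compute_integrals(symbols, coords)
    n_electrons = sum({"H": 1, "He": 2, "O": 8}[s] for s in symbols) - charge
    fix = MoleculeFixture(
        name=name,
        symbols=tuple(symbols),
        coordinates=np.asarray(coords, dtype=float),
        n_electrons=n_electrons,
        spin_multiplicity=multiplicity,
        overlap=S,
        hcore=hcore,
        eri=eri,
        enuc=enuc,
    )
    fix.validate()
    return fix


@functools.lru_cache(maxsize=None)
def _cached_registry_fixture(name: str) -> MoleculeFixture:
    symbols, coords, charge, mult = _REGISTRY[name]
    return _build(name, symbols, coords, charge, mult)


def list_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(
    name: str | None = None,
    *,
    xyz_path: str | None = None,
    charge: int = 0,
    spin_multiplicity: int = 1,
) -> MoleculeFixture:
    """Look up a bundled fixture by name, or build one from an XYZ file."""
    if (name is None) == (xyz_path is None):
        raise ValueError("give either a registry name or an xyz_path")
    if name is not None:
        if name not in _REGISTRY:
            raise KeyError(f"unknown fixture {name!r}; available: {list_fixtures()}")
        return _cached_registry_fixture(name)
    symbols, coords = read_xyz(xyz_path)
    return _build(xyz_path, symbols, coords, charge, spin_multiplicity)


def read_xyz(path: str) -> tuple[list[str], np.ndarray]:
    """Standard XYZ dialect: count line, comment line, `element x y z` in Angstrom."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError("first XYZ line must be the atom count") from exc
    rows = lines[2 : 2 + n]
    if len(rows) != n:
        raise ValueError(f"XYZ file promises {n} atoms but has {len(rows)}")
    symbols, coords = [], []
    for row in rows:
        parts = row.split()
        sym = parts[0].capitalize()
        if sym not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {sym!r}")
        symbols.append(sym)
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.asarray(coords)


# -- HDF5 container (datasets: S, h, eri; scalar enuc; metadata as attrs) ----

def save_fixture(fixture: MoleculeFixture, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("fixture")
        g.create_dataset("S", data=fixture.overlap)
        g.create_dataset("h", data=fixture.hcore)
        g.create_dataset("eri", data=fixture.eri)
        g.create_dataset("coordinates", data=fixture.coordinates)
        g.attrs["enuc"] = fixture.enuc
        g.attrs["name"] = fixture.name
        g.attrs["symbols"] = ",".join(fixture.symbols)
        g.attrs["n_electrons"] = fixture.n_electrons
        g.attrs["spin_multiplicity"] = fixture.spin_multiplicity
        g.attrs["basis"] = fixture.basis


def load_fixture(path: str) -> MoleculeFixture:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["fixture"]
        fix = MoleculeFixture(
            name=str(g.attrs["name"]),
            symbols=tuple(str(g.attrs["symbols"]).split(",")),
            coordinates=np.array(g["coordinates"]),
            n_electrons=int(g.attrs["n_electrons"]),
            spin_multiplicity=int(g.attrs["spin_multiplicity"]),
            overlap=np.array(g["S"]),
            hcore=np.array(g["h"]),
            eri=np.array(g["eri"]),
            enuc=float(g.attrs["enuc"]),
            basis=str(g.attrs["basis"]),
        )
    fix.validate()
    return fix
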