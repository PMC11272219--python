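"""Atomic models in a triclinic P1 cell.

The model is deliberately minimal: point scatterers with a constant
per-element electron count, an isotropic Debye-Waller factor
exp(-B s^2 / 4) and an occupancy.  Two-state systems are expressed with
conformer tags "A" (reference/resting) and "B" (activated), mirroring the
altloc convention of PDB files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "Atom",
    "AtomicModel",
    "read_pdb",
    "write_pdb",
]

# occ_A + occ_B may exceed 1 by at most this much before the model is rejected
_OCC_TOL = 1e-6


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not (0.0 < ang < 180.0):
                raise ValueError(f"cell angle {name} must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return float(self._gemmi.volume)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 fractional-to-Cartesian matrix (PDB convention: a along x, b in xy)."""
        return np.array(self._gemmi.orth.mat.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 Cartesian-to-fractional matrix (inverse of :attr:`orth_matrix`)."""
        return np.linalg.inv(self.orth_matrix)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional coordinates (..., 3) to Cartesian Angstrom."""
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.frac_matrix.T

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Angstrom) of Miller indices (..., 3).

        1/d^2 = h . G* . h with G* the reciprocal metric tensor.
        """
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        gstar = self.frac_matrix @ self.frac_matrix.T
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def min_image_cart(self, dfrac: np.ndarray) -> np.ndarray:
        """Cartesian displacement of fractional differences under the minimum-image
        convention (wraps each fractional component into [-0.5, 0.5))."""
        dfrac = np.asarray(dfrac, dtype=float)
        wrapped = dfrac - np.round(dfrac)
        return self.orthogonalize(wrapped)


@dataclass
class Atom:
    """Point scatterer.

    Parameters
    ----------
    name : role label, e.g. ``"CA"`` or ``"WAT1"``; names define atom
        correspondence between models.
    element : chemical symbol, used for the electron count on file round trips.
    z_electrons : electron count (constant scattering factor).
    frac : fractional coordinates in the unit cell.
    b_iso : isotropic B-factor in Angstrom^2.
    occ : occupancy in [0, 1].
    conformer : ``"A"`` (reference) or ``"B"`` (activated).
    """

    name: str
    element: str
    z_electrons: float
    frac: np.ndarray
    b_iso: float = 15.0
    occ: float = 1.0
    conformer: str = "A"

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float).reshape(3)
        if not (0.0 <= self.occ <= 1.0):
            raise ValueError(f"occupancy of {self.name} must be in [0, 1]")
        if self.b_iso < 0:
            raise ValueError(f"B-factor of {self.name} must be >= 0")
        if self.z_electrons <= 0:
            raise ValueError(f"electron count of {self.name} must be > 0")

    def copy(self) -> "Atom":
        return dataclasses.replace(self, frac=self.frac.copy())


Selection = Callable[[Atom], bool] | str | Sequence[str] | None


def _selector(selection: Selection) -> Callable[[Atom], bool]:
    if selection is None:
        return lambda atom: True
    if callable(selection):
        return selection
    if isinstance(selection, str):
        prefix = selection
        return lambda atom: atom.name.startswith(prefix)
    names = set(selection)
    return lambda atom: atom.name in names


@dataclass
class AtomicModel:
    """Ordered collection of atoms in a P1 cell.

    Atom order is stable and meaningful: it defines per-atom correspondence
    for displacement profiles and coordinate spreads.
    """

    cell: UnitCell
    atoms: list[Atom] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self._check_conformer_occupancies()

    def _check_conformer_occupancies(self) -> None:
        by_name: dict[str, dict[str, float]] = {}
        for atom in self.atoms:
            by_name.setdefault(atom.name, {})[atom.conformer] = atom.occ
        for name, occs in by_name.items():
            if "A" in occs and "B" in occs:
                if occs["A"] + occs["B"] > 1.0 + _OCC_TOL:
                    raise ValueError(
                        f"conformers of atom {name} have total occupancy "
                        f"{occs['A'] + occs['B']:.4f} > 1"
                    )

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self, label: str | None = None) -> "AtomicModel":
        return AtomicModel(
            cell=self.cell,
            atoms=[a.copy() for a in self.atoms],
            label=self.label if label is None else label,
        )

    def select(self, selection: Selection = None, conformer: str | None = None) -> "AtomicModel":
        pred = _selector(selection)
        atoms = [
            a.copy()
            for a in self.atoms
            if pred(a) and (conformer is None or a.conformer == conformer)
        ]
        return AtomicModel(cell=self.cell, atoms=atoms, label=self.label)

    def frac_coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.frac for a in self.atoms])

    def cart_coords(self) -> np.ndarray:
        return self.cell.orthogonalize(self.frac_coords())

    def occupancies(self) -> np.ndarray:
        return np.array([a.occ for a in self.atoms], dtype=float)

    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms], dtype=float)

    def z_electrons(self) -> np.ndarray:
        return np.array([a.z_electrons for a in self.atoms], dtype=float)

    def names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def with_occupancy(self, occ: float, conformer: str | None = None) -> "AtomicModel":
        out = self.copy()
        for atom in out.atoms:
            if conformer is None or atom.conformer == conformer:
                atom.occ = occ
        return out


def two_state_model(
    model_a: AtomicModel,
    model_b: AtomicModel,
    f: float,
    label: str = "two-state",
) -> AtomicModel:
    """Merge a reference and an activated model into one two-conformer model.

    Conformer A atoms carry occupancy ``1 - f``, conformer B atoms carry
    ``f``.  Both input models must list atoms in the same order with the
    same names.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("occupancy f must be in [0, 1]")
    if model_a.names() != model_b.names():
        raise ValueError("models must share atom names in the same order")
    atoms: list[Atom] = []
    for atom in model_a.atoms:
        a = atom.copy()
        a.occ = 1.0 - f
        a.conformer = "A"
        atoms.append(a)
    for atom in model_b.atoms:
        b = atom.copy()
        b.occ = f
        b.conformer = "B"
        atoms.append(b)
    return AtomicModel(cell=model_a.cell, atoms=atoms, label=label)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed; fixed-column PDB v3.3 layout)
# ---------------------------------------------------------------------------

def write_pdb(model: AtomicModel, path) -> None:
    """Write the model as a one-chain PDB file.

    Each distinct atom name becomes its own residue so that arbitrary toy
    models round-trip; conformer tags map onto the altloc column.
    """
    st = gemmi.Structure()
    st.cell = model.cell._gemmi
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain("A")
    seq: dict[str, int] = {}
    for atom in model.atoms:
        if atom.name not in seq:
            seq[atom.name] = len(seq) + 1
    residues: dict[str, gemmi.Residue] = {}
    for atom in model.atoms:
        if atom.name not in residues:
            res = gemmi.Residue()
            res.name = "HOH" if atom.name.upper().startswith(("WAT", "HOH")) else "TOY"
            res.seqid = gemmi.SeqId(seq[atom.name], " ")
            residues[atom.name] = res
        res = residues[atom.name]
        g = gemmi.Atom()
        g.name = atom.name[:4]
        g.element = gemmi.Element(atom.element)
        g.altloc = atom.conformer if atom.conformer else "\0"
        g.occ = atom.occ
        g.b_iso = atom.b_iso
        cart = model.cell.orthogonalize(atom.frac)
        g.pos = gemmi.Position(*cart)
        res.add_atom(g)
    for name in seq:
        chain.add_residue(residues[name])
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path) -> AtomicModel:
    """Read ATOM/HETATM records into an :class:`AtomicModel`.

    The altloc column maps to the conformer tag (blank -> "A"); the electron
    count is the element's atomic number.
    """
    st = gemmi.read_structure(str(path))
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    ucell = cell
    atoms: list[Atom] = []
    for gmodel in st:
        for chain in gmodel:
            for res in chain:
                for g in res:
                    frac = ucell.fractionalize(np.array([g.pos.x, g.pos.y, g.pos.z]))
                    conformer = g.altloc if g.altloc and g.altloc != "\0" else "A"
                    atoms.append(
                        Atom(
                            name=g.name,
                            element=g.element.name,
                            z_electrons=float(g.element.atomic_number),
                            frac=frac % 1.0,
                            b_iso=g.b_iso,
                            occ=g.occ,
                            conformer=conformer,
                        )
                    )
        break  # single-model files only
    return AtomicModel(cell=cell, atoms=atoms, label=str(path))
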