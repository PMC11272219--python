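"""Built-in synthetic two-state crystal systems.

These toy systems define the study conditions for every test and example in
the package: a small P1 cell holding a "protein" of point scatterers plus a
few waters, a resting (dark) conformation, and an activated (light)
conformation in which a subset of atoms moves by a few tenths of an
Angstrom and a transient water appears.  Serial-diffraction frames are then
drawn from the coherent two-state ground truth by :mod:`bootsfx.framesim`.

Default conditions: 18 x 20 x 22 Angstrom P1 cell, 2.5 Angstrom data,
activated-state occupancy f = 0.27, mean displacement ~0.4 Angstrom over
half of the protein atoms, thirteen logarithmically spaced time delays from
16 ns to 1.725 ms plus a resting dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal import Atom, AtomicModel, UnitCell

__all__ = [
    "default_cell",
    "make_two_state_models",
    "make_time_series",
    "DEFAULT_D_MIN",
    "DEFAULT_F_TRUE",
]

DEFAULT_D_MIN = 2.5
DEFAULT_F_TRUE = 0.27
DEFAULT_DISPLACEMENT = 0.4  # Angstrom, mean shift of the moving atoms

_ELEMENTS = [("C", 6.0), ("N", 7.0), ("O", 8.0), ("S", 16.0)]


def default_cell() -> UnitCell:
    return UnitCell(18.0, 20.0, 22.0, 90.0, 90.0, 90.0)


def _place_atoms(rng: np.random.Generator, cell: UnitCell, n: int,
                 min_dist: float = 2.0) -> np.ndarray:
    """Rejection-sample fractional positions with a minimum pair distance."""
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place atoms with the requested spacing")
        cand = rng.random(3)
        ok = True
        for p in placed:
            d = cand - p
            if np.linalg.norm(cell.min_image_cart(d)) < min_dist:
                ok = False
                break
        if ok:
            placed.append(cand)
    return np.stack(placed)


def make_two_state_models(
    seed: int = 7,
    n_protein: int = 16,
    n_moving: int = 4,
    n_waters: int = 2,
    displacement: float = DEFAULT_DISPLACEMENT,
    cell: UnitCell | None = None,
    transient_water: bool = True,
) -> tuple[AtomicModel, AtomicModel]:
    """Build matched dark and light models.

    The first ``n_moving`` protein atoms move in the light state by random
    directions with magnitudes ~ displacement (lognormal, 20% spread).  Half
    of the protein atoms are named ``CA*`` so Cα-style selections work.  If
    ``transient_water`` is set, a water named WAT_T is present only in the
    light model (occupancy 0 in the dark model), giving the difference map a
    known gained-density feature.
    """
    cell = cell or default_cell()
    rng = np.random.default_rng(seed)
    n_total = n_protein + n_waters + (1 if transient_water else 0)
    frac = _place_atoms(rng, cell, n_total)
    atoms_dark: list[Atom] = []
    for i in range(n_protein):
        el, z = _ELEMENTS[int(rng.integers(0, len(_ELEMENTS) - 1))]
        name = f"CA{i + 1}" if i < n_protein // 2 else f"{el}{i + 1}"
        atoms_dark.append(
            Atom(
                name=name,
                element=el,
                z_electrons=z,
                frac=frac[i],
                b_iso=float(rng.uniform(10.0, 25.0)),
                occ=1.0,
                conformer="A",
            )
        )
    for j in range(n_waters):
        atoms_dark.append(
            Atom(
                name=f"WAT{j + 1}",
                element="O",
                z_electrons=8.0,
                frac=frac[n_protein + j],
                b_iso=float(rng.uniform(15.0, 30.0)),
                occ=1.0,
                conformer="A",
            )
        )
    if transient_water:
        atoms_dark.append(
            Atom(
                name="WAT_T",
                element="O",
                z_electrons=8.0,
                frac=frac[-1],
                b_iso=20.0,
                occ=0.0,  # absent in the resting state
                conformer="A",
            )
        )
    dark = AtomicModel(cell=cell, atoms=atoms_dark, label="dark (resting)")

    light = dark.copy(label="light (activated)")
    directions = rng.normal(size=(n_moving, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    magnitudes = displacement * rng.lognormal(0.0, 0.2, size=n_moving)
    shifts = directions * magnitudes[:, None]
    if n_moving > 0:
        # localized internal rearrangement: zero net translation, so the
        # change carries no component along the (near-)null rigid-shift mode
        # of amplitude-only refinement
        shifts = shifts - shifts.mean(axis=0)
        shifts *= displacement * len(shifts) / np.linalg.norm(shifts, axis=1).sum()
    inv_orth = cell.frac_matrix
    for i in range(n_moving):
        light.atoms[i].frac = (light.atoms[i].frac + inv_orth @ shifts[i]) % 1.0
        light.atoms[i].b_iso = float(
            np.clip(light.atoms[i].b_iso + rng.normal(0.0, 2.0), 5.0, 60.0)
        )
    if transient_water:
        light.atoms[-1].occ = 1.0  # the transient water orders in the light state
    return dark, light


@dataclass
class DelaySpec:
    """One time delay of a synthetic series."""

    label: str
    time_seconds: float
    model_light: AtomicModel
    f: float


def make_time_series(
    seed: int = 7,
    n_delays: int = 13,
    f: float = DEFAULT_F_TRUE,
    transient_window: tuple[int, int] = (3, 9),
    **model_kwargs,
) -> tuple[AtomicModel, list[DelaySpec]]:
    """A resting model plus logarithmically spaced delays (16 ns to 1.725 ms).

    The activated-state occupancy is constant across delays; the transient
    water WAT_T is ordered only for delay indices inside
    ``transient_window`` (half-open), so quantified difference density about
    it rises and falls along the series.
    """
    dark, light = make_two_state_models(seed=seed, transient_water=True, **model_kwargs)
    times = np.geomspace(16e-9, 1.725e-3, n_delays)
    delays: list[DelaySpec] = []
    lo, hi = transient_window
    for i, t in enumerate(times):
        model_t = light.copy(label=f"light @ {t:.3g}s")
        if not (lo <= i < hi):
            for atom in model_t.atoms:
                if atom.name == "WAT_T":
                    atom.occ = 0.0
        label = f"delay_{i:02d}"
        delays.append(DelaySpec(label=label, time_seconds=float(t), model_light=model_t, f=f))
    return dark, delays
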