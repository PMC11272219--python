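"""Direct-summation structure factors and two-state mixing.

F(hkl) = sum_j occ_j z_j exp(-B_j s^2 / 4) exp(+2 pi i h.x_j), s = 1/d.

Scattering factors are constant electron counts (no Cromer-Mann tables);
the isotropic Debye-Waller term carries all resolution dependence.  This
keeps amplitudes reproducible in closed form while preserving everything
the downstream appraisal operations rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal import AtomicModel, Selection, _selector
from .reflections import ReflectionSet, generate_hkl

__all__ = ["structure_factors", "mix_states", "rmsd_profile", "DisplacementProfile"]


def structure_factors(model: AtomicModel, d_min: float, role: str = "calculated") -> ReflectionSet:
    """Direct-summation structure factors on the Friedel half-sphere to d_min."""
    if len(model) == 0:
        raise ValueError("cannot compute structure factors of an empty model")
    hkl = generate_hkl(model.cell, d_min)
    values = structure_factors_at(model, hkl)
    return ReflectionSet.from_complex(
        hkl, values, cell=model.cell, d_min=d_min, role=role
    )


def structure_factors_at(model: AtomicModel, hkl: np.ndarray) -> np.ndarray:
    """Complex F at the given Miller indices (vectorized direct summation)."""
    hkl = np.asarray(hkl, dtype=float).reshape(-1, 3)
    frac = model.frac_coords()                    # (M, 3)
    occ = model.occupancies()
    z = model.z_electrons()
    b = model.b_factors()
    s2 = 1.0 / model.cell.d_spacings(hkl) ** 2    # (N,)
    dw = np.exp(-np.outer(s2, b) / 4.0)           # (N, M)
    phases = np.exp(2j * np.pi * (hkl @ frac.T))  # (N, M)
    return (dw * phases) @ (occ * z)


def mix_states(F_dark: ReflectionSet, F_light: ReflectionSet, f: float) -> ReflectionSet:
    """Coherent complex mixture F = (1-f) F_dark + f F_light.

    This realizes the ground truth that amplitude extrapolation approximates:
    a crystal in which a fraction f of the molecules occupy the activated
    conformation.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("occupancy f must be in [0, 1]")
    F_dark.require_same_hkl(F_light)
    mixed = (1.0 - f) * F_dark.complex_values + f * F_light.complex_values
    return ReflectionSet.from_complex(
        F_dark.hkl, mixed, cell=F_dark.cell, d_min=F_dark.d_min, role="calculated"
    )


@dataclass
class DisplacementProfile:
    """Per-atom Cartesian displacements between two matched models."""

    names: list[str]
    displacements: np.ndarray  # Angstrom, one per selected atom

    @property
    def mean(self) -> float:
        return float(np.mean(self.displacements))


def rmsd_profile(
    model_ref: AtomicModel,
    model_act: AtomicModel,
    selection: Selection = None,
) -> DisplacementProfile:
    """Per-atom displacement (Angstrom) between matched atoms of two models.

    Atoms are matched by their stable order after applying the selection;
    names must agree pairwise.  Displacements use the minimum-image
    convention in the (shared) cell.
    """
    pred = _selector(selection)
    ref = [a for a in model_ref.atoms if pred(a)]
    act = [a for a in model_act.atoms if pred(a)]
    if not ref or not act:
        raise ValueError("selection matches no atoms")
    if len(ref) != len(act) or any(r.name != a.name for r, a in zip(ref, act)):
        raise ValueError("models do not share a matched atom correspondence")
    dfrac = np.stack([a.frac - r.frac for r, a in zip(ref, act)])
    cart = model_ref.cell.min_image_cart(dfrac)
    disp = np.linalg.norm(cart, axis=1)
    return DisplacementProfile(names=[a.name for a in ref], displacements=disp)
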