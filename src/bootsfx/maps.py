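"""Real-space density maps and Fourier syntheses.

Maps are real scalar grids on the unit cell, synthesized by inverse
discrete Fourier transform of half-sphere coefficients with Friedel
completion.  F(000) is always excluded, so every synthesized map has zero
mean by construction.  Grid samples sit at fractional positions i/n; each
sample is the center of its voxel.

Density convention: rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x), matching
the structure-factor convention F = sum_j exp(+2 pi i h.x_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import AtomicModel, Selection, UnitCell, _selector
from .reflections import ReflectionSet
from .sfcalc import structure_factors_at

__all__ = [
    "DensityMap",
    "grid_shape_for",
    "synthesize_map",
    "difference_map",
    "sigma_scale",
    "map_pearson",
    "omit_map",
]


@dataclass
class DensityMap:
    """Scalar density on an (nx, ny, nz) grid over the unit cell."""

    values: np.ndarray
    cell: UnitCell
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-d array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def sigma(self) -> float:
        """Root-mean-square density of the map."""
        return float(np.sqrt(np.mean(self.values**2)))

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size

    def copy(self, label: str | None = None) -> "DensityMap":
        return DensityMap(
            values=self.values.copy(),
            cell=self.cell,
            label=self.label if label is None else label,
            meta=dict(self.meta),
        )

    def sample_frac_coords(self) -> np.ndarray:
        """Fractional coordinates of all grid samples, shape (N, 3)."""
        nx, ny, nz = self.shape
        fx, fy, fz = np.meshgrid(
            np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz, indexing="ij"
        )
        return np.stack([fx.ravel(), fy.ravel(), fz.ravel()], axis=1)


def grid_shape_for(cell: UnitCell, d_min: float, factor: float = 3.0) -> tuple[int, int, int]:
    """Even grid dimensions giving spacing <= d_min / factor along each axis."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = int(np.ceil(length * factor / d_min))
        if n % 2:
            n += 1
        dims.append(max(n, 4))
    return tuple(dims)


def _resolve_grid(
    refls: ReflectionSet, grid: tuple[int, int, int] | None
) -> tuple[int, int, int]:
    if grid is not None:
        return tuple(int(n) for n in grid)
    if refls.cell is None:
        raise ValueError("cannot infer a grid without a cell")
    d_min = refls.d_min
    if d_min is None:
        d_min = float(np.min(refls.d_spacings())) if len(refls) else 1.0
    return grid_shape_for(refls.cell, d_min)


def _synthesize(
    hkl: np.ndarray,
    coeffs: np.ndarray,
    cell: UnitCell,
    grid: tuple[int, int, int],
    label: str,
) -> DensityMap:
    nx, ny, nz = grid
    lim = np.max(np.abs(hkl), axis=0) if len(hkl) else np.zeros(3)
    if len(hkl) and (lim[0] >= nx / 2 or lim[1] >= ny / 2 or lim[2] >= nz / 2):
        raise ValueError("grid too coarse for the highest Miller index (aliasing)")
    A = np.zeros((nx, ny, nz), dtype=complex)
    if len(hkl):
        h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
        A[h % nx, k % ny, l % nz] = coeffs
        A[(-h) % nx, (-k) % ny, (-l) % nz] = np.conj(coeffs)
    rho = np.fft.fftn(A).real / cell.volume
    return DensityMap(values=rho, cell=cell, label=label)


def grid_structure_factors(
    values: np.ndarray, cell: UnitCell, hkl: np.ndarray
) -> np.ndarray:
    """Forward transform of a real grid sampled at the given Miller indices.

    F(h) = V * IFFT(rho)[h]; used for the flat-solvent contribution.
    """
    coeffs = np.fft.ifftn(values) * cell.volume
    nx, ny, nz = values.shape
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    return coeffs[h % nx, k % ny, l % nz]


def synthesize_map(
    refls: ReflectionSet,
    grid: tuple[int, int, int] | None = None,
    label: str = "",
) -> DensityMap:
    """Fourier synthesis of amplitudes+phases into a real density map."""
    if len(refls) and not refls.has_phases:
        raise ValueError("map synthesis requires phases")
    gshape = _resolve_grid(refls, grid)
    if refls.cell is None:
        raise ValueError("map synthesis requires a cell")
    coeffs = refls.complex_values if len(refls) else np.zeros(0, dtype=complex)
    return _synthesize(refls.hkl, coeffs, refls.cell, gshape, label)


def difference_map(
    F_act: ReflectionSet,
    F_ref: ReflectionSet,
    phases_ref: ReflectionSet | None = None,
    grid: tuple[int, int, int] | None = None,
    weighting: str = "none",
) -> DensityMap:
    """Isomorphous difference Fourier map.

    Synthesizes FT[(F_act - F_ref) exp(i Phi_ref)] on the hkl common to the
    activated amplitudes, the reference amplitudes and the reference phases.
    Reflections missing in any input are dropped and counted in ``meta``.
    """
    if weighting != "none":
        raise ValueError("only unweighted difference coefficients are supported")
    phase_source = phases_ref if phases_ref is not None else F_ref
    if not phase_source.has_phases:
        raise ValueError("reference phases are required for a difference map")
    ia, ir = F_act.common_indices(F_ref)
    hkl_common = F_act.hkl[ia]
    # restrict further to hkl with phases
    tmp = ReflectionSet(hkl=hkl_common, amplitude=np.zeros(len(hkl_common)))
    it, ip = tmp.common_indices(phase_source)
    hkl = hkl_common[it]
    damp = F_act.amplitude[ia][it] - F_ref.amplitude[ir][it]
    coeffs = damp * np.exp(1j * phase_source.phase[ip])
    cell = F_act.cell or F_ref.cell or phase_source.cell
    if cell is None:
        raise ValueError("difference map requires a cell")
    ref_for_grid = ReflectionSet(
        hkl=hkl, amplitude=np.abs(damp), cell=cell, d_min=F_act.d_min or F_ref.d_min
    )
    gshape = _resolve_grid(ref_for_grid, grid)
    out = _synthesize(hkl, coeffs, cell, gshape, label="difference map")
    n_total = max(len(F_act), len(F_ref))
    out.meta["n_used"] = len(hkl)
    out.meta["n_dropped"] = n_total - len(hkl)
    return out


def sigma_scale(dmap: DensityMap) -> DensityMap:
    """Express the map in units of its rms density (sigma)."""
    s = dmap.sigma
    if s == 0:
        raise ValueError("cannot sigma-scale an identically zero map")
    out = dmap.copy()
    out.values = out.values / s
    out.meta["sigma_scaled"] = True
    return out


def map_pearson(map_a: DensityMap, map_b: DensityMap) -> float:
    """Pearson correlation of two maps over voxels (same grid required)."""
    if map_a.shape != map_b.shape:
        raise ValueError(f"grid mismatch: {map_a.shape} vs {map_b.shape}")
    a = map_a.values.ravel()
    b = map_b.values.ravel()
    return float(np.corrcoef(a, b)[0, 1])


def _min_image_distances(
    cell: UnitCell, frac_points: np.ndarray, center_frac: np.ndarray
) -> np.ndarray:
    d = frac_points - np.asarray(center_frac, dtype=float).reshape(1, 3)
    cart = cell.min_image_cart(d)
    return np.linalg.norm(cart, axis=1)


def solvent_mask(
    model: AtomicModel,
    grid: tuple[int, int, int],
    r_probe: float,
    exclusion_centers: np.ndarray | None = None,
    exclusion_radius: float = 0.0,
) -> np.ndarray:
    """Boolean grid: True where flat solvent lives (beyond r_probe of every
    atom and outside any exclusion sphere)."""
    nx, ny, nz = grid
    probe = DensityMap(values=np.zeros(grid), cell=model.cell)
    pts = probe.sample_frac_coords()
    mask = np.ones(len(pts), dtype=bool)
    for atom in model.atoms:
        mask &= _min_image_distances(model.cell, pts, atom.frac) > r_probe
    if exclusion_centers is not None and exclusion_radius > 0:
        for center in np.atleast_2d(exclusion_centers):
            mask &= _min_image_distances(model.cell, pts, center) > exclusion_radius
    return mask.reshape(grid)


def omit_map(
    F_obs: ReflectionSet,
    model: AtomicModel,
    omit: Selection,
    polder_exclusion_radius: float | None = None,
    solvent: dict | None = None,
    grid: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Fobs - Fcalc omit map, optionally Polder-style.

    The omitted atoms are removed from the model before computing F_calc.
    With a flat-solvent term (``solvent={"k_sol": ..., "r_probe": ...}``),
    a constant density fills voxels beyond r_probe of every remaining atom;
    a Polder exclusion radius keeps that solvent out of spheres around the
    omitted atoms so weak density there is not flattened away.  Without a
    solvent term the exclusion radius is a documented no-op.

    F_calc is scaled to F_obs by the closed-form least-squares factor
    k = sum(F_obs |Fc|) / sum(|Fc|^2) before the difference synthesis.
    """
    pred = _selector(omit)
    omitted = [a for a in model.atoms if pred(a)]
    if not omitted:
        raise ValueError("omit selection matches no atoms")
    partial = AtomicModel(
        cell=model.cell,
        atoms=[a.copy() for a in model.atoms if not pred(a)],
        label=model.label + " (omit)",
    )
    if len(partial) == 0:
        raise ValueError("omit selection removes every atom")
    cell = model.cell
    ref_for_grid = ReflectionSet(
        hkl=F_obs.hkl, amplitude=F_obs.amplitude, cell=cell, d_min=F_obs.d_min
    )
    gshape = _resolve_grid(ref_for_grid, grid)
    fcalc = structure_factors_at(partial, F_obs.hkl)
    if solvent is not None and solvent.get("k_sol", 0.0) > 0:
        centers = np.stack([a.frac for a in omitted])
        mask = solvent_mask(
            partial,
            gshape,
            r_probe=solvent.get("r_probe", 1.5),
            exclusion_centers=centers if polder_exclusion_radius else None,
            exclusion_radius=polder_exclusion_radius or 0.0,
        )
        rho_sol = solvent["k_sol"] * mask.astype(float)
        f_sol = grid_structure_factors(rho_sol, cell, F_obs.hkl)
        fcalc = fcalc + f_sol
    amp_calc = np.abs(fcalc)
    denom = float(np.sum(amp_calc**2))
    if denom == 0:
        raise ValueError("calculated amplitudes are all zero")
    k = float(np.sum(F_obs.amplitude * amp_calc)) / denom
    coeffs = (F_obs.amplitude - k * amp_calc) * np.exp(1j * np.angle(fcalc))
    out = _synthesize(F_obs.hkl, coeffs, cell, gshape, label="omit map")
    out.meta["scale_k"] = k
    out.meta["n_omitted"] = len(omitted)
    return out
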