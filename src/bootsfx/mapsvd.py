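"""SVD analysis of resampled difference-map ensembles and density quantification.

A stack of m maps on a shared grid forms the n x m matrix A (voxels by
maps), decomposed as A = U S V^T.  The first left singular vector, scaled
by S1/sqrt(m), serves as a denoised consensus map; its sign is fixed so it
correlates positively with the voxel-wise mean of the stack.

Density around named atoms is quantified by summing map values within a
sphere (voxel-center inclusion), after zeroing values whose magnitude falls
below a pedestal expressed in multiples of that map's own rms sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal import AtomicModel
from .maps import DensityMap, _min_image_distances, sigma_scale

__all__ = [
    "MapStack",
    "SVDResult",
    "stack_maps",
    "svd_decompose",
    "principal_map",
    "integrate_sphere",
    "quantify_series",
]

DEFAULT_RADIUS = 0.8           # Angstrom, integration sphere
DEFAULT_PEDESTAL_DIFF = 2.0    # sigma multiples, difference maps
DEFAULT_PEDESTAL_OMIT = 0.1    # sigma multiples, omit maps


@dataclass
class MapStack:
    """n_voxels x m matrix of maps sharing one grid and cell."""

    matrix: np.ndarray = field(repr=False)
    grid: tuple[int, int, int]
    cell: object
    provenance: list = field(default_factory=list)

    @property
    def n_maps(self) -> int:
        return self.matrix.shape[1]

    def column_map(self, j: int) -> DensityMap:
        return DensityMap(
            values=self.matrix[:, j].reshape(self.grid), cell=self.cell
        )

    def mean_map(self) -> DensityMap:
        return DensityMap(
            values=self.matrix.mean(axis=1).reshape(self.grid), cell=self.cell
        )


@dataclass
class SVDResult:
    U: np.ndarray = field(repr=False)
    S: np.ndarray
    Vt: np.ndarray = field(repr=False)

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.S) @ self.Vt


def stack_maps(maps: list[DensityMap]) -> MapStack:
    """Column-stack maps (input order preserved) into a voxels-by-maps matrix."""
    if len(maps) < 2:
        raise ValueError("need at least two maps to stack")
    grid = maps[0].shape
    for m in maps[1:]:
        if m.shape != grid:
            raise ValueError(f"grid mismatch: {m.shape} vs {grid}")
    matrix = np.stack([m.values.ravel() for m in maps], axis=1)
    return MapStack(
        matrix=matrix,
        grid=grid,
        cell=maps[0].cell,
        provenance=[m.label for m in maps],
    )


def svd_decompose(stack: MapStack) -> SVDResult:
    """Thin SVD of the stack; singular values descending, U/V orthonormal."""
    if not np.any(stack.matrix):
        raise ValueError("cannot decompose an all-zero stack")
    U, S, Vt = np.linalg.svd(stack.matrix, full_matrices=False)
    return SVDResult(U=U, S=S, Vt=Vt)


def principal_map(svd: SVDResult, stack: MapStack) -> DensityMap:
    """First left singular vector as a map, scaled by S1/sqrt(m).

    The sign is fixed so the component correlates positively with the
    voxel-wise mean of the stack (SVD leaves the sign arbitrary).
    """
    u1 = svd.U[:, 0] * (svd.S[0] / np.sqrt(stack.n_maps))
    mean = stack.matrix.mean(axis=1)
    denom = np.linalg.norm(u1) * np.linalg.norm(mean)
    r = float(u1 @ mean / denom) if denom > 0 else 0.0
    if abs(r) < 1e-6:
        raise ValueError(
            "principal component is uncorrelated with the stack mean; "
            "sign convention is ambiguous, fix the sign manually"
        )
    if r < 0:
        u1 = -u1
    return DensityMap(
        values=u1.reshape(stack.grid), cell=stack.cell, label="principal SVD component"
    )


def integrate_sphere(
    dmap: DensityMap,
    center_frac: np.ndarray,
    radius: float = DEFAULT_RADIUS,
    pedestal: float = 0.0,
) -> float:
    """Signed density integral within a sphere about a fractional center.

    Voxels whose center lies within ``radius`` of the center contribute
    value * voxel_volume, after zeroing voxels with |value| below
    ``pedestal`` times the map's rms sigma.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    values = dmap.values.ravel()
    if pedestal > 0:
        s = dmap.sigma
        if s == 0:
            raise ValueError("pedestal masking needs a map with nonzero sigma")
        values = np.where(np.abs(values) < pedestal * s, 0.0, values)
    pts = dmap.sample_frac_coords()
    dist = _min_image_distances(dmap.cell, pts, np.asarray(center_frac))
    inside = dist <= radius
    if not np.any(inside):
        raise ValueError(
            "no voxel center falls inside the sphere; use a finer grid"
        )
    return float(values[inside].sum() * dmap.voxel_volume)


def quantify_series(
    maps_by_delay: dict,
    atoms: dict[str, np.ndarray] | AtomicModel,
    radius: float = DEFAULT_RADIUS,
    pedestal: float = DEFAULT_PEDESTAL_DIFF,
    scale_replicates: bool = True,
) -> pd.DataFrame:
    """Integrated density around named centers, per time delay, with error bars.

    Parameters
    ----------
    maps_by_delay : mapping of delay label -> list of replicate DensityMaps.
    atoms : mapping name -> fractional center, or a model whose atom names
        resolve the centers.
    radius, pedestal : integration sphere radius (Angstrom) and pedestal in
        sigma multiples.
    scale_replicates : sigma-scale each replicate map before integrating
        (values then carry sigma-scaled density units).

    Returns a tidy table (delay, atom, mean, std, n_replicates) where the
    statistics run over replicate maps; std is the population standard
    deviation, the resampling error bar.
    """
    if isinstance(atoms, AtomicModel):
        centers = {}
        for atom in atoms.atoms:
            centers.setdefault(atom.name, atom.frac)
    else:
        centers = dict(atoms)
    if not centers:
        raise ValueError("no centers to quantify")
    rows = []
    for delay, replicates in maps_by_delay.items():
        if len(replicates) == 0:
            raise ValueError(f"delay {delay!r} has no replicate maps")
        for name, frac in centers.items():
            vals = []
            for rep in replicates:
                m = sigma_scale(rep) if scale_replicates else rep
                vals.append(integrate_sphere(m, frac, radius=radius, pedestal=pedestal))
            vals = np.asarray(vals)
            rows.append(
                {
                    "delay": delay,
                    "atom": name,
                    "mean": float(vals.mean()),
                    "std": float(vals.std()),
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(rows)


def resolve_center(model: AtomicModel, name: str) -> np.ndarray:
    """Fractional position of the first atom with the given name."""
    for atom in model.atoms:
        if atom.name == name:
            return atom.frac
    raise ValueError(f"atom name {name!r} not found in model {model.label!r}")
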