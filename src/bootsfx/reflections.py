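"""Indexed structure-factor records (ReflectionSet).

Amplitudes are non-negative; phases are stored internally in radians and
exposed in degrees at I/O boundaries.  A set covers a Friedel half-sphere
(h > 0, or h = 0 and k > 0, or h = k = 0 and l > 0); Friedel mates are
implied by the real-density assumption.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crystal import UnitCell

__all__ = ["ReflectionSet", "generate_hkl"]

ROLES = ("reference", "activated", "extrapolated", "calculated")


def generate_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Miller indices of the canonical Friedel half-sphere with d >= d_min."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    # search box: |h_i| <= len_i / d_min is a valid bound up to cell skew;
    # pad by one index and filter on the true d-spacing afterwards.
    hmax = int(np.ceil(cell.a / d_min)) + 1
    kmax = int(np.ceil(cell.b / d_min)) + 1
    lmax = int(np.ceil(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    half = (
        (hkl[:, 0] > 0)
        | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
        | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    )
    hkl = hkl[half]
    d = cell.d_spacings(hkl)
    hkl = hkl[d >= d_min]
    if len(hkl) == 0:
        raise ValueError(
            f"d_min = {d_min} Angstrom admits zero reflections in this cell"
        )
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap radians into [-pi, pi)."""
    return (phi + np.pi) % (2.0 * np.pi) - np.pi


class ReflectionSet:
    """Indexed amplitudes with optional phases and sigmas.

    Parameters
    ----------
    hkl : (N, 3) integer Miller indices, unique, no (0,0,0).
    amplitude : (N,) non-negative structure-factor amplitudes.
    phase : (N,) phases in radians, or None when unknown (merged amplitudes).
    sigma : (N,) non-negative uncertainties, or None.
    cell : unit cell the indices refer to.
    d_min : resolution cutoff in Angstrom (records must satisfy d >= d_min).
    role : one of "reference", "activated", "extrapolated", "calculated".
    """

    def __init__(
        self,
        hkl: np.ndarray,
        amplitude: np.ndarray,
        phase: np.ndarray | None = None,
        sigma: np.ndarray | None = None,
        cell: UnitCell | None = None,
        d_min: float | None = None,
        role: str = "calculated",
        meta: dict | None = None,
    ) -> None:
        hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
        amplitude = np.asarray(amplitude, dtype=float).reshape(-1)
        if len(hkl) != len(amplitude):
            raise ValueError("hkl and amplitude lengths differ")
        if np.any(np.all(hkl == 0, axis=1)):
            raise ValueError("(0,0,0) is not a valid reflection")
        uniq = np.unique(hkl, axis=0)
        if len(uniq) != len(hkl):
            raise ValueError("duplicate hkl records")
        if np.any(amplitude < 0):
            raise ValueError("amplitudes must be >= 0")
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if phase is not None:
            phase = _wrap_phase(np.asarray(phase, dtype=float).reshape(-1))
            if len(phase) != len(hkl):
                raise ValueError("phase length mismatch")
        if sigma is not None:
            sigma = np.asarray(sigma, dtype=float).reshape(-1)
            if len(sigma) != len(hkl):
                raise ValueError("sigma length mismatch")
            if np.any(sigma < 0):
                raise ValueError("sigmas must be >= 0")
        if cell is not None and d_min is not None:
            d = cell.d_spacings(hkl)
            if np.any(d < d_min - 1e-9):
                raise ValueError("records below the d_min cutoff")
        self.hkl = hkl
        self.amplitude = amplitude
        self.phase = phase
        self.sigma = sigma
        self.cell = cell
        self.d_min = d_min
        self.role = role
        self.meta = dict(meta or {})

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_complex(
        cls,
        hkl: np.ndarray,
        values: np.ndarray,
        cell: UnitCell | None = None,
        d_min: float | None = None,
        role: str = "calculated",
        sigma: np.ndarray | None = None,
    ) -> "ReflectionSet":
        values = np.asarray(values, dtype=complex).reshape(-1)
        return cls(
            hkl=hkl,
            amplitude=np.abs(values),
            phase=np.angle(values),
            sigma=sigma,
            cell=cell,
            d_min=d_min,
            role=role,
        )

    # -- basic views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def has_phases(self) -> bool:
        return self.phase is not None

    @property
    def complex_values(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError("reflection set has no phases")
        return self.amplitude * np.exp(1j * self.phase)

    @property
    def phase_degrees(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError("reflection set has no phases")
        return np.degrees(self.phase)

    def d_spacings(self) -> np.ndarray:
        if self.cell is None:
            raise ValueError("reflection set has no cell")
        return self.cell.d_spacings(self.hkl)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "h": self.hkl[:, 0],
            "k": self.hkl[:, 1],
            "l": self.hkl[:, 2],
            "F": self.amplitude,
        }
        if self.phase is not None:
            data["phase"] = np.degrees(self.phase)
        if self.sigma is not None:
            data["sigF"] = self.sigma
        return pd.DataFrame(data)

    # -- index algebra -----------------------------------------------------

    def _index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(row): i for i, row in enumerate(self.hkl)}

    def common_indices(self, other: "ReflectionSet") -> tuple[np.ndarray, np.ndarray]:
        """Positions of the shared hkl in self and other (hkl-sorted)."""
        omap = other._index_map()
        pairs = [
            (i, omap[tuple(row)]) for i, row in enumerate(self.hkl) if tuple(row) in omap
        ]
        if not pairs:
            raise ValueError("reflection sets share no hkl")
        idx_self = np.array([p[0] for p in pairs], dtype=int)
        idx_other = np.array([p[1] for p in pairs], dtype=int)
        return idx_self, idx_other

    def require_same_hkl(self, other: "ReflectionSet") -> None:
        if len(self) != len(other) or not np.array_equal(self.hkl, other.hkl):
            smap = set(map(tuple, self.hkl))
            omap = set(map(tuple, other.hkl))
            only = sorted(smap.symmetric_difference(omap))
            first = only[0] if only else tuple(self.hkl[0])
            raise ValueError(f"hkl sets differ; first mismatch: {first}")

    def take(self, idx: np.ndarray, role: str | None = None) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl[idx],
            amplitude=self.amplitude[idx],
            phase=None if self.phase is None else self.phase[idx],
            sigma=None if self.sigma is None else self.sigma[idx],
            cell=self.cell,
            d_min=self.d_min,
            role=role or self.role,
            meta=dict(self.meta),
        )

    def intensities(self) -> np.ndarray:
        """|F|^2 (used as ground-truth intensities by the frame simulator)."""
        return self.amplitude**2
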