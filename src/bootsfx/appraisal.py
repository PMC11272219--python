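"""Two-state reciprocal-space refinement, occupancy scans and coordinate errors.

The refinement engine is a bounded quasi-Newton least-squares fit of the
coordinates and isotropic B-factors of the free atoms against observed
amplitudes,

    T = sum_hkl (F_obs - k |F_calc|)^2,

with the scale k refit in closed form at every evaluation
(k = sum F_obs |F_calc| / sum |F_calc|^2).  In partial-occupancy mode
F_calc is the coherent sum of a frozen reference conformer (occupancy 1-f)
and the free activated conformer (occupancy f); in extrapolated mode a
single free conformer at full occupancy is refined against extrapolated
amplitudes.  No geometric restraints are applied (toy models are sparse).

A deterministic hash of (h, k, l, seed) assigns the R-free set, so the
split is independent of reflection ordering.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .crystal import AtomicModel, Selection, _selector, two_state_model
from .extrapolation import extrapolate
from .reflections import ReflectionSet
from .sfcalc import DisplacementProfile, rmsd_profile, structure_factors_at

__all__ = [
    "RefinementOptions",
    "RefinedModel",
    "ScanResult",
    "CoordinateSpread",
    "refine",
    "occupancy_scan",
    "coordinate_spread",
    "sigma_free",
    "b_to_u",
    "compare_approaches",
]

MODES = ("partial_occupancy", "extrapolated")
_EIGHT_PI2 = 8.0 * np.pi**2


@dataclass
class RefinementOptions:
    """Knobs of the reciprocal-space refinement."""

    mode: str = "partial_occupancy"
    f: float = 1.0
    max_cycles: int = 5
    tol: float = 1e-10          # convergence on relative target decrease
    parameters: tuple[str, ...] = ("coordinates", "b_factors")
    frozen_conformer: str = "A"
    free_fraction: float = 0.05  # R-free set size
    free_seed: int = 0
    maxiter_per_cycle: int = 60
    # Amplitude-only refinement has a (near-)null rigid-translation mode of
    # the free conformer: in extrapolated mode amplitudes are exactly
    # invariant under a uniform shift (the floating P1 origin), and in
    # partial-occupancy mode a shift merely decorrelates the two conformers.
    # The displacement field is therefore parameterized with its net
    # translation projected out (pseudo-origin fixing).
    fix_net_translation: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0.0 < self.f <= 1.0):
            raise ValueError("occupancy f must be in (0, 1]")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if not (0.0 < self.free_fraction <= 0.5):
            raise ValueError("free_fraction must be in (0, 0.5]")
        for p in self.parameters:
            if p not in ("coordinates", "b_factors"):
                raise ValueError(f"unknown parameter set entry {p!r}")


@dataclass
class RefinedModel:
    model: AtomicModel
    r_factor: float
    r_free: float
    target_trace: list[float]
    options: RefinementOptions
    n_work: int
    n_free: int

    @property
    def converged(self) -> bool:
        return len(self.target_trace) < self.options.max_cycles + 1


def free_set_mask(hkl: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Deterministic R-free assignment from a hash of (h, k, l, seed)."""
    out = np.empty(len(hkl), dtype=bool)
    threshold = int(fraction * 2**32)
    for i, (h, k, l) in enumerate(hkl):
        digest = hashlib.blake2b(
            struct.pack("<4q", int(h), int(k), int(l), int(seed)), digest_size=4
        ).digest()
        out[i] = struct.unpack("<I", digest)[0] < threshold
    return out


def _r_factor(f_obs: np.ndarray, f_calc: np.ndarray, k: float) -> float:
    denom = float(np.sum(f_obs))
    if denom == 0:
        raise ValueError("observed amplitudes sum to zero")
    return float(np.sum(np.abs(f_obs - k * f_calc)) / denom)


def refine(F_obs: ReflectionSet, model: AtomicModel, opts: RefinementOptions) -> RefinedModel:
    """Refine free-atom coordinates/B-factors against observed amplitudes.

    In partial_occupancy mode the input model must carry conformers
    ``opts.frozen_conformer`` (held fixed, occupancy set to 1-f) and one
    other conformer (free, occupancy f).  In extrapolated mode every atom
    is free at its given occupancy.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    work_model = model.copy()
    if opts.mode == "partial_occupancy":
        frozen_tag = opts.frozen_conformer
        free_atoms = [a for a in work_model.atoms if a.conformer != frozen_tag]
        fixed_atoms = [a for a in work_model.atoms if a.conformer == frozen_tag]
        if not free_atoms:
            raise ValueError("no free conformer atoms to refine")
        for a in fixed_atoms:
            a.occ = 1.0 - opts.f
        for a in free_atoms:
            a.occ = opts.f
    else:
        free_atoms = list(work_model.atoms)
        fixed_atoms = []

    hkl = F_obs.hkl
    f_obs = F_obs.amplitude
    cell = model.cell
    s2 = 1.0 / cell.d_spacings(hkl) ** 2
    free_mask = free_set_mask(hkl, opts.free_fraction, opts.free_seed)
    if free_mask.all() or not free_mask.any():
        # tiny sets can hash to a degenerate split; fall back to every 20th
        free_mask = np.zeros(len(hkl), dtype=bool)
        free_mask[:: max(len(hkl) // max(int(len(hkl) * opts.free_fraction), 1), 2)] = True
    work = ~free_mask

    if fixed_atoms:
        fixed_model = AtomicModel(cell=cell, atoms=fixed_atoms)
        f_fixed = structure_factors_at(fixed_model, hkl)
    else:
        f_fixed = np.zeros(len(hkl), dtype=complex)

    occ_z = np.array([a.occ * a.z_electrons for a in free_atoms])
    refine_xyz = "coordinates" in opts.parameters
    refine_b = "b_factors" in opts.parameters
    n_free_atoms = len(free_atoms)
    x0_frac = np.stack([a.frac for a in free_atoms])
    x0_b = np.array([a.b_iso for a in free_atoms])

    fix_trans = opts.fix_net_translation and refine_xyz and n_free_atoms > 1

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Parameters are displacements from the start (plus B's); with
        pseudo-origin fixing the net translation is projected out."""
        pos = 0
        frac, b = x0_frac, x0_b
        if refine_xyz:
            u = x[: 3 * n_free_atoms].reshape(n_free_atoms, 3)
            if fix_trans:
                u = u - u.mean(axis=0)
            frac = x0_frac + u
            pos = 3 * n_free_atoms
        if refine_b:
            b = x[pos : pos + n_free_atoms]
        return frac, b

    hklf = hkl.astype(float)

    def target_and_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        frac, b = unpack(x)
        dw = np.exp(-np.outer(s2, b) / 4.0)
        ph = np.exp(2j * np.pi * (hklf @ frac.T))
        terms = dw * ph * occ_z  # (N, n_free)
        f_calc = f_fixed + terms.sum(axis=1)
        amp = np.abs(f_calc)
        if not np.all(np.isfinite(amp)):
            bad = int(np.argmax(~np.isfinite(amp)))
            raise FloatingPointError(f"non-finite F_calc at hkl {tuple(hkl[bad])}")
        denom = float(np.sum(amp[work] ** 2))
        if denom == 0:
            raise ValueError("calculated amplitudes vanish on the working set")
        k = float(np.sum(f_obs[work] * amp[work])) / denom
        resid = f_obs - k * amp
        t = float(np.sum(resid[work] ** 2))
        # dT/dA (envelope: dT/dk = 0 at the refit k); free-set hkl carry 0
        w = np.where(work, -2.0 * k * resid, 0.0)
        safe_amp = np.where(amp > 0, amp, 1.0)
        u = np.conj(f_calc) / safe_amp
        m = (w * u)[:, None] * terms  # (N, n_free)
        grads = []
        if refine_xyz:
            gx = -2.0 * np.pi * np.einsum("hd,hj->jd", hklf, m.imag)
            if fix_trans:
                gx = gx - gx.mean(axis=0)
            grads.append(gx.ravel())
        if refine_b:
            gb = -0.25 * (s2[:, None] * m.real).sum(axis=0)
            grads.append(gb)
        grad = np.concatenate(grads) if grads else np.zeros(0)
        return t, grad

    parts = []
    if refine_xyz:
        parts.append(np.zeros(3 * n_free_atoms))
    if refine_b:
        parts.append(x0_b)
    x = np.concatenate(parts) if parts else np.zeros(0)
    bounds = None
    if refine_b:
        bounds = [(None, None)] * (3 * n_free_atoms if refine_xyz else 0) + [
            (0.0, 1000.0)
        ] * n_free_atoms
    trace = [target_and_grad(x)[0]]
    for _cycle in range(opts.max_cycles):
        res = minimize(
            target_and_grad,
            x,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter_per_cycle},
        )
        x = res.x
        trace.append(float(res.fun))
        prev, curr = trace[-2], trace[-1]
        if prev - curr <= opts.tol * max(abs(prev), 1.0):
            break

    frac, b = unpack(x)
    for atom, fr, bi in zip(free_atoms, frac, b):
        atom.frac = fr % 1.0
        atom.b_iso = float(bi)

    # final R-factors with the converged scale
    dw = np.exp(-np.outer(s2, b) / 4.0)
    ph = np.exp(2j * np.pi * (hklf @ frac.T))
    f_calc = f_fixed + (dw * ph * occ_z).sum(axis=1)
    amp = np.abs(f_calc)
    k = float(np.sum(f_obs[work] * amp[work])) / float(np.sum(amp[work] ** 2))
    r_work = _r_factor(f_obs[work], amp[work], k)
    r_free = _r_factor(f_obs[free_mask], amp[free_mask], k)
    return RefinedModel(
        model=work_model,
        r_factor=r_work,
        r_free=r_free,
        target_trace=trace,
        options=opts,
        n_work=int(work.sum()),
        n_free=int(free_mask.sum()),
    )


# ---------------------------------------------------------------------------
# Occupancy scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Occupancy-scan products: displacement profiles, 1/f fit and the
    correlation-selected occupancy."""

    f_grid: np.ndarray
    atom_names: list[str]
    profiles: np.ndarray          # (n_f, n_atoms) displacements in Angstrom
    mean_displacement: np.ndarray  # (n_f,)
    correlations: np.ndarray       # (n_f,) Pearson vs the grid-mean profile
    fit_slope: float
    fit_intercept: float
    fit_r2: float
    fit_domain: tuple[float, float]
    f_best: float
    f_best_range: tuple[float, float]
    models: list[RefinedModel] | None = None
    flags: dict = field(default_factory=dict)

    def predicted_mean_displacement(self, f: float) -> float:
        """Mean displacement predicted by the fitted 1/f line."""
        return self.fit_slope / f + self.fit_intercept


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def occupancy_scan(
    F_obs: ReflectionSet,
    model_dark: AtomicModel,
    model_light_init: AtomicModel,
    f_grid: np.ndarray,
    opts: RefinementOptions | None = None,
    selection: Selection = None,
    F_dark: ReflectionSet | None = None,
    fit_domain_min: float = 0.25,
    keep_models: bool = False,
) -> ScanResult:
    """Refine at each occupancy of the grid and characterize the 1/f law.

    For each modeled f the activated conformer is refined (partial-occupancy
    mode, or extrapolated mode with ``F_dark`` supplying the reference
    amplitudes), its per-atom displacement profile from the reference model
    is computed, and the profile's Pearson correlation against the grid-mean
    profile is recorded.  A least-squares line of mean displacement vs 1/f
    is fit over f >= ``fit_domain_min``.  The correlation-selected occupancy
    is the argmax, reported as a range when ties fall within 1e-3.
    """
    opts = opts or RefinementOptions()
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any((f_grid <= 0) | (f_grid > 1)):
        raise ValueError("f grid must lie in (0, 1]")
    if opts.mode == "extrapolated" and F_dark is None:
        raise ValueError("extrapolated-mode scans need the reference amplitudes")

    profiles = []
    models: list[RefinedModel] = []
    ref_model = model_dark.select(conformer="A")
    for f in f_grid:
        import dataclasses as _dc

        opts_f = _dc.replace(opts, f=float(f))
        if opts.mode == "partial_occupancy":
            model = two_state_model(model_dark, model_light_init, float(f))
            try:
                refined = refine(F_obs, model, opts_f)
            except (ValueError, FloatingPointError) as exc:
                raise RuntimeError(f"refinement failed at f = {f:.4g}: {exc}") from exc
            moved = refined.model.select(conformer="B")
        else:
            f_ext = extrapolate(F_obs, F_dark, float(f)).F_ext
            init = model_light_init.with_occupancy(1.0)
            try:
                refined = refine(f_ext, init, opts_f)
            except (ValueError, FloatingPointError) as exc:
                raise RuntimeError(f"refinement failed at f = {f:.4g}: {exc}") from exc
            moved = refined.model
        prof = rmsd_profile(ref_model, moved, selection)
        profiles.append(prof.displacements)
        models.append(refined)
    names = rmsd_profile(ref_model, moved, selection).names
    profiles = np.stack(profiles)
    mean_disp = profiles.mean(axis=1)
    grid_mean_profile = profiles.mean(axis=0)

    flags = {}
    if len(f_grid) == 1:
        correlations = np.array([1.0])
        flags["single_point_grid"] = True
    else:
        correlations = np.array(
            [_pearson(p, grid_mean_profile) for p in profiles]
        )

    domain = f_grid >= fit_domain_min
    if domain.sum() >= 2:
        inv_f = 1.0 / f_grid[domain]
        slope, intercept = np.polyfit(inv_f, mean_disp[domain], 1)
        pred = slope * inv_f + intercept
        ss_res = float(np.sum((mean_disp[domain] - pred) ** 2))
        ss_tot = float(np.sum((mean_disp[domain] - mean_disp[domain].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        slope = intercept = np.nan
        r2 = np.nan
        flags["fit_domain_too_small"] = True

    best = float(np.max(correlations))
    ties = f_grid[correlations >= best - 1e-3]
    f_best = float(np.min(ties))
    return ScanResult(
        f_grid=f_grid,
        atom_names=names,
        profiles=profiles,
        mean_displacement=mean_disp,
        correlations=correlations,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        fit_r2=float(r2),
        fit_domain=(fit_domain_min, float(f_grid.max())),
        f_best=f_best,
        f_best_range=(float(np.min(ties)), float(np.max(ties))),
        models=models if keep_models else None,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Coordinate errors
# ---------------------------------------------------------------------------

@dataclass
class CoordinateSpread:
    """Per-atom rmsd from the mean position over replicate models."""

    atom_names: list[str]
    spread: np.ndarray          # Angstrom
    mean_frac: np.ndarray       # (n_atoms, 3) mean positions

    @property
    def mean(self) -> float:
        return float(np.mean(self.spread))


def _as_model(m) -> AtomicModel:
    return m.model if isinstance(m, RefinedModel) else m


def coordinate_spread(
    models: list,
    selection: Selection = None,
    conformer: str | None = None,
) -> CoordinateSpread:
    """Spread of each atom's position over replicate models.

    spread_j = sqrt(mean_i |x_ij - mean_i x_ij|^2), Cartesian, with
    minimum-image unwrapping relative to the first model.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    sel_models = [
        _as_model(m).select(selection, conformer=conformer) for m in models
    ]
    names = sel_models[0].names()
    if not names:
        raise ValueError("selection matches no atoms")
    for m in sel_models[1:]:
        if m.names() != names:
            raise ValueError("replicate models do not share atom ordering")
    cell = sel_models[0].cell
    ref = sel_models[0].frac_coords()
    # unwrap each replicate's coordinates around the first model
    stack = []
    for m in sel_models:
        d = m.frac_coords() - ref
        stack.append(ref + (d - np.round(d)))
    frac = np.stack(stack)                    # (n_models, n_atoms, 3)
    mean_frac = frac.mean(axis=0)
    dev = frac - mean_frac
    cart = np.einsum("mij,kj->mik", dev, cell.orth_matrix)
    spread = np.sqrt(np.mean(np.sum(cart**2, axis=2), axis=0))
    return CoordinateSpread(atom_names=names, spread=spread, mean_frac=mean_frac)


def sigma_free(
    n_atoms: float,
    n_obs: float,
    r_free: float,
    d_min: float,
    completeness: float,
    completeness_exponent: float = -1.5,
) -> float:
    """Closed-form (DPI-style) coordinate-error estimate in Angstrom.

    sigma_free = sqrt(0.65 * (N_a / N_o) * R_free^2 * d_min^2 * C^e)

    with C the completeness and e the completeness exponent.  The default
    e = -3/2 makes the error grow as completeness falls; the exponent is
    exposed because published renderings of the formula are typographically
    ambiguous about its sign.
    """
    if n_obs <= 0:
        raise ValueError("N_o must be positive")
    if n_atoms <= 0 or r_free <= 0 or d_min <= 0:
        raise ValueError("all inputs must be positive")
    if not (0.0 < completeness <= 1.0):
        raise ValueError("completeness must be in (0, 1]")
    val = (
        0.65
        * (n_atoms / n_obs)
        * r_free**2
        * d_min**2
        * completeness**completeness_exponent
    )
    return float(np.sqrt(val))


def b_to_u(b: float) -> float:
    """RMS displacement amplitude <u> from an isotropic B via B = 8 pi^2 <u^2>."""
    if b < 0:
        raise ValueError("B must be >= 0")
    return float(np.sqrt(b / _EIGHT_PI2))


def compare_approaches(
    models_partial: list,
    models_extrapolated: list,
    selection: Selection = None,
    reference: AtomicModel | None = None,
) -> tuple[pd.DataFrame, float]:
    """Compare mean coordinates recovered by the two refinement routes.

    Per matched atom: the separation of the two mean positions, the summed
    spread error bars, and an agreement flag (separation < summed bars).
    The second return value is the Pearson correlation of the two mean
    displacement-from-reference profiles (NaN without a reference model).
    """
    sp = coordinate_spread(models_partial, selection, conformer="B")
    se = coordinate_spread(
        models_extrapolated,
        selection,
        conformer=None,
    )
    if sp.atom_names != se.atom_names:
        raise ValueError("the two sets do not share atom ordering")
    cell = _as_model(models_partial[0]).cell
    dfrac = sp.mean_frac - se.mean_frac
    separation = np.linalg.norm(cell.min_image_cart(dfrac), axis=1)
    bars = sp.spread + se.spread
    corr = np.nan
    if reference is not None:
        ref = reference.select(selection, conformer="A")
        ref_frac = ref.frac_coords()
        if ref.names() != sp.atom_names:
            raise ValueError("reference model does not match atom ordering")
        dp = np.linalg.norm(cell.min_image_cart(sp.mean_frac - ref_frac), axis=1)
        de = np.linalg.norm(cell.min_image_cart(se.mean_frac - ref_frac), axis=1)
        corr = _pearson(dp, de)
    table = pd.DataFrame(
        {
            "atom": sp.atom_names,
            "separation": separation,
            "spread_partial": sp.spread,
            "spread_extrapolated": se.spread,
            "summed_bars": bars,
            "agree": separation < bars,
        }
    )
    return table, float(corr)
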