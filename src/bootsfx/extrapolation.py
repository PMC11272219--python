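"""Structure-factor extrapolation to a hypothetical full-occupancy dataset.

F_ext = (1/f) * F_obs(activated) + (1 - 1/f) * F_obs(reference)

applied to amplitudes, with non-positive extrapolated amplitudes rejected
and logged ("fgenick"-style policy).  Sigma propagation assumes independent
errors: sigma_ext^2 = (sigma_act/f)^2 + ((1 - 1/f) * sigma_ref)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reflections import ReflectionSet

__all__ = ["ExtrapolationResult", "extrapolate", "remix"]


@dataclass
class ExtrapolationResult:
    F_ext: ReflectionSet
    f: float
    rejected_hkl: np.ndarray = field(repr=False)  # (n_rej, 3)
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_hkl)

    @property
    def rejection_fraction(self) -> float:
        total = len(self.F_ext) + self.n_rejected
        return self.n_rejected / total if total else 0.0


def extrapolate(
    F_light: ReflectionSet,
    F_dark: ReflectionSet,
    f: float,
    policy: str = "reject_nonpositive",
) -> ExtrapolationResult:
    """Amplitude extrapolation to occupancy 1 with rejection bookkeeping."""
    if not (0.0 < f <= 1.0):
        raise ValueError("occupancy f must be in (0, 1]")
    if policy != "reject_nonpositive":
        raise ValueError(f"unknown policy {policy!r}")
    il, id_ = F_light.common_indices(F_dark)
    fl = F_light.amplitude[il]
    fd = F_dark.amplitude[id_]
    fext = fl / f + (1.0 - 1.0 / f) * fd
    sig = None
    if F_light.sigma is not None and F_dark.sigma is not None:
        sig = np.sqrt(
            (F_light.sigma[il] / f) ** 2 + ((1.0 - 1.0 / f) * F_dark.sigma[id_]) ** 2
        )
    keep = fext > 0.0
    rejected = F_light.hkl[il][~keep]
    reasons = [f"F_ext = {v:.6g} <= 0" for v in fext[~keep]]
    refls = ReflectionSet(
        hkl=F_light.hkl[il][keep],
        amplitude=fext[keep],
        sigma=None if sig is None else sig[keep],
        cell=F_light.cell or F_dark.cell,
        d_min=F_light.d_min,
        role="extrapolated",
        meta={"f": f, "n_rejected": int((~keep).sum())},
    )
    return ExtrapolationResult(
        F_ext=refls, f=f, rejected_hkl=rejected, rejection_reasons=reasons
    )


def remix(F_ext: ReflectionSet, F_dark: ReflectionSet, f: float) -> ReflectionSet:
    """Algebraic inverse of extrapolation: f*F_ext + (1-f)*F_dark.

    remix(extrapolate(F_light, F_dark, f).F_ext, F_dark, f) reproduces
    F_light exactly on the retained hkl.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError("occupancy f must be in (0, 1]")
    ie, id_ = F_ext.common_indices(F_dark)
    amp = f * F_ext.amplitude[ie] + (1.0 - f) * F_dark.amplitude[id_]
    return ReflectionSet(
        hkl=F_ext.hkl[ie],
        amplitude=amp,
        cell=F_ext.cell or F_dark.cell,
        d_min=F_ext.d_min,
        role="activated",
    )
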