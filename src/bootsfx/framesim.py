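"""Synthetic serial-diffraction frames.

Each frame emulates one still diffraction pattern from one microcrystal:
a random subset of reflections is observed, each with a frame-wide scale
(crystal size / beam fluctuations), a per-observation partiality, and
additive Gaussian background-subtraction noise.  Observations may therefore
be negative, as in real background-subtracted serial data.

The noise model is an explicit stand-in with documented defaults:

* frame scale  s ~ LogNormal(0, scale_sigma)
* partiality   p ~ Uniform(partiality_min, 1)
* noise        N(0, (noise_frac * median I_true)^2), sigma recorded as that sd

Per-frame randomness derives from ``SeedSequence((seed, frame_id))`` so any
subset of frames is reproducible independently of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import AtomicModel
from .reflections import ReflectionSet
from .sfcalc import mix_states, structure_factors

__all__ = ["Frame", "FrameSet", "simulate_frames", "two_state_frameset"]

# study-condition defaults for the synthetic generator
DEFAULT_OBS_FRACTION = 0.3
DEFAULT_SCALE_SIGMA = 0.3
DEFAULT_PARTIALITY_MIN = 0.1
DEFAULT_NOISE_FRAC = 0.1


@dataclass
class Frame:
    """One still pattern: partial intensities for a subset of reflections."""

    frame_id: int
    hkl: np.ndarray          # (n, 3) int
    i_partial: np.ndarray    # (n,) may be negative
    sigma: np.ndarray        # (n,) >= 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.i_partial = np.asarray(self.i_partial, dtype=float).reshape(-1)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(-1)
        if np.any(self.sigma < 0):
            raise ValueError("sigmas must be >= 0")


@dataclass
class FrameSet:
    """Ordered frames plus the generator parameters that produced them."""

    frames: list[Frame]
    truth_label: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.frame_id for f in self.frames]
        if ids != list(range(len(ids))):
            raise ValueError("frame_ids must be unique and dense from 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _frame_rng(seed: int, frame_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(frame_id))))


def simulate_frames(
    F_true: ReflectionSet,
    n_frames: int,
    obs_fraction: float = DEFAULT_OBS_FRACTION,
    scale_sigma: float = DEFAULT_SCALE_SIGMA,
    partiality_min: float = DEFAULT_PARTIALITY_MIN,
    noise_frac: float = DEFAULT_NOISE_FRAC,
    seed: int | None = None,
    truth_label: str = "",
) -> FrameSet:
    """Draw per-frame partial intensities from ground-truth |F|^2.

    Each frame observes a Bernoulli(obs_fraction) subset of the reflections;
    I_p = s_frame * p_obs * I_true + noise.  A seed is mandatory: the
    generator refuses silent nondeterminism.
    """
    if seed is None:
        raise ValueError("seed is required (no silent nondeterminism)")
    if not (0.0 < obs_fraction <= 1.0):
        raise ValueError("obs_fraction must be in (0, 1]")
    if not (0.0 < partiality_min <= 1.0):
        raise ValueError("partiality_min must be in (0, 1]")
    if noise_frac < 0 or scale_sigma < 0:
        raise ValueError("noise parameters must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    i_true = F_true.intensities()
    noise_sd = noise_frac * float(np.median(i_true))
    frames: list[Frame] = []
    for frame_id in range(n_frames):
        rng = _frame_rng(seed, frame_id)
        obs = rng.random(len(i_true)) < obs_fraction if obs_fraction < 1.0 else np.ones(
            len(i_true), dtype=bool
        )
        n_obs = int(obs.sum())
        scale = float(rng.lognormal(0.0, scale_sigma)) if scale_sigma > 0 else 1.0
        part = (
            rng.uniform(partiality_min, 1.0, size=n_obs)
            if partiality_min < 1.0
            else np.ones(n_obs)
        )
        values = scale * part * i_true[obs]
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=n_obs)
        frames.append(
            Frame(
                frame_id=frame_id,
                hkl=F_true.hkl[obs],
                i_partial=values,
                sigma=np.full(n_obs, noise_sd),
                scale=scale,
            )
        )
    params = {
        "n_frames": n_frames,
        "obs_fraction": obs_fraction,
        "scale_sigma": scale_sigma,
        "partiality_min": partiality_min,
        "noise_frac": noise_frac,
        "seed": int(seed),
    }
    return FrameSet(frames=frames, truth_label=truth_label, params=params)


def expected_scale() -> float:
    """Analytic E[s] for the lognormal frame scale (default sigma)."""
    return float(np.exp(DEFAULT_SCALE_SIGMA**2 / 2.0))


def two_state_frameset(
    model_dark: AtomicModel,
    model_light: AtomicModel,
    f: float,
    d_min: float,
    n_frames: int,
    seed: int,
    n_frames_light: int | None = None,
    **noise,
) -> tuple[FrameSet, FrameSet]:
    """Dark and light frame sets from a coherent two-state ground truth.

    Light frames are drawn from |(1-f) F_dark + f F_light|^2, dark frames
    from |F_dark|^2.  Disjoint per-set seeds derive from the master seed via
    SeedSequence spawning.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("occupancy f must be in [0, 1]")
    if model_dark.names() != model_light.names():
        raise ValueError("models must share atom correspondence")
    F_dark = structure_factors(model_dark, d_min, role="reference")
    F_light = structure_factors(model_light, d_min, role="activated")
    F_mix = mix_states(F_dark, F_light, f)
    seed_dark, seed_light = (
        int(s) for s in np.random.SeedSequence(int(seed)).generate_state(2) >> 1
    )
    fs_dark = simulate_frames(
        F_dark, n_frames, seed=seed_dark, truth_label="dark", **noise
    )
    nl = n_frames if n_frames_light is None else n_frames_light
    fs_light = simulate_frames(
        F_mix, nl, seed=seed_light, truth_label=f"light(f={f})", **noise
    )
    return fs_dark, fs_light
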