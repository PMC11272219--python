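"""Fixed-size bootstrap resampling of frames and Monte-Carlo merging.

The resampling unit is the frame (one diffraction pattern / one crystal),
never the individual reflection observation.  Merging is a plain
Monte-Carlo mean of the partial observations across the selected frames,
counting a frame drawn k times k-fold; no per-frame scale refinement is
attempted, which is the established serial-crystallography baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .framesim import FrameSet
from .reflections import ReflectionSet

__all__ = [
    "ResamplePlan",
    "MergedData",
    "bootstrap_plan",
    "expected_multiplicity",
    "merge_frames",
    "intensities_to_amplitudes",
    "half_set_rsplit",
]

DEFAULT_MIN_MEASUREMENTS = 3


@dataclass
class ResamplePlan:
    """Bootstrap index multisets: n_resamples draws of sample_size frames."""

    n_frames: int
    sample_size: int
    n_resamples: int
    seed: int
    indices: np.ndarray = field(repr=False)  # (n_resamples, sample_size)

    def __iter__(self):
        return iter(self.indices)


def bootstrap_plan(n_frames: int, sample_size: int, n_resamples: int, seed: int) -> ResamplePlan:
    """Draw fixed-size frame subsets with replacement, reproducibly."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sample_size < 1 or n_resamples < 1:
        raise ValueError("sample_size and n_resamples must be >= 1")
    rng = np.random.default_rng(int(seed))
    indices = rng.integers(0, n_frames, size=(n_resamples, sample_size))
    return ResamplePlan(
        n_frames=n_frames,
        sample_size=sample_size,
        n_resamples=n_resamples,
        seed=int(seed),
        indices=indices,
    )


def expected_multiplicity(n_frames: int, sample_size: int, n_resamples: int) -> float:
    """Expected number of times each frame is selected across all replicates.

    With n_resamples fixed-size draws of sample_size from n_frames with
    replacement, each frame is selected n_resamples*sample_size/n_frames
    times on average.
    """
    if n_frames < 1 or sample_size < 1 or n_resamples < 1:
        raise ValueError("all counts must be >= 1")
    return n_resamples * sample_size / n_frames


@dataclass
class MergedData:
    """Per-hkl Monte-Carlo means with standard errors and multiplicities."""

    table: pd.DataFrame  # columns: h, k, l, i_mean, sem, multiplicity
    n_dropped: int
    min_measurements: int
    replicate_id: int | None = None

    @property
    def hkl(self) -> np.ndarray:
        return self.table[["h", "k", "l"]].to_numpy(dtype=int)

    @property
    def i_mean(self) -> np.ndarray:
        return self.table["i_mean"].to_numpy()

    @property
    def sem(self) -> np.ndarray:
        return self.table["sem"].to_numpy()

    @property
    def multiplicity(self) -> np.ndarray:
        return self.table["multiplicity"].to_numpy(dtype=int)


def merge_frames(
    frames: FrameSet,
    indices: np.ndarray,
    min_measurements: int = DEFAULT_MIN_MEASUREMENTS,
    replicate_id: int | None = None,
) -> MergedData:
    """Monte-Carlo merge of the selected frames (with-replacement semantics).

    A frame drawn k times contributes its observations k-fold.  Reflections
    with fewer than ``min_measurements`` contributing observations are
    dropped and counted.
    """
    indices = np.asarray(indices, dtype=int).ravel()
    if indices.size == 0:
        raise ValueError("empty frame selection")
    if indices.min() < 0 or indices.max() >= frames.n_frames:
        raise ValueError("frame index out of range")
    hkl_all = np.concatenate([frames.frames[i].hkl for i in indices])
    i_all = np.concatenate([frames.frames[i].i_partial for i in indices])
    uniq, inv = np.unique(hkl_all, axis=0, return_inverse=True)
    count = np.bincount(inv)
    total = np.bincount(inv, weights=i_all)
    mean = total / count
    sumsq = np.bincount(inv, weights=i_all**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(count > 1, (sumsq - count * mean**2) / (count - 1), 0.0)
    var = np.clip(var, 0.0, None)  # guard tiny negative round-off
    sem = np.sqrt(var / count)
    stats = pd.DataFrame(
        {
            "h": uniq[:, 0],
            "k": uniq[:, 1],
            "l": uniq[:, 2],
            "i_mean": mean,
            "sem": sem,
            "multiplicity": count,
        }
    )
    n_before = len(stats)
    stats = stats[stats["multiplicity"] >= min_measurements].reset_index(drop=True)
    return MergedData(
        table=stats,
        n_dropped=n_before - len(stats),
        min_measurements=min_measurements,
        replicate_id=replicate_id,
    )


def intensities_to_amplitudes(
    merged: MergedData,
    policy: str = "clip_sqrt",
    cell=None,
    d_min: float | None = None,
    role: str = "reference",
) -> ReflectionSet:
    """Convert merged intensities to amplitudes: F = sqrt(max(I, 0)).

    Negative intensities clip to zero-amplitude records, which are retained
    and flagged (count in ``meta``).  sigF = sem / (2F) for F > 0 (linear
    error propagation of F = sqrt(I)), sqrt(sem) as the degenerate fallback.
    """
    if policy != "clip_sqrt":
        raise ValueError(f"unknown policy {policy!r}")
    if len(merged.table) == 0:
        raise ValueError("merged data is empty")
    i = merged.i_mean
    sem = merged.sem
    f = np.sqrt(np.clip(i, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.where(f > 0, sem / (2.0 * np.where(f > 0, f, 1.0)), np.sqrt(sem))
    n_negative = int(np.sum(i < 0))
    refls = ReflectionSet(
        hkl=merged.hkl,
        amplitude=f,
        sigma=sig,
        cell=cell,
        d_min=d_min,
        role=role,
        meta={
            "n_observations": int(merged.multiplicity.sum()),
            "n_negative_intensities": n_negative,
            "negative_fraction": n_negative / len(i),
            "n_zero_amplitude": int(np.sum(f == 0)),
            "policy": "clip_sqrt",
        },
    )
    return refls


def half_set_rsplit(frames: FrameSet, indices: np.ndarray, seed: int) -> float:
    """Rsplit between two random half-sets of the selected frame draws.

    Rsplit = 2^(-1/2) * sum|I1 - I2| / (0.5 * sum(I1 + I2)) over hkl merged
    in both halves.
    """
    indices = np.asarray(indices, dtype=int).ravel()
    if indices.size < 2:
        raise ValueError("need at least two frame draws for half-sets")
    rng = np.random.default_rng(int(seed))
    perm = rng.permutation(indices.size)
    half = indices.size // 2
    m1 = merge_frames(frames, indices[perm[:half]], min_measurements=1)
    m2 = merge_frames(frames, indices[perm[half:]], min_measurements=1)
    t1 = m1.table.set_index(["h", "k", "l"])["i_mean"]
    t2 = m2.table.set_index(["h", "k", "l"])["i_mean"]
    common = t1.index.intersection(t2.index)
    if len(common) == 0:
        raise ValueError("half-sets share no hkl")
    i1 = t1.loc[common].to_numpy()
    i2 = t2.loc[common].to_numpy()
    denom = 0.5 * np.sum(i1 + i2)
    if denom == 0:
        raise ValueError("degenerate half-sets (zero total intensity)")
    return float(np.sum(np.abs(i1 - i2)) / (np.sqrt(2.0) * denom))
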