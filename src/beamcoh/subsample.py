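"""Sensor-array subsampling: repeat reconstruction over random channel subsets.

Each iteration reconstructs the full pairwise coherence and null-coherence
volumes from a random subset of sensors (subset size drawn uniformly from a
range, channels without replacement).  The spatial noise of the difference
map varies across iterations while true interactions persist, so the
across-iteration mean suppresses realization-specific structure; dividing
the mean difference by the across-iteration standard deviation of the
difference yields a z-like map used for detection.

Two data modes are supported.  For recorded data the Fourier-coefficient
matrix is fixed and only the channel subset varies.  In the simulation study
every iteration additionally redraws the source and noise coefficients of
the same underlying configuration (the generative parameters are fixed, the
realization is not), so the aggregate also averages over observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .beamform import PAIR_COND_GUARD, dual_pair_maps, fixed_orientations, invert_csd, pair_gram
from .connectivity import dual_corrected_volume, far_pair_mask
from .forward import Leadfield, SourceGrid

__all__ = [
    "SubsamplePlan",
    "SubsampleAggregate",
    "draw_sensor_subset",
    "aggregate_maps",
    "run_subsamples",
]

#: standard deviations below this floor are flagged and clamped
STD_FLOOR = 1e-12


@dataclass(frozen=True)
class SubsamplePlan:
    """Number of iterations and channel-count range of the subsampling."""

    n_iterations: int = 100
    channel_range: tuple[int, int] = (50, 150)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.channel_range
        if lo < 2 or hi < lo:
            raise ValueError("channel range must satisfy 2 <= min <= max")
        if self.n_iterations < 2:
            raise ValueError("need at least 2 iterations")


@dataclass(frozen=True)
class SubsampleAggregate:
    """Across-iteration aggregate of the subsampled reconstructions.

    ``z`` is (mean coherence - mean null) / std(coherence - null), with the
    sample (n-1) standard deviation, floored at ``STD_FLOOR`` (floored pairs
    are flagged in ``degenerate``).  ``n_valid`` counts the iterations in
    which each pair was admissible; pairs valid in fewer than 2 iterations
    are masked invalid.
    """

    mean_coherence: np.ndarray
    mean_null: np.ndarray
    std_difference: np.ndarray
    z: np.ndarray
    n_valid: np.ndarray
    valid: np.ndarray
    degenerate: np.ndarray
    channel_subsets: list[np.ndarray]


def draw_sensor_subset(
    rng: np.random.Generator, n_total: int, lo: int, hi: int
) -> np.ndarray:
    """Random channel subset: size uniform on [lo, hi], channels w/o replacement."""
    if hi > n_total:
        raise ValueError("channel range exceeds the number of available channels")
    size = int(rng.integers(lo, hi + 1))
    return np.sort(rng.choice(n_total, size=size, replace=False))


def aggregate_maps(
    coh_stack: np.ndarray, null_stack: np.ndarray, valid_stack: np.ndarray
) -> SubsampleAggregate:
    """Aggregate per-iteration coherence/null volumes into mean, std and z.

    Stacks have shape (n_iterations, N, N); ``valid_stack`` marks the pairs
    admissible in each iteration.  The aggregate is invariant to the order
    of iterations.
    """
    v = valid_stack & np.isfinite(coh_stack) & np.isfinite(null_stack)
    coh = np.where(v, coh_stack, 0.0)
    null = np.where(v, null_stack, 0.0)
    diff = coh - null
    n = v.sum(axis=0)
    valid = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_coh = coh.sum(axis=0) / n
        mean_null = null.sum(axis=0) / n
        mean_diff = diff.sum(axis=0) / n
        ss = ((diff - np.where(v, mean_diff, 0.0)) ** 2 * v).sum(axis=0)
        std = np.sqrt(ss / np.maximum(n - 1, 1))
        degenerate = valid & (std < STD_FLOOR)
        z = (mean_coh - mean_null) / np.maximum(std, STD_FLOOR)
    for m in (mean_coh, mean_null, std, z):
        m[~valid] = np.nan
    return SubsampleAggregate(
        mean_coherence=mean_coh,
        mean_null=mean_null,
        std_difference=std,
        z=z,
        n_valid=n,
        valid=valid,
        degenerate=degenerate,
        channel_subsets=[],
    )


def run_subsamples(
    data: np.ndarray | Callable[[np.random.Generator], np.ndarray],
    lead: Leadfield | np.ndarray,
    grid: SourceGrid,
    plan: SubsamplePlan,
    orientation: str = "fixed",
    cond_guard: float = PAIR_COND_GUARD,
) -> SubsampleAggregate:
    """Run the dual-beamformer pipeline over random sensor subsets.

    Parameters
    ----------
    data : either a fixed (channels, observations) complex Fourier-coefficient
        matrix (recorded-data mode), or a callable ``rng -> X`` that redraws
        a fresh realization of the same configuration for every iteration
        (simulation mode).
    lead : oriented gain matrix (channels, N) when ``orientation="fixed"``
        (the default: the orientation is computed once from the full array
        and reused), or a free-orientation :class:`Leadfield` when
        ``orientation="per_subsample"``.
    plan : iteration count, channel range and master seed.  Iteration i uses
        the deterministic child stream i of the master seed, so aggregates
        are bit-reproducible.
    """
    redraw = data if callable(data) else None
    X_fixed = None if callable(data) else np.asarray(data)
    if orientation == "fixed":
        H_full = np.asarray(lead)
        lead_free = None
    elif orientation == "per_subsample":
        if not isinstance(lead, Leadfield):
            raise TypeError("per-subsample orientation needs a free Leadfield")
        lead_free = lead
        H_full = None
    else:
        raise ValueError("orientation must be 'fixed' or 'per_subsample'")
    streams = np.random.SeedSequence(plan.seed).spawn(plan.n_iterations)
    n_src = grid.n_sources
    far_mask = far_pair_mask(grid)
    # streaming (masked) accumulation: equivalent to stacking all iteration
    # volumes and calling aggregate_maps, without the memory traffic
    n = np.zeros((n_src, n_src), dtype=np.int32)
    s_coh = np.zeros((n_src, n_src))
    s_null = np.zeros((n_src, n_src))
    s_diff2 = np.zeros((n_src, n_src))
    subsets = []
    lo, hi = plan.channel_range
    for it, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        X = redraw(rng) if redraw is not None else X_fixed
        n_total, n_obs = X.shape
        idx = draw_sensor_subset(rng, n_total, lo, hi)
        subsets.append(idx)
        Xi = X[idx]
        csd = invert_csd(Xi @ Xi.conj().T / n_obs)
        if lead_free is not None:
            Hi, _ = fixed_orientations(lead_free.gain[idx], csd.inverse)
        else:
            Hi = H_full[idx]
        dual = dual_pair_maps(pair_gram(Hi, csd), cond_guard=cond_guard)
        vol = dual_corrected_volume(dual, grid, far_mask=far_mask)
        v = vol.valid & np.isfinite(vol.coherence) & np.isfinite(vol.null)
        coh = np.where(v, vol.coherence, 0.0)
        null = np.where(v, vol.null, 0.0)
        diff = coh - null
        n += v
        s_coh += coh
        s_null += null
        s_diff2 += diff * diff
    valid = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_coh = s_coh / n
        mean_null = s_null / n
        mean_diff = mean_coh - mean_null
        ss_ = s_diff2 - n * mean_diff**2
        std = np.sqrt(np.maximum(ss_, 0.0) / np.maximum(n - 1, 1))
        degenerate = valid & (std < STD_FLOOR)
        z = mean_diff / np.maximum(std, STD_FLOOR)
    for m in (mean_coh, mean_null, std, z):
        m[~valid] = np.nan
    return SubsampleAggregate(
        mean_coherence=mean_coh,
        mean_null=mean_null,
        std_difference=std,
        z=z,
        n_valid=n,
        valid=valid,
        degenerate=degenerate,
        channel_subsets=subsets,
    )
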