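"""Coherence, imaginary coherency, and the null-coherence bias estimate.

The null coherence approximates the coherence expected between two dipoles
under the hypothesis of no true interaction: with spatially white residual
noise, the estimated cross-spectral density of a non-interacting pair is
proportional to the inner product of the two spatial filters.  The scale is
fitted per seed dipole as a regression line through the origin of the
absolute cross-spectra against the absolute filter inner products over all
target dipoles; normalizing by the estimated powers yields a source x source
null-coherence volume, which is subtracted from (or divided into) the
estimated coherence before peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beamform import DualMaps, SingleMaps
from .forward import SourceGrid

__all__ = [
    "coherence",
    "imag_coherency_map",
    "fit_null_scale",
    "fit_null_scales",
    "null_coherence_volume",
    "corrected_map",
    "far_pair_mask",
    "fit_exclusion_mask",
    "CorrectedVolume",
    "dual_corrected_volume",
    "single_corrected_volume",
]

#: minimum number of target points for the per-seed scale fit
MIN_FIT_POINTS = 10


def coherence(cross, p1, p2):
    """Magnitude coherence |cross| / sqrt(p1 * p2); NaN where power vanishes."""
    cross = np.abs(np.asarray(cross, dtype=complex))
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((p1 > 0) & (p2 > 0), cross / np.sqrt(p1 * p2), np.nan)
    return out[()] if out.ndim == 0 else out


def imag_coherency_map(single: SingleMaps) -> np.ndarray:
    """|Im(coherency)| for every dipole pair, from single-dipole filters.

    This is the comparator that discards the real (instantaneous) part of
    the interaction: insensitive to zero-lag leakage, but blind to true
    couplings at phase differences near 0 or 180 degrees.
    """
    out = np.abs(np.imag(single.coherency))
    out[~single.valid] = np.nan
    return out


def fit_null_scale(
    cross_abs_row: np.ndarray,
    winner_abs_row: np.ndarray,
    include: np.ndarray | None = None,
    min_points: int = MIN_FIT_POINTS,
) -> float:
    """Least-squares slope through the origin of |cross| on |filter inner|.

    ``include`` masks the admissible target dipoles (the seed itself and
    near-seed targets are excluded by the caller).  Requires at least
    ``min_points`` valid points; raises otherwise.
    """
    y = np.asarray(cross_abs_row, dtype=float)
    x = np.asarray(winner_abs_row, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if include is not None:
        mask &= include
    if mask.sum() < min_points:
        raise ValueError(f"need >= {min_points} valid points for the scale fit")
    sxx = float((x[mask] ** 2).sum())
    if sxx <= 0:
        raise ValueError("all filter inner products vanish; scale undefined")
    return float((x[mask] * y[mask]).sum() / sxx)


def fit_null_scales(
    cross_abs: np.ndarray,
    winner_abs: np.ndarray,
    include: np.ndarray,
    min_points: int = MIN_FIT_POINTS,
    trim_quantile: float | None = None,
) -> np.ndarray:
    """Per-seed scale fits, vectorized over seed rows.

    Seeds with fewer than ``min_points`` admissible targets, or with
    vanishing inner products, get NaN.  ``trim_quantile`` optionally drops
    the largest |cross| fraction per seed before fitting (e.g. 0.01): a
    robustness measure against a seed's own strong true interactions
    inflating its scale estimate.  Off by default, since large cross-spectra
    may be exactly the couplings one wants to detect.
    """
    admissible = include & np.isfinite(winner_abs) & np.isfinite(cross_abs)
    if trim_quantile is not None:
        if not 0 < trim_quantile < 1:
            raise ValueError("trim_quantile must be in (0, 1)")
        y_masked = np.where(admissible, cross_abs, -np.inf)
        cut = np.nanquantile(
            np.where(admissible, cross_abs, np.nan), 1 - trim_quantile, axis=1
        )
        admissible = admissible & (y_masked <= cut[:, None])
    x = np.where(admissible, winner_abs, 0.0)
    y = np.where(admissible, cross_abs, 0.0)
    npts = admissible.sum(axis=1)
    sxx = (x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scales = sxy / sxx
    scales[(npts < min_points) | (sxx <= 0)] = np.nan
    return scales


def far_pair_mask(grid: SourceGrid) -> np.ndarray:
    """Pairs separated by more than one grid spacing (data-independent)."""
    return grid.pairwise_distances() > grid.spacing * (1 + 1e-9)


def fit_exclusion_mask(
    grid: SourceGrid, valid: np.ndarray, far_mask: np.ndarray | None = None
) -> np.ndarray:
    """Admissible (seed, target) points for the scale fit.

    Excludes invalid pairs, the seed itself, and targets within one grid
    spacing of the seed (where residual seed leakage would bias the fit).
    ``far_mask`` may pass a precomputed :func:`far_pair_mask`.
    """
    if far_mask is None:
        far_mask = far_pair_mask(grid)
    return valid & far_mask


def null_coherence_volume(
    scales: np.ndarray, winner_abs: np.ndarray, power_i: np.ndarray, power_j: np.ndarray
) -> np.ndarray:
    """Null coherence: scale(i) * |w_i^H w_j| / sqrt(p_i p_j), symmetrized.

    ``power_i[i, j]`` / ``power_j[i, j]`` are the powers of dipoles i and j
    entering pair (i, j) (equal outer products of a power vector for the
    single-dipole variant).  The seed-wise evaluations (i, j) and (j, i) are
    averaged, making the volume symmetric.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = scales[:, None] * winner_abs / np.sqrt(power_i * power_j)
    return (raw + raw.T) / 2


def corrected_map(
    coh: np.ndarray, null: np.ndarray, mode: str = "subtract", eps_factor: float = 1e-6
) -> np.ndarray:
    """Leakage-corrected connectivity map.

    mode="subtract": coh - null (the simulation default); mode="divide":
    coh / max(null, eps) with eps = ``eps_factor`` times the median valid
    null value (the recommendation for real data, where averaging across
    many subsamples stabilizes the null estimate).
    """
    if coh.shape != null.shape:
        raise ValueError("coherence and null volumes differ in shape")
    if mode == "subtract":
        return coh - null
    if mode == "divide":
        positive = np.isfinite(null) & (null > 0)
        med = np.median(null[positive]) if positive.any() else 1.0
        eps = eps_factor * med
        return coh / np.maximum(null, eps)
    raise ValueError(f"unknown correction mode: {mode!r}")


@dataclass(frozen=True)
class CorrectedVolume:
    """Coherence, null coherence and corrected map with a validity mask."""

    coherence: np.ndarray
    null: np.ndarray
    corrected: np.ndarray
    valid: np.ndarray
    scales: np.ndarray  # per-seed fitted null scale


def dual_corrected_volume(
    dual: DualMaps,
    grid: SourceGrid,
    mode: str = "subtract",
    far_mask: np.ndarray | None = None,
) -> CorrectedVolume:
    """Null-corrected coherence volume from two-dipole beamformer estimates."""
    include = fit_exclusion_mask(grid, dual.valid, far_mask)
    scales = fit_null_scales(dual.cross_abs, dual.winner_abs, include)
    null = null_coherence_volume(scales, dual.winner_abs, dual.power, dual.power.T)
    corr = corrected_map(dual.coherence, null, mode=mode)
    valid = dual.valid & np.isfinite(corr)
    return CorrectedVolume(
        coherence=dual.coherence, null=null, corrected=corr, valid=valid, scales=scales
    )


def single_corrected_volume(
    single: SingleMaps,
    grid: SourceGrid,
    mode: str = "subtract",
    far_mask: np.ndarray | None = None,
) -> CorrectedVolume:
    """Null-corrected coherence volume from single-dipole beamformer estimates."""
    include = fit_exclusion_mask(grid, single.valid, far_mask)
    scales = fit_null_scales(single.cross_abs, single.winner_abs, include)
    p = single.power
    pi = np.broadcast_to(p[:, None], single.winner_abs.shape)
    null = null_coherence_volume(scales, single.winner_abs, pi, pi.T)
    coh = np.abs(single.coherency)
    corr = corrected_map(coh, null, mode=mode)
    valid = single.valid & np.isfinite(corr)
    return CorrectedVolume(
        coherence=coh, null=null, corrected=corr, valid=valid, scales=scales
    )
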