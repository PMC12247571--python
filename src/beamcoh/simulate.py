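"""Frequency-domain simulation of coupled dipole sources and sensor noise.

Sensor-level data are complex Fourier-coefficient matrices (channels x
observations) for a single frequency bin.  Source activity is drawn from a
circularly-symmetric complex Gaussian with a parametrized cross-spectral
density: the first ``n_interacting`` sources are coherent at level ``rho``
with phase difference ``phi`` and relative amplitude ``a``; the remaining
sources are independent background activity of amplitude ``1 - a``.  Signal
and noise matrices are normalized by the Frobenius norm of their
cross-spectra and mixed with weight ``sigma`` (signal-to-sensor-noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationConfig",
    "SourceCSD",
    "SensorSpectra",
    "source_csd_matrix",
    "draw_complex_gaussian",
    "mix_to_sensors",
    "generate_noise",
    "empty_room_covariance",
    "combine_snr",
    "spectral_observation_count",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    rho : intended coherence between the interacting sources, in [0, 1].
    phi : phase difference of the interaction, radians.
    a : relative amplitude of the interacting sources, in (0, 1); the
        interacting/background amplitude ratio is a / (1 - a).
    snr_sigma : signal-to-sensor-noise mixing weight, in [0, 1].
    """

    rho: float = 0.3
    phi: float = 0.0
    a: float = 0.7
    snr_sigma: float = 0.6
    n_sources: int = 20
    n_interacting: int = 2
    n_obs: int = 350
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if not 0 < self.a < 1:
            raise ValueError("a must be in (0, 1)")
        if not 0 <= self.snr_sigma <= 1:
            raise ValueError("snr_sigma must be in [0, 1]")
        if not 2 <= self.n_interacting <= self.n_sources:
            raise ValueError("need 2 <= n_interacting <= n_sources")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")


@dataclass(frozen=True)
class SourceCSD:
    """Hermitian positive-semidefinite source cross-spectral density."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("CSD must be square")
        if not np.allclose(m, m.conj().T, atol=1e-12):
            raise ValueError("CSD must be Hermitian")
        object.__setattr__(self, "matrix", m)

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SensorSpectra:
    """Complex Fourier-coefficient matrix with a role tag.

    ``coefficients`` is channels x observations (or sources x observations
    for source-level spectra, tagged role="source").
    """

    coefficients: np.ndarray
    role: str = "mixed"  # signal | noise | mixed | source

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=complex)
        if c.ndim != 2 or c.shape[1] < 1:
            raise ValueError("coefficients must be 2-D with >= 1 observation")
        if not np.isfinite(c).all():
            raise ValueError("non-finite Fourier coefficients")
        object.__setattr__(self, "coefficients", c)

    @property
    def n_observations(self) -> int:
        return self.coefficients.shape[1]


def source_csd_matrix(
    rho: float, phi: float, a: float, n_sources: int, n_interacting: int = 2
) -> SourceCSD:
    """Parametrized source CSD: D @ A @ D.

    D = diag(a, ..., a, 1-a, ..., 1-a) with ``a`` for the first
    ``n_interacting`` sources, and A the identity with off-diagonal entries
    rho * exp(+/- i phi) coupling the interacting sources pairwise.  The
    population coherence between any two interacting sources is exactly rho,
    independent of a and phi.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1] (CSD not PSD otherwise)")
    if not 0 < a < 1:
        raise ValueError("a must be in (0, 1)")
    if not 2 <= n_interacting <= n_sources:
        raise ValueError("need 2 <= n_interacting <= n_sources")
    amp = np.full(n_sources, 1.0 - a)
    amp[:n_interacting] = a
    A = np.eye(n_sources, dtype=complex)
    for i in range(n_interacting):
        for j in range(i + 1, n_interacting):
            A[i, j] = rho * np.exp(1j * phi)
            A[j, i] = rho * np.exp(-1j * phi)
    m = amp[:, None] * A * amp[None, :]
    return SourceCSD(matrix=m)


def _csd_sqrt(csd: SourceCSD) -> np.ndarray:
    """Matrix square root of a PSD CSD (eigendecomposition; negative
    eigenvalues beyond round-off raise)."""
    w, v = np.linalg.eigh(csd.matrix)
    tol = -1e-10 * max(w.max(), 1e-300)
    if w.min() < tol:
        raise ValueError("CSD is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0, None))


def draw_complex_gaussian(
    csd: SourceCSD, n_obs: int, seed: int | np.random.Generator = 0
) -> SensorSpectra:
    """Circularly-symmetric complex Gaussian draws with population CSD ``csd``.

    Standard complex normals (real and imaginary parts iid N(0, 1/2)) are
    colored by the matrix square root of the CSD, so E[S S^H] / n_obs equals
    the requested CSD.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = _csd_sqrt(csd)
    n = csd.n_sources
    z = (rng.standard_normal((n, n_obs)) + 1j * rng.standard_normal((n, n_obs))) / np.sqrt(2)
    return SensorSpectra(coefficients=L @ z, role="source")


def mix_to_sensors(
    gain: np.ndarray, sources: SensorSpectra, selection: np.ndarray | None = None
) -> SensorSpectra:
    """Project source spectra to the sensors: Xs = H S.

    ``gain`` is an oriented (channels x grid-sources) matrix; ``selection``
    picks the active dipole columns (one per row of the source spectra).
    """
    H = np.asarray(gain, dtype=float)
    if selection is not None:
        H = H[:, np.asarray(selection, dtype=int)]
    S = sources.coefficients
    if H.shape[1] != S.shape[0]:
        raise ValueError(
            f"gain has {H.shape[1]} columns but {S.shape[0]} sources were given"
        )
    return SensorSpectra(coefficients=H @ S, role="signal")


def generate_noise(
    n_channels: int,
    n_obs: int,
    seed: int | np.random.Generator = 0,
    covariance: np.ndarray | None = None,
) -> SensorSpectra:
    """Complex Gaussian sensor noise, spatially white by default.

    An optional Hermitian PSD ``covariance`` colors the noise across
    channels (emulating structured instrumental/environmental noise).
    """
    if n_channels < 1 or n_obs < 1:
        raise ValueError("n_channels and n_obs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = (
        rng.standard_normal((n_channels, n_obs))
        + 1j * rng.standard_normal((n_channels, n_obs))
    ) / np.sqrt(2)
    if covariance is not None:
        L = _csd_sqrt(SourceCSD(matrix=np.asarray(covariance, dtype=complex)))
        z = L @ z
    return SensorSpectra(coefficients=z, role="noise")


def empty_room_covariance(
    n_channels: int,
    seed: int = 0,
    n_env: int = 8,
    env_fraction: float = 0.99,
    spread_decades: float = 1.5,
) -> np.ndarray:
    """Synthetic empty-room noise covariance (Hermitian PSD).

    Emulates the spatial structure of an MEG empty-room recording at a single
    frequency: a small number of high-variance environmental field components
    (power-line harmonics, vibration, distant magnetic disturbances project
    onto the array as a few smooth spatial patterns) on top of a spatially
    white intrinsic sensor-noise floor.  ``env_fraction`` of the total
    variance sits in ``n_env`` random components whose strengths span
    ``spread_decades`` decades.  This is a synthetic stand-in for a measured
    empty-room covariance; real recordings are typically at least this
    strongly dominated by their environmental subspace.
    """
    if not 0 <= env_fraction < 1:
        raise ValueError("env_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((n_channels, n_env)) + 1j * rng.standard_normal(
        (n_channels, n_env)
    )
    B /= np.linalg.norm(B, axis=0)
    strengths = 10.0 ** rng.uniform(0, spread_decades, n_env)
    Q = (B * strengths) @ B.conj().T
    Q *= env_fraction / np.real(np.trace(Q))
    Q += (1.0 - env_fraction) / n_channels * np.eye(n_channels)
    return (Q + Q.conj().T) / 2


def combine_snr(
    signal: SensorSpectra, noise: SensorSpectra, snr_sigma: float
) -> SensorSpectra:
    """Mix signal and noise spectra: X = sigma * Xs + (1 - sigma) * Xn.

    Each input is first rescaled so that the Frobenius norm of its
    cross-spectrum X X^H equals 1, making ``snr_sigma`` a dimensionless
    signal-to-sensor-noise weight.
    """
    if not 0 <= snr_sigma <= 1:
        raise ValueError("snr_sigma must be in [0, 1]")
    Xs, Xn = signal.coefficients, noise.coefficients
    if Xs.shape != Xn.shape:
        raise ValueError("signal and noise shapes differ")

    def _normalize(X):
        scale = np.linalg.norm(X @ X.conj().T)
        if scale == 0:
            raise ValueError("zero-norm input cannot be SNR-normalized")
        return X / np.sqrt(scale)

    X = snr_sigma * _normalize(Xs) + (1.0 - snr_sigma) * _normalize(Xn)
    return SensorSpectra(coefficients=X, role="mixed")


def spectral_observation_count(
    record_length: float, epoch_length: float, smoothing: float
) -> tuple[int, int]:
    """Multitaper bookkeeping: tapers per epoch and total observations.

    For epochs of ``epoch_length`` seconds and a spectral smoothing
    half-bandwidth of ``smoothing`` Hz, the number of Slepian tapers is
    ``2 * epoch_length * smoothing - 1`` and every taper of every epoch
    contributes one observation (Fourier-coefficient column).
    """
    if record_length <= 0 or epoch_length <= 0:
        raise ValueError("durations must be positive")
    if smoothing * epoch_length < 1:
        raise ValueError("smoothing too small for the epoch length (no taper)")
    n_tapers = int(round(2 * epoch_length * smoothing - 1))
    n_epochs = int(np.floor(record_length / epoch_length))
    return n_tapers, n_epochs * n_tapers
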