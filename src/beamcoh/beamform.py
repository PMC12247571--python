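"""Single- and two-dipole unit-gain beamformers in the frequency domain.

A linearly constrained minimum variance (LCMV/DICS) spatial filter for a
dipole with gain vector h is  w^T = (h^T C^-1 h)^-1 h^T C^-1, where C is the
sensor cross-spectral density.  The two-dipole variant constrains a pair of
dipoles with an identity gain, W^T H = I_2 with H = [h1 h2], which cancels
the reciprocal zero-lag leakage between the two locations.

All-to-all pair quantities are computed from two Gram matrices,

    G = H^T C^-1 H      (beamformer Gram, g_ij = h_i^T C^-1 h_j)
    K = H^T C^-2 H      (filter kernel, inner products of C^-1-projected gains)

from which every per-pair 2x2 filter product follows in closed form.  This
makes the N^2 pair sweep a handful of dense matrix products plus elementwise
algebra, and is verified in the tests against the literal per-pair loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SensorCSD",
    "SpatialFilter",
    "PairGram",
    "DualMaps",
    "SingleMaps",
    "invert_csd",
    "fixed_orientation",
    "fixed_orientations",
    "single_filter",
    "pair_filter",
    "pair_gram",
    "dual_pair_maps",
    "single_dipole_maps",
]

#: relative eigenvalue tolerance for the truncated pseudo-inverse
PINV_RTOL = 1e-10
#: condition-number guard for the 2x2 pair Gram
PAIR_COND_GUARD = 1e6


@dataclass(frozen=True)
class SensorCSD:
    """Sensor cross-spectral density with its (pseudo-)inverse."""

    matrix: np.ndarray
    inverse: np.ndarray
    rank: int

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SpatialFilter:
    """Unit-gain filter row vector for one target dipole."""

    weights: np.ndarray  # (n_channels,)
    target: int = -1


def invert_csd(
    matrix: np.ndarray, ridge: float = 0.0, rtol: float = PINV_RTOL
) -> SensorCSD:
    """Invert a Hermitian CSD without regularization by default.

    Full-rank matrices get the exact inverse; rank-deficient ones a truncated
    Moore-Penrose pseudo-inverse (eigenvalues below ``rtol`` times the largest
    are discarded).  ``ridge > 0`` adds ridge * mean(diag) to the diagonal
    before inversion (off by default).
    """
    C = np.asarray(matrix, dtype=complex)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("CSD must be square")
    scale = np.abs(C).max()
    if scale == 0:
        raise ValueError("CSD is identically zero")
    if not np.allclose(C, C.conj().T, atol=1e-10 * scale):
        raise ValueError("CSD must be Hermitian")
    C = (C + C.conj().T) / 2
    if ridge > 0:
        C = C + ridge * np.real(np.trace(C)) / C.shape[0] * np.eye(C.shape[0])
    w, v = np.linalg.eigh(C)
    keep = w > rtol * w.max()
    rank = int(keep.sum())
    inv = (v[:, keep] / w[keep]) @ v[:, keep].conj().T
    return SensorCSD(matrix=C, inverse=inv, rank=rank)


def fixed_orientation(
    h_free: np.ndarray, csd_inverse: np.ndarray, rtol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """Power-maximizing dipole orientation for a free-orientation gain.

    The beamformer output power at orientation q is 1 / (h(q)^T C^-1 h(q)),
    so the optimum minimizes the quadratic form q^T Re(H^T C^-1 H) q.  The
    search is restricted to the row space of H (singular directions of the
    gain, e.g. the magnetically silent radial orientation in a spherical
    conductor, are excluded); within it, the optimum is the eigenvector of
    the reduced Gram with the smallest eigenvalue.  The sign is fixed so the
    largest-magnitude component of q is positive.

    Returns (oriented gain vector, unit orientation).
    """
    H = np.asarray(h_free, dtype=float)
    if H.ndim != 2 or H.shape[1] != 3:
        raise ValueError("free-orientation gain must have 3 columns")
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    if s[0] == 0:
        raise ValueError("degenerate (all-zero) gain")
    keep = s > rtol * s[0]
    V = Vt[keep].T  # (3, k) basis of non-silent orientations
    M = np.real(np.einsum("ci,cd,dj->ij", H @ V, csd_inverse, H @ V))
    M = (M + M.T) / 2
    w, vec = np.linalg.eigh(M)
    q = V @ vec[:, 0]
    q = q / np.linalg.norm(q)
    if q[np.argmax(np.abs(q))] < 0:
        q = -q
    return H @ q, q


def fixed_orientations(
    gain_free: np.ndarray, csd_inverse: np.ndarray, rtol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed orientation for every dipole of a (channels, N, 3) leadfield.

    Batched equivalent of :func:`fixed_orientation` (dipoles are grouped by
    the rank of their gain block so the reduced eigenproblems can be solved
    in stacks).  Returns (oriented gain (channels, N), orientations (N, 3)).
    Dipoles with an all-zero gain get a zero column and an arbitrary unit
    orientation.
    """
    Hf = np.asarray(gain_free, dtype=float)
    n_ch, n_src, _ = Hf.shape
    T = np.tensordot(csd_inverse, Hf, axes=(1, 0))  # (ch, N, 3)
    M = np.real(np.einsum("cnk,cnl->nkl", Hf, T))
    M = (M + M.transpose(0, 2, 1)) / 2
    _, s, Vt = np.linalg.svd(Hf.transpose(1, 0, 2), full_matrices=False)
    smax = s[:, 0]
    H = np.zeros((n_ch, n_src))
    Q = np.zeros((n_src, 3))
    Q[:, 2] = 1.0
    nonzero = smax > 0
    k_count = (s > rtol * smax[:, None]).sum(axis=1)
    for k in (1, 2, 3):
        sel = np.nonzero(nonzero & (k_count == k))[0]
        if sel.size == 0:
            continue
        V = Vt[sel, :k, :].transpose(0, 2, 1)  # (m, 3, k) non-silent bases
        Mr = np.einsum("nji,njl,nlm->nim", V, M[sel], V)
        _, vec = np.linalg.eigh(Mr)
        q = np.einsum("nij,nj->ni", V, vec[:, :, 0])
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        comp = np.take_along_axis(
            q, np.argmax(np.abs(q), axis=1)[:, None], axis=1
        )[:, 0]
        q[comp < 0] *= -1
        Q[sel] = q
        H[:, sel] = np.einsum("cnk,nk->cn", Hf[:, sel, :], q)
    return H, Q


def single_filter(h: np.ndarray, csd_inverse: np.ndarray, tol: float = 1e-300) -> SpatialFilter:
    """LCMV/DICS unit-gain filter: w^T = (h^T C^-1 h)^-1 h^T C^-1."""
    h = np.asarray(h)
    num = h @ csd_inverse  # row vector h^T C^-1
    g = np.real(num @ h)
    if not g > tol:
        raise ValueError("insensitive location: h^T C^-1 h is not positive")
    return SpatialFilter(weights=num / g)


def pair_filter(
    h1: np.ndarray,
    h2: np.ndarray,
    csd_inverse: np.ndarray,
    cond_guard: float = PAIR_COND_GUARD,
) -> np.ndarray:
    """Two-dipole identity-gain filter W^T = (H^T C^-1 H)^-1 H^T C^-1.

    Returns the 2 x channels filter matrix (rows are the per-dipole filters).
    Near-collinear gain pairs (2x2 Gram condition number above ``cond_guard``)
    raise, since the identity-gain constraint is then ill-posed.
    """
    Hp = np.column_stack([h1, h2])
    B = Hp.T @ csd_inverse  # (2, channels)
    Gp = B @ Hp  # (2, 2)
    ev = np.linalg.eigvalsh((Gp + Gp.conj().T) / 2)
    if ev[0] <= 0 or ev[1] / ev[0] > cond_guard:
        raise ValueError("near-collinear dipole pair: identity gain ill-posed")
    return np.linalg.solve(Gp, B)


@dataclass(frozen=True)
class PairGram:
    """Gram matrices driving the vectorized all-pairs computation."""

    gram: np.ndarray  # (N, N) complex, H^T C^-1 H
    kernel: np.ndarray  # (N, N) complex, H^T C^-2 H

    @property
    def n_sources(self) -> int:
        return self.gram.shape[0]


def pair_gram(gain: np.ndarray, csd: SensorCSD) -> PairGram:
    """Compute G = H^T C^-1 H and K = H^T C^-2 H for an oriented leadfield."""
    H = np.asarray(gain)
    A = csd.inverse @ H  # (channels, N)
    G = H.conj().T @ A
    K = A.conj().T @ A
    return PairGram(gram=G, kernel=K)


@dataclass(frozen=True)
class DualMaps:
    """All-to-all two-dipole beamformer estimates.

    For each admissible ordered pair (i, j): ``cross_abs[i, j]`` is the
    magnitude of the pair-filter cross-spectral density estimate,
    ``power[i, j]`` the power of dipole i estimated within the pair (i, j)
    (so the partner power is ``power[j, i]``), ``winner_abs[i, j]`` the
    magnitude of the filter inner product w_i^H w_j of the two pair-filter
    rows, and ``coherence[i, j]`` the magnitude coherence.  ``valid`` masks
    pairs excluded by the collinearity guard; invalid entries are NaN.
    """

    cross_abs: np.ndarray
    power: np.ndarray
    winner_abs: np.ndarray
    coherence: np.ndarray
    valid: np.ndarray


def dual_pair_maps(pg: PairGram, cond_guard: float = PAIR_COND_GUARD) -> DualMaps:
    """Vectorized two-dipole estimates for every dipole pair.

    Writing the 2x2 pair Gram as [[p, q], [q*, r]] (p = g_ii, r = g_jj,
    q = g_ij), the pair-filter source CSD is its inverse, hence

        cross_ij = -q / det,   power_i|ij = r / det,   det = p r - |q|^2,

    and the filter inner product of the two rows of W is the (1, 2) entry of
    Gp^-1 Kp Gp^-1 with Kp the 2x2 block of the kernel K.
    """
    G, K = pg.gram, pg.kernel
    gd = np.real(np.diagonal(G)).copy()
    p = gd[:, None]
    r = gd[None, :]
    absG = np.abs(G)
    absG2 = absG**2
    det = p * r - absG2
    # eigenvalues of the Hermitian 2x2 Gram -> condition guard
    half_tr = (p + r) / 2
    disc = np.sqrt(np.maximum((p - r) ** 2 / 4 + absG2, 0.0))
    lam_min = half_tr - disc
    valid = (lam_min > 0) & (half_tr + disc <= cond_guard * lam_min)
    np.fill_diagonal(valid, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        cross_abs = absG / det
        power = r / det  # power of dipole i within pair (i, j)
        kd = np.real(np.diagonal(K))
        winner = G * G * np.conj(K)
        winner += (p * r) * K
        winner -= (r * kd[:, None] + p * kd[None, :]) * G
        winner /= det
        winner /= det
        winner_abs = np.abs(winner)
        coherence = absG / np.sqrt(p * r)
    for m in (cross_abs, power, winner_abs, coherence):
        m[~valid] = np.nan
    return DualMaps(
        cross_abs=cross_abs,
        power=power,
        winner_abs=winner_abs,
        coherence=coherence,
        valid=valid,
    )


@dataclass(frozen=True)
class SingleMaps:
    """All-to-all single-dipole beamformer estimates.

    ``coherency`` is the complex coherency g_ij / sqrt(g_ii g_jj); ``power``
    is the per-dipole output power 1 / g_ii; ``cross_abs`` and ``winner_abs``
    are the magnitudes of the pairwise cross-spectral density and of the
    filter inner products of the unit-gain single-dipole filters.
    """

    cross_abs: np.ndarray
    power: np.ndarray  # (N,)
    winner_abs: np.ndarray
    coherency: np.ndarray
    valid: np.ndarray


def single_dipole_maps(pg: PairGram, tol: float = 1e-300) -> SingleMaps:
    """Vectorized single-dipole estimates for every dipole pair."""
    G, K = pg.gram, pg.kernel
    gd = np.real(np.diagonal(G)).copy()
    ok = gd > tol
    gd_safe = np.where(ok, gd, np.nan)
    denom = gd_safe[:, None] * gd_safe[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        cross_abs = np.abs(G) / denom
        winner_abs = np.abs(K) / denom
        coherency = G / np.sqrt(denom)
        power = 1.0 / gd_safe
    valid = ok[:, None] & ok[None, :]
    np.fill_diagonal(valid, False)
    for m in (cross_abs, winner_abs, coherency):
        m[~valid] = np.nan
    return SingleMaps(
        cross_abs=cross_abs,
        power=power,
        winner_abs=winner_abs,
        coherency=coherency,
        valid=valid,
    )
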