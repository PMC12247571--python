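"""Thresholding, 6-D clustering, connection scoring and FROC evaluation.

A corrected connectivity volume over N grid dipoles is thresholded by
keeping the pct% largest pairwise values (counted against the full N x N
matrix, so pct = 0.001 keeps round(1e-5 * N^2) edges; each unordered pair
is emitted once).  Suprathreshold edges live in the 6-dimensional product
space of the two endpoint grids; spatially connected edges are clustered
(two edges are neighbors when both endpoints are within the 26-neighborhood
of the other edge's endpoints, in either endpoint pairing).  Each cluster
splits into two dipole assemblies; clusters whose assemblies share dipoles
are auto-connections driven by leakage blur and are discarded.  A detected
connection is a hit when the summed distance of the two true dipoles to the
nearest voxels of the two assemblies is at most a tolerance (2 cm); all
other valid connections count as false positives, yielding FROC curves
across the threshold ladder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .forward import SourceGrid

__all__ = [
    "DEFAULT_THRESHOLDS",
    "HIT_RULE_MAX_PCT",
    "EdgeSet",
    "Cluster",
    "edge_count",
    "threshold_edges",
    "cluster_edges_6d",
    "filter_clusters",
    "score_detection",
    "near_active_false_positive",
    "froc",
]

#: relative threshold ladder (percent of N^2 pairwise values kept)
DEFAULT_THRESHOLDS = (5.0, 1.0, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005)
#: the hit rule considers detections at thresholds strictly below this pct
HIT_RULE_MAX_PCT = 0.01
#: hit tolerance: summed distance of the true dipoles to the closest
#: assembly voxels, meters
HIT_TOLERANCE = 0.02


def edge_count(pct: float, n_dipoles: int) -> int:
    """Edges kept by a pct% relative threshold: round-half-up of pct% of N^2."""
    if not 0 < pct <= 100:
        raise ValueError("pct must be in (0, 100]")
    return int(np.floor(pct / 100.0 * n_dipoles**2 + 0.5))


@dataclass(frozen=True)
class EdgeSet:
    """Suprathreshold unordered dipole pairs, sorted by descending value."""

    pairs: np.ndarray  # (K, 2) int, i < j
    values: np.ndarray  # (K,)
    pct: float
    n_dipoles: int

    @property
    def count(self) -> int:
        return self.pairs.shape[0]


def threshold_edges(
    volume: np.ndarray, pct: float, valid: np.ndarray | None = None
) -> EdgeSet:
    """Keep the ``edge_count(pct, N)`` largest pairwise values of a volume.

    The diagonal (and any invalid entries) is masked before selection; ties
    at the cut are broken by the lower flattened upper-triangle index.  The
    volume is treated as symmetric: selection runs over unordered pairs.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 2 or vol.shape[0] != vol.shape[1] or vol.size == 0:
        raise ValueError("volume must be a non-empty square matrix")
    n = vol.shape[0]
    k = edge_count(pct, n)
    iu, ju = np.triu_indices(n, k=1)
    vals = vol[iu, ju].copy()
    ok = np.isfinite(vals)
    if valid is not None:
        ok &= valid[iu, ju]
    vals[~ok] = -np.inf
    k = min(k, int(ok.sum()))
    if k == 0:
        return EdgeSet(
            pairs=np.empty((0, 2), dtype=int),
            values=np.empty(0),
            pct=pct,
            n_dipoles=n,
        )
    # descending value, ascending flat index on ties
    order = np.lexsort((np.arange(vals.size), -vals))[:k]
    return EdgeSet(
        pairs=np.column_stack([iu[order], ju[order]]),
        values=vals[order],
        pct=pct,
        n_dipoles=n,
    )


@dataclass(frozen=True)
class Cluster:
    """A connected set of suprathreshold edges and its two dipole assemblies."""

    edges: np.ndarray  # (m, 2) oriented (assembly_a, assembly_b) endpoints
    assembly_a: np.ndarray  # dipole indices
    assembly_b: np.ndarray

    @property
    def is_auto_connection(self) -> bool:
        return bool(np.intersect1d(self.assembly_a, self.assembly_b).size)


def _neighbor_offsets() -> np.ndarray:
    """Half of the 728 nonzero 6-D Chebyshev-1 offsets (lexicographically > 0)."""
    rng = [-1, 0, 1]
    offs = np.array(np.meshgrid(*([rng] * 6), indexing="ij")).reshape(6, -1).T
    nz = np.any(offs != 0, axis=1)
    offs = offs[nz]
    # keep one of each +/- pair
    keep = []
    for o in offs:
        for c in o:
            if c > 0:
                keep.append(True)
                break
            if c < 0:
                keep.append(False)
                break
    return offs[np.array(keep)]


_HALF_OFFSETS = _neighbor_offsets()


def cluster_edges_6d(edges: EdgeSet, grid: SourceGrid) -> list[Cluster]:
    """Connected components of suprathreshold edges in 6-D grid space.

    Edges (i, j) and (k, l) are adjacent when dist(i, k) and dist(j, l) are
    both within one 26-neighborhood step (Chebyshev distance <= 1 on the
    lattice, i.e. Euclidean distance <= spacing * sqrt(3)), or the same with
    the (k, l) endpoints swapped.  Implemented by inserting both orderings of
    every edge into the 6-D lattice, labeling connected components under the
    full 3^6 - 1 neighborhood, and merging every component with its mirror
    image.  The orientation of each cluster's edges (which endpoint belongs
    to which assembly) is propagated through one chirality of the component.
    """
    K = edges.count
    if K == 0:
        return []
    lat = grid.lattice_indices
    # ordered voxels: first K are (i, j), next K the mirrored (j, i)
    a = np.concatenate([edges.pairs[:, 0], edges.pairs[:, 1]])
    b = np.concatenate([edges.pairs[:, 1], edges.pairs[:, 0]])
    coords = np.hstack([lat[a], lat[b]]).astype(np.int64)  # (2K, 6)
    shift = coords.min(axis=0)
    coords = coords - shift + 1
    base = int(coords.max()) + 3
    weights = base ** np.arange(6, dtype=np.int64)
    keys = coords @ weights
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    rows, cols = [], []
    for off in _HALF_OFFSETS:
        nk = keys + off @ weights
        pos = np.searchsorted(sorted_keys, nk)
        pos = np.clip(pos, 0, sorted_keys.size - 1)
        hit = sorted_keys[pos] == nk
        rows.append(np.nonzero(hit)[0])
        cols.append(order[pos[hit]])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    graph = coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(2 * K, 2 * K)
    )
    n_comp, labels = connected_components(graph, directed=False)
    # merge each component with its mirror (voxel v <-> v + K mod 2K)
    mirror_pairs = np.column_stack([labels[:K], labels[K:]])
    merge_graph = coo_matrix(
        (np.ones(K, dtype=np.int8), (mirror_pairs[:, 0], mirror_pairs[:, 1])),
        shape=(n_comp, n_comp),
    )
    _, merged = connected_components(merge_graph, directed=False)
    clusters = []
    for g in np.unique(merged):
        comp_labels = np.nonzero(merged == g)[0]
        rep = comp_labels.min()  # one chirality fixes the assembly orientation
        sel = np.nonzero(labels[: 2 * K] == rep)[0]
        firsts = a[sel]
        seconds = b[sel]
        clusters.append(
            Cluster(
                edges=np.column_stack([firsts, seconds]),
                assembly_a=np.unique(firsts),
                assembly_b=np.unique(seconds),
            )
        )
    return clusters


def filter_clusters(clusters: list[Cluster]) -> list[Cluster]:
    """Valid connections: clusters whose two assemblies are disjoint."""
    return [c for c in clusters if not c.is_auto_connection]


def score_detection(
    connections: list[Cluster],
    true_pair_positions: np.ndarray,
    grid_positions: np.ndarray,
    tolerance: float = HIT_TOLERANCE,
) -> tuple[bool, int]:
    """Hit flag and false-positive count against the true dipole pair.

    A connection matches when the summed distance of true dipole 1 to its
    closest voxel in one assembly and of true dipole 2 to its closest voxel
    in the other assembly is at most ``tolerance`` (both assembly pairings
    are tried).  Returns (hit, number of non-matching valid connections).
    """
    tp = np.asarray(true_pair_positions, dtype=float).reshape(2, 3)
    n_match = 0
    for c in connections:
        pa = grid_positions[c.assembly_a]
        pb = grid_positions[c.assembly_b]
        d1a = np.linalg.norm(pa - tp[0], axis=1).min()
        d2b = np.linalg.norm(pb - tp[1], axis=1).min()
        d1b = np.linalg.norm(pb - tp[0], axis=1).min()
        d2a = np.linalg.norm(pa - tp[1], axis=1).min()
        if min(d1a + d2b, d1b + d2a) <= tolerance:
            n_match += 1
    return n_match > 0, len(connections) - n_match


def near_active_false_positive(
    connections: list[Cluster],
    active_positions: np.ndarray,
    grid_positions: np.ndarray,
    tolerance: float = HIT_TOLERANCE,
) -> bool:
    """Does any connection fall in the direct vicinity of two active dipoles?

    True when some valid connection's assemblies are within the summed-
    distance tolerance of a pair of *distinct* activated dipoles.  In
    zero-coupling simulations every such connection is a false positive
    (leakage blur around activated sources masquerading as an interaction).
    """
    ap = np.asarray(active_positions, dtype=float)
    if ap.shape[0] < 2:
        return False
    for c in connections:
        pa = grid_positions[c.assembly_a]
        pb = grid_positions[c.assembly_b]
        da = np.linalg.norm(ap[:, None, :] - pa[None, :, :], axis=2).min(axis=1)
        db = np.linalg.norm(ap[:, None, :] - pb[None, :, :], axis=2).min(axis=1)
        summed = da[:, None] + db[None, :]
        np.fill_diagonal(summed, np.inf)
        if summed.min() <= tolerance:
            return True
    return False


def froc(records) -> "pandas.DataFrame":  # noqa: F821
    """FROC table: hit rate and mean false positives per threshold.

    ``records`` is an iterable of mappings with keys ``pct``, ``hit`` and
    ``n_false_positives`` (one per configuration x threshold), or a
    DataFrame with those columns.
    """
    import pandas as pd

    df = pd.DataFrame(records)
    out = (
        df.groupby("pct", sort=False)
        .agg(hit_rate=("hit", "mean"), mean_false_positives=("n_false_positives", "mean"))
        .reset_index()
    )
    return out.sort_values("pct", ascending=False, ignore_index=True)
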