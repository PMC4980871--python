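"""Pairwise distances in the input space.

Distances are stored condensed (upper triangle, pairs i < j), which keeps a
10^4-point problem (~5 x 10^7 distances) in a single flat array.  Each
:class:`DistanceSet` is tagged with the metric it came from so downstream
stages can tell exact geodesics from graph approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .shapes import PointCloud

__all__ = [
    "DistanceSet",
    "euclidean_distances",
    "arc_distances",
    "hamming_distances",
    "load_precomputed",
    "condensed_index",
]

_VALID_TAGS = {"euclidean", "hamming", "arc", "graph", "user"}


@dataclass
class DistanceSet:
    """Condensed collection of pairwise distances.

    ``values[k]`` is the distance between points ``i < j`` with
    ``k = condensed_index(i, j, n_points)`` when the set is complete
    (``is_complete``); geodesic sets restricted to a source subsample keep
    only the surviving pairs and set ``is_complete = False``.
    """

    values: np.ndarray
    n_points: int
    metric_tag: str = "user"
    is_complete: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.metric_tag not in _VALID_TAGS:
            raise ValueError(f"unknown metric_tag {self.metric_tag!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances contain non-finite values")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        expected = self.n_points * (self.n_points - 1) // 2
        if self.is_complete and len(self.values) != expected:
            raise ValueError(
                f"expected {expected} condensed distances for "
                f"{self.n_points} points, got {len(self.values)}")

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    def pair(self, i: int, j: int) -> float:
        """Distance between points i and j (complete sets only)."""
        if not self.is_complete:
            raise ValueError("pair lookup requires a complete distance set")
        if i == j:
            return 0.0
        return float(self.values[condensed_index(i, j, self.n_points)])

    def to_square(self) -> np.ndarray:
        if not self.is_complete:
            raise ValueError("cannot reshape an incomplete distance set")
        return squareform(self.values)


def condensed_index(i: int, j: int, n: int) -> int:
    """Position of pair (i, j), i != j, in the condensed upper triangle."""
    if i > j:
        i, j = j, i
    return n * i - (i * (i + 1)) // 2 + (j - i - 1)


def euclidean_distances(cloud: PointCloud) -> DistanceSet:
    """All-pairs Euclidean (L2) distances of a point cloud."""
    if cloud.n_points < 2:
        raise ValueError("need at least 2 points")
    return DistanceSet(pdist(cloud.coords), cloud.n_points, "euclidean")


def arc_distances(cloud: PointCloud, chunk: int = 512) -> DistanceSet:
    """Exact geodesic (arc-length) distances on the unit sphere.

    Rows are normalized defensively; distances are ``arccos`` of dot
    products, computed in row blocks so the full Gram matrix is never
    materialized.
    """
    X = cloud.coords
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm point cannot lie on the sphere")
    X = X / norms
    n = X.shape[0]
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for start in range(0, n - 1, chunk):
        stop = min(start + chunk, n - 1)
        block = np.arccos(np.clip(X[start:stop] @ X.T, -1.0, 1.0))
        for local, i in enumerate(range(start, stop)):
            m = n - i - 1
            out[pos:pos + m] = block[local, i + 1:]
            pos += m
    return DistanceSet(out, n, "arc")


def hamming_distances(alignment) -> DistanceSet:
    """Edit-count (Hamming) distances between aligned sequences.

    Any literal symbol mismatch counts as one edit; the gap symbol is an
    ordinary character, so two aligned gaps agree.  Input is an
    :class:`idgraph.io.MSA` or any object with equal-length ``sequences``.
    """
    seqs = list(alignment.sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    arr = np.array([list(s.upper().replace(".", "-")) for s in seqs])
    n = arr.shape[0]
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i in range(n - 1):
        m = n - i - 1
        out[pos:pos + m] = (arr[i + 1:] != arr[i]).sum(axis=1)
        pos += m
    return DistanceSet(out, n, "hamming")


def load_precomputed(matrix, n_points: int | None = None,
                     atol: float = 1e-8) -> DistanceSet:
    """Validate a user-supplied distance matrix (square or condensed).

    Square input must be symmetric within ``atol``, non-negative, with a
    zero diagonal.  A 1-D condensed vector needs ``n_points`` declared (or
    inferable from its length).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim == 2:
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix is not square: {m.shape}")
        if not np.allclose(m, m.T, atol=atol):
            raise ValueError(f"matrix is asymmetric beyond tolerance {atol}")
        if np.any(np.abs(np.diag(m)) > atol):
            raise ValueError("matrix has a nonzero diagonal")
        if np.any(m < -atol):
            raise ValueError("matrix has negative entries")
        sym = np.maximum(0.0, 0.5 * (m + m.T))
        np.fill_diagonal(sym, 0.0)
        return DistanceSet(squareform(sym, checks=False), m.shape[0], "user")
    if m.ndim == 1:
        if n_points is None:
            # infer N from len = N(N-1)/2
            n_points = int(round((1 + np.sqrt(1 + 8 * len(m))) / 2))
        if n_points * (n_points - 1) // 2 != len(m):
            raise ValueError(
                f"condensed length {len(m)} inconsistent with "
                f"n_points={n_points}")
        return DistanceSet(m, n_points, "user")
    raise ValueError("matrix must be 1-D (condensed) or 2-D (square)")
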