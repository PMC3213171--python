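"""Shortest Retroactive Distance (ShReD) and the derived modularity matrix.

The ShReD of an ordered vertex pair (i, j) is the shortest directed path
length i → j plus the shortest return path length j → i, in unit edge
counts.  It is finite exactly when i and j share a strongly connected
component, zero on the diagonal, and at least 2 off the diagonal (there are
no self-edges).  Infinity is represented by IEEE ``inf``, whose saturating
addition keeps unreachable pairs infinite through every sum.

The modularity matrix G compares each actual round trip against an expected
round trip P derived from the two endpoints' average finite ShReDs; a
shorter-than-expected round trip scores positive and pulls the pair into the
same module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .network import ReactionNetwork

__all__ = [
    "ShredMatrix",
    "ModularityMatrix",
    "all_pairs_shortest",
    "shred_matrix",
    "local_retroactivity_filter",
    "expected_shred",
    "modularity_matrix",
    "shred_modularity",
    "newman_connectivity_matrix",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class ShredMatrix:
    """Symmetric round-trip distance matrix aligned with a vertex order."""

    values: np.ndarray
    vertices: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", tuple(self.vertices))
        V = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", V)
        n = len(self.vertices)
        if V.shape != (n, n):
            raise ValueError(f"matrix shape {V.shape} does not match {n} vertices")
        if np.diag(V).any():
            raise ValueError("ShReD diagonal must be zero")
        if not np.array_equal(V, V.T):
            raise ValueError("ShReD matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.vertices)

    def finite_offdiagonal(self) -> np.ndarray:
        mask = np.isfinite(self.values)
        np.fill_diagonal(mask, False)
        return mask


@dataclass(frozen=True)
class ModularityMatrix:
    """Expected-vs-actual ShReD matrix G with its ingredients.

    ``P`` holds the expected round-trip lengths, ``D`` the per-vertex counts
    of finite non-zero ShReDs, and ``G = P − S`` on finite off-diagonal
    entries (zero on the diagonal and wherever the ShReD is infinite).
    """

    G: np.ndarray
    P: np.ndarray
    D: np.ndarray
    vertices: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.vertices)


def all_pairs_shortest(net: ReactionNetwork) -> np.ndarray:
    """Directed all-pairs shortest path matrix in unit edge counts
    (Floyd–Warshall); ``inf`` marks unreachable pairs, diagonal is zero."""
    if net.n == 0:
        return np.zeros((0, 0))
    return floyd_warshall(net.adjacency(), directed=True, unweighted=True)


def shred_matrix(d: np.ndarray, vertices: Sequence[str]) -> ShredMatrix:
    """Fold a directed distance matrix into the symmetric ShReD matrix
    S = d + dᵀ (forward plus return path; infinite if either is missing)."""
    d = np.asarray(d, dtype=float)
    if np.diag(d).any():
        raise ValueError("distance matrix must have a zero diagonal")
    return ShredMatrix(values=d + d.T, vertices=tuple(vertices))


def local_retroactivity_filter(S: ShredMatrix, limit: int = 2) -> ShredMatrix:
    """Restrict to local (nearest-neighbour) retroactivity: round trips
    longer than ``limit`` edges become infinite.  With the default limit of
    2 only reversible-reaction pairs and opposed irreversible pairs survive.
    Idempotent, and never creates finite entries."""
    if limit < 2:
        raise ValueError("limit must be at least 2")
    V = S.values.copy()
    V[V > limit] = np.inf
    return ShredMatrix(values=V, vertices=S.vertices)


def expected_shred(S: ShredMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Expected round-trip matrix P and finite-ShReD counts D.

    avg_i is the mean of vertex i's finite non-zero ShReDs (0 when it has
    none — such a vertex's G row is zeroed by the infinity rule anyway) and
    P[i, j] = (avg_i + avg_j) / 2.
    """
    mask = S.finite_offdiagonal()
    D = mask.sum(axis=1)
    sums = np.where(mask, S.values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        avg = np.where(D > 0, sums / np.maximum(D, 1), 0.0)
    P = (avg[:, None] + avg[None, :]) / 2.0
    return P, D


def modularity_matrix(
    S: ShredMatrix, P: np.ndarray, D: np.ndarray
) -> ModularityMatrix:
    """G[i, j] = P[i, j] − S[i, j] on finite off-diagonal entries, else 0."""
    mask = S.finite_offdiagonal()
    G = np.where(mask, P - S.values, 0.0)
    return ModularityMatrix(G=G, P=P, D=np.asarray(D), vertices=S.vertices)


def shred_modularity(
    net: ReactionNetwork, local_limit: int | None = None
) -> tuple[ShredMatrix, ModularityMatrix]:
    """Full pipeline for one (sub)network: distances → ShReD → (P, D) → G.

    ``local_limit`` applies the local-retroactivity ablation before the
    expected values are computed.
    """
    S = shred_matrix(all_pairs_shortest(net), net.vertices)
    if local_limit is not None:
        S = local_retroactivity_filter(S, local_limit)
    P, D = expected_shred(S)
    return S, modularity_matrix(S, P, D)


def newman_connectivity_matrix(net: ReactionNetwork) -> ModularityMatrix:
    """Newman's connectivity-based modularity matrix B = A − k kᵀ / (2m) on
    the undirected simple graph, as the baseline metric that ignores edge
    direction and retroactivity.  Every row sums to zero."""
    if net.n == 0:
        raise ValueError("network must be nonempty")
    A = net.adjacency()
    A = np.where((A + A.T) > 0, 1.0, 0.0)  # undirected simple graph
    k = A.sum(axis=1)
    m = k.sum() / 2.0
    B = A - (np.outer(k, k) / (2.0 * m) if m > 0 else 0.0)
    return ModularityMatrix(
        G=B, P=np.zeros_like(B), D=k.astype(int), vertices=net.vertices
    )


def write_matrix_tsv(
    M: np.ndarray, vertices: Sequence[str], path: str | Path
) -> None:
    """TSV export in the network's declared vertex order; infinite entries
    are spelled ``Inf`` literally."""
    vertices = tuple(vertices)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(vertices) + "\n")
        for i, v in enumerate(vertices):
            cells = [
                "Inf" if np.isinf(x) else format(float(x), "g") for x in np.asarray(M)[i]
            ]
            fh.write(v + "\t" + "\t".join(cells) + "\n")
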