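"""Recursive spectral bipartition of a reaction network by ShReD modularity.

Each connected subnetwork is split in two along the sign pattern of the
leading eigenvector of its modularity matrix, the split being accepted only
if (i) the modularity score Q is positive, (ii) the eigenvector carries both
signs, and (iii) — for the ShReD metrics — each daughter retains at least
one directed cycle, so that partitioning never strands a module without a
retroactive interaction.  Disconnected subnetworks are first separated into
their weakly connected components.  Applied recursively this yields a
hierarchical tree of modules, with "black" tree edges marking accepted
spectral splits and "red" edges marking component formation.

Distances, and hence G, are recomputed on every induced subnetwork: removing
vertices changes shortest paths, so parent matrices are never sliced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import count
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .network import ReactionNetwork, undirected_components
from .shred import ModularityMatrix, newman_connectivity_matrix, shred_modularity

__all__ = [
    "PartitionVector",
    "PartitionNode",
    "BipartitionRejection",
    "leading_eigenpair",
    "assign_sides",
    "modularity_score",
    "has_cycle",
    "try_bipartition",
    "partition_hierarchy",
    "tree_to_dict",
    "tree_to_json",
    "write_leaf_assignments_tsv",
    "write_tree_dot",
    "iter_nodes",
]

logger = logging.getLogger(__name__)

#: Q must exceed this to count as "greater than zero" (floating-point guard).
Q_TOL = 1e-9
#: eigenvector entries below this magnitude are treated as exact zeros
ZERO_TOL = 1e-12

METRIC_SHRED = "shred"
METRIC_NEWMAN = "newman"
METRIC_LOCAL = "local"
_METRICS = (METRIC_SHRED, METRIC_NEWMAN, METRIC_LOCAL)


@dataclass(frozen=True)
class PartitionVector:
    """Spectral solution for one bipartition attempt."""

    v: np.ndarray       # unit-norm leading eigenvector
    eigenvalue: float
    s: np.ndarray       # ±1 side assignments
    Q: float


@dataclass(frozen=True)
class BipartitionRejection:
    """Why a subnetwork was left unsplit."""

    reason: str  # 'too_small' | 'single_signed' | 'nonpositive_q' | 'acyclic_side'
    Q: float | None = None

    def __bool__(self) -> bool:
        return False


@dataclass
class PartitionNode:
    """One node of the hierarchical module tree.

    ``edge_kind`` describes the edge from the parent: ``black`` for an
    accepted spectral split, ``red`` for a connected-component separation,
    ``root`` for the root.  Children's member sets always partition the
    parent's members.
    """

    id: int
    members: tuple[str, ...]
    edge_kind: str = "root"
    children: list["PartitionNode"] = field(default_factory=list)
    Q: float | None = None              # score of the accepted split below this node
    rejection: str | None = None        # named criterion that stopped the recursion
    report: dict | None = None          # filled by module_metrics.annotate_tree

    @property
    def is_leaf(self) -> bool:
        return not self.children


def leading_eigenpair(G: np.ndarray) -> tuple[float, np.ndarray]:
    """Algebraically largest eigenpair of a symmetric matrix.

    The eigenvector is unit-norm with its sign canonicalized so that its
    first entry of magnitude above the zero tolerance is negative.  Either
    orientation yields the same split score, but exact-zero entries always
    land on the −1 side, so the orientation decides which side they join;
    fixing it makes the split deterministic and groups zero-entry vertices
    with the side containing the first vertex.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    w, V = np.linalg.eigh(G)
    return float(w[-1]), _canonical_sign(V[:, -1])


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    for x in v:
        if abs(x) > ZERO_TOL:
            return v if x < 0 else -v
    return v


def assign_sides(v: np.ndarray) -> np.ndarray:
    """Map an eigenvector to ±1 sides: strictly positive entries go to +1,
    non-positive entries — zeros included — to −1."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("eigenvector must be nonempty")
    return np.where(v > ZERO_TOL, 1.0, -1.0)


def modularity_score(G: np.ndarray, s: np.ndarray) -> float:
    """Q = Σ_i Σ_j G[i, j]·s_i·s_j, the full double sum over ordered pairs
    (the diagonal contributes zero by construction of G)."""
    s = np.asarray(s, dtype=float)
    return float(s @ np.asarray(G, dtype=float) @ s)


def _best_spectral_split(G: np.ndarray) -> PartitionVector:
    """Spectral solution with a tie-handling fallback: when the leading
    eigenvalue is (numerically) degenerate, each tied eigenvector's sign
    pattern is scored and the best Q kept (first in canonical order wins
    ties)."""
    w, V = np.linalg.eigh(np.asarray(G, dtype=float))
    lam = float(w[-1])
    tol = 1e-8 * max(1.0, abs(lam))
    tied = np.flatnonzero(w >= lam - tol)
    best: PartitionVector | None = None
    for k in tied:
        v = _canonical_sign(V[:, k])
        s = assign_sides(v)
        Q = modularity_score(G, s)
        if best is None or Q > best.Q + Q_TOL:
            best = PartitionVector(v=v, eigenvalue=float(w[k]), s=s, Q=Q)
    assert best is not None
    return best


def has_cycle(net: ReactionNetwork, members: Iterable[str] | None = None) -> bool:
    """Directed-cycle test by iterative removal of zero-in-degree vertices
    (topological-sort style): if every vertex can be peeled off the graph is
    acyclic; if at some point no vertex has zero incoming edges, a cycle
    remains."""
    sub = net if members is None else net.subgraph(members)
    indeg = {v: 0 for v in sub.vertices}
    succs: dict[str, list[str]] = {v: [] for v in sub.vertices}
    for (u, v) in sub.edges:
        indeg[v] += 1
        succs[u].append(v)
    frontier = [v for v, d in indeg.items() if d == 0]
    remaining = len(indeg)
    while frontier:
        v = frontier.pop()
        remaining -= 1
        for w in succs[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                frontier.append(w)
    return remaining > 0


def _submatrix(
    net: ReactionNetwork, members: Sequence[str], metric: str, local_limit: int
) -> tuple[ReactionNetwork, ModularityMatrix]:
    sub = net.subgraph(members)
    if metric == METRIC_NEWMAN:
        return sub, newman_connectivity_matrix(sub)
    limit = local_limit if metric == METRIC_LOCAL else None
    _, M = shred_modularity(sub, local_limit=limit)
    return sub, M


def try_bipartition(
    net: ReactionNetwork,
    members: Iterable[str] | None = None,
    *,
    metric: str = METRIC_SHRED,
    local_limit: int = 2,
) -> tuple[tuple[str, ...], tuple[str, ...], PartitionVector] | BipartitionRejection:
    """Attempt one spectral bipartition of the induced subnetwork.

    Returns the two sides (the one containing the smallest vertex id first)
    plus the spectral solution, or a :class:`BipartitionRejection` naming
    the failed criterion.  The modularity matrix is always recomputed on the
    induced subnetwork.  The daughter-cycle requirement applies to the ShReD
    metrics only; the Newman baseline uses Newman's original criteria.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    members = tuple(members) if members is not None else net.vertices
    if len(members) < 2:
        return BipartitionRejection("too_small")
    sub, M = _submatrix(net, members, metric, local_limit)
    pv = _best_spectral_split(M.G)
    if not (pv.s > 0).any() or not (pv.s < 0).any():
        return BipartitionRejection("single_signed", Q=pv.Q)
    if pv.Q <= Q_TOL:
        return BipartitionRejection("nonpositive_q", Q=pv.Q)
    side_a = tuple(v for v, si in zip(sub.vertices, pv.s) if si < 0)
    side_b = tuple(v for v, si in zip(sub.vertices, pv.s) if si > 0)
    if min(side_b) < min(side_a):
        side_a, side_b = side_b, side_a
    if metric != METRIC_NEWMAN:
        if not (has_cycle(sub, side_a) and has_cycle(sub, side_b)):
            return BipartitionRejection("acyclic_side", Q=pv.Q)
    return side_a, side_b, pv


def partition_hierarchy(
    net: ReactionNetwork,
    *,
    metric: str = METRIC_SHRED,
    local_limit: int = 2,
) -> PartitionNode:
    """Build the full hierarchical tree of binary partitions.

    At every node the members are first separated into weakly connected
    components (red children, only when more than one); a connected node is
    then offered to :func:`try_bipartition` (black children on acceptance).
    Node ids are assigned in deterministic preorder.
    """
    ids = count()

    def grow(members: tuple[str, ...], edge_kind: str) -> PartitionNode:
        node = PartitionNode(id=next(ids), members=members, edge_kind=edge_kind)
        comps = undirected_components(net.subgraph(members))
        if len(comps) > 1:
            logger.info(
                "node %d (n=%d): %d disconnected components", node.id, len(members), len(comps)
            )
            for comp in comps:
                ordered = tuple(v for v in net.vertices if v in comp)
                node.children.append(grow(ordered, "red"))
            return node
        result = try_bipartition(net, members, metric=metric, local_limit=local_limit)
        if isinstance(result, BipartitionRejection):
            node.rejection = result.reason
            logger.info(
                "node %d (n=%d): leaf, rejected (%s%s)",
                node.id,
                len(members),
                result.reason,
                "" if result.Q is None else f", Q={result.Q:.4g}",
            )
            return node
        side_a, side_b, pv = result
        node.Q = pv.Q
        logger.info(
            "node %d (n=%d): accepted split %d|%d, Q=%.4g",
            node.id,
            len(members),
            len(side_a),
            len(side_b),
            pv.Q,
        )
        node.children.append(grow(side_a, "black"))
        node.children.append(grow(side_b, "black"))
        return node

    return grow(net.vertices, "root")


# ---------------------------------------------------------------------------
# Tree serialization


def iter_nodes(root: PartitionNode):
    """Preorder traversal."""
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def tree_to_dict(root: PartitionNode) -> dict:
    return {
        "id": root.id,
        "edge_kind": root.edge_kind,
        "members": list(root.members),
        "Q": root.Q,
        "rejection": root.rejection,
        "report": root.report,
        "children": [tree_to_dict(c) for c in root.children],
    }


def tree_to_json(root: PartitionNode) -> str:
    import json

    return json.dumps(tree_to_dict(root), indent=2, sort_keys=True) + "\n"


def write_leaf_assignments_tsv(root: PartitionNode, path: str | Path) -> None:
    """Flat per-reaction table: reaction_id, leaf module id, leaf depth
    (black edges from the root)."""
    rows: list[tuple[str, int, int]] = []

    def walk(node: PartitionNode, depth: int) -> None:
        for child in node.children:
            walk(child, depth + (1 if child.edge_kind == "black" else 0))
        if node.is_leaf:
            for r in node.members:
                rows.append((r, node.id, depth))

    walk(root, 0)
    rows.sort()
    with open(path, "w") as fh:
        fh.write("reaction_id\tmodule_id\tdepth\n")
        for r, mid, depth in rows:
            fh.write(f"{r}\t{mid}\t{depth}\n")


def write_tree_dot(root: PartitionNode, path: str | Path) -> None:
    """Graphviz export; black edges are spectral splits, red edges are
    component separations."""
    lines = ["digraph partition_tree {", "  node [shape=box];"]
    for node in iter_nodes(root):
        label = f"module {node.id}\\nn={len(node.members)}"
        if node.report and node.report.get("dominant_group"):
            label += f"\\n{node.report['dominant_group']}"
        if node.Q is not None:
            label += f"\\nQ={node.Q:.3g}"
        lines.append(f'  n{node.id} [label="{label}"];')
        for child in node.children:
            color = "red" if child.edge_kind == "red" else "black"
            lines.append(f"  n{node.id} -> n{child.id} [color={color}];")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
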