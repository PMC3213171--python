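"""Per-module annotations: cycle counts, homogeneity, ShReD summaries,
depth and height in the partition tree."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .network import ReactionNetwork
from .partition import PartitionNode, iter_nodes
from .shred import ShredMatrix, all_pairs_shortest, shred_matrix

__all__ = [
    "ModuleReport",
    "count_cycles",
    "homogeneity_index",
    "group_fractions",
    "shred_summary",
    "annotate_tree",
    "write_module_report_tsv",
    "write_depth_aggregates_tsv",
]

CYCLE_CAP = 1000
NA_GROUP = "NA"


@dataclass(frozen=True)
class ModuleReport:
    """Metrics attached to one partition-tree node.

    ``n_cycles`` is the number of unique simple directed cycles, truncated
    at the cap (cycle counting is output-sensitive and can be exponential);
    ``cycles_capped`` records whether the cap was hit.  ``mean_shred`` is
    ``None`` when the module has no finite retroactive pair — a cycle-free
    module has no round trips, not round trips of length zero.  ``depth``
    and ``height`` count black (spectral-split) tree edges only.
    """

    n_reactions: int
    n_cycles: int
    cycles_capped: bool
    homogeneity: float | None
    group_fractions: dict[str, float] | None
    dominant_group: str | None
    mean_shred: float | None
    n_finite_shreds: int
    depth: int
    height: int


def count_cycles(
    net: ReactionNetwork, members: Iterable[str] | None = None, cap: int = CYCLE_CAP
) -> tuple[int, bool]:
    """Count unique simple directed cycles in the induced subgraph by
    Johnson's enumeration, aborting once ``cap`` cycles have been seen.
    Returns (count, capped)."""
    if cap < 1:
        raise ValueError("cap must be at least 1")
    sub = net if members is None else net.subgraph(members)
    n = 0
    for _ in nx.simple_cycles(sub.to_networkx()):
        n += 1
        if n >= cap:
            return cap, True
    return n, False


def group_fractions(
    members: Iterable[str], groups: Mapping[str, str] | None
) -> dict[str, float]:
    """Fraction of members per canonical group; members without a label
    fall into the implicit ``NA`` group.  Fractions sum to 1."""
    members = tuple(members)
    if not members:
        raise ValueError("empty member set")
    counts: dict[str, int] = {}
    for m in members:
        label = (groups or {}).get(m, NA_GROUP)
        counts[label] = counts.get(label, 0) + 1
    return {g: c / len(members) for g, c in sorted(counts.items())}


def homogeneity_index(
    members: Iterable[str], groups: Mapping[str, str] | None
) -> float:
    """Fraction of the module occupied by its best-represented canonical
    group (the largest pie slice); in (0, 1]."""
    return max(group_fractions(members, groups).values())


def shred_summary(S: ShredMatrix) -> tuple[float | None, int]:
    """(mean of finite off-diagonal ShReDs, number of finite unordered
    pairs); the mean is None when the module has no finite pair."""
    mask = np.triu(S.finite_offdiagonal())
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        return None, 0
    return float(S.values[mask].mean()), n_pairs


def annotate_tree(
    root: PartitionNode,
    net: ReactionNetwork,
    groups: Mapping[str, str] | None = None,
    cap: int = CYCLE_CAP,
) -> PartitionNode:
    """Attach a :class:`ModuleReport` to every node of a partition tree.

    Depth counts black edges from the root down to the node; height counts
    the longest black-edge path from the node to a descendant leaf.  Red
    (component-formation) edges contribute to neither.  ShReD summaries are
    computed on each node's induced subnetwork.
    """
    if groups is None:
        groups = net.groups

    def walk(node: PartitionNode, depth: int) -> int:
        height = 0
        for child in node.children:
            black = 1 if child.edge_kind == "black" else 0
            height = max(height, black + walk(child, depth + black))
        sub = net.subgraph(node.members)
        S = shred_matrix(all_pairs_shortest(sub), sub.vertices)
        mean_shred, n_finite = shred_summary(S)
        n_cycles, capped = count_cycles(sub, cap=cap)
        fracs = group_fractions(node.members, groups) if node.members else None
        node.report = asdict(
            ModuleReport(
                n_reactions=len(node.members),
                n_cycles=n_cycles,
                cycles_capped=capped,
                homogeneity=max(fracs.values()) if fracs else None,
                group_fractions=fracs,
                dominant_group=max(fracs, key=fracs.__getitem__) if fracs else None,
                mean_shred=mean_shred,
                n_finite_shreds=n_finite,
                depth=depth,
                height=height,
            )
        )
        return height

    walk(root, 0)
    return root


def write_module_report_tsv(root: PartitionNode, path: str | Path) -> None:
    """One row per tree node with the full ModuleReport."""
    cols = [
        "module_id",
        "n_reactions",
        "n_cycles",
        "homogeneity",
        "mean_shred",
        "n_finite_shreds",
        "depth",
        "height",
        "dominant_group",
        "is_leaf",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for node in iter_nodes(root):
            r = node.report or {}
            n_cycles = r.get("n_cycles")
            if r.get("cycles_capped"):
                n_cycles = f">={n_cycles}"
            mean_shred = r.get("mean_shred")
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        node.id,
                        r.get("n_reactions", len(node.members)),
                        n_cycles,
                        _fmt(r.get("homogeneity")),
                        _fmt(mean_shred),
                        r.get("n_finite_shreds"),
                        r.get("depth"),
                        r.get("height"),
                        r.get("dominant_group"),
                        int(node.is_leaf),
                    ]
                )
                + "\n"
            )


def _fmt(x) -> str:
    return "" if x is None else format(float(x), ".6g")


def write_depth_aggregates_tsv(root: PartitionNode, path: str | Path) -> None:
    """Per-depth (and per-height) aggregates across tree nodes: module
    count, mean cycles, mean homogeneity, mean ShReD, total finite ShReDs —
    the quantities plotted against depth/height in hierarchy analyses."""
    by_depth: dict[int, list[dict]] = {}
    for node in iter_nodes(root):
        if node.report:
            by_depth.setdefault(node.report["depth"], []).append(node.report)
    with open(path, "w") as fh:
        fh.write(
            "depth\tn_modules\tmean_n_cycles\tmean_homogeneity\t"
            "mean_mean_shred\ttotal_finite_shreds\tmean_height\n"
        )
        for depth in sorted(by_depth):
            reports = by_depth[depth]
            cycles = [r["n_cycles"] for r in reports]
            homog = [r["homogeneity"] for r in reports if r["homogeneity"] is not None]
            means = [r["mean_shred"] for r in reports if r["mean_shred"] is not None]
            total = sum(r["n_finite_shreds"] for r in reports)
            heights = [r["height"] for r in reports]
            fh.write(
                f"{depth}\t{len(reports)}\t{_fmt(np.mean(cycles))}\t"
                f"{_fmt(np.mean(homog) if homog else None)}\t"
                f"{_fmt(np.mean(means) if means else None)}\t{total}\t"
                f"{_fmt(np.mean(heights))}\n"
            )
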