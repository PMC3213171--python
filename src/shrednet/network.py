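"""Reaction-centric directed graph built from a stoichiometric model.

Vertices are reactions.  An edge i → j records that reaction i produces a
species that reaction j either consumes (substrate–product edge) or responds
to allosterically (regulatory edge).  Metabolites themselves are treated as
shared resources and do not appear as vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .model import ModelError, StoichiometricModel

__all__ = [
    "EdgeData",
    "ReactionNetwork",
    "build_reaction_graph",
    "undirected_components",
    "write_edge_list_tsv",
]

SUBSTRATE_PRODUCT = "substrate-product"
ALLOSTERIC = "allosteric"


@dataclass(frozen=True)
class EdgeData:
    """Provenance of a collapsed edge: every (species, kind) pair that
    mediates the interaction.  Parallel edges from multiple shared species
    collapse to one unweighted edge; the graph itself is unweighted."""

    mediators: tuple[tuple[str, str], ...]  # (species_id, kind)

    @property
    def kinds(self) -> frozenset[str]:
        return frozenset(kind for _, kind in self.mediators)

    @property
    def provenance(self) -> str:
        # a single label for reporting: substrate-product wins if both apply
        return SUBSTRATE_PRODUCT if SUBSTRATE_PRODUCT in self.kinds else ALLOSTERIC


@dataclass(frozen=True)
class ReactionNetwork:
    """Directed reaction graph with stable vertex order.

    ``vertices`` fixes the order used by every matrix downstream (ShReD,
    modularity); ``edges`` maps ordered pairs to mediator provenance.
    Self-edges are never stored.
    """

    vertices: tuple[str, ...]
    edges: dict[tuple[str, str], EdgeData]
    groups: dict[str, str] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", tuple(self.vertices))
        vset = set(self.vertices)
        if len(vset) != len(self.vertices):
            raise ModelError("duplicate vertex identifiers")
        for (u, v) in self.edges:
            if u not in vset or v not in vset:
                raise ModelError(f"edge ({u!r}, {v!r}) references unknown vertex")
            if u == v:
                raise ModelError(f"self-edge on {u!r} is not allowed")

    @property
    def n(self) -> int:
        return len(self.vertices)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def index(self, vertex: str) -> int:
        return self.vertices.index(vertex)

    def adjacency(self, order: Sequence[str] | None = None) -> np.ndarray:
        """0/1 adjacency matrix in the given (default: declared) order."""
        order = tuple(order) if order is not None else self.vertices
        pos = {v: i for i, v in enumerate(order)}
        A = np.zeros((len(order), len(order)))
        for (u, v) in self.edges:
            if u in pos and v in pos:
                A[pos[u], pos[v]] = 1.0
        return A

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for (u, v), data in self.edges.items():
            g.add_edge(u, v, mediators=data.mediators)
        return g

    def subgraph(self, members: Iterable[str]) -> "ReactionNetwork":
        """Induced subgraph; vertex order follows the parent's declared order."""
        keep = set(members)
        unknown = keep - set(self.vertices)
        if unknown:
            raise ModelError(f"unknown vertices: {sorted(unknown)}")
        verts = tuple(v for v in self.vertices if v in keep)
        edges = {
            (u, v): data for (u, v), data in self.edges.items() if u in keep and v in keep
        }
        groups = None
        if self.groups is not None:
            groups = {r: g for r, g in self.groups.items() if r in keep}
        return ReactionNetwork(vertices=verts, edges=edges, groups=groups)


def build_reaction_graph(model: StoichiometricModel) -> ReactionNetwork:
    """Construct the reaction-centric graph from stoichiometry and regulation.

    Edge rules
    ----------
    - substrate–product: i → j when some species m is producible by i and
      consumable by j.  An irreversible reaction produces its positive-
      coefficient species and consumes its negative-coefficient species; a
      reversible reaction can both produce and consume every species it
      touches, so its reactant and product sides contribute in both
      directions.
    - allosteric: i → j when a species producible by i has a nonzero entry
      for j in the regulatory matrix.  Activation and inhibition both create
      the edge; the sign is annotation only.

    Self-edges are discarded; multiple mediating species collapse onto one
    edge, with all mediators kept as provenance.
    """
    S, R = model.S, model.R
    rev = np.asarray(model.reversible, dtype=bool)
    producible = (S > 0) | (rev[np.newaxis, :] & (S != 0))
    consumable = (S < 0) | (rev[np.newaxis, :] & (S != 0))
    regulates = R != 0

    edges: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for m, species in enumerate(model.species_ids):
        producers = np.flatnonzero(producible[m])
        consumers = np.flatnonzero(consumable[m])
        targets = np.flatnonzero(regulates[m])
        for i in producers:
            src = model.reaction_ids[i]
            for j in consumers:
                if i == j:
                    continue
                edges.setdefault((src, model.reaction_ids[j]), []).append(
                    (species, SUBSTRATE_PRODUCT)
                )
            for j in targets:
                if i == j:
                    continue
                edges.setdefault((src, model.reaction_ids[j]), []).append(
                    (species, ALLOSTERIC)
                )
    return ReactionNetwork(
        vertices=model.reaction_ids,
        edges={
            pair: EdgeData(mediators=tuple(sorted(meds))) for pair, meds in edges.items()
        },
        groups=dict(model.groups) if model.groups is not None else None,
    )


def undirected_components(net: ReactionNetwork) -> list[set[str]]:
    """Weakly connected components via breadth-first traversal on the
    undirected view; returned in deterministic order (smallest member id
    first)."""
    if net.n == 0:
        return []
    comps = nx.connected_components(net.to_networkx().to_undirected())
    return sorted((set(c) for c in comps), key=lambda c: min(c))


def write_edge_list_tsv(net: ReactionNetwork, path: str | Path) -> None:
    """TSV export: source, target, provenance, comma-joined mediators."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tprovenance\tmediators\n")
        for (u, v) in sorted(net.edges):
            data = net.edges[(u, v)]
            meds = ",".join(f"{sp}[{kind}]" for sp, kind in data.mediators)
            fh.write(f"{u}\t{v}\t{data.provenance}\t{meds}\n")
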