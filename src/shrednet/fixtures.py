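"""Built-in example networks and random generators.

The centrepiece is an 8-reaction worked example: two directed triangles
(R1–R3 and R4–R6) joined into one strongly connected hexagon, plus a
detached 2-cycle (R7, R8) reachable through a single one-way bridge.  Its
ShReD matrix, modularity matrix, leading eigenvector, split score and final
module structure are all known in closed form, so the fixture doubles as an
end-to-end oracle: construction re-verifies every one of those values and
fails loudly on any drift.
"""

from __future__ import annotations

import math

import numpy as np

from .metrics import count_cycles
from .model import StoichiometricModel
from .network import EdgeData, ReactionNetwork, ALLOSTERIC, SUBSTRATE_PRODUCT
from .partition import (
    BipartitionRejection,
    has_cycle,
    leading_eigenpair,
    modularity_score,
    assign_sides,
    partition_hierarchy,
    try_bipartition,
)
from .shred import shred_modularity

__all__ = [
    "FixtureError",
    "FIG_EXAMPLE_EDGES",
    "example_network",
    "toy_stoichiometric_model",
    "random_cyclic_network",
]


class FixtureError(AssertionError):
    """An oracle check on a built-in fixture failed."""


#: Edge list of the worked example: triangle R1→R2→R3→R1 (R3→R1 being the
#: network's single allosteric inhibition), triangle R4→R5→R6→R4, the
#: hexagon closure R3→R4 / R6→R1, a one-way bridge R6→R7 into the
#: reversible-style pair R7⇄R8.
FIG_EXAMPLE_EDGES: tuple[tuple[str, str], ...] = (
    ("R1", "R2"),
    ("R2", "R3"),
    ("R3", "R1"),
    ("R3", "R4"),
    ("R4", "R5"),
    ("R5", "R6"),
    ("R6", "R4"),
    ("R6", "R1"),
    ("R6", "R7"),
    ("R7", "R8"),
    ("R8", "R7"),
)

EXAMPLE_GROUPS = {
    "R1": "GLYCO", "R2": "GLYCO", "R3": "GLYCO",
    "R4": "TCA", "R5": "TCA", "R6": "TCA",
    "R7": "TRANS", "R8": "TRANS",
}


def example_network(*, verify: bool = True, bridge: tuple[str, str] = ("R6", "R7")) -> ReactionNetwork:
    """The 8-reaction worked example as a plain edge-list network.

    ``bridge`` places the single one-way edge tying the hexagon to the
    {R7, R8} pair; any non-returning placement leaves every closed-form
    value unchanged (it creates no new cycle), which the verification
    asserts.  With ``verify`` (default) the full oracle suite runs on the
    constructed network and raises :class:`FixtureError` on any mismatch.
    """
    edges = [e for e in FIG_EXAMPLE_EDGES if e != ("R6", "R7")] + [bridge]
    if bridge[0] not in {f"R{i}" for i in range(1, 7)} or bridge[1] not in {"R7", "R8"}:
        raise ValueError("bridge must run from the hexagon into the R7/R8 pair")
    net = ReactionNetwork(
        vertices=tuple(f"R{i}" for i in range(1, 9)),
        edges={
            (u, v): EdgeData(
                mediators=((f"{u}->{v}", ALLOSTERIC if (u, v) == ("R3", "R1") else SUBSTRATE_PRODUCT),)
            )
            for (u, v) in edges
        },
        groups=dict(EXAMPLE_GROUPS),
    )
    if verify:
        verify_example(net)
    return net


def verify_example(net: ReactionNetwork, *, check_tree: bool = True) -> None:
    """Re-derive every closed-form scalar of the worked example and compare.

    ``check_tree`` additionally verifies the final module structure (three
    single-cycle terminal modules).  The printed scalars are invariant to
    any non-returning bridge placement, but the terminal structure also
    requires the bridge to run *between* the accepted sides so the
    component split can sever it.
    """

    def check(cond: bool, what: str) -> None:
        if not cond:
            raise FixtureError(f"worked-example oracle check failed: {what}")

    S, M = shred_modularity(net)
    idx = {v: i for i, v in enumerate(net.vertices)}
    from .shred import all_pairs_shortest  # local import to keep surface tidy

    d = all_pairs_shortest(net)
    check(d[idx["R1"], idx["R3"]] == 2, "forward distance R1→R3 is 2")
    check(d[idx["R3"], idx["R1"]] == 1, "return distance R3→R1 is 1")
    check(S.values[idx["R1"], idx["R3"]] == 3, "ShReD(R1,R3) = 3")
    # the alternative R1–R3 round trip through R4,R5,R6 has length 6
    check(
        d[idx["R3"], idx["R4"]] + d[idx["R4"], idx["R1"]] + d[idx["R1"], idx["R3"]] == 6,
        "second R1–R3 cycle has length 6",
    )
    avg = np.array(
        [
            np.mean([x for x in S.values[i] if 0 < x < math.inf]) for i in range(8)
        ]
    )
    check(abs(avg[idx["R1"]] - 4.8) < 1e-12, "average ShReD of R1 is 4.8")
    check(abs(avg[idx["R2"]] - 4.8) < 1e-12, "average ShReD of R2 is 4.8")
    check(abs(M.P[idx["R1"], idx["R2"]] - 4.8) < 1e-12, "P(R1,R2) = 4.8")
    check(abs(M.G[idx["R1"], idx["R2"]] - 1.8) < 1e-12, "G(R1,R2) = 1.8")

    lam, v = leading_eigenpair(M.G)
    mags = np.round(np.abs(v), 2)
    check(
        list(mags) == [0.41, 0.41, 0.41, 0.41, 0.41, 0.41, 0.0, 0.0],
        "leading eigenvector magnitudes are [0.41×6, 0, 0]",
    )
    signs = np.sign(np.round(v, 6))
    check(
        abs(sum(signs[:3])) == 3 and abs(sum(signs[3:6])) == 3 and signs[0] == -signs[3],
        "eigenvector splits the two triangles by sign",
    )
    Q = modularity_score(M.G, assign_sides(v))
    check(abs(Q - 43.2) < 1e-9, "Q = 43.2")

    result = try_bipartition(net)
    check(not isinstance(result, BipartitionRejection), "first split is accepted")
    side_a, side_b, _ = result  # type: ignore[misc]
    check(
        {frozenset(side_a), frozenset(side_b)}
        == {frozenset({"R1", "R2", "R3", "R7", "R8"}), frozenset({"R4", "R5", "R6"})},
        "accepted split is {R1,R2,R3,R7,R8} | {R4,R5,R6}",
    )

    if check_tree:
        leaves = list(_leaves(partition_hierarchy(net)))
        check(
            {frozenset(l.members) for l in leaves}
            == {frozenset({"R1", "R2", "R3"}), frozenset({"R4", "R5", "R6"}), frozenset({"R7", "R8"})},
            "three terminal modules",
        )
        for leaf in leaves:
            n_cycles, _ = count_cycles(net, leaf.members)
            check(n_cycles == 1, f"terminal module {set(leaf.members)} holds one cycle")
            check(has_cycle(net, leaf.members), "terminal module is cyclic")


def _leaves(node):
    if not node.children:
        yield node
    for child in node.children:
        yield from _leaves(child)


def toy_stoichiometric_model() -> StoichiometricModel:
    """Species-level model whose reaction graph is the worked example.

    Eleven metabolites feed eight irreversible reactions; M4 (the product of
    R3) allosterically inhibits R1, providing the network's single
    regulatory edge, and the opposed pair R7/R8 interconverts M10 and M11,
    forming the local 2-cycle.
    """
    species = tuple(f"M{i}" for i in range(1, 12))
    reactions = tuple(f"R{i}" for i in range(1, 9))
    #               reaction:  consumes      -> produces
    recipe = {
        "R1": ({"M1", "M8"}, {"M2"}),
        "R2": ({"M2"}, {"M3"}),
        "R3": ({"M3"}, {"M4"}),
        "R4": ({"M4", "M7"}, {"M5"}),
        "R5": ({"M5"}, {"M6"}),
        "R6": ({"M6"}, {"M7", "M8", "M9"}),
        "R7": ({"M9", "M10"}, {"M11"}),
        "R8": ({"M11"}, {"M10"}),
    }
    S = np.zeros((len(species), len(reactions)))
    for j, rid in enumerate(reactions):
        consumed, produced = recipe[rid]
        for m in consumed:
            S[species.index(m), j] = -1
        for m in produced:
            S[species.index(m), j] = 1
    R = np.zeros_like(S)
    R[species.index("M4"), reactions.index("R1")] = -1  # feedback inhibition
    return StoichiometricModel(
        species_ids=species,
        reaction_ids=reactions,
        S=S,
        reversible=(False,) * len(reactions),
        R=R,
        groups=dict(EXAMPLE_GROUPS),
    )


def random_cyclic_network(
    n: int, edge_prob: float, seed: int, *, max_tries: int = 1000
) -> ReactionNetwork:
    """Seeded Erdős–Rényi-style directed graph guaranteed to contain at
    least one directed cycle (resampled until it does).  The seed and the
    number of attempts are recorded in ``meta`` for provenance."""
    if n < 2:
        raise ValueError("need at least 2 vertices")
    if not 0 < edge_prob <= 1:
        raise ValueError("edge_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    vertices = tuple(f"R{i}" for i in range(1, n + 1))
    for attempt in range(1, max_tries + 1):
        mask = rng.random((n, n)) < edge_prob
        np.fill_diagonal(mask, False)
        edges = {
            (vertices[i], vertices[j]): EdgeData(mediators=((f"m{i}_{j}", SUBSTRATE_PRODUCT),))
            for i, j in zip(*np.nonzero(mask))
        }
        net = ReactionNetwork(
            vertices=vertices,
            edges=edges,
            meta={"seed": seed, "edge_prob": edge_prob, "attempts": attempt},
        )
        if has_cycle(net):
            return net
    raise RuntimeError(
        f"no cyclic graph found in {max_tries} draws (n={n}, p={edge_prob}, seed={seed})"
    )
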