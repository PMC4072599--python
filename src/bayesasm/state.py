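"""Assembly states and the bubble-aware proposal mechanism.

An assembly hypothesis is a boolean vector over the graph's edge indices.
A vector is *valid* when every node has at most one active incoming and at
most one active outgoing edge, so the active edges decompose into
vertex-disjoint paths and cycles, each spelling one contig.

A single perturbation picks one edge uniformly at random.  An active edge
is simply deactivated (splitting its path).  An inactive edge is activated
and extended from both endpoints by uniform random walks over inactive
edges until each walk meets the existing assembly or runs out of
continuations; the branch of the pre-existing assembly displaced between
the two attachment points is then deactivated.  This flips an entire
bubble branch in one move instead of waiting for each of its edges to
activate independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .graph import AssemblyGraph, spell_path

__all__ = [
    "AssemblyState",
    "random_state",
    "perturb",
    "propose",
    "validate",
    "active_paths",
    "active_contigs",
    "active_contigs_info",
    "state_to_line",
    "state_from_line",
    "state_summary_json",
]


@dataclass
class AssemblyState:
    """Boolean vector over edge indices; one assembly hypothesis."""

    active: np.ndarray  # bool, length E

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)

    def copy(self) -> "AssemblyState":
        return AssemblyState(self.active.copy())

    def key(self) -> bytes:
        """Hashable identity of the vector (for memoization)."""
        return self.active.tobytes()

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, AssemblyState) and np.array_equal(
            self.active, other.active
        )


def validate(s: AssemblyState, g: AssemblyGraph) -> bool:
    """True iff every node has <= 1 active incoming and <= 1 active
    outgoing edge (a path cannot take multiple branches through a bubble)."""
    if len(s.active) != g.n_edges:
        return False
    out_used = np.zeros(g.n_nodes, dtype=np.int64)
    in_used = np.zeros(g.n_nodes, dtype=np.int64)
    for ei in np.flatnonzero(s.active):
        src, tgt = g.edges[ei]
        out_used[src] += 1
        in_used[tgt] += 1
    return bool((out_used <= 1).all() and (in_used <= 1).all())


def active_paths(
    s: AssemblyState, g: AssemblyGraph
) -> list[tuple[list[int], bool]]:
    """Decompose the active edges into maximal paths and cycles.

    Returns (edge index list, is_cycle) per component, deterministically
    ordered.  Assumes ``s`` is valid.
    """
    nxt: dict[int, int] = {}  # node -> active out-edge
    has_in: set[int] = set()
    for ei in np.flatnonzero(s.active):
        src, tgt = g.edges[ei]
        nxt[src] = int(ei)
        has_in.add(tgt)
    comps: list[tuple[list[int], bool]] = []
    used: set[int] = set()
    # open paths start at a node with an active out-edge but no active in-edge
    for start in sorted(n for n in nxt if n not in has_in):
        path = []
        node = start
        while node in nxt and nxt[node] not in used:
            ei = nxt[node]
            path.append(ei)
            used.add(ei)
            node = g.edges[ei][1]
        comps.append((path, False))
    # remaining active edges form cycles
    for ei in sorted(int(i) for i in np.flatnonzero(s.active)):
        if ei in used:
            continue
        cyc = [ei]
        used.add(ei)
        node = g.edges[ei][1]
        while True:
            nei = nxt[node]
            if nei == ei:
                break
            cyc.append(nei)
            used.add(nei)
            node = g.edges[nei][1]
        comps.append((cyc, True))
    return comps


def active_contigs(s: AssemblyState, g: AssemblyGraph) -> list[str]:
    """Spelled contigs of the maximal active paths/cycles, longest first
    then lexicographic.  Isolated nodes contribute no contig."""
    return [c for c, _ in active_contigs_info(s, g)]


def active_contigs_info(
    s: AssemblyState, g: AssemblyGraph
) -> list[tuple[str, bool]]:
    """(contig, is_circular) per maximal active path/cycle, longest first.

    Circularity matters to the likelihood: reads may wrap the origin of a
    circular contig but not run off the end of a linear one.
    """
    contigs = [
        (spell_path(g, path), is_cycle) for path, is_cycle in active_paths(s, g)
    ]
    return sorted(contigs, key=lambda c: (-len(c[0]), c[0]))


def state_stats(s: AssemblyState, g: AssemblyGraph) -> tuple[int, int]:
    """(total assembled length, number of contigs)."""
    contigs = active_contigs(s, g)
    return sum(len(c) for c in contigs), len(contigs)


def _walk(
    vec: np.ndarray,
    g: AssemblyGraph,
    start: int,
    entered_by: int,
    rng: np.random.Generator,
    forward: bool,
    max_steps: int,
) -> int:
    """Random walk over inactive edges, activating them as it goes.

    The walk stops at the first node that already touches an active edge
    other than the one just traversed (it has "met the existing assembly",
    which includes the chain under construction, so the walk also stops
    cleanly if it loops back on itself), or at a node with no inactive
    continuation.  Returns the final node.
    """
    node = start
    for _ in range(max_steps):
        incident = g.out_edges(node) + g.in_edges(node)
        if any(vec[ei] and ei != entered_by for ei in incident):
            return node
        cand = [
            ei
            for ei in (g.out_edges(node) if forward else g.in_edges(node))
            if not vec[ei]
        ]
        if not cand:
            return node
        ei = cand[int(rng.integers(len(cand)))] if len(cand) > 1 else cand[0]
        vec[ei] = True
        entered_by = ei
        node = g.edges[ei][1] if forward else g.edges[ei][0]
    return node


def _active_out_edge(vec: np.ndarray, g: AssemblyGraph, node: int) -> int | None:
    for ei in g.out_edges(node):
        if vec[ei]:
            return ei
    return None


def _active_in_edge(vec: np.ndarray, g: AssemblyGraph, node: int) -> int | None:
    for ei in g.in_edges(node):
        if vec[ei]:
            return ei
    return None


def _try_activate(
    s: AssemblyState, g: AssemblyGraph, edge: int, rng: np.random.Generator
) -> AssemblyState | None:
    """Activate ``edge``, extend by random walks, displace the old branch."""
    old = s.active
    vec = old.copy()
    src, tgt = g.edges[edge]
    vec[edge] = True
    cap = 2 * g.n_edges + 2
    b = _walk(vec, g, tgt, edge, rng, forward=True, max_steps=cap)
    a = _walk(vec, g, src, edge, rng, forward=False, max_steps=cap)

    def _old_active_out(node: int) -> int | None:
        for ei in g.out_edges(node):
            if old[ei]:
                return ei
        return None

    def _old_active_in(node: int) -> int | None:
        for ei in g.in_edges(node):
            if old[ei]:
                return ei
        return None

    o_a = _old_active_out(a)
    i_b = _old_active_in(b)

    if o_a is not None:
        # trace the displaced branch of the pre-existing path from a to b
        seg = []
        ei = o_a
        found = False
        for _ in range(g.n_edges):
            seg.append(ei)
            node = g.edges[ei][1]
            if node == b:
                found = True
                break
            nxt = _old_active_out(node)
            if nxt is None or not old[nxt]:
                break
            ei = nxt
        if found:
            for e2 in seg:
                vec[e2] = False
            o_a = None
            i_b = None
    if o_a is not None:
        vec[o_a] = False
    if i_b is not None and vec[i_b]:
        vec[i_b] = False
    out = AssemblyState(vec)
    return out if validate(out, g) else None


def perturb(
    s: AssemblyState, g: AssemblyGraph, rng: np.random.Generator
) -> AssemblyState:
    """One random single-edge perturbation yielding a valid state.

    A perturbation that cannot produce a valid state is re-drawn; after E
    failed draws the state is returned unchanged.
    """
    E = g.n_edges
    for _ in range(E):
        edge = int(rng.integers(E))
        if s.active[edge]:
            out = s.copy()
            out.active[edge] = False
            return out
        out = _try_activate(s, g, edge, rng)
        if out is not None:
            return out
    return s.copy()


def propose(
    s: AssemblyState,
    g: AssemblyGraph,
    rng: np.random.Generator,
    n_perturbations: int = 3,
) -> AssemblyState:
    """Composition of ``n_perturbations`` single perturbations."""
    if n_perturbations < 1:
        raise ValueError("n_perturbations must be >= 1")
    for _ in range(n_perturbations):
        s = perturb(s, g, rng)
    return s


def random_state(g: AssemblyGraph, rng: np.random.Generator) -> AssemblyState:
    """Random valid initial state: E single perturbations applied to the
    all-inactive vector."""
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    s = AssemblyState(np.zeros(g.n_edges, dtype=bool))
    for _ in range(g.n_edges):
        s = perturb(s, g, rng)
    return s


# -- serialization ------------------------------------------------------


def state_to_line(s: AssemblyState) -> str:
    return "".join("1" if x else "0" for x in s.active)


def state_from_line(line: str) -> AssemblyState:
    return AssemblyState(np.array([c == "1" for c in line.strip()], dtype=bool))


def state_summary_json(s: AssemblyState, g: AssemblyGraph) -> str:
    total, n = state_stats(s, g)
    return json.dumps(
        {"total_length": total, "n_contigs": n, "n_active_edges": s.n_active}
    )
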