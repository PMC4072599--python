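"""Assembly graphs.

A de Bruijn graph of the reads (nodes = k-mers, edges = observed (k+1)-mer
adjacencies) is reduced to a minimal "bubble-only" assembly graph by

1. recursively trimming all tips (for a circular target genome every node of
   in- or out-degree zero is spurious and is removed to a fixpoint; for a
   linear genome only short tips are trimmed),
2. merging every unambiguous path into a single node whose annotation
   accumulates one extra nucleotide per merged k-mer, and
3. keeping the largest weakly connected component.

Paths of edges through the reduced graph spell candidate assemblies by
concatenating node annotations with k-1 overlap.  Edge indices are stable:
edges are enumerated sorted by (source annotation, target annotation), so a
boolean vector over edge indices is reproducible across runs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "AssemblyGraph",
    "build_debruijn",
    "trim_tips",
    "merge_unambiguous_paths",
    "largest_weak_component",
    "reduce_graph",
    "spell_path",
    "count_bubbles",
    "write_gfa",
    "read_gfa",
    "write_dot",
]

_ACGT = frozenset("ACGT")


class AssemblyGraph:
    """Directed graph of sequence-annotated nodes with stably indexed edges.

    Node ids are 0..N-1 assigned in lexicographic order of the node
    annotations; edges are sorted by (source annotation, target annotation).
    Instances are immutable by convention: reduction operations return new
    graphs.
    """

    def __init__(
        self,
        k: int,
        seqs: Sequence[str],
        edges: Iterable[tuple[int, int]],
        _normalized: bool = False,
    ) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        if _normalized:
            self.seqs = tuple(seqs)
            self.edges = tuple(edges)
        else:
            order = sorted(range(len(seqs)), key=lambda i: (seqs[i], i))
            remap = {old: new for new, old in enumerate(order)}
            self.seqs = tuple(seqs[i] for i in order)
            eset = {(remap[s], remap[t]) for s, t in edges}
            self.edges = tuple(
                sorted(eset, key=lambda e: (self.seqs[e[0]], self.seqs[e[1]]))
            )
        for s, t in self.edges:
            if not (0 <= s < len(self.seqs) and 0 <= t < len(self.seqs)):
                raise ValueError(f"edge ({s},{t}) references a missing node")
        self._out: dict[int, list[int]] = defaultdict(list)
        self._in: dict[int, list[int]] = defaultdict(list)
        for idx, (s, t) in enumerate(self.edges):
            self._out[s].append(idx)
            self._in[t].append(idx)

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.seqs)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_edges(self, node: int) -> list[int]:
        """Edge indices leaving ``node``."""
        return self._out.get(node, [])

    def in_edges(self, node: int) -> list[int]:
        return self._in.get(node, [])

    def out_degree(self, node: int) -> int:
        return len(self._out.get(node, ()))

    def in_degree(self, node: int) -> int:
        return len(self._in.get(node, ()))

    def total_annotation_length(self) -> int:
        return sum(len(s) for s in self.seqs)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AssemblyGraph)
            and self.k == other.k
            and self.seqs == other.seqs
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"AssemblyGraph(k={self.k}, nodes={self.n_nodes}, "
            f"edges={self.n_edges})"
        )


def _kmer_windows(seq: str, k: int) -> Iterable[str]:
    """All length-k windows of ``seq`` made only of A/C/G/T."""
    if set(seq) <= _ACGT:
        for i in range(len(seq) - k + 1):
            yield seq[i : i + k]
    else:
        bad = [i for i, c in enumerate(seq) if c not in _ACGT]
        ok_until = -1
        bi = 0
        for i in range(len(seq) - k + 1):
            while bi < len(bad) and bad[bi] < i:
                bi += 1
            if bi < len(bad) and bad[bi] < i + k:
                continue
            yield seq[i : i + k]


def build_debruijn(reads, k: int, min_count: int = 1) -> AssemblyGraph:
    """Build the de Bruijn graph of the reads.

    ``reads`` is an iterable of strings or objects with a ``bases``
    attribute.  One node per distinct k-mer with abundance >= ``min_count``;
    one edge per observed (k+1)-mer whose two constituent k-mers are both
    kept.  Windows containing non-ACGT characters (e.g. N) are skipped.
    No reverse-complement canonicalization is performed: callers are
    expected to orient reads onto a single strand first
    (see :func:`bayesasm.read_io.oriented_sequences`).
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be odd and >= 3")
    seqs = [getattr(r, "bases", r) for r in reads]
    if not any(len(s) >= k for s in seqs):
        raise ValueError(f"no read reaches length k={k}; graph would be empty")
    counts: Counter[str] = Counter()
    adjacencies: set[str] = set()
    for s in seqs:
        s = s.upper()
        counts.update(_kmer_windows(s, k))
        adjacencies.update(_kmer_windows(s, k + 1))
    kept = {kmer for kmer, c in counts.items() if c >= min_count}
    node_seqs = sorted(kept)
    index = {kmer: i for i, kmer in enumerate(node_seqs)}
    edges = set()
    for adj in adjacencies:
        a, b = adj[:-1], adj[1:]
        if a in index and b in index:
            edges.add((index[a], index[b]))
    return AssemblyGraph(k, node_seqs, edges)


def _subgraph(g: AssemblyGraph, keep: set[int]) -> AssemblyGraph:
    seqs = [g.seqs[i] for i in sorted(keep)]
    remap = {old: new for new, old in enumerate(sorted(keep))}
    edges = [
        (remap[s], remap[t]) for s, t in g.edges if s in keep and t in keep
    ]
    return AssemblyGraph(g.k, seqs, edges)


def trim_tips(g: AssemblyGraph, linear: bool = False) -> AssemblyGraph:
    """Recursively remove all tips.

    Circular mode (default): remove every node of in-degree 0 or out-degree
    0, repeatedly, until none remain (removing a tip may expose a new one).
    A self-edge gives its node in- and out-degree 1, so a fully collapsed
    cycle survives.

    Linear mode: only tip chains whose spelled length is shorter than 2k are
    removed (a softer threshold appropriate when true sequence ends exist).
    """
    if not linear:
        indeg = {n: g.in_degree(n) for n in range(g.n_nodes)}
        outdeg = {n: g.out_degree(n) for n in range(g.n_nodes)}
        alive = set(range(g.n_nodes))
        queue = [n for n in alive if indeg[n] == 0 or outdeg[n] == 0]
        while queue:
            n = queue.pop()
            if n not in alive:
                continue
            alive.discard(n)
            for ei in g.out_edges(n):
                t = g.edges[ei][1]
                if t in alive:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        queue.append(t)
            for ei in g.in_edges(n):
                s = g.edges[ei][0]
                if s in alive:
                    outdeg[s] -= 1
                    if outdeg[s] == 0:
                        queue.append(s)
        return _subgraph(g, alive)

    # linear mode: iterate to fixpoint, removing short dangling chains
    cur = g
    changed = True
    while changed:
        changed = False
        k = cur.k
        to_remove: set[int] = set()
        for start in range(cur.n_nodes):
            source_tip = cur.in_degree(start) == 0
            sink_tip = cur.out_degree(start) == 0
            if not (source_tip or sink_tip):
                continue
            # follow the unambiguous chain inward from the tip end
            chain = [start]
            node = start
            step = (
                (lambda n: cur.edges[cur.out_edges(n)[0]][1])
                if source_tip
                else (lambda n: cur.edges[cur.in_edges(n)[0]][0])
            )
            fwd_deg = cur.out_degree if source_tip else cur.in_degree
            back_deg = cur.in_degree if source_tip else cur.out_degree
            while fwd_deg(node) == 1:
                nxt = step(node)
                if back_deg(nxt) != 1 or nxt in chain:
                    break
                chain.append(nxt)
                node = nxt
            length = len(cur.seqs[chain[0]]) + sum(
                len(cur.seqs[n]) - (k - 1) for n in chain[1:]
            )
            if length < 2 * k:
                to_remove.update(chain)
        if to_remove:
            cur = _subgraph(cur, set(range(cur.n_nodes)) - to_remove)
            changed = True
    return cur


def merge_unambiguous_paths(g: AssemblyGraph) -> AssemblyGraph:
    """Merge every maximal unambiguous chain into a single node.

    An edge (u, v), u != v, is mergeable when u has out-degree 1 and v has
    in-degree 1; chains of mergeable edges collapse to one node whose
    annotation is the first node's annotation extended by each subsequent
    node's annotation minus the k-1 overlap.  A fully unambiguous cycle
    collapses to a single node carrying one self-edge, so every non-empty
    reduced graph keeps at least one edge.
    """
    k = g.k
    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    for s, t in g.edges:
        if s != t and g.out_degree(s) == 1 and g.in_degree(t) == 1:
            succ[s] = t
            pred[t] = s

    visited: set[int] = set()
    groups: list[tuple[list[int], bool]] = []  # (chain nodes, is_cycle)
    # open chains first: start where a mergeable run begins
    for n in range(g.n_nodes):
        if n in visited:
            continue
        if (n in succ or n in pred) and n not in pred:
            chain = [n]
            node = n
            while node in succ:
                node = succ[node]
                chain.append(node)
            visited.update(chain)
            groups.append((chain, False))
    # remaining mergeable nodes form pure cycles
    for n in range(g.n_nodes):
        if n in visited or n not in succ:
            continue
        cycle = [n]
        node = succ[n]
        while node != n:
            cycle.append(node)
            node = succ[node]
        visited.update(cycle)
        # deterministic start: lexicographically smallest annotation
        start = min(range(len(cycle)), key=lambda i: (g.seqs[cycle[i]], cycle[i]))
        cycle = cycle[start:] + cycle[:start]
        groups.append((cycle, True))

    node_map: dict[int, int] = {}
    new_seqs: list[str] = []
    self_edges: list[int] = []
    for chain, is_cycle in groups:
        seq = g.seqs[chain[0]]
        for n in chain[1:]:
            seq += g.seqs[n][k - 1 :]
        nid = len(new_seqs)
        new_seqs.append(seq)
        for n in chain:
            node_map[n] = nid
        if is_cycle:
            self_edges.append(nid)
    for n in range(g.n_nodes):
        if n not in node_map:
            node_map[n] = len(new_seqs)
            new_seqs.append(g.seqs[n])

    consumed = set()
    for chain, is_cycle in groups:
        for a, b in zip(chain, chain[1:]):
            consumed.add((a, b))
        if is_cycle:
            consumed.add((chain[-1], chain[0]))
    new_edges = {
        (node_map[s], node_map[t]) for s, t in g.edges if (s, t) not in consumed
    }
    new_edges.update((nid, nid) for nid in self_edges)
    return AssemblyGraph(k, new_seqs, new_edges)


def largest_weak_component(g: AssemblyGraph) -> AssemblyGraph:
    """Subgraph induced by the weakly connected component of greatest total
    annotation length (ties: the component containing the lexicographically
    smallest annotation)."""
    if g.n_nodes == 0:
        raise ValueError("empty graph has no components")
    comps = list(nx.weakly_connected_components(g.to_networkx()))
    best = sorted(
        comps,
        key=lambda c: (
            -sum(len(g.seqs[n]) for n in c),
            min(g.seqs[n] for n in c),
        ),
    )[0]
    return _subgraph(g, set(best))


def reduce_graph(g: AssemblyGraph, linear: bool = False) -> AssemblyGraph:
    """Full reduction: trim tips, merge unambiguous paths, keep the largest
    weakly connected component."""
    g = trim_tips(g, linear=linear)
    if g.n_nodes == 0:
        return g
    g = merge_unambiguous_paths(g)
    return largest_weak_component(g)


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically minimal rotation of ``s``."""
    if not s:
        return s
    ss = s + s
    f = [-1] * len(ss)
    least = 0
    for j in range(1, len(ss)):
        c = ss[j]
        i = f[j - least - 1]
        while i != -1 and c != ss[least + i + 1]:
            if c < ss[least + i + 1]:
                least = j - i - 1
            i = f[i]
        if c != ss[least + i + 1]:
            if c < ss[least]:
                least = j
            f[j - least] = -1
        else:
            f[j - least] = i + 1
    return ss[least : least + len(s)]


def spell_path(
    g: AssemblyGraph, path: Sequence[int], start_node: int | None = None
) -> str:
    """Spell the contig of a contiguous edge path.

    The first node's annotation is extended, for each subsequent node, by
    its annotation minus the first k-1 characters.  For a closed cycle
    (target of the last edge equals source of the first) the trailing k-1
    characters are trimmed and the string is rotated to its lexicographically
    minimal rotation, giving a canonical circular spelling.  An empty path
    with ``start_node`` spells that node's annotation.
    """
    k = g.k
    if not path:
        if start_node is None:
            raise ValueError("empty path requires start_node")
        return g.seqs[start_node]
    seen = set()
    for ei in path:
        if ei in seen:
            raise ValueError(f"edge {ei} repeated in path")
        seen.add(ei)
    for a, b in zip(path, path[1:]):
        if g.edges[a][1] != g.edges[b][0]:
            raise ValueError("path is not contiguous")
    closed = g.edges[path[-1]][1] == g.edges[path[0]][0]
    nodes = [g.edges[path[0]][0]] + [g.edges[ei][1] for ei in path]
    if closed:
        nodes = nodes[:-1]
    out = [g.seqs[nodes[0]]]
    for n in nodes[1:]:
        out.append(g.seqs[n][k - 1 :])
    s = "".join(out)
    if closed:
        s = s[: len(s) - (k - 1)]
        s = _least_rotation(s)
    return s


def count_bubbles(g: AssemblyGraph) -> int:
    """Number of fork nodes (out-degree >= 2), i.e. bubble openings."""
    return sum(1 for n in range(g.n_nodes) if g.out_degree(n) >= 2)


# -- serialization ------------------------------------------------------


def write_gfa(g: AssemblyGraph, path: str | Path) -> None:
    """Write GFA1: S-lines carry node annotations, L-lines the k-1 overlap."""
    with open(path, "w") as fh:
        fh.write(f"H\tVN:Z:1.0\tks:i:{g.k}\n")
        for i, seq in enumerate(g.seqs):
            fh.write(f"S\tn{i}\t{seq}\n")
        for s, t in g.edges:
            fh.write(f"L\tn{s}\t+\tn{t}\t+\t{g.k - 1}M\n")


def read_gfa(path: str | Path) -> AssemblyGraph:
    k = None
    names: list[str] = []
    seqs: list[str] = []
    links: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "H":
                for tag in parts[1:]:
                    if tag.startswith("ks:i:"):
                        k = int(tag.split(":")[2])
            elif parts[0] == "S":
                names.append(parts[1])
                seqs.append(parts[2])
            elif parts[0] == "L":
                links.append((parts[1], parts[3]))
                if k is None and parts[5].endswith("M"):
                    k = int(parts[5][:-1]) + 1
    if k is None:
        raise ValueError("cannot determine k from GFA (no ks header or L line)")
    index = {name: i for i, name in enumerate(names)}
    edges = [(index[a], index[b]) for a, b in links]
    return AssemblyGraph(k, seqs, edges)


def _ramp_color(x: float) -> str:
    """Grey (0.0) to dark red (1.0) hex ramp."""
    x = min(1.0, max(0.0, x))
    grey = (190, 190, 190)
    dark_red = (139, 0, 0)
    rgb = tuple(round(g + (r - g) * x) for g, r in zip(grey, dark_red))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def write_dot(
    g: AssemblyGraph,
    path: str | Path,
    node_freqs: Sequence[float] | None = None,
    edge_freqs: Sequence[float] | None = None,
) -> None:
    """Write DOT with node size proportional to log sequence length and an
    optional posterior color ramp (grey 0.0 -> dark red 1.0)."""
    import math

    with open(path, "w") as fh:
        fh.write("digraph assembly {\n")
        for i, seq in enumerate(g.seqs):
            size = 0.3 + 0.25 * math.log10(max(len(seq), 1))
            attrs = [
                f'label="n{i}\\n{len(seq)}bp"',
                f"width={size:.2f}",
                f"height={size:.2f}",
                "style=filled",
            ]
            if node_freqs is not None:
                attrs.append(f'fillcolor="{_ramp_color(node_freqs[i])}"')
            else:
                attrs.append('fillcolor="#bebebe"')
            fh.write(f"  n{i} [{', '.join(attrs)}];\n")
        for idx, (s, t) in enumerate(g.edges):
            attrs = []
            if edge_freqs is not None:
                attrs.append(f'color="{_ramp_color(edge_freqs[idx])}"')
                attrs.append(f'label="{edge_freqs[idx]:.2f}"')
            suffix = f" [{', '.join(attrs)}]" if attrs else ""
            fh.write(f"  n{s} -> n{t}{suffix};\n")
        fh.write("}\n")
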