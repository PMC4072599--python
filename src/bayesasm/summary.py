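"""Posterior summaries: convergence diagnostics, majority-rule consensus,
and posterior annotation of external assemblies.

Edge (and node) sampling frequencies approximate posterior probabilities of
assembly features.  The majority-rule consensus activates every edge whose
frequency reaches a threshold (default 0.5), resolving validity conflicts
greedily by descending frequency, and spells the resulting paths into
contigs annotated with the minimum edge posterior along each contig.
External assemblies (FASTA) are annotated by exact matching: a node matches
if its annotation occurs as an exact substring of an external contig on
either strand; an edge matches through its junction (k+1)-mer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import AssemblyGraph, write_dot, write_gfa
from .read_io import revcomp, write_fasta
from .sampler import ChainTrace, cumulative_edge_frequencies
from .state import AssemblyState, active_paths, validate
from .graph import spell_path

__all__ = [
    "ConsensusAssembly",
    "FeatureAnnotation",
    "cross_chain_sd",
    "frequency_agreement",
    "majority_consensus",
    "annotate_external",
    "write_outputs",
]


@dataclass
class ConsensusAssembly:
    """Majority-rule consensus: a valid state plus annotated contigs."""

    state: AssemblyState
    contigs: list[tuple[str, float]]  # (sequence, min edge posterior)
    threshold: float
    dropped_edges: list[int]  # supra-threshold edges removed for validity
    tie_edges: list[int]  # edges involved in frequency ties at a conflict


@dataclass(frozen=True)
class FeatureAnnotation:
    """Posterior and external-assembly matches for one graph feature."""

    feature_id: str  # "node:<i>" or "edge:<i>"
    posterior: float
    matched_in: frozenset[str]


def cross_chain_sd(chains: Sequence[ChainTrace]) -> np.ndarray:
    """Average-over-edges SD across chains of cumulative edge frequencies,
    one value per sample index (the convergence diagnostic series)."""
    if len(chains) < 2:
        raise ValueError("need >= 2 chains")
    lengths = {t.n_records for t in chains}
    if len(lengths) != 1:
        raise ValueError("chains must have equal record counts")
    cums = np.stack([cumulative_edge_frequencies(t) for t in chains])
    # cums: (n_chains, R, E); SD across chains, mean over edges
    return cums.std(axis=0, ddof=0).mean(axis=1)


def frequency_agreement(
    chain_a: ChainTrace, chain_b: ChainTrace
) -> tuple[list[tuple[float, float]], float]:
    """Paired final cumulative edge frequencies and their max abs deviation."""
    fa = chain_a.vectors.mean(axis=0)
    fb = chain_b.vectors.mean(axis=0)
    pairs = list(zip(fa.tolist(), fb.tolist()))
    max_dev = float(np.abs(fa - fb).max()) if len(fa) else 0.0
    return pairs, max_dev


def majority_consensus(
    freqs: np.ndarray,
    g: AssemblyGraph,
    threshold: float = 0.5,
) -> ConsensusAssembly:
    """Activate edges with frequency >= threshold, resolving validity
    conflicts greedily by descending frequency (ties: lower edge index,
    flagged in the output)."""
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != g.n_edges:
        raise ValueError("frequency vector length != number of edges")
    order = sorted(
        (i for i in range(g.n_edges) if freqs[i] >= threshold),
        key=lambda i: (-freqs[i], i),
    )
    active = np.zeros(g.n_edges, dtype=bool)
    out_used: set[int] = set()
    in_used: set[int] = set()
    dropped: list[int] = []
    tie_edges: list[int] = []
    for ei in order:
        s, t = g.edges[ei]
        if s in out_used or t in in_used:
            dropped.append(ei)
            # flag ties: another supra-threshold edge at the same node with
            # the same frequency was kept instead
            for ej in order:
                if ej == ei or not active[ej]:
                    continue
                s2, t2 = g.edges[ej]
                if (s2 == s or t2 == t) and freqs[ej] == freqs[ei]:
                    tie_edges.extend([ej, ei])
            continue
        active[ei] = True
        out_used.add(s)
        in_used.add(t)
    state = AssemblyState(active)
    assert validate(state, g)
    contigs: list[tuple[str, float]] = []
    for path, _is_cycle in active_paths(state, g):
        seq = spell_path(g, path)
        post = float(min(freqs[ei] for ei in path))
        contigs.append((seq, post))
    contigs.sort(key=lambda c: (-len(c[0]), c[0]))
    return ConsensusAssembly(
        state=state,
        contigs=contigs,
        threshold=threshold,
        dropped_edges=sorted(dropped),
        tie_edges=sorted(set(tie_edges)),
    )


def _junction_string(g: AssemblyGraph, edge_idx: int) -> str:
    """(k+1)-length string spanning an edge after overlap merge."""
    s, t = g.edges[edge_idx]
    k = g.k
    return g.seqs[s][-k:] + g.seqs[t][k - 1 : k]


def annotate_external(
    g: AssemblyGraph,
    edge_freqs: np.ndarray,
    node_freqs: np.ndarray,
    external: dict[str, Sequence[str]],
) -> list[FeatureAnnotation]:
    """Annotate graph features with posteriors and exact matches against
    external assemblies.

    ``external`` maps assembly name to its contig sequences.  A feature
    matches an assembly iff its sequence (node annotation, or edge junction
    string) occurs exactly, on either strand, in some contig.
    """
    haystacks = {}
    for name, contigs in external.items():
        if not contigs:
            raise ValueError(f"external assembly {name!r} has no sequences")
        haystacks[name] = [(c.upper(), revcomp(c.upper())) for c in contigs]

    def _matches(query: str) -> frozenset[str]:
        found = set()
        for name, seqs in haystacks.items():
            for fwd, rc in seqs:
                if query in fwd or query in rc:
                    found.add(name)
                    break
        return frozenset(found)

    out: list[FeatureAnnotation] = []
    for i, seq in enumerate(g.seqs):
        out.append(
            FeatureAnnotation(f"node:{i}", float(node_freqs[i]), _matches(seq))
        )
    for ei in range(g.n_edges):
        out.append(
            FeatureAnnotation(
                f"edge:{ei}", float(edge_freqs[ei]), _matches(_junction_string(g, ei))
            )
        )
    return out


def write_feature_tsv(
    annotations: Sequence[FeatureAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tposterior\tmatched_in\n")
        for a in annotations:
            fh.write(
                f"{a.feature_id}\t{a.posterior:.6f}\t"
                f"{','.join(sorted(a.matched_in))}\n"
            )


def read_feature_tsv(path: str | Path) -> list[FeatureAnnotation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            fid, post, matched = line.rstrip("\n").split("\t")
            names = frozenset(n for n in matched.split(",") if n)
            out.append(FeatureAnnotation(fid, float(post), names))
    return out


def write_outputs(
    consensus: ConsensusAssembly,
    edge_freqs: np.ndarray,
    g: AssemblyGraph,
    outdir: str | Path,
    node_freqs: np.ndarray | None = None,
    diagnostics: dict | None = None,
) -> dict[str, Path]:
    """Write consensus FASTA (posterior-annotated headers), annotated
    GFA/DOT, a feature TSV and optional diagnostics JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "consensus.fasta"
    records = [
        (f"contig{i} posterior={post:.3f} length={len(seq)}", seq)
        for i, (seq, post) in enumerate(consensus.contigs)
    ]
    write_fasta(records, fasta)
    paths["fasta"] = fasta
    if not consensus.contigs:
        import warnings

        warnings.warn("consensus assembly is empty; FASTA has no records")

    gfa = outdir / "graph.gfa"
    write_gfa(g, gfa)
    paths["gfa"] = gfa

    if node_freqs is None:
        node_freqs = np.zeros(g.n_nodes)
        for ei in range(g.n_edges):
            s, t = g.edges[ei]
            node_freqs[s] = max(node_freqs[s], edge_freqs[ei])
            node_freqs[t] = max(node_freqs[t], edge_freqs[ei])
    dot = outdir / "graph.dot"
    write_dot(g, dot, node_freqs=node_freqs, edge_freqs=edge_freqs)
    paths["dot"] = dot

    tsv = outdir / "features.tsv"
    annotations = [
        FeatureAnnotation(f"node:{i}", float(node_freqs[i]), frozenset())
        for i in range(g.n_nodes)
    ] + [
        FeatureAnnotation(f"edge:{i}", float(edge_freqs[i]), frozenset())
        for i in range(g.n_edges)
    ]
    write_feature_tsv(annotations, tsv)
    paths["tsv"] = tsv

    if diagnostics is not None:
        diag = outdir / "diagnostics.json"
        with open(diag, "w") as fh:
            json.dump(diagnostics, fh, indent=2)
            fh.write("\n")
        paths["diagnostics"] = diag
    return paths
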