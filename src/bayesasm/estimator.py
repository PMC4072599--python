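"""Model/Results interface for Bayesian assembly.

:class:`BayesianAssembly` is built from paired-end reads (plus graph and
prior settings); :meth:`BayesianAssembly.fit` runs independent Metropolis
chains and returns an :class:`AssemblyResults` carrying the traces, the
posterior edge/node frequencies with convergence diagnostics, the
majority-rule consensus, and a printable summary table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import graph as graph_mod
from . import read_io
from .model import CachedPosterior, PriorConfig, ReadModel
from .sampler import ChainTrace, acceptance_rate, node_frequencies, run_chains
from .summary import (
    ConsensusAssembly,
    annotate_external,
    cross_chain_sd,
    frequency_agreement,
    majority_consensus,
    write_outputs,
)

__all__ = ["BayesianAssembly", "AssemblyResults"]


class BayesianAssembly:
    """Posterior distribution over assemblies of a read set.

    Parameters
    ----------
    pairs:
        A :class:`~bayesasm.read_io.ReadPairSet`.  Reads are oriented onto
        a single strand (forward mates plus reverse-complemented reverse
        mates) before graph construction and likelihood evaluation.
    k:
        k-mer size for the de Bruijn graph (odd, default 31).
    min_count:
        Minimum k-mer abundance retained at graph construction.  The
        default 5 suppresses k-mers created by isolated sequencing errors
        (which otherwise survive tip-trimming as spurious bubbles) while
        retaining minor-haplotype k-mers at typical coverage; set to 1 for
        the raw, unfiltered graph.
    linear:
        Use the softer linear-genome tip trimming instead of trimming to a
        fixpoint (default False: circular target).
    priors / read_model:
        Probability model configuration.
    """

    def __init__(
        self,
        pairs: read_io.ReadPairSet,
        k: int = 31,
        min_count: int = 5,
        linear: bool = False,
        priors: PriorConfig | None = None,
        read_model: ReadModel | None = None,
    ) -> None:
        self.pairs = pairs
        self.k = k
        self.min_count = min_count
        self.linear = linear
        self.priors = priors or PriorConfig()
        self.read_model = read_model or ReadModel()
        self.reads = read_io.oriented_sequences(pairs)
        raw = graph_mod.build_debruijn(self.reads, k, min_count=min_count)
        self.graph = graph_mod.reduce_graph(raw, linear=linear)

    @classmethod
    def from_fastq(
        cls,
        r1: str | Path,
        r2: str | Path,
        min_mean_quality: float | None = 37.0,
        n_pairs: int | None = None,
        adapters: Sequence[str] = (),
        **kwargs,
    ) -> "BayesianAssembly":
        """Build from FASTQ mates, applying the subset-selection filter
        (adapter screen, mean quality, then first-n) before assembly."""
        pairs = read_io.ReadPairSet.from_files(r1, r2)
        pairs = read_io.adapter_filter(pairs, adapters)
        if min_mean_quality is not None:
            pairs = read_io.mean_quality_filter(pairs, min_mean_quality)
        if n_pairs is not None:
            pairs = read_io.take_first(pairs, n_pairs)
        return cls(pairs, **kwargs)

    def fit(
        self,
        n_iterations: int = 20000,
        n_chains: int = 3,
        n_perturbations: int = 3,
        seed: int = 0,
        record_mode: str = "all_iterations",
    ) -> "AssemblyResults":
        """Run independent Metropolis chains and summarize the posterior."""
        posterior = CachedPosterior(
            self.graph, self.reads, self.priors, self.read_model
        )
        traces = run_chains(
            self.graph,
            self.reads,
            n_chains=n_chains,
            n_iterations=n_iterations,
            seed=seed,
            n_perturbations=n_perturbations,
            record_mode=record_mode,
            logpost_fn=posterior,
        )
        return AssemblyResults(self, traces, posterior)


class AssemblyResults:
    """Posterior summaries of fitted MCMC assembly chains."""

    def __init__(
        self,
        model: BayesianAssembly,
        traces: list[ChainTrace],
        posterior: CachedPosterior | None = None,
    ) -> None:
        self.model = model
        self.graph = model.graph
        self.traces = traces
        self.posterior = posterior
        vecs = np.concatenate([t.vectors for t in traces])
        self.edge_freqs = vecs.mean(axis=0)
        self.node_freqs = np.stack(
            [node_frequencies(t, self.graph) for t in traces]
        ).mean(axis=0)
        self.acceptance_rates = [acceptance_rate(t) for t in traces]

    # -- diagnostics -----------------------------------------------------
    def convergence_sd(self) -> np.ndarray:
        """Cross-chain mean SD of cumulative edge frequencies (a series)."""
        return cross_chain_sd(self.traces)

    def max_pairwise_deviation(self) -> float:
        """Max |freq_a - freq_b| over edges and chain pairs."""
        best = 0.0
        for i in range(len(self.traces)):
            for j in range(i + 1, len(self.traces)):
                _, dev = frequency_agreement(self.traces[i], self.traces[j])
                best = max(best, dev)
        return best

    def diagnostics(self) -> dict:
        sd = self.convergence_sd()
        return {
            "acceptance_rates": self.acceptance_rates,
            "final_cross_chain_sd": float(sd[-1]),
            "max_pairwise_frequency_deviation": self.max_pairwise_deviation(),
            "n_posterior_evaluations": (
                self.posterior.n_evaluations if self.posterior else None
            ),
        }

    # -- summaries -------------------------------------------------------
    def consensus(self, threshold: float = 0.5) -> ConsensusAssembly:
        return majority_consensus(self.edge_freqs, self.graph, threshold)

    def annotate(self, external: dict[str, Sequence[str]]):
        return annotate_external(
            self.graph, self.edge_freqs, self.node_freqs, external
        )

    def edge_table(self) -> pd.DataFrame:
        g = self.graph
        rows = []
        for ei, (s, t) in enumerate(g.edges):
            rows.append(
                {
                    "edge": ei,
                    "source": s,
                    "target": t,
                    "posterior": self.edge_freqs[ei],
                }
            )
        return pd.DataFrame(rows)

    def summary(self, threshold: float = 0.5) -> str:
        """Printable overview of the fitted posterior."""
        cons = self.consensus(threshold)
        diag = self.diagnostics()
        lines = [
            "Bayesian assembly posterior",
            "===========================",
            f"graph: {self.graph.n_nodes} nodes, {self.graph.n_edges} edges, "
            f"k={self.graph.k}",
            f"chains: {len(self.traces)} x {self.traces[0].n_proposals} "
            "iterations",
            "acceptance rates: "
            + ", ".join(f"{r:.3f}" for r in self.acceptance_rates),
            f"final cross-chain SD of cumulative edge frequencies: "
            f"{diag['final_cross_chain_sd']:.4f}",
            f"max pairwise edge-frequency deviation: "
            f"{diag['max_pairwise_frequency_deviation']:.4f}",
            f"majority-rule consensus (threshold {threshold}): "
            f"{len(cons.contigs)} contig(s), "
            f"{sum(len(c) for c, _ in cons.contigs)} bp",
        ]
        for i, (seq, post) in enumerate(cons.contigs):
            lines.append(
                f"  contig{i}: {len(seq)} bp, min edge posterior {post:.3f}"
            )
        if cons.dropped_edges:
            lines.append(
                f"  dropped supra-threshold edges (validity): "
                f"{cons.dropped_edges}"
            )
        lines.append("edge posteriors:")
        for ei in range(self.graph.n_edges):
            s, t = self.graph.edges[ei]
            lines.append(
                f"  edge {ei} (n{s}->n{t}): {self.edge_freqs[ei]:.3f}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path, threshold: float = 0.5):
        return write_outputs(
            self.consensus(threshold),
            self.edge_freqs,
            self.graph,
            outdir,
            node_freqs=self.node_freqs,
            diagnostics=self.diagnostics(),
        )
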