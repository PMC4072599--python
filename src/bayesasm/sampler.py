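"""Metropolis MCMC over assembly states.

Each step proposes a new state (a fixed number of bubble-aware
perturbations, default 3) and computes the posterior odds ratio
R = P(new)/P(old).  If R > 1 the proposal is accepted outright; otherwise
it is accepted with probability R.  No Hastings correction is applied:
the acceptance rule is the plain odds ratio, and any bias introduced by
asymmetry of the proposal kernel is quantified empirically against
enumeration on small graphs (see the test suite and methods note) rather
than silently corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .graph import AssemblyGraph
from .model import CachedPosterior, PriorConfig, ReadModel
from .state import AssemblyState, propose, random_state

__all__ = [
    "ChainConfig",
    "ChainTrace",
    "metropolis_step",
    "run_chain",
    "run_chains",
    "acceptance_rate",
    "edge_frequencies",
    "node_frequencies",
    "cumulative_edge_frequencies",
    "write_trace_tsv",
]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain settings."""

    n_iterations: int
    n_perturbations: int = 3
    seed: int = 0
    record_mode: str = "all_iterations"  # or "accepted_only"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.record_mode not in ("all_iterations", "accepted_only"):
            raise ValueError(f"unknown record_mode {self.record_mode!r}")


@dataclass
class ChainTrace:
    """Per-iteration record of one chain plus acceptance bookkeeping."""

    iterations: np.ndarray  # int, shape (R,)
    vectors: np.ndarray  # bool, shape (R, E)
    log_posteriors: np.ndarray  # float, shape (R,)
    accepted: np.ndarray  # bool, shape (R,)
    n_proposals: int = 0
    n_accepted: int = 0
    seed: int = 0

    @property
    def n_records(self) -> int:
        return len(self.iterations)

    @property
    def n_edges(self) -> int:
        return self.vectors.shape[1]


def metropolis_step(
    current: AssemblyState,
    logpost_current: float,
    g: AssemblyGraph,
    logpost_fn: Callable[[AssemblyState], float],
    rng: np.random.Generator,
    n_perturbations: int = 3,
    propose_fn: Callable[[AssemblyState], AssemblyState] | None = None,
) -> tuple[AssemblyState, float, bool]:
    """One Metropolis step; returns (state, log posterior, accepted)."""
    if propose_fn is None:
        new = propose(current, g, rng, n_perturbations)
    else:
        new = propose_fn(current)
    logpost_new = logpost_fn(new)
    log_r = logpost_new - logpost_current
    if log_r > 0 or rng.random() < math.exp(log_r):
        return new, logpost_new, True
    return current, logpost_current, False


def run_chain(
    g: AssemblyGraph,
    reads,
    chain_cfg: ChainConfig,
    prior_cfg: PriorConfig | None = None,
    model: ReadModel | None = None,
    logpost_fn: Callable[[AssemblyState], float] | None = None,
    initial: AssemblyState | None = None,
) -> ChainTrace:
    """Run one Metropolis chain; deterministic given the config seed.

    ``logpost_fn`` overrides the posterior (for stubbed tests and shared
    caches); by default a :class:`CachedPosterior` is built from
    (reads, priors, read model).
    """
    if logpost_fn is None:
        logpost_fn = CachedPosterior(
            g, reads, prior_cfg or PriorConfig(), model or ReadModel()
        )
    rng = np.random.default_rng(chain_cfg.seed)
    current = initial if initial is not None else random_state(g, rng)
    logpost = logpost_fn(current)

    record_all = chain_cfg.record_mode == "all_iterations"
    its: list[int] = []
    vecs: list[np.ndarray] = []
    lps: list[float] = []
    accs: list[bool] = []
    n_acc = 0
    for it in range(chain_cfg.n_iterations):
        current, logpost, accepted = metropolis_step(
            current, logpost, g, logpost_fn, rng, chain_cfg.n_perturbations
        )
        if accepted:
            n_acc += 1
        if record_all or accepted:
            its.append(it)
            vecs.append(current.active.copy())
            lps.append(logpost)
            accs.append(accepted)
    return ChainTrace(
        iterations=np.array(its, dtype=np.int64),
        vectors=(
            np.array(vecs, dtype=bool)
            if vecs
            else np.zeros((0, g.n_edges), dtype=bool)
        ),
        log_posteriors=np.array(lps),
        accepted=np.array(accs, dtype=bool),
        n_proposals=chain_cfg.n_iterations,
        n_accepted=n_acc,
        seed=chain_cfg.seed,
    )


def run_chains(
    g: AssemblyGraph,
    reads,
    n_chains: int,
    n_iterations: int,
    seed: int,
    n_perturbations: int = 3,
    prior_cfg: PriorConfig | None = None,
    model: ReadModel | None = None,
    record_mode: str = "all_iterations",
    logpost_fn: Callable[[AssemblyState], float] | None = None,
    share_cache: bool = True,
) -> list[ChainTrace]:
    """Run independent chains with seeds spawned from ``seed``.

    With ``share_cache`` the chains share one memoizing posterior (the
    posterior value of a state does not depend on the chain evaluating it).
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_chains) % (2**31)
    if logpost_fn is None and share_cache:
        logpost_fn = CachedPosterior(
            g, reads, prior_cfg or PriorConfig(), model or ReadModel()
        )
    traces = []
    for cseed in child_seeds:
        cfg = ChainConfig(
            n_iterations=n_iterations,
            n_perturbations=n_perturbations,
            seed=int(cseed),
            record_mode=record_mode,
        )
        traces.append(
            run_chain(g, reads, cfg, prior_cfg, model, logpost_fn=logpost_fn)
        )
    return traces


def acceptance_rate(t: ChainTrace) -> float:
    if t.n_proposals < 1:
        raise ValueError("no proposals recorded")
    return t.n_accepted / t.n_proposals


def edge_frequencies(t: ChainTrace, burn_in: int = 0) -> np.ndarray:
    """Per-edge fraction of post-burn-in records in which the edge is active."""
    if burn_in >= t.n_records:
        raise ValueError("burn_in must be < number of records")
    return t.vectors[burn_in:].mean(axis=0)


def node_frequencies(
    t: ChainTrace, g: AssemblyGraph, burn_in: int = 0
) -> np.ndarray:
    """Per-node fraction of records in which >= 1 incident edge is active."""
    if burn_in >= t.n_records:
        raise ValueError("burn_in must be < number of records")
    incident = np.zeros((g.n_nodes, g.n_edges), dtype=bool)
    for ei, (s, tgt) in enumerate(g.edges):
        incident[s, ei] = True
        incident[tgt, ei] = True
    vecs = t.vectors[burn_in:]
    active_nodes = vecs @ incident.T > 0
    return active_nodes.mean(axis=0)


def cumulative_edge_frequencies(t: ChainTrace) -> np.ndarray:
    """Shape (R, E): running fraction of records with each edge active."""
    csum = np.cumsum(t.vectors, axis=0, dtype=np.float64)
    counts = np.arange(1, t.n_records + 1, dtype=np.float64)[:, None]
    return csum / counts


def write_trace_tsv(t: ChainTrace, path: str | Path) -> None:
    """TSV with iteration, accepted, log_posterior and per-edge 0/1 columns."""
    with open(path, "w") as fh:
        cols = ["iteration", "accepted", "log_posterior"] + [
            f"e{i}" for i in range(t.n_edges)
        ]
        fh.write("\t".join(cols) + "\n")
        for i in range(t.n_records):
            row = [
                str(int(t.iterations[i])),
                str(int(t.accepted[i])),
                f"{t.log_posteriors[i]:.6f}",
            ] + [str(int(v)) for v in t.vectors[i]]
            fh.write("\t".join(row) + "\n")


def write_run_summary(
    traces: Sequence[ChainTrace], path: str | Path, extra: dict | None = None
) -> None:
    summary = {
        "n_chains": len(traces),
        "seeds": [t.seed for t in traces],
        "acceptance_rates": [acceptance_rate(t) for t in traces],
        "n_records": [t.n_records for t in traces],
    }
    if extra:
        summary.update(extra)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
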