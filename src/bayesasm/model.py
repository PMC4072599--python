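"""Unnormalized log posterior of an assembly state.

The posterior combines

* a read-generation log likelihood in the LAP (log average probability)
  style: the mean over reads of the log probability that the proposed
  assembly generated the read, where a read's probability is the sum of its
  placement probabilities over every position and strand of every contig,
  divided by the number of possible placements, under an i.i.d. per-base
  substitution error model (match prob 1-eps, each specific mismatch
  eps/3); and

* gamma log priors on the total assembled length (mode 5,386 bp by
  default, the phiX174 genome length) and on the contig count (mode 1, one
  circular chromosome).  "Centered at" is read as the gamma *mode*:
  with shape alpha > 1 and scale theta = center/(alpha-1) the density is
  maximized exactly at the center, pinning the maximum a priori assembly
  at the expected genome length while the shape controls how informative
  the prior is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .graph import AssemblyGraph
from .read_io import SequenceRead, revcomp
from .state import AssemblyState, active_contigs_info

__all__ = [
    "GammaPrior",
    "ReadModel",
    "PriorConfig",
    "LOG_FLOOR",
    "log_prior",
    "placement_log_prob",
    "read_log_prob",
    "lap_score",
    "log_likelihood",
    "load_config",
    "log_posterior",
    "CachedPosterior",
]

#: Finite stand-in for log(0): assigned to empty/degenerate assemblies so
#: the sampler can still compare them.
LOG_FLOOR = -1.0e12

_SEED_LEN = 16


@dataclass(frozen=True)
class GammaPrior:
    """Gamma distribution parameterized by shape and mode.

    shape: alpha > 1; center: the mode c > 0.  The scale is derived as
    theta = c/(alpha-1), which makes (alpha-1)*theta = c exactly.
    """

    shape: float
    center: float

    def __post_init__(self) -> None:
        if self.shape <= 1:
            raise ValueError(
                "mode parameterization requires shape > 1 "
                f"(got {self.shape})"
            )
        if self.center <= 0:
            raise ValueError("center must be > 0")

    @property
    def scale(self) -> float:
        return self.center / (self.shape - 1)

    def logpdf(self, x: float) -> float:
        """Gamma log density; LOG_FLOOR for x <= 0."""
        if x <= 0:
            return LOG_FLOOR
        a, th = self.shape, self.scale
        return (a - 1) * math.log(x) - x / th - gammaln(a) - a * math.log(th)


@dataclass(frozen=True)
class ReadModel:
    """Per-base substitution model for read placement.

    error_rate: probability a base was miscalled (each of the 3 wrong bases
    equally likely).  placement: "exhaustive" scores every start position,
    "seeded" uses exact 16-mer seed-and-extend (sound for low error rates,
    where unseeded placements are astronomically improbable), "auto" picks
    seeded for reads of length >= 32.  min_log_prob: floor for unplaceable
    reads; None derives the worst-possible-placement floor per evaluation.
    """

    error_rate: float = 0.002
    min_log_prob: float | None = None
    placement: str = "auto"

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.75):
            raise ValueError("error_rate must be in [0, 0.75)")
        if self.placement not in ("auto", "exhaustive", "seeded"):
            raise ValueError(f"unknown placement mode {self.placement!r}")

    @property
    def log_match(self) -> float:
        return math.log1p(-self.error_rate)

    @property
    def log_mismatch(self) -> float:
        return math.log(self.error_rate / 3) if self.error_rate > 0 else -math.inf

    def floor(self, read_length: int, denom: float) -> float:
        if self.min_log_prob is not None:
            return self.min_log_prob
        if self.error_rate == 0 or denom <= 0:
            return LOG_FLOOR
        return read_length * self.log_mismatch - math.log(denom)


@dataclass(frozen=True)
class PriorConfig:
    """Priors on total assembled length and contig count.

    mode: "full" (likelihood + priors), "flat" (log prior == 0),
    "prior_only" (log likelihood == 0).
    """

    length_prior: GammaPrior = GammaPrior(shape=5.0, center=5386.0)
    contig_prior: GammaPrior = GammaPrior(shape=5.0, center=1.0)
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "flat", "prior_only"):
            raise ValueError(f"unknown prior mode {self.mode!r}")


def log_prior(total_length: float, n_contigs: float, cfg: PriorConfig) -> float:
    """Sum of the two gamma log densities (0 in flat mode)."""
    if cfg.mode == "flat":
        return 0.0
    if total_length <= 0 or n_contigs <= 0:
        return LOG_FLOOR
    return cfg.length_prior.logpdf(total_length) + cfg.contig_prior.logpdf(
        n_contigs
    )


# -- placement ---------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def placement_log_prob(
    read: str, contig: str, start: int, strand: str, model: ReadModel
) -> float:
    """Log probability of the read generated from ``contig[start:start+len]``
    on the given strand ('+' or '-'; '-' compares the reverse complement)."""
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    query = read if strand == "+" else revcomp(read)
    if not (0 <= start <= len(contig) - len(read)):
        raise ValueError("start out of range")
    window = contig[start : start + len(read)]
    mismatches = sum(1 for a, b in zip(query, window) if a != b)
    matches = len(read) - mismatches
    if mismatches == 0:
        return matches * model.log_match
    if model.error_rate == 0:
        return -math.inf
    return matches * model.log_match + mismatches * model.log_mismatch


def _n_placements(contig_length: int, read_length: int, circular: bool) -> int:
    """Start positions per strand for one contig."""
    if read_length > contig_length:
        return 0
    return contig_length if circular else contig_length - read_length + 1


def _placement_lognum_exhaustive(
    contig: str, read_fwd: str, read_rc: str, model: ReadModel, circular: bool
) -> float:
    """log sum over both strands and all start positions of the placement
    probability (numerator of the average read probability).

    Circular contigs are extended by a wrapped prefix so reads may span the
    origin; start positions are restricted to 0..L-1.
    """
    ell = len(read_fwd)
    L = len(contig)
    n = _n_placements(L, ell, circular)
    if n <= 0:
        return -math.inf
    hay = _encode(contig + contig[: ell - 1]) if circular else _encode(contig)
    terms = []
    for q in (read_fwd, read_rc):
        qa = _encode(q)
        windows = np.lib.stride_tricks.sliding_window_view(hay, ell)[:n]
        mm = (windows != qa).sum(axis=1)
        if model.error_rate == 0:
            exact = int((mm == 0).sum())
            if exact:
                terms.append(math.log(exact))
            continue
        terms.append(
            logsumexp((ell - mm) * model.log_match + mm * model.log_mismatch)
        )
    if not terms:
        return -math.inf
    return float(logsumexp(terms))


class _SeededContigIndex:
    """Exact 16-mer positional index of one contig for seed-and-extend.

    For a circular contig the index covers the wrapped extension and
    candidate starts are reduced modulo the contig length.
    """

    def __init__(self, contig: str, circular: bool, max_read_length: int):
        self.L = len(contig)
        self.circular = circular
        ext = contig + contig[: max_read_length - 1] if circular else contig
        self.arr = _encode(ext)
        self.ext_len = len(ext)
        self.index: dict[str, list[int]] = {}
        for i in range(len(ext) - _SEED_LEN + 1):
            self.index.setdefault(ext[i : i + _SEED_LEN], []).append(i)

    def candidates(self, query: str) -> set[int]:
        """Candidate start positions from exact seed hits at offsets
        0, 16, 32, ... of the query."""
        cands: set[int] = set()
        ell = len(query)
        n = _n_placements(self.L, ell, self.circular)
        if n <= 0:
            return cands
        for off in range(0, ell - _SEED_LEN + 1, _SEED_LEN):
            for pos in self.index.get(query[off : off + _SEED_LEN], ()):
                start = pos - off
                if self.circular:
                    start %= self.L
                if 0 <= start < n and start + ell <= self.ext_len:
                    cands.add(start)
        return cands

    def lognum(self, query_fwd: str, query_rc: str, model: ReadModel) -> float:
        terms = []
        ell = len(query_fwd)
        for q in (query_fwd, query_rc):
            qa = _encode(q)
            for start in self.candidates(q):
                mm = int((self.arr[start : start + ell] != qa).sum())
                if mm and model.error_rate == 0:
                    continue
                terms.append((ell - mm) * model.log_match + mm * model.log_mismatch)
        if not terms:
            return -math.inf
        # lightweight log-sum-exp: the candidate list is short
        m = max(terms)
        return m + math.log(sum(math.exp(t - m) for t in terms))


def _use_seeded(model: ReadModel, read_length: int) -> bool:
    if model.placement == "seeded":
        return True
    if model.placement == "exhaustive":
        return False
    return read_length >= 2 * _SEED_LEN


def _contig_lognum(
    contig: str, read: str, model: ReadModel, circular: bool = False
) -> float:
    rc = revcomp(read)
    if _use_seeded(model, len(read)):
        idx = _SeededContigIndex(contig, circular, len(read))
        return idx.lognum(read, rc, model)
    return _placement_lognum_exhaustive(contig, read, rc, model, circular)


def _norm_circular(
    contigs: Sequence[str], circular: Sequence[bool] | None
) -> list[bool]:
    if circular is None:
        return [False] * len(contigs)
    return list(circular)


def read_log_prob(
    read: str,
    contigs: Sequence[str],
    model: ReadModel,
    circular: Sequence[bool] | None = None,
) -> float:
    """Log average probability that the contig set generated the read.

    log [ sum over contigs/strands/positions of the placement probability ]
    minus log [ 2 * sum_c n_c ], where n_c is the number of start positions
    on contig c (L_c - l + 1 for a linear contig, L_c for a circular one);
    the floor if there is no valid placement mass.
    """
    circ = _norm_circular(contigs, circular)
    ell = len(read)
    denom = 2 * sum(_n_placements(len(c), ell, cc) for c, cc in zip(contigs, circ))
    if denom == 0:
        return model.floor(ell, denom)
    terms = [
        _contig_lognum(c, read, model, cc)
        for c, cc in zip(contigs, circ)
        if len(c) >= ell
    ]
    terms = [t for t in terms if t > -math.inf]
    if not terms:
        return model.floor(ell, denom)
    return float(logsumexp(terms)) - math.log(denom)


def lap_score(
    contigs: Sequence[str],
    reads: Sequence[SequenceRead | str],
    model: ReadModel,
    circular: Sequence[bool] | None = None,
) -> float:
    """Log average probability: the mean over reads of ``read_log_prob``.

    This is the per-read-normalized assembly quality score; the posterior
    uses the total log likelihood (N times this value), since the
    probability of the whole read set is the product over reads.
    """
    if not reads:
        return 0.0
    seqs = [getattr(r, "bases", r) for r in reads]
    return sum(read_log_prob(s, contigs, model, circular) for s in seqs) / len(
        seqs
    )


def log_likelihood(
    contigs: Sequence[str],
    reads: Sequence[SequenceRead | str],
    model: ReadModel,
    average: bool = False,
    circular: Sequence[bool] | None = None,
) -> float:
    """Read-generation log likelihood of the contig set.

    By default the total over reads (the quantity entering Bayes' rule);
    with ``average=True`` the per-read mean, i.e. the LAP score.
    """
    if not reads:
        return 0.0
    total = lap_score(contigs, reads, model, circular) * len(reads)
    return total / len(reads) if average else total


def log_posterior(
    s: AssemblyState,
    g: AssemblyGraph,
    reads: Sequence[SequenceRead | str],
    cfg: PriorConfig,
    model: ReadModel,
) -> float:
    """Unnormalized log posterior of a state."""
    info = active_contigs_info(s, g)
    contigs = [c for c, _ in info]
    circ = [cc for _, cc in info]
    total = sum(len(c) for c in contigs)
    lp = log_prior(total, len(contigs), cfg)
    if cfg.mode == "prior_only":
        return lp
    return log_likelihood(contigs, reads, model, circular=circ) + lp


class CachedPosterior:
    """Memoizing log-posterior evaluator for MCMC.

    Caches (a) the per-read log placement-mass vector for every distinct
    contig string and (b) the final log posterior for every distinct state
    vector.  Assembly proposals change only a few contigs, and the chain
    revisits states, so both caches hit constantly.
    """

    def __init__(
        self,
        g: AssemblyGraph,
        reads: Sequence[SequenceRead | str],
        cfg: PriorConfig,
        model: ReadModel,
    ) -> None:
        self.g = g
        self.cfg = cfg
        self.model = model
        self.read_seqs = [getattr(r, "bases", r) for r in reads]
        self.read_lengths = np.array([len(s) for s in self.read_seqs])
        self._contig_cache: dict[tuple[str, bool], np.ndarray] = {}
        self._state_cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def _contig_lognums(self, contig: str, circ: bool) -> np.ndarray:
        hit = self._contig_cache.get((contig, circ))
        if hit is not None:
            return hit
        min_ell = int(self.read_lengths.min()) if len(self.read_lengths) else 0
        if _use_seeded(self.model, min_ell):
            max_ell = int(self.read_lengths.max())
            idx = _SeededContigIndex(contig, circ, max_ell)
            out = np.array(
                [
                    idx.lognum(rs, revcomp(rs), self.model)
                    if len(rs) <= len(contig)
                    else -math.inf
                    for rs in self.read_seqs
                ]
            )
        else:
            out = np.array(
                [
                    _contig_lognum(contig, rs, self.model, circ)
                    if len(rs) <= len(contig)
                    else -math.inf
                    for rs in self.read_seqs
                ]
            )
        self._contig_cache[(contig, circ)] = out
        return out

    def _likelihood(self, info: list[tuple[str, bool]]) -> float:
        if not self.read_seqs:
            return 0.0
        # per-read denominator: 2 * sum_c (circular ? L_c : max(L_c-l+1, 0))
        denom = np.zeros(len(self.read_seqs), dtype=np.int64)
        for c, circ in info:
            L = len(c)
            if circ:
                denom += np.where(self.read_lengths <= L, L, 0)
            else:
                denom += np.maximum(L - self.read_lengths + 1, 0)
        denom *= 2
        if info:
            stack = np.stack([self._contig_lognums(c, circ) for c, circ in info])
            with np.errstate(divide="ignore"):
                lognum = logsumexp(stack, axis=0)
        else:
            lognum = np.full(len(self.read_seqs), -math.inf)
        out = np.empty(len(self.read_seqs))
        for i, (ln, d) in enumerate(zip(lognum, denom)):
            if d == 0 or ln == -math.inf:
                out[i] = self.model.floor(int(self.read_lengths[i]), float(d))
            else:
                out[i] = ln - math.log(d)
        return float(out.sum())

    def __call__(self, s: AssemblyState) -> float:
        key = s.key()
        hit = self._state_cache.get(key)
        if hit is not None:
            return hit
        self.n_evaluations += 1
        info = active_contigs_info(s, self.g)
        total = sum(len(c) for c, _ in info)
        lp = log_prior(total, len(info), self.cfg)
        if self.cfg.mode != "prior_only":
            lp += self._likelihood(info)
        self._state_cache[key] = lp
        return lp


def load_config(path) -> tuple[PriorConfig, ReadModel]:
    """Parse a key=value configuration file into (PriorConfig, ReadModel).

    Recognized keys: prior.length.center, prior.length.shape,
    prior.contig.center, prior.contig.shape, prior.mode,
    model.error_rate, model.min_log_prob, model.placement.
    Lines starting with '#' and blank lines are ignored.
    """
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    known = {
        "prior.length.center", "prior.length.shape",
        "prior.contig.center", "prior.contig.shape", "prior.mode",
        "model.error_rate", "model.min_log_prob", "model.placement",
    }
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    priors = PriorConfig(
        length_prior=GammaPrior(
            shape=float(values.get("prior.length.shape", 5.0)),
            center=float(values.get("prior.length.center", 5386.0)),
        ),
        contig_prior=GammaPrior(
            shape=float(values.get("prior.contig.shape", 5.0)),
            center=float(values.get("prior.contig.center", 1.0)),
        ),
        mode=values.get("prior.mode", "full"),
    )
    model = ReadModel(
        error_rate=float(values.get("model.error_rate", 0.002)),
        min_log_prob=(
            float(values["model.min_log_prob"])
            if "model.min_log_prob" in values
            else None
        ),
        placement=values.get("model.placement", "auto"),
    )
    return priors, model
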