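"""Synthetic circular genomes and paired-end reads.

The generator emulates the summary statistics of the phiX174 MiSeq test
subset: a ~5.4 kb circular genome, 2,000 read pairs of maximum length
251 bp, mean insert size 357 bp, low substitution error, and constant
Q38 base qualities (so simulated data passes the mean-quality > 37 filter
by construction).  Variant haplotypes inject biallelic sites that appear
as bubbles in the reduced assembly graph.

Two presets are provided: the default end-to-end conditions use
fixed-length 251 bp reads, while :func:`simulate_phix_like` draws variable
read lengths (max 251, mean ~125 bp) so that the emulated dataset also
reproduces the ~93x fold coverage of the real subset, whose reads vary in
length below the 251 bp maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .read_io import ReadPairSet, SequenceRead, revcomp

__all__ = [
    "SimulatedTruth",
    "simulate_genome",
    "simulate_paired_reads",
    "simulate_truth",
    "simulate_phix_like",
]

_BASES = "ACGT"
_DEFAULT_QUAL = 38


@dataclass
class SimulatedTruth:
    """A known circular genome, its variants, and the generated reads."""

    genome: str
    variants: list[tuple[int, str, float]]  # (position, alt base, fraction)
    reads: ReadPairSet
    seed: int
    params: dict = field(default_factory=dict)

    def haplotype(self, with_variants: bool) -> str:
        if not with_variants:
            return self.genome
        seq = list(self.genome)
        for pos, alt, _frac in self.variants:
            seq[pos] = alt
        return "".join(seq)


def simulate_genome(
    length: int,
    n_variants: int,
    min_spacing: int,
    rng: np.random.Generator,
    variant_fraction: float = 0.1,
) -> tuple[str, list[tuple[int, str, float]]]:
    """Uniform random circular genome plus biallelic variant sites.

    Variant positions are pairwise >= ``min_spacing`` apart (also around
    the circular wrap); each variant's alternative base differs from the
    reference and carries the minor haplotype fraction.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    if n_variants * max(min_spacing, 1) >= length:
        raise ValueError("infeasible variant spacing for this genome length")
    genome = "".join(rng.choice(list(_BASES), size=length))
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_variants:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not place variants with requested spacing")
        p = int(rng.integers(length))
        circ_dist = lambda a, b: min((a - b) % length, (b - a) % length)
        if all(circ_dist(p, q) >= min_spacing for q in positions):
            positions.append(p)
    variants = []
    for p in sorted(positions):
        ref = genome[p]
        choices = [b for b in _BASES if b != ref]
        alt = choices[int(rng.integers(3))]
        variants.append((p, alt, variant_fraction))
    return genome, variants


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        wrong = [b for b in _BASES if b != arr[i]]
        arr[i] = wrong[int(rng.integers(3))]
    return "".join(arr)


def simulate_paired_reads(
    genome: str,
    variants: list[tuple[int, str, float]],
    n_pairs: int,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    rng: np.random.Generator,
    length_sampler=None,
) -> ReadPairSet:
    """Paired reads from a circular genome.

    Fragment starts are uniform on the circle; insert lengths are normal
    (clamped to be at least as long as the longer mate); the forward mate
    is taken from the 5' end of the fragment and the reverse mate is the
    reverse complement of its 3' end.  Each variant is applied to a
    fragment independently with its haplotype fraction.  Substitution
    errors are i.i.d. per base; qualities are constant Q38.

    ``length_sampler(rng) -> (len_fwd, len_rev)`` overrides the fixed
    ``read_length`` to emulate variable-length libraries.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    L = len(genome)
    pairs = []
    for i in range(n_pairs):
        if length_sampler is None:
            len_f = len_r = read_length
        else:
            len_f, len_r = length_sampler(rng)
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        insert = max(insert, len_f, len_r)
        start = int(rng.integers(L))
        doubled = genome + genome  # circular wrap, linearized
        fragment = doubled[start : start + insert]
        while len(fragment) < insert:  # insert longer than genome: keep wrapping
            fragment += genome
            fragment = fragment[:insert]
        # haplotype choice per variant site
        frag_list = None
        for pos, alt, frac in variants:
            if rng.random() < frac:
                if frag_list is None:
                    frag_list = list(fragment)
                off = (pos - start) % L
                while off < insert:
                    frag_list[off] = alt
                    off += L
        if frag_list is not None:
            fragment = "".join(frag_list)
        fwd = _apply_errors(fragment[:len_f], error_rate, rng)
        rev = _apply_errors(revcomp(fragment[-len_r:]), error_rate, rng)
        pairs.append(
            (
                SequenceRead(f"sim_{i}/1", fwd, (_DEFAULT_QUAL,) * len(fwd)),
                SequenceRead(f"sim_{i}/2", rev, (_DEFAULT_QUAL,) * len(rev)),
            )
        )
    return ReadPairSet(pairs, provenance="simulated")


def simulate_truth(
    seed: int,
    length: int = 5386,
    n_variants: int = 2,
    min_spacing: int = 500,
    variant_fraction: float = 0.1,
    n_pairs: int = 2000,
    read_length: int = 251,
    insert_mean: float = 357.0,
    insert_sd: float = 40.0,
    error_rate: float = 0.002,
    length_sampler=None,
) -> SimulatedTruth:
    """End-to-end study conditions: 5,386 bp circular genome, 2 biallelic
    sites on a 10% minor haplotype, 2,000 pairs of 251 bp reads, insert
    357 +/- 40 bp, substitution error 0.002."""
    rng = np.random.default_rng(seed)
    genome, variants = simulate_genome(
        length, n_variants, min_spacing, rng, variant_fraction
    )
    reads = simulate_paired_reads(
        genome,
        variants,
        n_pairs,
        read_length,
        insert_mean,
        insert_sd,
        error_rate,
        rng,
        length_sampler=length_sampler,
    )
    return SimulatedTruth(
        genome=genome,
        variants=variants,
        reads=reads,
        seed=seed,
        params=dict(
            n_pairs=n_pairs,
            read_length=read_length,
            insert_mean=insert_mean,
            insert_sd=insert_sd,
            error_rate=error_rate,
            length=length,
            n_variants=n_variants,
            variant_fraction=variant_fraction,
        ),
    )


def _phix_length_sampler(rng: np.random.Generator) -> tuple[int, int]:
    """Variable mate lengths: max 251, mean ~125.3 bp.

    1% of mates keep the full 251 bp machine length; the rest are drawn
    uniformly from 34..214 bp (quality-trimmed tail), matching the real
    subset's summary statistics (max length 251, ~93x coverage from 2,000
    pairs of a 5,386 bp genome)."""

    def one() -> int:
        if rng.random() < 0.01:
            return 251
        return int(rng.integers(34, 215))

    return one(), one()


def simulate_phix_like(seed: int) -> SimulatedTruth:
    """File-S1-emulating preset: 2,000 pairs, max read length 251 bp,
    insert 357 bp, ~93x coverage of a 5,386 bp circular genome."""
    return simulate_truth(seed, length_sampler=_phix_length_sampler)
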