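"""Paired-end read handling.

Reads are parsed from standard 4-line FASTQ (Phred-33), optionally
gzip-compressed.  Filtering follows the subset-selection protocol used for
the PhiX test data: keep a pair only if both mates have arithmetic mean
quality strictly greater than a threshold (default 37) and neither mate
contains a user-supplied adapter substring, then keep the first ``n`` pairs
in file order.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRead",
    "ReadPairSet",
    "parse_fastq",
    "write_fastq",
    "write_fasta",
    "mean_quality_filter",
    "adapter_filter",
    "take_first",
    "coverage_stats",
    "oriented_sequences",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRead:
    """A single sequencing read with per-base Phred qualities."""

    identifier: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.identifier!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.identifier!r}: negative quality value")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        """Arithmetic mean Phred quality; 0.0 for an empty read."""
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


@dataclass
class ReadPairSet:
    """An ordered collection of (forward, reverse) mate pairs."""

    pairs: list[tuple[SequenceRead, SequenceRead]] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[SequenceRead, SequenceRead]]:
        return iter(self.pairs)

    def all_reads(self) -> list[SequenceRead]:
        out: list[SequenceRead] = []
        for fwd, rev in self.pairs:
            out.append(fwd)
            out.append(rev)
        return out

    @classmethod
    def from_files(cls, r1: str | Path, r2: str | Path) -> "ReadPairSet":
        fwd = parse_fastq(r1)
        rev = parse_fastq(r2)
        if len(fwd) != len(rev):
            raise ValueError(
                f"unequal mate counts: {len(fwd)} in {r1}, {len(rev)} in {r2}"
            )
        return cls(pairs=list(zip(fwd, rev)), provenance=f"{r1},{r2}")


def _open_text(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return io.TextIOWrapper(raw)


def parse_fastq(source) -> list[SequenceRead]:
    """Parse Phred-33 FASTQ from a path or text handle.

    Raises ``ValueError`` on malformed records, including base/quality
    length mismatches.
    """
    handle = _open_text(source)
    reads = []
    for rec in SeqIO.parse(handle, "fastq"):
        reads.append(
            SequenceRead(
                identifier=rec.description or rec.id,
                bases=str(rec.seq).upper(),
                quals=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def _to_record(read: SequenceRead) -> SeqRecord:
    rec = SeqRecord(Seq(read.bases), id=read.identifier.split()[0] if read.identifier else "read",
                    description=read.identifier)
    rec.letter_annotations["phred_quality"] = list(read.quals)
    return rec


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write((_to_record(r) for r in reads), fh, "fastq")


def write_fasta(seqs: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) records as FASTA."""
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def mean_quality_filter(pairs: ReadPairSet, threshold: float = 37.0) -> ReadPairSet:
    """Keep pairs in which *both* mates have mean quality strictly > threshold."""
    kept = [
        (f, r)
        for f, r in pairs
        if f.mean_quality > threshold and r.mean_quality > threshold
    ]
    return ReadPairSet(kept, provenance=pairs.provenance)


def adapter_filter(pairs: ReadPairSet, adapters: Sequence[str] = ()) -> ReadPairSet:
    """Drop pairs in which either mate contains any adapter as an exact substring."""
    if not adapters:
        return ReadPairSet(list(pairs.pairs), provenance=pairs.provenance)
    ups = [a.upper() for a in adapters]
    kept = [
        (f, r)
        for f, r in pairs
        if not any(a in f.bases or a in r.bases for a in ups)
    ]
    return ReadPairSet(kept, provenance=pairs.provenance)


def take_first(pairs: ReadPairSet, n: int) -> ReadPairSet:
    """First min(n, len) pairs in input order."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return ReadPairSet(list(pairs.pairs[:n]), provenance=pairs.provenance)


def coverage_stats(
    pairs: ReadPairSet, genome_length: int
) -> tuple[int, int, float]:
    """(max read length, total bases, fold coverage = total/genome_length)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    max_len = 0
    total = 0
    for f, r in pairs:
        max_len = max(max_len, len(f), len(r))
        total += len(f) + len(r)
    return max_len, total, total / genome_length


def oriented_sequences(pairs: ReadPairSet) -> list[str]:
    """Forward-mate bases plus reverse-complemented reverse mates.

    On a library whose fragments are all reported on one reference strand,
    this orients every read onto that strand, yielding a single-strand k-mer
    set for graph construction.
    """
    out: list[str] = []
    for f, r in pairs:
        out.append(f.bases)
        out.append(revcomp(r.bases))
    return out
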