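"""Genome sequence container and FASTA I/O.

Bacterial chromosomes are circular by default; all coordinates are 0-based
half-open. Windows that run past the end of a circular sequence wrap around
the origin.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("ACGTN")


@dataclass
class GenomeSequence:
    """A single (typically circular) nucleotide sequence.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header up to first whitespace).
    seq : str
        Uppercase nucleotide string over {A, C, G, T, N}.
    circular : bool
        Whether coordinates wrap around the origin. Default True, the
        appropriate choice for bacterial chromosomes.
    """

    id: str
    seq: str
    circular: bool = True
    _at_cumsum: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError("genome sequence is empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - ALPHABET
        if bad:
            pos = min(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"non-ACGTN character {self.seq[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps across the origin when circular."""
        return self.fetch(start, end - start)

    def _slice_mod(self, start: int, end: int) -> str:
        n = len(self.seq)
        if end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise ValueError("slice beyond end of linear genome")
        return self.seq[start:] + self.seq[: end - n]

    def fetch(self, start: int, length: int) -> str:
        """Sequence of ``length`` bp beginning at ``start`` (mod genome size)."""
        n = len(self.seq)
        if length > n:
            raise ValueError("requested slice longer than genome")
        start %= n
        return self._slice_mod(start, start + length)

    def at_fraction(self, start: int, end: int) -> float:
        """Fraction of A/T bases in [start, end), wrapping if needed."""
        if self._at_cumsum is None:
            arr = np.frombuffer(self.seq.encode(), dtype=np.uint8)
            is_at = (arr == ord("A")) | (arr == ord("T"))
            self._at_cumsum = np.concatenate([[0], np.cumsum(is_at)])
        n = len(self.seq)
        length = end - start
        if length <= 0:
            raise ValueError("empty interval")
        if length > n:
            raise ValueError("interval longer than genome")
        start %= n
        end = start + length
        cs = self._at_cumsum
        if end <= n:
            count = cs[end] - cs[start]
        else:
            count = (cs[n] - cs[start]) + cs[end - n]
        return float(count) / length


def read_fasta(path: str | Path, circular: bool = True) -> GenomeSequence:
    """Read a single-record FASTA (optionally gzipped) into a GenomeSequence."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        ids = [r.id for r in records]
        if len(set(ids)) < len(ids):
            raise ValueError(f"duplicate record ids in {path}")
        raise ValueError(
            f"{path} contains {len(records)} records; expected a single chromosome"
        )
    rec = records[0]
    return GenomeSequence(id=rec.id, seq=str(rec.seq).upper(), circular=circular)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.seq), width):
            fh.write(genome.seq[i : i + width] + "\n")
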