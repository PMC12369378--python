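"""Genomic interval sets (0-based half-open) with BED serialization.

The container is deliberately small: sorted start/end arrays plus optional
names and scores. EPODs, peaks, motif loci and shuffled placements all travel
through it. Intervals may wrap past the genome end (``end > genome_length``)
when produced by circular placement; consumers that need linear coordinates
split on the origin explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class IntervalSet:
    starts: np.ndarray
    ends: np.ndarray
    names: list[str] | None = None
    scores: np.ndarray | None = None
    chrom: str = "genome"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts and ends differ in length")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must have positive length")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    def sort(self) -> "IntervalSet":
        order = np.lexsort((self.ends, self.starts))
        return IntervalSet(
            self.starts[order],
            self.ends[order],
            [self.names[i] for i in order] if self.names else None,
            self.scores[order] if self.scores is not None else None,
            self.chrom,
        )

    def merge(self, bookended: bool = True) -> "IntervalSet":
        """Union-merge overlapping (and, by default, bookended) intervals."""
        if len(self) == 0:
            return IntervalSet(np.array([]), np.array([]), chrom=self.chrom)
        s = self.sort()
        out_s, out_e = [s.starts[0]], [s.ends[0]]
        for a, b in zip(s.starts[1:], s.ends[1:]):
            if a < out_e[-1] or (bookended and a == out_e[-1]):
                out_e[-1] = max(out_e[-1], b)
            else:
                out_s.append(a)
                out_e.append(b)
        return IntervalSet(np.array(out_s), np.array(out_e), chrom=self.chrom)

    def coverage_mask(self, genome_length: int) -> np.ndarray:
        """Boolean per-bp coverage over a circular genome of given length."""
        mask = np.zeros(genome_length, dtype=bool)
        for a, b in zip(self.starts, self.ends):
            a_m = a % genome_length
            b_m = a_m + (b - a)
            if b_m <= genome_length:
                mask[a_m:b_m] = True
            else:
                mask[a_m:] = True
                mask[: b_m - genome_length] = True
        return mask

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """For each interval in self, whether it shares >=1 bp with `other`."""
        if len(other) == 0:
            return np.zeros(len(self), dtype=bool)
        o = other.sort()
        # an interval [a,b) overlaps some [s,e) iff exists s < b and e > a
        idx = np.searchsorted(o.starts, self.ends, side="left")
        out = np.zeros(len(self), dtype=bool)
        max_end = np.maximum.accumulate(o.ends)
        out[idx > 0] = max_end[idx[idx > 0] - 1] > self.starts[idx > 0]
        return out


def mask_to_intervals(mask: np.ndarray) -> IntervalSet:
    """Maximal True-runs of a circular boolean mask as intervals; a run that
    crosses the origin is reported once with end > mask length."""
    n = len(mask)
    if mask.all():
        return IntervalSet(np.array([0]), np.array([n]))
    if not mask.any():
        return IntervalSet(np.array([]), np.array([]))
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [n]])
    if mask[0] and mask[-1]:  # wrap: join last run into first
        starts = starts[1:].copy()
        ends_first = ends[0]
        ends = ends[1:].copy()
        ends[-1] = n + ends_first
    return IntervalSet(starts, ends)


def read_bed(path: str | Path, chrom: str = "genome") -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = df[3].astype(str).tolist() if df.shape[1] > 3 else None
    scores = df[4].to_numpy(float) if df.shape[1] > 4 else None
    return IntervalSet(
        df[1].to_numpy(np.int64), df[2].to_numpy(np.int64), names, scores,
        chrom=str(df[0].iloc[0]) if len(df) else chrom,
    )


def write_bed(ivs: IntervalSet, path: str | Path) -> None:
    cols: dict = {
        "chrom": ivs.chrom,
        "start": ivs.starts,
        "end": ivs.ends,
    }
    if ivs.names is not None or ivs.scores is not None:
        cols["name"] = ivs.names if ivs.names is not None else "."
    if ivs.scores is not None:
        cols["score"] = ivs.scores
        cols["strand"] = "."
    pd.DataFrame(cols).to_csv(path, sep="\t", header=False, index=False)


def jaccard(a: IntervalSet, b: IntervalSet, genome_length: int) -> float:
    """bp-level Jaccard index between the coverages of two interval sets."""
    ma = a.coverage_mask(genome_length)
    mb = b.coverage_mask(genome_length)
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ma, mb).sum() / union)
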