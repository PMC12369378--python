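"""bedGraph I/O for dense per-bp tracks.

Tracks are plain numpy vectors covering the whole chromosome at 1 bp
resolution. On disk they are run-length-encoded bedGraph (0-based half-open);
positions omitted from the file read back as 0 and runs of NaN are omitted
when writing.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    track = np.zeros(genome_length, dtype=float)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        return track
    if len(df) == 0:
        return track
    starts = df["start"].to_numpy(np.int64)
    ends = df["end"].to_numpy(np.int64)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    if starts[0] < 0 or ends[-1] > genome_length:
        i = 0 if starts[0] < 0 else len(starts) - 1
        raise ValueError(
            f"{path}: interval [{starts[i]}, {ends[i]}) outside genome "
            f"of length {genome_length} (line {order[i] + 1})"
        )
    if np.any(starts[1:] < ends[:-1]):
        j = int(np.argmax(starts[1:] < ends[:-1])) + 1
        raise ValueError(f"{path}: overlapping intervals near line {order[j] + 1}")
    values = df["value"].to_numpy(float)[order]
    for a, b, v in zip(starts, ends, values):
        track[a:b] = v
    return track


def write_bedgraph(track: np.ndarray, path: str | Path, chrom: str = "genome") -> None:
    """Run-length-encode a dense track; NaN runs are omitted."""
    track = np.asarray(track, dtype=float)
    n = len(track)
    # boundaries where the value changes (NaN == NaN for this purpose)
    same = (track[1:] == track[:-1]) | (np.isnan(track[1:]) & np.isnan(track[:-1]))
    breaks = np.flatnonzero(~same) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])
    values = track[starts]
    keep = ~np.isnan(values)
    pd.DataFrame({
        "chrom": chrom,
        "start": starts[keep],
        "end": ends[keep],
        "value": values[keep],
    }).to_csv(path, sep="\t", header=False, index=False)
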