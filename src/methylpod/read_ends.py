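"""Read-end tracks around dense methylation-site clusters.

5' and 3' read-end counts are combined and normalized to ends per million;
positional matrices around cluster midpoints expose strand-break-like
pile-ups (or their absence) at the clusters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet


@dataclass
class EndTrack:
    combined: np.ndarray  # raw 5' + 3' counts per bp
    total_ends: int
    normalized: np.ndarray  # ends per million total ends


def normalized_end_track(ends5: np.ndarray, ends3: np.ndarray) -> EndTrack:
    ends5 = np.asarray(ends5, float)
    ends3 = np.asarray(ends3, float)
    if ends5.shape != ends3.shape:
        raise ValueError("end tracks differ in length")
    if np.any(ends5 < 0) or np.any(ends3 < 0):
        raise ValueError("end counts must be nonnegative")
    combined = ends5 + ends3
    total = combined.sum()
    if total == 0:
        raise ValueError("no read ends in input")
    return EndTrack(combined, int(total), combined * 1e6 / total)


def cluster_end_matrix(
    track: EndTrack, clusters: IntervalSet, flank: int = 100
) -> pd.DataFrame:
    """Normalized end counts in flank-extended windows around each cluster,
    aligned on cluster midpoints.

    Rows are offsets from the cluster midpoint; columns are clusters. All
    windows are padded to the widest cluster so rows align.
    """
    n = len(track.normalized)
    widths = clusters.lengths + 2 * flank
    half = int(np.ceil(widths.max() / 2))
    offsets = np.arange(-half, half)
    cols = {}
    for i, (a, b) in enumerate(zip(clusters.starts, clusters.ends)):
        mid = (a + b) // 2
        idx = (mid + offsets) % n
        vals = track.normalized[idx].copy()
        # positions outside this cluster's own flanked window are padding
        w = int(widths[i])
        lo = -int(np.ceil(w / 2))
        inside = (offsets >= lo) & (offsets < lo + w)
        vals[~inside] = np.nan
        cols[f"cluster_{i}_{a % n}"] = vals
    return pd.DataFrame(cols, index=pd.Index(offsets, name="offset"))
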