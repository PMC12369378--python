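"""Extended protein occupancy domain (EPOD) calling.

EPODs are >= 1 kb regions of continuously high total protein occupancy.
A domain is a maximal region, at least 1,024 bp long, over which the 768 bp
rolling median of the robust-z track stays above a threshold (so the median
of the 768 bp rolling median over the region exceeds it); the threshold is
the 90th (strict) or 75th (loose) percentile of the 256 bp rolling-median
track over the whole chromosome. Replicate-level calls are union-merged and
filtered by the irreproducible discovery rate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .idr import pairwise_max_idr
from .intervals import IntervalSet, mask_to_intervals
from .rolling import rolling_median_circular

SEED_WINDOW = 1024
MEDIAN_INNER = 768
MEDIAN_THRESH = 256
PERCENTILE = {"strict": 90.0, "loose": 75.0}


@dataclass
class EpodCall:
    start: int
    end: int
    mode: str


def call_epods(robust_z: np.ndarray, mode: str = "strict") -> list[EpodCall]:
    """Call EPODs from one replicate's robust-z track (circular)."""
    if mode not in PERCENTILE:
        raise ValueError("mode must be 'strict' or 'loose'")
    z = np.asarray(robust_z, float)
    if len(z) < SEED_WINDOW:
        raise ValueError("chromosome shorter than the 1,024 bp seed window")
    m256 = rolling_median_circular(z, MEDIAN_THRESH)
    threshold = np.percentile(m256, PERCENTILE[mode])  # linear interpolation
    m768 = rolling_median_circular(z, MEDIAN_INNER)
    # maximal runs where the 768 bp rolling median clears the threshold;
    # over such a run the median of m768 trivially exceeds the threshold,
    # and only runs of >= 1,024 bp qualify as domains
    ivs = mask_to_intervals(m768 > threshold)
    keep = ivs.lengths >= SEED_WINDOW
    return [
        EpodCall(int(a), int(b), mode)
        for a, b in zip(ivs.starts[keep], ivs.ends[keep])
    ]


def calls_to_intervals(calls: list[EpodCall]) -> IntervalSet:
    if not calls:
        return IntervalSet(np.array([]), np.array([]))
    return IntervalSet(
        np.array([c.start for c in calls]), np.array([c.end for c in calls])
    )


def _interval_mean_scores(ivs: IntervalSet, track: np.ndarray) -> np.ndarray:
    n = len(track)
    out = np.empty(len(ivs))
    for i, (a, b) in enumerate(zip(ivs.starts, ivs.ends)):
        idx = np.arange(a, b) % n
        out[i] = track[idx].mean()
    return out


def merge_and_idr_filter(
    per_replicate_calls: list[list[EpodCall]],
    scored_tracks: list[np.ndarray],
    alpha: float = 0.05,
) -> IntervalSet:
    """Union-merge replicate-level calls and keep candidates whose worst
    pairwise global IDR is <= alpha.

    Candidates are scored per replicate by the mean robust z inside the
    candidate interval. If the IDR EM fit degenerates (few candidates, or
    no irreproducible mass to anchor the null component), candidates called
    in every replicate are retained instead, with a warning.
    """
    if len(per_replicate_calls) < 2:
        raise ValueError("IDR needs >= 2 replicates")
    all_starts = [c.start for calls in per_replicate_calls for c in calls]
    all_ends = [c.end for calls in per_replicate_calls for c in calls]
    if not all_starts:
        return IntervalSet(np.array([]), np.array([]))
    union = IntervalSet(np.array(all_starts), np.array(all_ends))
    candidates = union.merge(bookended=True)
    if len(candidates) == 0:
        return candidates
    score_matrix = np.vstack(
        [_interval_mean_scores(candidates, t) for t in scored_tracks]
    )
    if len(candidates) < 4:
        warnings.warn("too few candidates for a stable IDR fit; "
                      "retaining candidates called in all replicates")
        keep = _called_in_all(candidates, per_replicate_calls)
    else:
        worst, ok = pairwise_max_idr(score_matrix)
        if ok:
            keep = worst <= alpha
        else:
            keep = _called_in_all(candidates, per_replicate_calls)
    sub = IntervalSet(candidates.starts[keep], candidates.ends[keep])
    sub.scores = score_matrix.mean(axis=0)[keep]
    return sub


def _called_in_all(
    candidates: IntervalSet, per_replicate_calls: list[list[EpodCall]]
) -> np.ndarray:
    keep = np.ones(len(candidates), dtype=bool)
    for calls in per_replicate_calls:
        keep &= candidates.overlaps_any(calls_to_intervals(calls))
    return keep
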