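"""Occupancy-track scoring: quantile normalization, log2 ratios, robust
z-scores, signed log10 p-values, jackknife replicate summaries, and
genotype-difference tracks.

The scoring chain for one genotype is: quantile-normalize all replicate
tracks of all data types together, rescale each track to median 100, add a
0.25 pseudocount, take per-replicate-pair log2(signal/input), convert to
robust z (median/MAD) and signed -log10 two-sided normal p, then summarise
the replicates by delete-one jackknife with a 95% normal CI.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAD_CONSISTENCY = 1.4826  # makes MAD estimate sigma for normal data


@dataclass
class RawTrack:
    genotype: str
    datatype: str  # "inp", "ipod", or "chip"
    replicate: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("coverage values must be nonnegative")


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a (positions x tracks) matrix.

    Each column's sorted values are replaced by the position-wise mean of all
    columns' sorted values; ties within a column receive the mean of the
    reference values their ranks span.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ref = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    for j in range(k):
        col = matrix[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = ref
        # ties: average the reference values assigned within each tied group
        out[:, j] = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
    return out


def normalize_replicates(
    tracks: list[RawTrack], pseudocount: float = 0.25, target_median: float = 100.0
) -> list[RawTrack]:
    """Joint quantile normalization, median scaling to 100, and pseudocount.

    Output tracks all have median exactly ``target_median + pseudocount``.
    Zero-variance tracks cannot be rank-mapped meaningfully; they are passed
    through scaling only, with a warning.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    lengths = {len(t.values) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("tracks differ in length")
    flat = [np.ptp(t.values) == 0 for t in tracks]
    varying = [t for t, f in zip(tracks, flat) if not f]
    if any(flat):
        warnings.warn("zero-variance track(s); quantile step skipped for them")
    if varying:
        mat = np.column_stack([t.values for t in varying])
        qn = quantile_normalize(mat)
    out = []
    j = 0
    for t, f in zip(tracks, flat):
        vals = t.values.copy() if f else qn[:, j]
        if not f:
            j += 1
        med = np.median(vals)
        if med > 0:
            vals = vals * (target_median / med)
        else:
            vals = vals + target_median  # all-zero track: degenerate but defined
        out.append(RawTrack(t.genotype, t.datatype, t.replicate, vals + pseudocount))
    return out


def log2_ratio_tracks(numerator: np.ndarray, input_track: np.ndarray) -> np.ndarray:
    numerator = np.asarray(numerator, float)
    input_track = np.asarray(input_track, float)
    if numerator.shape != input_track.shape:
        raise ValueError("track lengths differ")
    if np.any(numerator <= 0) or np.any(input_track <= 0):
        raise ValueError("tracks must be strictly positive (apply pseudocount first)")
    return np.log2(numerator / input_track)


def robust_scores(log2_ratio: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Robust z = (x - median) / (1.4826 * MAD) and signed -log10 two-sided
    normal tail p-value."""
    x = np.asarray(log2_ratio, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("MAD is zero; score a wider region")
    z = (x - med) / (MAD_CONSISTENCY * mad)
    # two-sided tail, floored to stay finite at extreme z
    logp = np.log10(2.0) + stats.norm.logsf(np.abs(z)) / np.log(10.0)
    logp = np.maximum(logp, np.log10(np.finfo(float).tiny))
    return z, np.sign(z) * (-logp)


def jackknife_summary(
    per_replicate: list[np.ndarray] | np.ndarray, z: float = 1.959964
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delete-one jackknife mean and 95% CI, per position.

    SE^2 = (n-1)/n * sum_i (theta_i - theta_bar)^2 over leave-one-out means.
    """
    mat = np.asarray(per_replicate, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 replicate vectors")
    n = mat.shape[0]
    total = mat.sum(axis=0)
    loo = (total[None, :] - mat) / (n - 1)  # leave-one-out means
    mean = total / n
    loo_bar = loo.mean(axis=0)
    se = np.sqrt((n - 1) / n * ((loo - loo_bar) ** 2).sum(axis=0))
    se[np.ptp(mat, axis=0) == 0] = 0.0  # zero dispersion => exactly zero SE
    return mean, mean - z * se, mean + z * se


def clamped_difference(mutant: np.ndarray, wildtype: np.ndarray) -> np.ndarray:
    """max(mutant, 0) - max(wildtype, 0), the genotype-subtraction rule that
    highlights mutant-specific occupancy while ignoring depleted background."""
    mutant = np.asarray(mutant, float)
    wildtype = np.asarray(wildtype, float)
    if mutant.shape != wildtype.shape:
        raise ValueError("track lengths differ")
    return np.maximum(mutant, 0.0) - np.maximum(wildtype, 0.0)


@dataclass
class ScoredTrack:
    """Replicate-summarised scores for one (genotype, datatype) pair."""

    genotype: str
    datatype: str
    log2_ratio: np.ndarray  # per-replicate matrix (replicates x positions)
    robust_z: np.ndarray
    log10p_signed: np.ndarray
    z_mean: np.ndarray
    z_ci_low: np.ndarray
    z_ci_high: np.ndarray


def score_experiment(
    tracks: list[RawTrack], genotype: str, signal: str = "ipod"
) -> ScoredTrack:
    """Run the full scoring chain for one genotype and signal data type.

    `tracks` holds the raw (un-normalized) tracks of every data type for the
    genotype; normalization is joint, ratios are per paired replicate.
    """
    mine = [t for t in tracks if t.genotype == genotype]
    normed = normalize_replicates(mine)
    by_key = {(t.datatype, t.replicate): t.values for t in normed}
    reps = sorted(r for d, r in by_key if d == signal)
    l2r, rz, lp = [], [], []
    for r in reps:
        if ("inp", r) not in by_key:
            raise ValueError(f"no input track paired with {signal} replicate {r}")
        ratio = log2_ratio_tracks(by_key[(signal, r)], by_key[("inp", r)])
        z, p = robust_scores(ratio)
        l2r.append(ratio)
        rz.append(z)
        lp.append(p)
    mean, lo, hi = jackknife_summary(np.array(rz))
    return ScoredTrack(genotype, signal, np.array(l2r), np.array(rz),
                       np.array(lp), mean, lo, hi)
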