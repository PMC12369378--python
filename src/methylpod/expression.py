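"""Expression integration: directional significance scores, EPOD-vs-non-EPOD
expression contrasts, and the regulon-coherence statistic.

Expression tables carry per-gene log2 fold changes (mutant vs wild type) and
q-values from an upstream transcript quantifier; regulon tables pair a
regulator with its targets and the annotated regulatory mode.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet

Q_FLOOR = 1e-300  # q-values of exactly 0 are floored here

MODE_SIGN = {"activator": 1.0, "repressor": -1.0}


@dataclass(frozen=True)
class RegulonEdge:
    regulator: str
    target: str
    mode: str  # activator | repressor | dual

    def __post_init__(self) -> None:
        if self.mode not in ("activator", "repressor", "dual"):
            raise ValueError(f"unknown regulatory mode {self.mode!r}")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, locus, start, end, log2fc, q (one contrast)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "start", "end", "log2fc", "q"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def read_regulon_table(path: str | Path) -> list[RegulonEdge]:
    df = pd.read_csv(path, sep="\t")
    return [RegulonEdge(r.regulator, r.target, r.mode) for r in df.itertuples()]


def directional_log10q(records: pd.DataFrame) -> pd.Series:
    """sign(log2fc) * (-log10 q) per gene — the continuous input format for
    directional gene-set enrichment. Missing q drops the record."""
    keep = records["q"].notna()
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} record(s) missing q-values were skipped")
    df = records[keep]
    q = np.maximum(df["q"].to_numpy(float), Q_FLOOR)
    vals = np.sign(df["log2fc"].to_numpy(float)) * (-np.log10(q))
    return pd.Series(vals, index=df["gene"].to_numpy(), name="directional_log10q")


def epod_expression_contrast(
    records: pd.DataFrame, epods: IntervalSet
) -> tuple[float, float]:
    """median(log2fc inside EPODs) - median(log2fc outside), with a
    two-sided Wilcoxon rank-sum p comparing the groups.

    A transcript is "inside" when its gene interval overlaps any EPOD by at
    least 1 bp.
    """
    genes = IntervalSet(records["start"].to_numpy(np.int64),
                        records["end"].to_numpy(np.int64))
    inside = genes.overlaps_any(epods)
    fc = records["log2fc"].to_numpy(float)
    if inside.all() or not inside.any():
        raise ValueError("need transcripts both inside and outside EPODs")
    delta = float(np.median(fc[inside]) - np.median(fc[~inside]))
    p = float(stats.ranksums(fc[inside], fc[~inside]).pvalue)
    return delta, p


def regulon_coherence(
    records: pd.DataFrame, edges: list[RegulonEdge], regulator: str
) -> float:
    """Concerted log2 fold change of a regulator's regulon.

    Each non-dual target contributes its log2fc multiplied by +1 for an
    activated target and -1 for a repressed one; the mean over targets is
    positive when the regulon moves as if the regulator's activity increased.
    """
    fc = dict(zip(records["gene"], records["log2fc"].astype(float)))
    vals = [
        MODE_SIGN[e.mode] * fc[e.target]
        for e in edges
        if e.regulator == regulator and e.mode in MODE_SIGN and e.target in fc
    ]
    if not vals:
        raise ValueError(f"no usable (non-dual, measured) targets for {regulator!r}")
    return float(np.mean(vals))


def regulon_coherence_table(
    records: pd.DataFrame, edges: list[RegulonEdge]
) -> pd.DataFrame:
    """Coherence for every regulator with usable targets, with the
    regulator's own log2fc reported alongside for interpretation."""
    fc = dict(zip(records["gene"], records["log2fc"].astype(float)))
    rows = []
    for reg in sorted({e.regulator for e in edges}):
        try:
            coh = regulon_coherence(records, edges, reg)
        except ValueError:
            continue
        n = sum(1 for e in edges
                if e.regulator == reg and e.mode in MODE_SIGN and e.target in fc)
        rows.append({"regulator": reg, "coherence": coh,
                     "n_targets": n, "regulator_log2fc": fc.get(reg, np.nan)})
    return pd.DataFrame(rows)
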