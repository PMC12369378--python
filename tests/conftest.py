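"""Shared fixtures: seeded synthetic datasets reused across test modules.

The heavyweight fixture is the standard occupancy simulation (1 Mb circular
genome, 10 planted 1.5-3 kb domains at 2.5x IPOD enrichment, depth 50, NB
dispersion 0.1, 3 replicates, seed 1); it is session-scoped so scoring and
EPOD calling run once.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from methylpod.epods import EpodCall, call_epods, merge_and_idr_filter
from methylpod.intervals import IntervalSet
from methylpod.scoring import ScoredTrack, score_experiment
from methylpod.simulate import (SimSpec, simulate_genome,
                                simulate_occupancy_experiment,
                                standard_occupancy_spec, truth_epod_intervals)


@dataclass
class StandardSim:
    spec: SimSpec
    scored: ScoredTrack
    strict_calls: list[list[EpodCall]]
    loose_calls: list[list[EpodCall]]
    strict_filtered: IntervalSet
    loose_filtered: IntervalSet
    truth: IntervalSet


@pytest.fixture(scope="session")
def standard_sim() -> StandardSim:
    spec = standard_occupancy_spec(seed=1)
    tracks, _ = simulate_occupancy_experiment(spec)
    scored = score_experiment(tracks, "WT", "ipod")
    strict = [call_epods(z, "strict") for z in scored.robust_z]
    loose = [call_epods(z, "loose") for z in scored.robust_z]
    zs = list(scored.robust_z)
    return StandardSim(
        spec=spec,
        scored=scored,
        strict_calls=strict,
        loose_calls=loose,
        strict_filtered=merge_and_idr_filter(strict, zs, 0.05),
        loose_filtered=merge_and_idr_filter(loose, zs, 0.05),
        truth=truth_epod_intervals(spec),
    )


@pytest.fixture(scope="session")
def cluster_genome():
    """200 kb genome with planted Dam/Dcm clusters of known densities."""
    spec = SimSpec(
        genome_length=200_000,
        seed=3,
        planted_motif_clusters=[
            ("dam", 7, 20_000), ("dam", 7, 50_000), ("dam", 6, 80_000),
            ("dam", 6, 120_000), ("dcm", 4, 150_000),
        ],
    )
    genome, truth = simulate_genome(spec)
    return genome, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
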