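#!/usr/bin/env python
"""Generate the study's synthetic datasets and record their planted truth.

Produces: a 1 Mb occupancy experiment (10 planted 1.5-3 kb domains at 2.5x
IPOD enrichment, depth 50, NB dispersion 0.1, 3 replicates), an 800 kb
genome carrying twelve density-6 and three density-7 Dam clusters, and an
expression table with a planted activator effect. Writes truth tables under
results/ and the full raw dataset (FASTA + bedGraphs) under scratch/sim/.
"""
from pathlib import Path

import pandas as pd

from methylpod.genome import write_fasta
from methylpod.intervals import write_bed
from methylpod.simulate import (SimSpec, simulate_genome,
                                simulate_occupancy_experiment,
                                standard_occupancy_spec,
                                truth_epod_intervals)
from methylpod.trackio import write_bedgraph

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sim"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    spec = standard_occupancy_spec(seed=SEED)
    tracks, truth = simulate_occupancy_experiment(spec)
    for t in tracks:
        write_bedgraph(t.values,
                       SCRATCH / f"WT_{t.datatype}_r{t.replicate}.bedgraph")
    truth.to_json(SCRATCH / "occupancy_truth.json")
    write_bed(truth_epod_intervals(spec), RESULTS / "planted_epods.bed")
    print(f"occupancy experiment: {len(tracks)} tracks, "
          f"{len(spec.planted_epods)} planted domains "
          f"({sum(L for _, L, _ in spec.planted_epods)} bp total)")

    pos6 = [30_000 + 60_000 * i for i in range(12)]
    pos7 = [115_000 + 200_000 * i for i in range(3)]
    gspec = SimSpec(genome_length=800_000, seed=SEED + 1,
                    planted_motif_clusters=(
                        [("dam", 6, p) for p in pos6]
                        + [("dam", 7, p) for p in pos7]))
    genome, gtruth = simulate_genome(gspec)
    write_fasta(genome, SCRATCH / "cluster_genome.fa")
    gtruth.to_json(SCRATCH / "cluster_truth.json")
    rows = [{"class": c["class"], "density": c["density"],
             "position": c["position"]}
            for c in gtruth["planted_motif_clusters"]]
    pd.DataFrame(rows).to_csv(RESULTS / "planted_clusters.tsv", sep="\t",
                              index=False)
    print(f"cluster genome: {len(rows)} planted Dam clusters "
          f"(12 at density 6, 3 at density 7)")


if __name__ == "__main__":
    main()
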