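"""End-to-end pipeline driver over a declarative run configuration.

The configuration (YAML) names the genome FASTA, the coverage tracks by
(genotype, datatype, replicate), optional expression/regulon tables, and
parameter overrides. ``run_pipeline`` executes score -> call-epods ->
sod / site-fraction / shuffle-test -> call-peaks -> expression contrasts ->
read-ends and writes a provenance manifest; identical inputs and seeds give
byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (ShuffleDesign, normalized_site_fraction,
                      poisson_depletion_test, shuffle_intervals,
                      symmetrized_overlap_distance)
from .epods import call_epods, merge_and_idr_filter
from .expression import (directional_log10q, epod_expression_contrast,
                         read_expression_table, read_regulon_table,
                         regulon_coherence_table)
from .genome import read_fasta
from .intervals import IntervalSet, write_bed
from .motifs import scan_motifs
from .peaks import kl_threshold_sweep
from .read_ends import cluster_end_matrix, normalized_end_track
from .scoring import score_experiment
from .trackio import read_bedgraph, write_bedgraph

DEFAULT_PARAMS = {
    "flank": 50,
    "idr_alpha": 0.05,
    "n_shuffles": 1000,
    "n_bins": 10,
    "seed": 0,
    "signal": "ipod",
    "read_end_flank": 100,
}


@dataclass
class RunConfig:
    genome: str
    tracks: dict = field(default_factory=dict)  # genotype -> datatype -> rep -> path
    expression: str | None = None
    regulons: str | None = None
    read_ends: dict | None = None  # genotype -> {"5": path, "3": path}
    out_dir: str = "pipeline_out"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def param(self, key):
        return self.params.get(key, DEFAULT_PARAMS[key])


def _load_raw_tracks(config: RunConfig, genome_length: int):
    from .scoring import RawTrack

    out = []
    for genotype, by_dtype in config.tracks.items():
        for dtype, by_rep in by_dtype.items():
            for rep, path in by_rep.items():
                vals = read_bedgraph(path, genome_length)
                out.append(RawTrack(genotype, dtype, int(rep), vals))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest (also written to
    ``out_dir/manifest.json``). Any stage failure raises with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "params": {k: config.param(k) for k in DEFAULT_PARAMS},
                      "stages": []}
    stage = "read-genome"
    try:
        genome = read_fasta(config.genome)
        n = len(genome)
        manifest["genome"] = {"id": genome.id, "length": n}

        stage = "score-tracks"
        raw = _load_raw_tracks(config, n)
        genotypes = sorted({t.genotype for t in raw})
        scored = {}
        for g in genotypes:
            for signal in ("ipod", "chip"):
                if any(t.genotype == g and t.datatype == signal for t in raw):
                    st = score_experiment(raw, g, signal)
                    scored[(g, signal)] = st
                    write_bedgraph(st.z_mean, out / f"{g}_{signal}_robust_z.bedgraph",
                                   chrom=genome.id)
        manifest["stages"].append({"stage": stage, "n_scored": len(scored)})

        stage = "call-epods"
        epods = {}
        for (g, signal), st in scored.items():
            if signal != config.param("signal"):
                continue
            strict = [call_epods(z, "strict") for z in st.robust_z]
            loose = [call_epods(z, "loose") for z in st.robust_z]
            tracks = list(st.robust_z)
            filt_s = merge_and_idr_filter(strict, tracks, config.param("idr_alpha"))
            filt_l = merge_and_idr_filter(loose, tracks, config.param("idr_alpha"))
            epods[g] = {"strict": filt_s, "loose": filt_l}
            for mode, ivs in epods[g].items():
                ivs.chrom = genome.id
                write_bed(ivs, out / f"{g}_epods_{mode}.bed")
        manifest["stages"].append(
            {"stage": stage,
             "n_epods": {g: len(v["strict"]) for g, v in epods.items()}})

        stage = "sod"
        sod_rows = []
        for i, a in enumerate(genotypes):
            for b in genotypes[i + 1:]:
                if a in epods and b in epods and len(epods[a]["strict"]) and len(epods[b]["strict"]):
                    sod = symmetrized_overlap_distance(
                        epods[a]["strict"], epods[a]["loose"],
                        epods[b]["strict"], epods[b]["loose"])
                    sod_rows.append({"comparison": f"{a}_vs_{b}",
                                     "statistic": "sod", "estimate": sod})
        if sod_rows:
            pd.DataFrame(sod_rows).to_csv(out / "sod.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "n_pairs": len(sod_rows)})

        stage = "site-fraction"
        sites = scan_motifs(genome, ("dam",))
        frac_rows = []
        for g, sets in epods.items():
            if len(sets["strict"]) == 0:
                continue
            ratio, ci = normalized_site_fraction(sites, sets["strict"], n)
            frac_rows.append({"comparison": g, "statistic": "dam_site_fraction",
                              "estimate": ratio, "ci_low": ci[0], "ci_high": ci[1]})
        if frac_rows:
            pd.DataFrame(frac_rows).to_csv(out / "site_fraction.tsv", sep="\t",
                                           index=False)
        manifest["stages"].append({"stage": stage, "n_rows": len(frac_rows)})

        stage = "shuffle-test"
        dep_rows = []
        for g, sets in epods.items():
            if len(sets["strict"]) < config.param("n_bins"):
                continue
            design = ShuffleDesign(n_shuffles=config.param("n_shuffles"),
                                   n_bins=config.param("n_bins"),
                                   seed=config.param("seed"))
            shuffles = shuffle_intervals(sets["strict"], n, design)
            beta, ci, p = poisson_depletion_test(sets["strict"], shuffles,
                                                 sites, design, genome)
            dep_rows.append({"comparison": g, "statistic": "poisson_beta_genomic",
                             "estimate": beta, "ci_low": ci[0], "ci_high": ci[1],
                             "p": p})
        if dep_rows:
            pd.DataFrame(dep_rows).to_csv(out / "depletion.tsv", sep="\t",
                                          index=False)
        manifest["stages"].append({"stage": stage, "n_rows": len(dep_rows)})

        stage = "call-peaks"
        peak_sets = {}
        for (g, signal), st in scored.items():
            if signal != "chip":
                continue
            sweep = kl_threshold_sweep(st.z_mean, seed=config.param("seed"))
            peak_sets[g] = sweep
            sweep.peaks_at_2.chrom = genome.id
            write_bed(sweep.peaks_at_2, out / f"{g}_peaks_2.0.bed")
            pd.DataFrame({"threshold": sweep.thresholds,
                          "n_peaks": sweep.n_peaks,
                          "kl": sweep.kl_values}).to_csv(
                out / f"{g}_kl_sweep.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"stage": stage,
             "best_thresholds": {g: s.best_threshold for g, s in peak_sets.items()}})

        if config.expression:
            stage = "expression"
            expr = read_expression_table(config.expression)
            directional_log10q(expr).to_csv(out / "directional_log10q.tsv",
                                            sep="\t", header=True)
            wt = genotypes[0]
            if wt in epods and len(epods[wt]["strict"]):
                delta, p = epod_expression_contrast(expr, epods[wt]["strict"])
                pd.DataFrame([{"comparison": "epod_vs_nonepod",
                               "statistic": "delta_median_log2fc",
                               "estimate": delta, "p": p}]).to_csv(
                    out / "expr_contrast.tsv", sep="\t", index=False)
            if config.regulons:
                edges = read_regulon_table(config.regulons)
                regulon_coherence_table(expr, edges).to_csv(
                    out / "regulon_coherence.tsv", sep="\t", index=False)
            manifest["stages"].append({"stage": stage})

        if config.read_ends:
            stage = "read-ends"
            for g, paths in config.read_ends.items():
                e5 = read_bedgraph(paths["5"], n)
                e3 = read_bedgraph(paths["3"], n)
                track = normalized_end_track(e5, e3)
                write_bedgraph(track.normalized,
                               out / f"{g}_read_ends_per_million.bedgraph",
                               chrom=genome.id)
            manifest["stages"].append({"stage": stage})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
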