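"""Seeded synthetic datasets with planted ground truth.

Everything the pipeline consumes can be generated here: circular genomes
with controlled GC and planted methylation-motif clusters, negative-binomial
coverage tracks with planted occupancy domains and promoter-scale peaks,
expression tables with regulator-mode-consistent planted effects, and
read-end tracks. Every simulator takes a seed and emits a machine-readable
truth record so recovery tests never peek at internals.

The default occupancy conditions — 1 Mb circular genome, 10 planted domains
of 1.5-3 kb at 2.5x enrichment, mean depth 50, NB dispersion 0.1, 3
replicates — are the standard study conditions used throughout the test
suite and the acceptance script.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .genome import GenomeSequence
from .intervals import IntervalSet
from .motifs import MOTIF_LENGTH, MOTIFS, scan_motifs
from .scoring import RawTrack

BASES = np.array(list("ACGT"))


@dataclass
class SimSpec:
    genome_length: int = 1_000_000
    gc: float = 0.508  # E. coli-like GC content
    planted_motif_clusters: list = field(default_factory=list)  # (class, density, position)
    planted_epods: list = field(default_factory=list)  # (start, length, enrichment)
    planted_peaks: list = field(default_factory=list)  # (position, width, height)
    replicates: int = 3
    depth: float = 50.0
    nb_dispersion: float = 0.1
    expression_effects: list = field(default_factory=list)  # (regulator, mode, delta, noise_sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        for _, _, enr in self.planted_epods:
            if enr <= 0:
                raise ValueError("enrichment must be positive")


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside every simulated dataset."""

    payload: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.payload[key]

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(self.payload, indent=1, default=default))


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=n, p=p).astype(np.int8)


def _find_class_sites(seq_str: str, cls: str) -> list[int]:
    hits = []
    for word in MOTIFS[cls]:
        start = seq_str.find(word)
        while start != -1:
            hits.append(start)
            start = seq_str.find(word, start + 1)
    return sorted(hits)


def simulate_genome(spec: SimSpec) -> tuple[GenomeSequence, TruthSet]:
    """Random circular genome with motif clusters planted verbatim.

    A cluster of class c, density d is written as d same-class motifs spaced
    so that the central site's flanked window contains exactly d motifs; the
    surrounding region is scrubbed of accidental same-class matches first.
    """
    rng = np.random.default_rng(spec.seed)
    codes = _random_sequence(rng, spec.genome_length, spec.gc)
    planted = []
    for cls, density, pos in spec.planted_motif_clusters:
        mlen = MOTIF_LENGTH[cls]
        max_density = (100 // mlen) + 1  # sites fitting in flank+motif span
        if density < 1 or density > max_density:
            raise ValueError(
                f"density {density} impossible for {cls} in a "
                f"{100 + mlen} bp window (max {max_density})"
            )
        spacing = mlen if density == 1 else min(8, max(mlen, 100 // (density - 1)))
        span = (density - 1) * spacing + mlen
        if span > 100 + mlen:
            spacing = max(mlen, 100 // max(density - 1, 1))
            span = (density - 1) * spacing + mlen
        center_idx = (density - 1) // 2
        site_starts = [
            (pos + (i - center_idx) * spacing) % spec.genome_length
            for i in range(density)
        ]
        word = MOTIFS[cls][0]
        word_codes = np.array(["ACGT".index(b) for b in word], dtype=np.int8)
        scrub_lo, scrub_hi = pos - 60 - span, pos + 60 + span
        _scrub_region(codes, scrub_lo, scrub_hi, cls, rng,
                      protected=set())
        for s in site_starts:
            idx = (s + np.arange(mlen)) % spec.genome_length
            codes[idx] = word_codes
        protected = {(s + k) % spec.genome_length
                     for s in site_starts for k in range(mlen)}
        _scrub_region(codes, scrub_lo, scrub_hi, cls, rng, protected=protected)
        planted.append({"class": cls, "density": density, "position": pos,
                        "site_starts": sorted(site_starts)})
    byte_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = byte_bases[codes].tobytes().decode("ascii")
    genome = GenomeSequence(id=f"sim_{spec.seed}", seq=seq, circular=True)
    truth = TruthSet({"seed": spec.seed, "genome_length": spec.genome_length,
                      "gc": spec.gc, "planted_motif_clusters": planted})
    return genome, truth


def _scrub_region(
    codes: np.ndarray, lo: int, hi: int, cls: str,
    rng: np.random.Generator, protected: set[int]
) -> None:
    """Mutate away same-class motif occurrences in [lo, hi) that contain any
    unprotected base, without touching protected positions."""
    n = len(codes)
    mlen = MOTIF_LENGTH[cls]
    for _ in range(200):
        idx = np.arange(lo - mlen, hi + mlen) % n
        text = "".join(BASES[codes[idx]])
        offenders = []
        for s_rel in _find_class_sites(text, cls):
            positions = [(lo - mlen + s_rel + k) % n for k in range(mlen)]
            free = [p for p in positions if p not in protected]
            if len(free) == len(positions):  # fully unprotected: accidental
                offenders.append(free)
            elif free:
                offenders.append(free)  # stray overlapping a planted edge
        if not offenders:
            return
        for free in offenders:
            p = free[len(free) // 2]
            old = codes[p]
            choices = [c for c in range(4) if c != old]
            codes[p] = rng.choice(choices)
    raise RuntimeError("could not scrub region free of accidental motifs")


def _nb_draw(rng, mean: np.ndarray, dispersion: float, size=None) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def expected_tracks(spec: SimSpec) -> dict[str, np.ndarray]:
    """Per-channel expected (noise-free) coverage means."""
    n = spec.genome_length
    base = np.full(n, spec.depth)
    ipod = base.copy()
    for start, length, enr in spec.planted_epods:
        idx = (start + np.arange(length)) % n
        ipod[idx] = spec.depth * enr
    chip = base.copy()
    for pos, width, height in spec.planted_peaks:
        idx = (pos - width // 2 + np.arange(width)) % n
        chip[idx] = spec.depth * height
    return {"inp": base, "ipod": ipod, "chip": chip}


def simulate_occupancy_experiment(
    spec: SimSpec, genotype: str = "WT"
) -> tuple[list[RawTrack], TruthSet]:
    """Negative-binomial coverage tracks for one genotype: input, IPOD (with
    planted domains), and RNAP-ChIP (with planted peaks), per replicate."""
    if spec.depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(spec.seed)
    means = expected_tracks(spec)
    tracks = []
    for rep in range(1, spec.replicates + 1):
        for dtype in ("inp", "ipod", "chip"):
            vals = _nb_draw(rng, means[dtype], spec.nb_dispersion).astype(float)
            tracks.append(RawTrack(genotype, dtype, rep, vals))
    truth = TruthSet({
        "seed": spec.seed,
        "genotype": genotype,
        "planted_epods": [
            {"start": s, "end": s + L, "enrichment": e}
            for s, L, e in spec.planted_epods
        ],
        "planted_peaks": [
            {"position": p, "width": w, "height": h}
            for p, w, h in spec.planted_peaks
        ],
        "depth": spec.depth,
        "nb_dispersion": spec.nb_dispersion,
    })
    return tracks, truth


def standard_occupancy_spec(seed: int = 1, genome_length: int = 1_000_000,
                            n_domains: int = 10, enrichment: float = 2.5,
                            depth: float = 50.0, dispersion: float = 0.1,
                            replicates: int = 3) -> SimSpec:
    """The standard study conditions: 10 well-separated 1.5-3 kb domains at
    2.5x IPOD enrichment on a 1 Mb circular genome, depth 50, NB dispersion
    0.1, 3 replicates."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(1500, 3001, size=n_domains)
    # anchor domains on an even grid with jitter so they never collide
    pitch = genome_length // n_domains
    offsets = rng.integers(0, pitch - 3200, size=n_domains)
    starts = np.arange(n_domains) * pitch + offsets
    epods = [(int(s), int(L), enrichment) for s, L in zip(starts, lengths)]
    return SimSpec(genome_length=genome_length, planted_epods=epods,
                   replicates=replicates, depth=depth,
                   nb_dispersion=dispersion, seed=seed)


def truth_epod_intervals(spec: SimSpec) -> IntervalSet:
    return IntervalSet(
        np.array([s for s, _, _ in spec.planted_epods]),
        np.array([s + L for s, L, _ in spec.planted_epods]),
    )


def simulate_expression(
    spec: SimSpec, edges, n_genes: int = 2000, gene_length: int = 900,
) -> tuple["pd.DataFrame", TruthSet]:
    """Expression table with planted regulator-mode-consistent effects.

    Genes tile the genome evenly; baseline log2fc is Normal(0, noise_sd) and
    each (regulator, mode, delta, noise_sd) effect adds mode_sign * delta to
    that regulator's non-dual targets. q-values come from two-sided z-tests
    against the noise scale with Benjamini-Hochberg adjustment.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(spec.seed)
    names = [f"g{i:04d}" for i in range(n_genes)]
    pitch = spec.genome_length // n_genes
    starts = np.arange(n_genes) * pitch
    noise_sd = spec.expression_effects[0][3] if spec.expression_effects else 0.3
    log2fc = rng.normal(0.0, noise_sd, size=n_genes)
    truth_effects = []
    name_idx = {g: i for i, g in enumerate(names)}
    sign = {"activator": 1.0, "repressor": -1.0}
    for regulator, mode, delta, _sd in spec.expression_effects:
        targets = [e.target for e in edges
                   if e.regulator == regulator and e.mode != "dual"]
        for e in edges:
            if e.regulator == regulator and e.mode != "dual" and e.target in name_idx:
                log2fc[name_idx[e.target]] += sign[e.mode] * delta
        truth_effects.append({"regulator": regulator, "mode": mode,
                              "delta": delta, "n_targets": len(targets)})
    z = log2fc / noise_sd
    p = 2 * stats.norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame({
        "gene": names,
        "locus": [f"b{i:04d}" for i in range(n_genes)],
        "start": starts,
        "end": starts + gene_length,
        "log2fc": log2fc,
        "q": q,
    })
    truth = TruthSet({"seed": spec.seed, "noise_sd": noise_sd,
                      "effects": truth_effects})
    return df, truth


def simulate_read_ends(
    spec: SimSpec, rate: float = 0.05,
    pileups: list | None = None,
) -> tuple[np.ndarray, np.ndarray, TruthSet]:
    """Poisson 5'/3' end-count tracks with optional planted pile-ups
    (position, fold) multiplying the local rate."""
    rng = np.random.default_rng(spec.seed)
    lam5 = np.full(spec.genome_length, rate)
    lam3 = np.full(spec.genome_length, rate)
    for pos, fold in pileups or []:
        lam5[pos % spec.genome_length] *= fold
        lam3[pos % spec.genome_length] *= fold
    ends5 = rng.poisson(lam5)
    ends3 = rng.poisson(lam3)
    truth = TruthSet({"seed": spec.seed, "rate": rate,
                      "pileups": [list(p) for p in (pileups or [])]})
    return ends5, ends3, truth
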