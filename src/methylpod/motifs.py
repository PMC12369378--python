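"""Methyltransferase target-motif scanning, windowing, and density flagging.

Dam methylates adenine in 5'-GATC-3'; Dcm methylates the internal cytosine in
5'-CCWGG-3' (CCAGG / CCTGG). GATC is its own reverse complement and the two
Dcm words are mutual reverse complements, so scanning the forward strand
reports every genomic occurrence exactly once.

Each site is flanked by 50 bp on both sides (104 bp windows for Dam, 105 bp
for Dcm), and the "site density" of a window is the number of same-class
sites whose full motif lies within the window — the central site always
counts, so density >= 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeSequence
from .intervals import IntervalSet

MOTIFS = {"dam": ("GATC",), "dcm": ("CCAGG", "CCTGG")}
MOTIF_LENGTH = {"dam": 4, "dcm": 5}


@dataclass(frozen=True)
class MotifSite:
    motif_class: str  # "dam" or "dcm"
    start: int  # 0-based; may exceed genome length only transiently, never stored
    end: int  # half-open
    matched_text: str


@dataclass(frozen=True)
class MotifWindow:
    site: MotifSite
    win_start: int  # may be negative conceptually; stored mod genome length
    win_end: int  # win_start + window length (can exceed genome length = wrap)
    density: int


def scan_motifs(genome: GenomeSequence, classes=("dam",)) -> list[MotifSite]:
    """Find all forward-strand motif occurrences, sorted by start.

    For circular genomes, matches spanning the origin are included (their
    start lies near the end of the sequence and end wraps past it).
    """
    bad = set(classes) - set(MOTIFS)
    if bad:
        raise ValueError(f"unknown motif classes: {sorted(bad)}")
    n = len(genome)
    sites: list[MotifSite] = []
    for cls in classes:
        mlen = MOTIF_LENGTH[cls]
        # append a wrap margin so origin-spanning matches are found once
        margin = mlen - 1 if genome.circular else 0
        text = genome.seq + genome.seq[:margin]
        for word in MOTIFS[cls]:
            start = text.find(word)
            while start != -1:
                if start < n:  # starts within the genome => unique occurrence
                    sites.append(MotifSite(cls, start, start + mlen, word))
                start = text.find(word, start + 1)
    sites.sort(key=lambda s: (s.start, s.motif_class))
    return sites


def extend_and_flag(
    sites: list[MotifSite], genome: GenomeSequence, flank: int = 50
) -> list[MotifWindow]:
    """Extend each site by `flank` bp per side and count same-class sites
    whose full motif lies inside the extended window.

    Circular genomes wrap across the origin; linear genomes clamp at the ends.
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    n = len(genome)
    by_class: dict[str, np.ndarray] = {}
    for cls in {s.motif_class for s in sites}:
        arr = np.array(
            sorted(s.start for s in sites if s.motif_class == cls), dtype=np.int64
        )
        by_class[cls] = arr
    windows = []
    for site in sites:
        mlen = site.end - site.start
        if mlen + 2 * flank > n:
            raise ValueError("window longer than genome")
        if genome.circular:
            w0, w1 = site.start - flank, site.end + flank
        else:
            w0, w1 = max(0, site.start - flank), min(n, site.end + flank)
        starts = by_class[site.motif_class]
        # a same-class site [s, s+mlen) is inside iff w0 <= s and s+mlen <= w1,
        # evaluated on the circle when wrapping
        if genome.circular:
            # shift coordinates so the window starts at 0
            rel = (starts - w0) % n
            count = int(np.count_nonzero(rel + mlen <= w1 - w0))
        else:
            count = int(
                np.count_nonzero((starts >= w0) & (starts + mlen <= w1))
            )
        windows.append(MotifWindow(site, w0 % n if genome.circular else w0,
                                   (w0 % n if genome.circular else w0) + (w1 - w0),
                                   count))
    return windows


def collapse_density_loci(
    windows: list[MotifWindow], density: int, genome_length: int | None = None
) -> IntervalSet:
    """Select windows with exactly the given density and merge overlapping or
    bookended selections into maximal contiguous loci.

    This is the rule behind "unique loci" at a given site density: several
    clustered sites each carry a window with the same density flag, and those
    windows overlap, so a cluster collapses to a single locus.
    """
    if density < 1:
        raise ValueError("density must be >= 1")
    sel = [w for w in windows if w.density == density]
    if not sel:
        return IntervalSet(np.array([]), np.array([]))
    starts = np.array([w.win_start for w in sel], dtype=np.int64)
    ends = np.array([w.win_end for w in sel], dtype=np.int64)
    merged = IntervalSet(starts, ends).merge(bookended=True)
    if genome_length is not None and len(merged) >= 2:
        # circular closure: if the last locus wraps onto the first, join them
        first_s, last_e = merged.starts[0], merged.ends[-1]
        if last_e - genome_length >= first_s:
            new_starts = merged.starts[:-1].copy()
            new_ends = merged.ends[:-1].copy()
            new_starts[0] = merged.starts[-1]
            new_ends[0] = max(last_e, merged.ends[0] + genome_length)
            order = np.argsort(new_starts)
            merged = IntervalSet(new_starts[order], new_ends[order])
    return merged


def density_census(
    genome: GenomeSequence, motif_class: str = "dam", flank: int = 50
) -> dict[int, int]:
    """Unique-locus count per density level for one motif class."""
    sites = scan_motifs(genome, (motif_class,))
    windows = extend_and_flag(sites, genome, flank)
    levels = sorted({w.density for w in windows})
    return {
        d: len(collapse_density_loci(windows, d, len(genome))) for d in levels
    }


def collapse_rule_sensitivity(
    windows: list[MotifWindow], density: int, genome_length: int
) -> dict[str, int]:
    """Unique-locus counts for the given density under alternative collapsing
    rules, for reporting how sensitive the census is to the rule choice.

    Rules: ``merge_bookended`` (default: union of overlapping-or-touching
    windows), ``merge_overlap`` (strict >=1 bp overlap only), ``at_least``
    (windows with density >= the level, then merged).
    """
    sel_eq = [w for w in windows if w.density == density]
    sel_ge = [w for w in windows if w.density >= density]

    def n_loci(sel, bookended):
        if not sel:
            return 0
        ivs = IntervalSet(
            np.array([w.win_start for w in sel]),
            np.array([w.win_end for w in sel]),
        ).merge(bookended=bookended)
        return len(ivs)

    return {
        "merge_bookended": len(collapse_density_loci(windows, density, genome_length)),
        "merge_overlap": n_loci(sel_eq, False),
        "at_least": n_loci(sel_ge, True),
    }
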