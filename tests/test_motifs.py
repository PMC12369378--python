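"""Motif scanning, window densities, and cluster collapsing."""
import re

import numpy as np
import pytest

from methylpod.genome import GenomeSequence
from methylpod.motifs import (collapse_density_loci, collapse_rule_sensitivity,
                              density_census, extend_and_flag, scan_motifs)
from methylpod.simulate import SimSpec, simulate_genome


def _g(seq, circular=True):
    return GenomeSequence(id="t", seq=seq, circular=circular)


class TestScanMotifs:
    def test_single_dam_site(self):
        sites = scan_motifs(_g("AAGATCAA"), ("dam",))
        assert [(s.start, s.end) for s in sites] == [(2, 6)]
        assert sites[0].matched_text == "GATC"

    def test_adjacent_sites_both_reported(self):
        sites = scan_motifs(_g("GATCGATC", circular=False), ("dam",))
        assert [(s.start, s.end) for s in sites] == [(0, 4), (4, 8)]

    def test_dcm_both_words(self):
        sites = scan_motifs(_g("CCAGGTTCCTGG", circular=False), ("dcm",))
        assert [(s.start, s.matched_text) for s in sites] == [
            (0, "CCAGG"), (7, "CCTGG")]

    def test_origin_spanning_match_circular_only(self):
        # GA|TC wraps: sequence ends GA, begins TC
        g_circ = _g("TCAAAAGA", circular=True)
        g_lin = _g("TCAAAAGA", circular=False)
        assert [(s.start) for s in scan_motifs(g_circ, ("dam",))] == [6]
        assert scan_motifs(g_lin, ("dam",)) == []

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError, match="position 2"):
            _g("AAXGATC")

    def test_rejects_unknown_class(self):
        with pytest.raises(ValueError, match="unknown motif"):
            scan_motifs(_g("GATC"), ("dam", "bogus"))

    def test_count_matches_regex_oracle_on_random_sequence(self):
        rng = np.random.default_rng(7)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        g = _g(seq, circular=False)
        for classes, pattern in (
            (("dam",), "(?=GATC)"),
            (("dcm",), "(?=CCAGG|CCTGG)"),
        ):
            oracle = len(re.findall(pattern, seq))
            assert len(scan_motifs(g, classes)) == oracle

    def test_total_count_invariant_under_rotation(self):
        rng = np.random.default_rng(11)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        base = len(scan_motifs(_g(seq), ("dam", "dcm")))
        for k in (1, 17, 2500, 4999):
            rot = seq[k:] + seq[:k]
            assert len(scan_motifs(_g(rot), ("dam", "dcm"))) == base


class TestExtendAndFlag:
    def test_isolated_site_density_one(self):
        seq = "A" * 5000 + "GATC" + "A" * 5000
        g = _g(seq)
        wins = extend_and_flag(scan_motifs(g, ("dam",)), g)
        assert len(wins) == 1
        assert wins[0].density == 1
        assert wins[0].win_end - wins[0].win_start == 104

    def test_planted_cluster_density_seven(self, cluster_genome):
        genome, truth = cluster_genome
        wins = extend_and_flag(scan_motifs(genome, ("dam",)), genome)
        for cl in truth["planted_motif_clusters"]:
            if cl["class"] != "dam":
                continue
            central = [w.density for w in wins
                       if w.site.start in cl["site_starts"]]
            assert all(d == cl["density"] for d in central)

    def test_density_matches_brute_force(self, cluster_genome):
        genome, _ = cluster_genome
        sites = scan_motifs(genome, ("dam",))
        wins = extend_and_flag(sites, genome)
        starts = np.array([s.start for s in sites])
        n = len(genome)
        for w in wins[::37]:  # spot-check across the genome
            rel = (starts - w.win_start) % n
            brute = int(np.sum(rel + 4 <= w.win_end - w.win_start))
            assert w.density == brute

    def test_linear_genome_clamps_at_ends(self):
        g = _g("GATC" + "A" * 200, circular=False)
        wins = extend_and_flag(scan_motifs(g, ("dam",)), g)
        assert wins[0].win_start == 0
        assert wins[0].win_end == 54  # clamped left, full right flank

    def test_window_longer_than_genome_errors(self):
        g = _g("AGATCA")
        with pytest.raises(ValueError, match="longer than genome"):
            extend_and_flag(scan_motifs(g, ("dam",)), g, flank=50)


class TestCollapseDensityLoci:
    def test_overlapping_windows_merge_to_one_locus(self, cluster_genome):
        genome, truth = cluster_genome
        wins = extend_and_flag(scan_motifs(genome, ("dam",)), genome)
        loci7 = collapse_density_loci(wins, 7, len(genome))
        loci6 = collapse_density_loci(wins, 6, len(genome))
        # two planted clusters per density, each collapsing to one locus
        assert len(loci7) == 2
        assert len(loci6) == 2

    def test_disjoint_windows_stay_separate(self):
        seq = ("T" * 1000 + "GATC" + "T" * 1000) * 2 + "T" * 1000
        g = _g(seq)
        wins = extend_and_flag(scan_motifs(g, ("dam",)), g)
        loci = collapse_density_loci(wins, 1, len(g))
        assert len(loci) == 2

    def test_loci_are_disjoint_and_cover_selected_windows(self, cluster_genome):
        genome, _ = cluster_genome
        wins = extend_and_flag(scan_motifs(genome, ("dam",)), genome)
        for level in (1, 2, 6, 7):
            loci = collapse_density_loci(wins, level, len(genome))
            if len(loci) < 2:
                continue
            s = loci.sort()
            assert np.all(s.starts[1:] >= s.ends[:-1])

    def test_invalid_density_errors(self):
        with pytest.raises(ValueError):
            collapse_density_loci([], 0)

    def test_census_reports_all_levels(self, cluster_genome):
        genome, _ = cluster_genome
        census = density_census(genome, "dam")
        assert census[7] == 2 and census[6] == 2
        assert all(v >= 1 for v in census.values())

    def test_sensitivity_report_has_alternative_rules(self, cluster_genome):
        genome, _ = cluster_genome
        wins = extend_and_flag(scan_motifs(genome, ("dam",)), genome)
        rep = collapse_rule_sensitivity(wins, 7, len(genome))
        assert set(rep) == {"merge_bookended", "merge_overlap", "at_least"}
        assert rep["at_least"] >= rep["merge_bookended"] > 0


def test_simulated_background_motif_rate_matches_expectation():
    spec = SimSpec(genome_length=500_000, gc=0.5, seed=21)
    genome, _ = simulate_genome(spec)
    n_dam = len(scan_motifs(genome, ("dam",)))
    p = 0.25**4
    expected = spec.genome_length * p
    sd = np.sqrt(spec.genome_length * p * (1 - p))
    assert abs(n_dam - expected) < 3 * sd
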