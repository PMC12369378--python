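"""Interval-set comparisons: SOD, site fractions, shuffles, depletion
regression, window occupancancy, and density-stratified contrasts."""
import numpy as np
import pytest
from scipy import stats

from methylpod.compare import (ShuffleDesign, density_stratified_contrast,
                               interval_at_fraction, normalized_site_fraction,
                               poisson_depletion_test, shuffle_intervals,
                               symmetrized_overlap_distance,
                               window_mean_occupancy)
from methylpod.intervals import IntervalSet
from methylpod.motifs import MotifSite, extend_and_flag, scan_motifs
from methylpod.simulate import SimSpec, simulate_genome


def _ivs(pairs):
    s, e = zip(*pairs)
    return IntervalSet(np.array(s), np.array(e))


def _sites(positions):
    return [MotifSite("dam", int(p), int(p) + 4, "GATC") for p in positions]


class TestSymmetrizedOverlapDistance:
    def test_identical_sets_distance_zero(self):
        a = _ivs([(0, 100), (500, 700)])
        assert symmetrized_overlap_distance(a, a, a, a) == 0.0

    def test_disjoint_sets_distance_one(self):
        a = _ivs([(0, 100)])
        b = _ivs([(500, 700)])
        assert symmetrized_overlap_distance(a, a, b, b) == 1.0

    def test_quarter_fractions_give_three_quarters(self):
        # 4 strict intervals per side, exactly 1 overlapped by the other's
        # loose set => A_B = B_A = 0.25 => 1 - sqrt(1/16) = 0.75
        strict_a = _ivs([(0, 10), (100, 110), (200, 210), (300, 310)])
        strict_b = _ivs([(5, 15), (1100, 1110), (1200, 1210), (1300, 1310)])
        sod = symmetrized_overlap_distance(strict_a, strict_a,
                                           strict_b, strict_b)
        assert np.isclose(sod, 0.75)

    def test_symmetry_under_exchange(self, rng):
        for _ in range(20):
            a = _ivs(sorted((int(s), int(s) + int(l)) for s, l in zip(
                rng.integers(0, 9000, 5), rng.integers(10, 200, 5))))
            b = _ivs(sorted((int(s), int(s) + int(l)) for s, l in zip(
                rng.integers(0, 9000, 5), rng.integers(10, 200, 5))))
            am, bm = a.merge(), b.merge()
            d1 = symmetrized_overlap_distance(am, am, bm, bm)
            d2 = symmetrized_overlap_distance(bm, bm, am, am)
            assert np.isclose(d1, d2)
            assert 0.0 <= d1 <= 1.0

    def test_empty_strict_set_rejected(self):
        a = _ivs([(0, 10)])
        empty = IntervalSet(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            symmetrized_overlap_distance(empty, empty, a, a)


class TestNormalizedSiteFraction:
    def test_all_sites_inside_tenth_of_genome(self):
        ivs = _ivs([(0, 1000)])
        ratio, _ = normalized_site_fraction(_sites([10, 500, 900]), ivs, 10_000)
        assert np.isclose(ratio, 10.0)

    def test_no_sites_inside_gives_zero(self):
        ivs = _ivs([(5000, 6000)])
        ratio, _ = normalized_site_fraction(_sites([10, 500]), ivs, 10_000)
        assert ratio == 0.0

    def test_uniform_sites_ratio_near_one_with_ci(self, rng):
        n = 1_000_000
        sites = _sites(np.sort(rng.choice(n, 4000, replace=False)))
        starts = np.sort(rng.choice(np.arange(0, n - 2000, 5000), 100,
                                    replace=False))
        ivs = IntervalSet(starts, starts + rng.integers(500, 2000, 100))
        ratio, (lo, hi) = normalized_site_fraction(sites, ivs, n)
        assert lo <= 1.0 <= hi
        assert abs(ratio - 1.0) < 0.3

    def test_zero_coverage_rejected(self):
        empty = IntervalSet(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            normalized_site_fraction(_sites([1]), empty, 1000)


class TestShuffleIntervals:
    def test_lengths_preserved_every_shuffle(self, rng):
        ivs = _ivs([(0, 150), (1000, 1300), (5000, 5020)])
        out = shuffle_intervals(ivs, 100_000, ShuffleDesign(n_shuffles=20, seed=4))
        for sh in out:
            assert sorted(sh.lengths) == sorted(ivs.lengths)

    def test_no_overlap_mode_shares_zero_bp(self):
        starts = np.arange(0, 50_000, 5000)
        ivs = IntervalSet(starts, starts + 1000)
        out = shuffle_intervals(
            ivs, 100_000,
            ShuffleDesign(n_shuffles=10, allow_overlap_genomic=False, seed=4))
        orig_mask = ivs.coverage_mask(100_000)
        for sh in out:
            assert not np.any(sh.coverage_mask(100_000) & orig_mask)

    def test_start_positions_uniform_chi_squared(self):
        ivs = _ivs([(0, 100)])
        out = shuffle_intervals(ivs, 20_000, ShuffleDesign(n_shuffles=1000, seed=8))
        starts = np.array([sh.starts[0] for sh in out])
        counts, _ = np.histogram(starts, bins=20, range=(0, 20_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_reproducible_from_seed(self):
        ivs = _ivs([(0, 100), (300, 450)])
        d = ShuffleDesign(n_shuffles=5, seed=42)
        a = shuffle_intervals(ivs, 10_000, d)
        b = shuffle_intervals(ivs, 10_000, d)
        for x, y in zip(a, b):
            assert np.array_equal(x.starts, y.starts)

    def test_crowded_genome_rejected(self):
        ivs = _ivs([(0, 999)])
        with pytest.raises(RuntimeError, match="10,000"):
            shuffle_intervals(
                ivs, 1000,
                ShuffleDesign(n_shuffles=1, allow_overlap_genomic=False, seed=0))


@pytest.fixture(scope="module")
def depletion_setup():
    spec = SimSpec(genome_length=400_000, seed=12)
    genome, _ = simulate_genome(spec)
    rng = np.random.default_rng(99)
    starts = np.sort(rng.choice(np.arange(0, 395_000, 3500), 100, replace=False))
    ivs = IntervalSet(starts, starts + rng.integers(800, 1500, 100))
    return genome, ivs, rng


class TestPoissonDepletion:
    def test_null_ci_covers_zero(self, depletion_setup):
        genome, ivs, _ = depletion_setup
        rng = np.random.default_rng(7)
        pos = np.flatnonzero(rng.random(len(genome)) < 1 / 256)
        design = ShuffleDesign(n_shuffles=200, seed=5)
        sh = shuffle_intervals(ivs, len(genome), design)
        beta, (lo, hi), p = poisson_depletion_test(
            ivs, sh, _sites(pos), design, genome)
        assert lo <= 0 <= hi

    def test_planted_thinning_recovered(self, depletion_setup):
        genome, ivs, _ = depletion_setup
        rng = np.random.default_rng(8)
        mask = ivs.coverage_mask(len(genome))
        pos = np.flatnonzero(rng.random(len(genome)) < 1 / 256)
        keep = np.where(mask[pos], rng.random(len(pos)) < np.exp(-0.4), True)
        design = ShuffleDesign(n_shuffles=300, allow_overlap_genomic=False,
                               seed=5)
        sh = shuffle_intervals(ivs, len(genome), design)
        beta, (lo, hi), p = poisson_depletion_test(
            ivs, sh, _sites(pos[keep]), design, genome)
        assert abs(beta - (-0.4)) < 0.2
        assert hi < 0

    def test_degenerate_design_rejected(self, depletion_setup):
        genome, ivs, _ = depletion_setup
        design = ShuffleDesign(n_shuffles=1, seed=0)
        with pytest.raises(ValueError, match="indicator"):
            poisson_depletion_test(ivs, [], _sites([100]), design, genome)

    def test_at_fraction_matches_slice_count(self, depletion_setup):
        genome, ivs, _ = depletion_setup
        at = interval_at_fraction(ivs, genome)
        for i in (0, 17, 50):
            s = genome.slice(int(ivs.starts[i]), int(ivs.ends[i]))
            assert np.isclose(at[i], (s.count("A") + s.count("T")) / len(s))


class TestWindowMeanOccupancy:
    def _windows(self, genome, n=50):
        sites = scan_motifs(genome, ("dam",))[:n]
        return extend_and_flag(sites, genome)

    def test_constant_track(self, depletion_setup):
        genome, _, _ = depletion_setup
        wins = self._windows(genome)
        means = window_mean_occupancy(np.full(len(genome), 3.3), wins)
        assert np.allclose(means, 3.3)

    def test_spike_elevates_only_its_window(self, depletion_setup):
        genome, _, _ = depletion_setup
        wins = self._windows(genome, 10)
        track = np.zeros(len(genome))
        target = wins[3]
        track[(target.win_start + 52) % len(genome)] = 1000.0
        means = window_mean_occupancy(track, wins)
        assert means[3] > 0
        others = np.delete(means, 3)
        assert np.allclose(others[np.abs(
            np.array([w.win_start for w in np.delete(np.array(wins), 3)])
            - target.win_start) > 200], 0)

    def test_matches_direct_averaging(self, depletion_setup, rng):
        genome, _, _ = depletion_setup
        wins = self._windows(genome, 30)
        track = rng.normal(size=len(genome))
        means = window_mean_occupancy(track, wins)
        for w, m in zip(wins, means):
            idx = np.arange(w.win_start, w.win_end) % len(genome)
            assert np.isclose(m, track[idx].mean())


class TestDensityStratifiedContrast:
    def test_identical_genotypes_null(self, rng):
        means = rng.normal(size=200)
        dens = rng.integers(1, 4, 200)
        rows = density_stratified_contrast(means, means.copy(), dens)
        for r in rows:
            assert r["median_delta"] == 0
            assert r["p_bonferroni"] == 1.0 or np.isnan(r["p_bonferroni"])

    def test_planted_shift_detected_at_high_density(self, rng):
        n = 300
        dens = np.concatenate([np.full(250, 1), np.full(50, 5)])
        wt = rng.normal(0, 0.1, n)
        mut = wt + np.where(dens >= 5, -0.5, 0.0) + rng.normal(0, 0.05, n)
        rows = density_stratified_contrast(mut, wt, dens)
        by_d = {r["density"]: r for r in rows}
        assert by_d[5]["p_bonferroni"] < 0.01
        assert by_d[5]["significant"]
        assert abs(by_d[5]["median_delta"] + 0.5) < 0.1
        assert not by_d[1]["significant"]

    def test_bonferroni_not_below_raw(self, rng):
        mut = rng.normal(size=100)
        wt = rng.normal(size=100)
        dens = np.repeat([1, 2], 50)
        rows = density_stratified_contrast(mut, wt, dens)
        for r in rows:
            raw = stats.wilcoxon(
                (mut - wt)[dens == r["density"]], zero_method="wilcox").pvalue
            assert r["p_bonferroni"] >= raw - 1e-12

    def test_sparse_level_flagged_underpowered(self, rng):
        mut = rng.normal(size=20)
        wt = rng.normal(size=20)
        dens = np.array([1] * 17 + [7] * 3)
        rows = density_stratified_contrast(mut, wt, dens)
        by_d = {r["density"]: r for r in rows}
        assert by_d[7]["underpowered"]
        assert np.isnan(by_d[7]["p_bonferroni"])
        assert not by_d[1]["underpowered"]
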