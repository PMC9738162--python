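import numpy as np
import pytest
from scipy import stats

from ovprofiler import profiles as prof
from ovprofiler import simulate as sim
from ovprofiler.grid import build_bin_grid


def _flat_counts(grid, depth=500.0, seed=0):
    rng = np.random.default_rng(seed)
    return prof.CountProfile("s", grid, rng.poisson(depth, grid.n_bins))


class TestBinReads:
    def test_boundary_half_open(self, flat_grid):
        cp = prof.bin_reads([("chr1", 20_000, 60)], flat_grid)
        assert cp.counts[1] == 1
        assert cp.counts[0] == 0

    def test_mapq_strictly_over_threshold(self, flat_grid):
        cp = prof.bin_reads([("chr1", 0, 15), ("chr1", 0, 16)], flat_grid, 15)
        assert cp.counts[0] == 1

    def test_unknown_chrom_rejected_not_error(self, flat_grid):
        cp = prof.bin_reads([("chrZ", 0, 60)], flat_grid)
        assert cp.rejected_reads == 1
        assert cp.counts.sum() == 0

    def test_matches_brute_force_assignment(self, flat_grid):
        rng = np.random.default_rng(5)
        reads = [("chr1", int(rng.integers(0, 12_000_000)), int(rng.integers(0, 61)))
                 for _ in range(1000)]
        cp = prof.bin_reads(reads, flat_grid, 15)
        oracle = np.zeros(flat_grid.n_bins)
        for chrom, pos, mapq in reads:
            if mapq > 15:
                oracle[pos // 20_000] += 1
        np.testing.assert_array_equal(cp.counts, oracle)


class TestGCCorrection:
    def test_noop_under_no_bias(self, flat_grid):
        cp = _flat_counts(flat_grid, depth=2000.0)
        out = prof.correct_gc(cp)
        rel = np.abs(out.counts - cp.counts) / cp.counts
        assert rel.mean() < 0.01

    def test_decorrelates_injected_bias(self):
        grid = build_bin_grid([("chr1", 100_000_000)], 20_000, rng=2,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
        grid.mappability[:] = 1.0
        rng = np.random.default_rng(3)
        gc01 = (grid.gc - grid.gc.min()) / np.ptp(grid.gc)
        mu = 200.0 * (1.0 + gc01)   # monotone x2 across the GC range
        cp = prof.CountProfile("s", grid, rng.poisson(mu))
        rho_before = stats.spearmanr(cp.counts, grid.gc).statistic
        out = prof.correct_gc(cp)
        rho_after = stats.spearmanr(out.counts, grid.gc).statistic
        assert abs(rho_before) > 0.5
        assert abs(rho_after) < 0.05

    def test_median_preserved_after_renormalization(self, flat_grid):
        cp = _flat_counts(flat_grid)
        rp = prof.to_log2_ratios(prof.correct_gc(cp))
        ok = np.isfinite(rp.log2_ratios)
        assert np.median(rp.log2_ratios[ok]) == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_profile_errors(self, flat_grid):
        with pytest.raises(ValueError, match="empty profile"):
            prof.correct_gc(prof.CountProfile("s", flat_grid, np.zeros(flat_grid.n_bins)))

    def test_too_few_usable_bins_errors(self):
        grid = build_bin_grid([("chr1", 400_000)], 20_000,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
        with pytest.raises(ValueError):
            prof.correct_gc(_flat_counts(grid))


class TestMappability:
    def test_identity_when_all_one(self, flat_grid):
        cp = _flat_counts(flat_grid)
        out = prof.correct_mappability(cp)
        np.testing.assert_allclose(out.counts, cp.counts)

    def test_divides_by_mappability(self, flat_grid):
        flat_grid.mappability[:] = 0.5
        cp = prof.CountProfile("s", flat_grid, np.full(flat_grid.n_bins, 50.0))
        out = prof.correct_mappability(cp)
        np.testing.assert_allclose(out.counts, 100.0)

    def test_low_mappability_dropped_matches_brute_force(self):
        grid = build_bin_grid([("chr1", 50_000_000)], 20_000, rng=8,
                              blacklist_fraction=0.0, low_mappability_fraction=0.15)
        cp = _flat_counts(grid)
        out = prof.correct_mappability(cp)
        n_missing = int(np.sum(~np.isfinite(out.counts)))
        assert n_missing == int(np.sum(grid.mappability < 0.2))
        assert n_missing > 0


class TestLog2Ratios:
    def test_flat_profile_all_zero(self, flat_grid):
        cp = prof.CountProfile("s", flat_grid, np.full(flat_grid.n_bins, 80.0))
        rp = prof.to_log2_ratios(cp)
        np.testing.assert_allclose(rp.log2_ratios, 0.0, atol=1e-12)
        assert rp.noise_mapd == 0.0
        assert rp.qc_pass

    def test_double_median_bin_is_one(self, flat_grid):
        counts = np.full(flat_grid.n_bins, 100.0)
        counts[10] = 200.0
        rp = prof.to_log2_ratios(prof.CountProfile("s", flat_grid, counts))
        assert rp.log2_ratios[10] == pytest.approx(1.0, abs=1e-9)

    def test_zero_bins_missing_and_blacklist_missing(self, flat_grid):
        flat_grid.blacklist[3] = True
        counts = np.full(flat_grid.n_bins, 100.0)
        counts[5] = 0.0
        rp = prof.to_log2_ratios(prof.CountProfile("s", flat_grid, counts))
        assert np.isnan(rp.log2_ratios[3])
        assert np.isnan(rp.log2_ratios[5])

    def test_mapd_matches_brute_force(self, flat_grid):
        cp = _flat_counts(flat_grid, depth=60.0, seed=4)
        rp = prof.to_log2_ratios(cp)
        r = rp.log2_ratios[np.isfinite(rp.log2_ratios)]
        oracle = np.median(np.abs(np.diff(r)))
        assert rp.noise_mapd == pytest.approx(oracle, abs=1e-12)

    def test_scale_free(self, flat_grid):
        cp = _flat_counts(flat_grid, depth=100.0, seed=6)
        a = prof.to_log2_ratios(cp)
        b = prof.to_log2_ratios(prof.CountProfile("s", flat_grid, cp.counts * 5.0))
        np.testing.assert_allclose(a.log2_ratios, b.log2_ratios, atol=1e-12)

    def test_zero_median_errors(self, flat_grid):
        with pytest.raises(ValueError):
            prof.to_log2_ratios(prof.CountProfile("s", flat_grid,
                                                  np.zeros(flat_grid.n_bins)))


class TestAggregate:
    def test_constant_constituents(self, flat_grid):
        rp = prof.RatioProfile("s", flat_grid, np.full(flat_grid.n_bins, 0.3))
        agg = prof.aggregate_to_1mb(rp)
        assert agg.grid.bin_size == 1_000_000
        np.testing.assert_allclose(agg.log2_ratios, 0.3, atol=1e-12)

    def test_majority_missing_rule(self, flat_grid):
        r = np.full(flat_grid.n_bins, 0.1)
        r[:30] = np.nan           # first 1 MB window: 20/50 present
        r[50:75] = np.nan         # second window: 25/50 present (exactly 50%)
        rp = prof.RatioProfile("s", flat_grid, r)
        agg = prof.aggregate_to_1mb(rp)
        assert np.isnan(agg.log2_ratios[0])
        assert agg.log2_ratios[1] == pytest.approx(0.1)

    def test_piecewise_constant_preserved_interior(self, flat_grid):
        r = np.zeros(flat_grid.n_bins)
        r[200:] = 0.8             # boundary at a 1 MB multiple (bin 200)
        rp = prof.RatioProfile("s", flat_grid, r)
        agg = prof.aggregate_to_1mb(rp)
        np.testing.assert_allclose(agg.log2_ratios[:4], 0.0, atol=1e-12)
        np.testing.assert_allclose(agg.log2_ratios[4:], 0.8, atol=1e-12)

    def test_grid_mismatch_errors(self, flat_grid):
        rp = prof.RatioProfile("s", flat_grid, np.zeros(flat_grid.n_bins))
        with pytest.raises(ValueError):
            prof.aggregate_to_1mb(rp, agg_size=10_000)

    def test_noiseless_profile_recovers_log2_copy(self):
        genome = [("chr1", 20_000_000)]
        grid = build_bin_grid(genome, 20_000, rng=1, blacklist_fraction=0.0,
                              low_mappability_fraction=0.0)
        grid.mappability[:] = 1.0
        states = np.full(grid.n_bins, 2)
        states[400:600] = 4       # 8-12 Mb
        cfg = sim.SimConfig(genome=genome, ccne1_locus=("chr1", 0, 1),
                            gc_bias_strength=0.0, dispersion=0.0, mean_depth=5000.0)
        counts = sim.simulate_read_counts(states, grid, cfg, np.random.default_rng(2))
        rp = prof.to_log2_ratios(prof.CountProfile("s", grid, counts.astype(float)))
        agg = prof.aggregate_to_1mb(rp)
        np.testing.assert_allclose(agg.log2_ratios[9:11], 1.0, atol=0.05)
        np.testing.assert_allclose(agg.log2_ratios[:8], 0.0, atol=0.05)


class TestCalibration:
    def _profiles(self, grid, base, n=3, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return [
            prof.RatioProfile(f"s{i}", grid,
                              base + jitter * rng.normal(size=grid.n_bins))
            for i in range(n)
        ]

    def test_self_calibration_is_identity(self, flat_grid):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.3, flat_grid.n_bins)
        ps = self._profiles(flat_grid, base)
        model = prof.fit_calibration(ps, ps)
        assert abs(model.alpha) < 1e-8
        assert abs(model.beta - 1.0) < 1e-8

    def test_recovers_constructed_affine_map(self, flat_grid):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.4, flat_grid.n_bins)
        train = self._profiles(flat_grid, base)
        current = self._profiles(flat_grid, (base - 0.5) / 2.0)
        model = prof.fit_calibration(train, current)
        assert model.alpha == pytest.approx(0.5, abs=1e-8)
        assert model.beta == pytest.approx(2.0, abs=1e-8)
        # independent least-squares oracle on the sorted vectors
        x = np.sort((base - 0.5) / 2.0)
        y = np.sort(base)
        bx = np.vstack([x, np.ones_like(x)]).T
        beta_o, alpha_o = np.linalg.lstsq(bx, y, rcond=None)[0]
        assert model.beta == pytest.approx(beta_o, abs=1e-8)
        assert model.alpha == pytest.approx(alpha_o, abs=1e-8)

    def test_sample_order_invariance(self, flat_grid):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.3, flat_grid.n_bins)
        train = self._profiles(flat_grid, base, jitter=0.05, seed=3)
        cur = self._profiles(flat_grid, base * 1.3 + 0.1, jitter=0.05, seed=4)
        m1 = prof.fit_calibration(train, cur)
        m2 = prof.fit_calibration(train[::-1], cur[::-1])
        assert m1.alpha == pytest.approx(m2.alpha, abs=1e-12)
        assert m1.beta == pytest.approx(m2.beta, abs=1e-12)

    def test_degenerate_current_errors(self, flat_grid):
        rng = np.random.default_rng(3)
        train = self._profiles(flat_grid, rng.normal(size=flat_grid.n_bins))
        flat = self._profiles(flat_grid, np.zeros(flat_grid.n_bins))
        with pytest.raises(ValueError, match="underdetermined"):
            prof.fit_calibration(train, flat)

    def test_too_few_samples_errors(self, flat_grid):
        ps = self._profiles(flat_grid, np.random.default_rng(4).normal(size=flat_grid.n_bins))
        with pytest.raises(ValueError):
            prof.fit_calibration(ps[:1], ps)

    def test_idempotence(self, flat_grid):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 0.3, flat_grid.n_bins)
        train = self._profiles(flat_grid, base, jitter=0.02, seed=6)
        cur = self._profiles(flat_grid, base * 0.8 - 0.2, jitter=0.02, seed=7)
        model = prof.fit_calibration(train, cur)
        calibrated = [prof.apply_calibration(p, model) for p in cur]
        again = prof.fit_calibration(train, calibrated)
        assert abs(again.alpha) < 1e-8
        assert abs(again.beta - 1.0) < 1e-8
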