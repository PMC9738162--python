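import numpy as np
import pytest

from ovprofiler import profiles as prof
from ovprofiler import segmentation as seg
from ovprofiler import simulate as sim
from ovprofiler.grid import build_bin_grid


def _ratio_profile(values, grid=None, mapd_value=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = build_bin_grid([("chr1", 20_000 * len(values))], 20_000,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
    noise = prof.mapd(values, grid.chroms) if mapd_value is None else mapd_value
    return prof.RatioProfile("s", grid, values, noise_mapd=noise, qc_pass=True)


def brute_force_best_arc(x, min_w=2):
    """Independent exhaustive arc search (pure python)."""
    n = len(x)
    best, bi, bj = -1.0, -1, -1
    for i in range(0, n + 1):
        if i != 0 and i < min_w:
            continue
        for j in range(i + min_w, n + 1):
            if j != n and n - j < min_w:
                continue
            arc = x[i:j]
            comp = np.concatenate([x[:i], x[j:]])
            if len(comp) < min_w:
                continue
            m1, m2 = arc.mean(), comp.mean()
            ss = np.sum((arc - m1) ** 2) + np.sum((comp - m2) ** 2)
            varp = max(ss / max(n - 2, 1), 1e-12)
            t2 = (m1 - m2) ** 2 / (varp * (1 / len(arc) + 1 / len(comp)))
            if t2 > best:
                best, bi, bj = t2, i, j
    return best, bi, bj


class TestPreprocess30kb:
    def test_blacklisted_bins_missing(self):
        grid = build_bin_grid([("chr1", 15_000_000)], 30_000, rng=2,
                              blacklist_fraction=0.05, low_mappability_fraction=0.0)
        rng = np.random.default_rng(0)
        cp = prof.CountProfile("s", grid, rng.poisson(200, grid.n_bins))
        rp = seg.preprocess_30kb(cp)
        assert np.all(np.isnan(rp.log2_ratios[grid.blacklist]))

    def test_injected_spike_removed(self):
        grid = build_bin_grid([("chr1", 15_000_000)], 30_000, rng=3,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
        grid.mappability[:] = 1.0
        rng = np.random.default_rng(1)
        counts = rng.poisson(500, grid.n_bins).astype(float)
        counts[100] *= 8.0       # ratio approx +3 among flat neighbours
        cp = prof.CountProfile("s", grid, counts)
        rp = seg.preprocess_30kb(cp)
        assert np.isnan(rp.log2_ratios[100])

    def test_clean_profile_few_outliers(self):
        grid = build_bin_grid([("chr1", 60_000_000)], 30_000, rng=4,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
        cfg = sim.SimConfig(genome=[("chr1", 60_000_000)],
                            ccne1_locus=("chr1", 0, 1), bin_size=30_000)
        counts = sim.simulate_read_counts(np.full(grid.n_bins, 2), grid, cfg,
                                          np.random.default_rng(5))
        cp = prof.CountProfile("s", grid, counts)
        rp = seg.preprocess_30kb(cp)
        removed = np.mean(~np.isfinite(rp.log2_ratios))
        assert removed < 0.01


class TestSmoothing:
    def test_clean_profile_untouched(self):
        rng = np.random.default_rng(2)
        rp = _ratio_profile(rng.normal(0, 0.1, 300))
        out = seg.smooth_if_noisy(rp, mapd_threshold=0.45)
        assert out is rp

    def test_noisy_profile_mapd_decreases(self):
        rng = np.random.default_rng(3)
        rp = _ratio_profile(rng.normal(0, 0.6, 500))
        assert rp.noise_mapd > 0.45
        out = seg.smooth_if_noisy(rp, mapd_threshold=0.45)
        assert out.noise_mapd < rp.noise_mapd

    def test_step_edge_preserved_within_half_window(self):
        x = np.concatenate([np.zeros(100), np.ones(100)])
        rng = np.random.default_rng(4)
        noisy = x + rng.normal(0, 0.55, 200)
        rp = _ratio_profile(noisy)
        out = seg.smooth_if_noisy(rp, mapd_threshold=0.45, window=9)
        sm = out.log2_ratios
        # locate the edge by least-squares fit of a single step
        sse = [
            np.sum((sm[:k] - sm[:k].mean()) ** 2) + np.sum((sm[k:] - sm[k:].mean()) ** 2)
            for k in range(5, 195)
        ]
        edge = 5 + int(np.argmin(sse))
        assert abs(edge - 100) <= 5


class TestCBS:
    def test_constant_profile_single_segment_per_chrom(self):
        grid = build_bin_grid([("chr1", 2_000_000), ("chr2", 2_000_000)], 20_000,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
        rp = _ratio_profile(np.zeros(grid.n_bins), grid)
        sp = seg.segment_cbs(rp, n_perm=100, seed=1)
        assert len(sp.segments) == 2
        assert {s.chrom for s in sp.segments} == {"chr1", "chr2"}

    def test_noiseless_step_found_exactly(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        rp = _ratio_profile(x)
        sp = seg.segment_cbs(rp, n_perm=200, seed=2)
        assert len(sp.segments) == 2
        assert sp.segments[0].end_bin == 50
        assert sp.segments[1].start_bin == 50
        t2, i, j = seg._best_arc(x, 2)
        ot2, oi, oj = brute_force_best_arc(x)
        assert (i, j) == (oi, oj)

    def test_kernel_matches_exhaustive_oracle_random_profiles(self):
        rng = np.random.default_rng(5)
        for n in (10, 25, 60, 100):
            x = rng.normal(0, 1, n)
            x[n // 3: 2 * n // 3] += rng.uniform(0, 2)
            t2, i, j = seg._best_arc(np.ascontiguousarray(x), 2)
            ot2, oi, oj = brute_force_best_arc(x)
            assert t2 == pytest.approx(ot2, rel=1e-9)
            assert (i, j) == (oi, oj)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.3, 400)
        x[100:180] += 0.8
        rp = _ratio_profile(x)
        a = seg.segment_cbs(rp, n_perm=150, seed=9)
        b = seg.segment_cbs(rp, n_perm=150, seed=9)
        assert [(s.start_bin, s.end_bin) for s in a.segments] == \
               [(s.start_bin, s.end_bin) for s in b.segments]

    def test_segment_means_reconstruct_profile_mean(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.3, 300)
        x[40:90] -= 1.0
        x[200:260] += 0.7
        rp = _ratio_profile(x)
        sp = seg.segment_cbs(rp, n_perm=150, seed=3)
        total = sum(s.mean_log2 * s.n_bins for s in sp.segments)
        n = sum(s.n_bins for s in sp.segments)
        assert total / n == pytest.approx(x.mean(), abs=1e-9)

    def test_segments_partition_non_missing_bins(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.3, 250)
        x[rng.choice(250, 30, replace=False)] = np.nan
        x[100:150] += 1.2
        rp = _ratio_profile(x)
        sp = seg.segment_cbs(rp, n_perm=150, seed=4)
        covered = sum(s.n_bins for s in sp.segments)
        assert covered == int(np.isfinite(x).sum())

    def test_adjacent_segment_means_differ_post_merge(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.2, 300)
        x[100:200] += 0.6
        rp = _ratio_profile(x)
        sp = seg.segment_cbs(rp, n_perm=150, seed=5, merge_threshold=0.1)
        means = [s.mean_log2 for s in sp.segments]
        for a, b in zip(means[:-1], means[1:]):
            assert abs(a - b) >= 0.1


class TestCalling:
    def _segmented(self, means, n_bins=None):
        n_bins = n_bins or [50] * len(means)
        grid = build_bin_grid([("chr1", 20_000 * sum(n_bins))], 20_000,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
        segs, pos = [], 0
        for m, nb in zip(means, n_bins):
            segs.append(seg.Segment("chr1", pos, pos + nb, nb, float(m)))
            pos += nb
        return seg.SegmentedProfile("s", grid, segs)

    def test_zero_mean_neutral_both_paths(self):
        sp = self._segmented([0.0])
        seg.call_states(sp, rng=0)     # < 5 segments -> fallback
        assert sp.segments[0].call == "neutral"
        assert seg._fallback_call(0.0) == "neutral"

    def test_well_separated_means_fully_recovered(self):
        rng = np.random.default_rng(10)
        truth, means = [], []
        for _ in range(120):
            k = rng.integers(4)
            centers = [-1.0, 0.0, 0.45, 1.3]
            truth.append(seg.STATES[k])
            means.append(centers[k] + rng.normal(0, 0.05))
        sp = self._segmented(means)
        seg.call_states(sp, rng=1)
        calls = [s.call for s in sp.segments]
        assert calls == truth

    def test_responsibilities_match_density_oracle(self):
        rng = np.random.default_rng(11)
        means = np.concatenate([
            rng.normal(-1.0, 0.05, 30), rng.normal(0.0, 0.05, 60),
            rng.normal(0.45, 0.05, 30), rng.normal(1.3, 0.05, 20)])
        weights = np.ones(len(means)) * 50
        fit = seg._fit_mixture(means, weights, np.random.default_rng(0))
        assert fit is not None
        mu, var, pi = fit
        # oracle: explicit Gaussian density argmax
        dens = (np.exp(-0.5 * (means[:, None] - mu) ** 2 / var)
                / np.sqrt(var) * pi)
        oracle_states = dens.argmax(axis=1)
        sp = self._segmented(means, n_bins=[50] * len(means))
        seg.call_states(sp, rng=0)
        got = [seg.STATES.index(s.call) for s in sp.segments]
        assert got == oracle_states.tolist()

    def test_all_neutral_genome_no_gain_calls(self):
        rng = np.random.default_rng(12)
        sp = self._segmented(rng.normal(0, 0.03, 40))
        seg.call_states(sp, rng=2)
        assert all(s.call == "neutral" for s in sp.segments)

    def test_calling_invariant_to_chromosome_order(self):
        means = [-1.0, 0.0, 0.5, 1.4, 0.0, -0.95, 0.42, 0.01]
        sp1 = self._segmented(means)
        sp2 = self._segmented(means[::-1])
        seg.call_states(sp1, rng=3)
        seg.call_states(sp2, rng=3)
        assert [s.call for s in sp1.segments] == [s.call for s in sp2.segments][::-1]

    def test_fallback_thresholds(self):
        assert seg._fallback_call(-0.5) == "loss"
        assert seg._fallback_call(-0.25) == "neutral"
        assert seg._fallback_call(0.25) == "neutral"
        assert seg._fallback_call(0.3) == "gain"
        assert seg._fallback_call(0.85) == "gain"
        assert seg._fallback_call(0.9) == "amplification"


class TestCCNE1Status:
    def _called_profile(self, seg_defs):
        grid = build_bin_grid([("chr17", 9_000_000)], 30_000,
                              blacklist_fraction=0.0, low_mappability_fraction=0.0)
        segs = [seg.Segment("chr17", a, b, b - a, m, call=c)
                for a, b, m, c in seg_defs]
        return seg.SegmentedProfile("s", grid, segs)

    def test_no_overlapping_non_neutral_gives_none(self):
        sp = self._called_profile([(0, 300, 0.0, "neutral")])
        st = seg.ccne1_status(sp, ("chr17", 6_000_000, 6_400_000))
        assert st.status == "none"

    def test_gain_precedence_over_neutral(self):
        sp = self._called_profile([(0, 200, 0.0, "neutral"),
                                   (200, 220, 0.5, "gain"),
                                   (220, 300, 0.0, "neutral")])
        st = seg.ccne1_status(sp, ("chr17", 6_000_000, 6_400_000))
        assert st.status == "gain"
        assert st.supporting_segment.call == "gain"

    def test_amplification_beats_gain(self):
        sp = self._called_profile([(195, 205, 0.5, "gain"),
                                   (205, 215, 1.4, "amplification")])
        st = seg.ccne1_status(sp, ("chr17", 6_000_000, 6_400_000))
        assert st.status == "amplification"

    def test_unknown_chrom_errors(self):
        sp = self._called_profile([(0, 300, 0.0, "neutral")])
        with pytest.raises(ValueError):
            seg.ccne1_status(sp, ("chr5", 0, 100_000))

    def test_uncalled_segments_error(self):
        sp = self._called_profile([(0, 300, 0.0, None)])
        with pytest.raises(ValueError):
            seg.ccne1_status(sp, ("chr17", 6_000_000, 6_400_000))

    def test_end_to_end_copy6_amplicon_from_counts(self, small_config):
        grid = small_config.build_grid(30_000)
        states = np.full(grid.n_bins, 2)
        idx = grid.overlapping_bins("chr17", 5_800_000, 6_800_000)
        states[idx] = 6
        counts = sim.simulate_read_counts(states, grid, small_config,
                                          np.random.default_rng(3))
        cp = prof.CountProfile("s", grid, counts)
        rp = seg.preprocess_30kb(cp)
        sp = seg.segment_cbs(rp, n_perm=200, seed=1)
        seg.call_states(sp, rng=0)
        st = seg.ccne1_status(sp, small_config.ccne1_locus)
        assert st.status == "amplification"
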