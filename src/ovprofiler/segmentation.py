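"""Circular binary segmentation, noisy-profile smoothing, discrete
copy-number calling, and focal cyclin-E-locus status.

CBS: for the current stretch, the candidate change is the arc (i, j] that
maximizes the two-sample t statistic between arc and complement (the
circular complement of a linear arc yields the same partition, so linear
arcs suffice).  Significance is assessed by seeded permutations with early
stopping once the p-value can no longer drop below alpha; accepted splits
recurse.  Adjacent segments closer than a merge threshold are fused.

Calling fits a 4-component 1-D Gaussian mixture (loss < neutral < gain <
amplification, neutral anchored near 0) to bin-weighted segment means, with
fixed log2 thresholds as a fallback when components empty out or EM fails.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .grid import BinGrid
from .profiles import CountProfile, RatioProfile, correct_gc, correct_mappability, \
    to_log2_ratios, mapd

log = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SegmentedProfile",
    "CCNE1Status",
    "preprocess_30kb",
    "smooth_if_noisy",
    "segment_cbs",
    "call_states",
    "ccne1_status",
    "FALLBACK_THRESHOLDS",
]

STATES = ("loss", "neutral", "gain", "amplification")
#: fallback log2 cutpoints: loss < -0.25 <= neutral <= 0.25 < gain <= 0.85 < amp
FALLBACK_THRESHOLDS = (-0.25, 0.25, 0.85)
SMOOTH_MAPD_THRESHOLD = 0.45
MERGE_THRESHOLD = 0.1


@dataclass
class Segment:
    chrom: str
    start_bin: int      # grid bin index, inclusive
    end_bin: int        # exclusive
    n_bins: int         # non-missing bins in the segment
    mean_log2: float
    call: str | None = None


@dataclass
class SegmentedProfile:
    sample_id: str
    grid: BinGrid
    segments: list

    def to_frame(self) -> pd.DataFrame:
        g = self.grid
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [int(g.starts[s.start_bin]) for s in self.segments],
                "end": [int(g.ends[s.end_bin - 1]) for s in self.segments],
                "n_bins": [s.n_bins for s in self.segments],
                "mean_log2": [s.mean_log2 for s in self.segments],
                "call": [s.call for s in self.segments],
            }
        )

    def to_seg(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class CCNE1Status:
    sample_id: str
    status: str                      # none / gain / amplification
    supporting_segment: Segment | None = None


def preprocess_30kb(counts: CountProfile, grid: BinGrid | None = None,
                    outlier_window: int = 5, outlier_mapds: float = 4.0,
                    qc_threshold: float = SMOOTH_MAPD_THRESHOLD * 2) -> RatioProfile:
    """GC/mappability-corrected log2 ratios with blacklisted bins removed and
    running-median outliers set missing."""
    grid = counts.grid if grid is None else grid
    corrected = correct_mappability(correct_gc(counts, grid), grid)
    rp = to_log2_ratios(corrected, qc_threshold=qc_threshold)
    r = rp.log2_ratios.copy()
    noise = rp.noise_mapd
    for c, sl in grid.chrom_slices().items():
        v = r[sl]
        ok = np.isfinite(v)
        if ok.sum() < outlier_window:
            continue
        med = _running_median(v[ok], outlier_window)
        out = np.abs(v[ok] - med) > outlier_mapds * noise
        idx = np.flatnonzero(ok)[out]
        v[idx] = np.nan
        r[sl] = v
    return replace(rp, log2_ratios=r, noise_mapd=mapd(r, grid.chroms))


def _running_median(v: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty(len(v))
    for i in range(len(v)):
        out[i] = np.median(v[max(0, i - half): i + half + 1])
    return out


def smooth_if_noisy(rp: RatioProfile, mapd_threshold: float = SMOOTH_MAPD_THRESHOLD,
                    window: int = 9) -> RatioProfile:
    """Replace ratios by a centered rolling median when the profile is noisy
    (MAPD above threshold); clean profiles pass through untouched."""
    if not (np.isfinite(rp.noise_mapd) and rp.noise_mapd > mapd_threshold):
        return rp
    r = rp.log2_ratios.copy()
    for c, sl in rp.grid.chrom_slices().items():
        v = r[sl]
        ok = np.isfinite(v)
        if ok.sum() >= 2:
            sm = _running_median(v[ok], window)
            v[np.flatnonzero(ok)] = sm
            r[sl] = v
    return replace(rp, log2_ratios=r, noise_mapd=mapd(r, rp.grid.chroms))


@njit(cache=False)
def _best_arc(x, min_w):
    """Max two-sample t^2 over arcs x[i:j] vs complement; returns (t2, i, j).

    Interior flanks shorter than min_w are disallowed (i in {0} or >= min_w;
    j in {n} or <= n - min_w), and both arc and complement need >= min_w.
    """
    n = x.shape[0]
    P = np.empty(n + 1)
    Q = np.empty(n + 1)
    P[0] = 0.0
    Q[0] = 0.0
    for a in range(n):
        P[a + 1] = P[a] + x[a]
        Q[a + 1] = Q[a] + x[a] * x[a]
    S = P[n]
    SS = Q[n]
    best = -1.0
    bi = -1
    bj = -1
    if n < 2 * min_w:
        return best, bi, bj
    for i in range(0, n - min_w + 1):
        if i != 0 and i < min_w:
            continue
        for j in range(i + min_w, n + 1):
            if j != n and n - j < min_w:
                continue
            L = j - i
            n2 = n - L
            if n2 < min_w:
                break
            s1 = P[j] - P[i]
            m1 = s1 / L
            m2 = (S - s1) / n2
            varp = (SS - L * m1 * m1 - n2 * m2 * m2) / max(n - 2, 1)
            if varp < 1e-12:
                varp = 1e-12
            d = m1 - m2
            t2 = d * d / (varp * (1.0 / L + 1.0 / n2))
            if t2 > best:
                best = t2
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=False)
def _perm_pvalue(x, t2_obs, n_perm, stop_exceed, min_w, seed):
    """Permutation p-value for the observed max t^2, with early stop once the
    final p-value is guaranteed to be >= alpha."""
    np.random.seed(seed)
    y = x.copy()
    exceed = 0
    done = 0
    thresh = t2_obs * (1.0 - 1e-9)
    for _ in range(n_perm):
        for k in range(y.shape[0] - 1, 0, -1):
            r = np.random.randint(0, k + 1)
            tmp = y[k]
            y[k] = y[r]
            y[r] = tmp
        t2, _, _ = _best_arc(y, min_w)
        done += 1
        if t2 >= thresh:
            exceed += 1
            if exceed >= stop_exceed:
                break
    return (1.0 + exceed) / (1.0 + done)


def _segment_values(values, alpha, n_perm, min_width, seed_base):
    """Recursive CBS over a 1-D array; returns sorted breakpoint list."""
    bounds = []
    stop_exceed = int(np.ceil(alpha * (1 + n_perm)))
    counter = [0]

    def recurse(lo, hi):
        v = values[lo:hi]
        n = hi - lo
        if n < 2 * min_width:
            return
        t2, i, j = _best_arc(v, min_width)
        if t2 <= 0 or i < 0:
            return
        if np.ptp(v) < 1e-12:
            return
        counter[0] += 1
        seed = (seed_base + 1000003 * counter[0]) % (2**31 - 1)
        p = _perm_pvalue(v, t2, n_perm, stop_exceed, min_width, seed)
        if p >= alpha:
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        pieces = [0] + cuts + [n]
        for c in cuts:
            bounds.append(lo + c)
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(lo + a, lo + b)

    recurse(0, len(values))
    return sorted(bounds)


def _merge_segments(values, bounds, threshold):
    """Fuse adjacent pieces whose means differ by less than the threshold,
    closest pair first."""
    pieces = [(a, b) for a, b in zip([0] + bounds, bounds + [len(values)])]
    while len(pieces) > 1:
        means = [values[a:b].mean() for a, b in pieces]
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= threshold:
            break
        a, _ = pieces[k]
        _, b = pieces[k + 1]
        pieces[k: k + 2] = [(a, b)]
    return pieces


def segment_cbs(rp: RatioProfile, alpha: float = 0.01, n_perm: int = 1000,
                min_width: int = 2, seed: int = 0,
                merge_threshold: float = MERGE_THRESHOLD) -> SegmentedProfile:
    """CBS over the non-missing bins of each chromosome."""
    segments = []
    for chrom, sl in rp.grid.chrom_slices().items():
        r = rp.log2_ratios[sl]
        ok = np.flatnonzero(np.isfinite(r))
        if len(ok) == 0:
            continue
        values = np.ascontiguousarray(r[ok])
        chrom_seed = (seed + zlib_crc(chrom)) % (2**31 - 1)
        bounds = _segment_values(values, alpha, n_perm, min_width, chrom_seed)
        for a, b in _merge_segments(values, bounds, merge_threshold):
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bin=sl.start + int(ok[a]),
                    end_bin=sl.start + int(ok[b - 1]) + 1,
                    n_bins=b - a,
                    mean_log2=float(values[a:b].mean()),
                )
            )
    return SegmentedProfile(sample_id=rp.sample_id, grid=rp.grid, segments=segments)


def zlib_crc(s: str) -> int:
    import zlib

    return zlib.crc32(s.encode())


def _fallback_call(mean):
    lo, hi, amp = FALLBACK_THRESHOLDS
    if mean < lo:
        return "loss"
    if mean <= hi:
        return "neutral"
    if mean <= amp:
        return "gain"
    return "amplification"


def _fit_mixture(means, weights, rng, max_iter=500, tol=1e-8):
    """Weighted 1-D 4-component GMM with ordered means and neutral near 0.

    Returns (mu, var, pi) or None when a component empties out or EM fails.
    """
    init_mu = np.array([-0.6, 0.0, 0.45, 1.3])
    resp_init = np.argmin(np.abs(means[:, None] - init_mu[None, :]), axis=1)
    mu = init_mu.copy()
    var = np.full(4, 0.05)
    pi = np.full(4, 0.25)
    for k in range(4):
        w = weights[resp_init == k]
        if w.sum() > 0:
            mu[k] = np.average(means[resp_init == k], weights=w)
            pi[k] = w.sum() / weights.sum()
    pi = np.maximum(pi, 1e-6)
    pi /= pi.sum()
    prev = -np.inf
    for it in range(max_iter):
        logd = (
            -0.5 * (means[:, None] - mu[None, :]) ** 2 / var[None, :]
            - 0.5 * np.log(2 * np.pi * var[None, :])
            + np.log(pi[None, :])
        )
        m = logd.max(axis=1, keepdims=True)
        p = np.exp(logd - m)
        norm = p.sum(axis=1, keepdims=True)
        resp = p / norm
        ll = float(np.sum(weights * (np.log(norm[:, 0]) + m[:, 0])))
        wk = (resp * weights[:, None]).sum(axis=0)
        if np.any(wk < 1e-6 * weights.sum()):
            return None
        mu = (resp * weights[:, None] * means[:, None]).sum(axis=0) / wk
        var = (resp * weights[:, None] * (means[:, None] - mu[None, :]) ** 2).sum(axis=0) / wk
        var = np.maximum(var, 1e-4)
        pi = wk / weights.sum()
        # order constraint and neutral anchor
        mu[1] = np.clip(mu[1], -0.1, 0.1)
        for k in range(1, 4):
            mu[k] = max(mu[k], mu[k - 1] + 1e-3)
        mu[0] = min(mu[0], mu[1] - 1e-3)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            return mu, var, pi
        prev = ll
    log.warning("mixture EM did not converge; using fallback thresholds")
    return None


def call_states(segmented, rng: np.random.Generator | int | None = 0):
    """Assign loss/neutral/gain/amplification to every segment.

    ``segmented`` is one SegmentedProfile or a list (calling pools segments
    across the supplied profiles).  Falls back to fixed thresholds when there
    are too few segments or the mixture degenerates.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    profs = segmented if isinstance(segmented, (list, tuple)) else [segmented]
    all_segs = [s for p in profs for s in p.segments]
    means = np.array([s.mean_log2 for s in all_segs])
    weights = np.array([float(s.n_bins) for s in all_segs])
    fit = _fit_mixture(means, weights, rng) if len(all_segs) >= 5 else None
    if fit is None:
        for s in all_segs:
            s.call = _fallback_call(s.mean_log2)
    else:
        mu, var, pi = fit
        logd = (
            -0.5 * (means[:, None] - mu[None, :]) ** 2 / var[None, :]
            - 0.5 * np.log(var[None, :])
            + np.log(pi[None, :])
        )
        states = logd.argmax(axis=1)
        for s, k in zip(all_segs, states):
            s.call = STATES[int(k)]
    return segmented


def ccne1_status(segmented: SegmentedProfile, locus) -> CCNE1Status:
    """Status of the configured locus: amplification beats gain beats none
    among overlapping segments (half-open interval overlap)."""
    chrom, start, end = locus
    g = segmented.grid
    if chrom not in set(g.chroms.tolist()):
        raise ValueError(f"locus chromosome {chrom!r} not in grid")
    best, status = None, "none"
    for s in segmented.segments:
        if s.call is None:
            raise ValueError("segments are uncalled; run call_states first")
        if s.chrom != chrom:
            continue
        s_start = int(g.starts[s.start_bin])
        s_end = int(g.ends[s.end_bin - 1])
        if s_start < end and s_end > start:
            if s.call == "amplification":
                return CCNE1Status(segmented.sample_id, "amplification", s)
            if s.call == "gain" and status == "none":
                best, status = s, "gain"
    return CCNE1Status(segmented.sample_id, status, best)
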