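"""Binned read counts -> corrected log2 ratio profiles.

The 20 kb path feeds the 1 MB nearest-shrunken-centroids classifier input;
the 30 kb path feeds segmentation.  Corrections: lowess-smoothed GC bias,
division by mappability (bins below 0.2 dropped), median normalization to
log2 ratios, and a cross-dataset affine calibration fitted on sorted
location-wise averages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .grid import BinGrid, build_bin_grid

__all__ = [
    "CountProfile",
    "RatioProfile",
    "CalibrationModel",
    "bin_reads",
    "correct_gc",
    "correct_mappability",
    "to_log2_ratios",
    "aggregate_to_1mb",
    "fit_calibration",
    "apply_calibration",
    "mapd",
]

MIN_MAPPABILITY = 0.2
DEFAULT_QC_MAPD = 0.6


@dataclass
class CountProfile:
    """Raw or corrected per-bin counts for one sample (NaN = missing)."""

    sample_id: str
    grid: BinGrid
    counts: np.ndarray
    mapq_threshold: int = 15
    rejected_reads: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.grid.n_bins:
            raise ValueError("counts length does not match grid")
        if np.nanmin(self.counts, initial=0.0) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class RatioProfile:
    """Per-bin log2 count ratios (NaN = missing) with a MAPD noise metric."""

    sample_id: str
    grid: BinGrid
    log2_ratios: np.ndarray
    noise_mapd: float = float("nan")
    qc_pass: bool = True

    def __post_init__(self):
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        if len(self.log2_ratios) != self.grid.n_bins:
            raise ValueError("ratios length does not match grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chroms,
                "start": self.grid.starts,
                "end": self.grid.ends,
                "log2_ratio": self.log2_ratios,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA",
                               float_format="%.6g")


@dataclass
class CalibrationModel:
    """corrected = alpha + beta * ratio; maps a dataset onto a training scale."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("calibration slope must be positive")


def bin_reads(read_stream, grid: BinGrid, mapq_threshold: int = 15) -> CountProfile:
    """Count reads per bin; a read lands in the bin containing its leftmost
    aligned base.  Reads with MAPQ strictly greater than the threshold are
    retained; unknown chromosomes go to a reject tally."""
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    rejected = 0
    slices = grid.chrom_slices()
    for chrom, pos, mapq in read_stream:
        if mapq <= mapq_threshold:
            continue
        sl = slices.get(chrom)
        if sl is None:
            rejected += 1
            continue
        idx = sl.start + int(pos) // grid.bin_size
        if idx >= sl.stop or pos >= grid.ends[sl.stop - 1] or pos < 0:
            rejected += 1
            continue
        counts[idx] += 1
    return CountProfile(
        sample_id="binned",
        grid=grid,
        counts=counts,
        mapq_threshold=mapq_threshold,
        rejected_reads=rejected,
    )


def _usable_mask(counts, grid):
    return (~grid.blacklist) & np.isfinite(counts) & (counts > 0)


def correct_gc(profile: CountProfile, grid: BinGrid | None = None,
               span: float = 0.3, max_fit_points: int = 2000) -> CountProfile:
    """Divide counts by a lowess-smoothed expected count per GC value,
    rescaled to preserve the usable-bin median.

    For speed the curve is fitted on an evenly spaced (in GC order)
    subsample of at most ``max_fit_points`` bins and interpolated.
    """
    grid = profile.grid if grid is None else grid
    counts = profile.counts.astype(float)
    usable = _usable_mask(counts, grid)
    if not usable.any():
        raise ValueError("empty profile")
    if usable.sum() < 100:
        raise ValueError("need at least 100 usable bins for GC correction")
    gc_u = grid.gc[usable]
    c_u = counts[usable]
    order = np.argsort(gc_u, kind="stable")
    if len(order) > max_fit_points:
        pick = order[np.linspace(0, len(order) - 1, max_fit_points).astype(int)]
    else:
        pick = order
    curve = lowess(c_u[pick], gc_u[pick], frac=span, it=2, return_sorted=True)
    fit = np.interp(grid.gc, curve[:, 0], curve[:, 1])
    med = float(np.median(fit[usable]))
    fit = np.where(np.isfinite(fit) & (fit > 1e-9), fit, med if med > 0 else 1.0)
    corrected = counts * (med / fit)
    return replace(profile, counts=corrected)


def correct_mappability(profile: CountProfile, grid: BinGrid | None = None) -> CountProfile:
    """Divide counts by bin mappability; bins below 0.2 become missing."""
    grid = profile.grid if grid is None else grid
    m = grid.mappability
    if np.any((m < 0) | (m > 1)):
        raise ValueError("mappability must lie in [0, 1]")
    corrected = np.where(m >= MIN_MAPPABILITY, profile.counts / np.maximum(m, 1e-9), np.nan)
    return replace(profile, counts=corrected)


def mapd(ratios: np.ndarray, chroms: np.ndarray | None = None) -> float:
    """Median absolute pairwise difference of successive non-missing ratios
    (within chromosomes when ``chroms`` is given)."""
    r = np.asarray(ratios, dtype=float)
    diffs = []
    if chroms is None:
        chroms = np.zeros(len(r))
    for c in pd.unique(np.asarray(chroms)):
        v = r[np.asarray(chroms) == c]
        v = v[np.isfinite(v)]
        if len(v) > 1:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        return float("nan")
    return float(np.median(np.concatenate(diffs)))


def to_log2_ratios(profile: CountProfile, qc_threshold: float = DEFAULT_QC_MAPD) -> RatioProfile:
    """ratio_b = log2(count_b / median non-missing count), re-centered so the
    median non-missing ratio is exactly 0.  Zero-count and blacklisted bins
    are missing.  QC passes when MAPD is below the threshold."""
    grid = profile.grid
    counts = profile.counts.astype(float)
    missing = ~np.isfinite(counts) | (counts <= 0) | grid.blacklist
    vals = counts[~missing]
    if len(vals) == 0:
        raise ValueError("empty profile")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("profile median is zero")
    ratios = np.full(grid.n_bins, np.nan)
    ratios[~missing] = np.log2(vals / med)
    ratios[~missing] -= np.median(ratios[~missing])
    noise = mapd(ratios, grid.chroms)
    return RatioProfile(
        sample_id=profile.sample_id,
        grid=grid,
        log2_ratios=ratios,
        noise_mapd=noise,
        qc_pass=bool(np.isfinite(noise) and noise < qc_threshold),
    )


def aggregate_to_1mb(rp: RatioProfile, agg_size: int = 1_000_000,
                     min_fraction: float = 0.5) -> RatioProfile:
    """Mean of non-missing constituent ratios per 1 MB window; the window is
    missing when fewer than ``min_fraction`` of its constituents are present."""
    grid = rp.grid
    if agg_size <= grid.bin_size:
        raise ValueError("aggregation size must exceed the source bin size")
    out_grid = _plain_grid(grid.genome, agg_size)
    sums = np.zeros(out_grid.n_bins)
    n_present = np.zeros(out_grid.n_bins)
    n_total = np.zeros(out_grid.n_bins)
    out_slices = out_grid.chrom_slices()
    for chrom, sl in grid.chrom_slices().items():
        osl = out_slices[chrom]
        win = osl.start + grid.starts[sl] // agg_size
        r = rp.log2_ratios[sl]
        ok = np.isfinite(r)
        np.add.at(n_total, win, 1.0)
        np.add.at(n_present, win[ok], 1.0)
        np.add.at(sums, win[ok], r[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / n_present
    frac = np.divide(n_present, n_total, out=np.zeros_like(n_present), where=n_total > 0)
    means[frac < min_fraction] = np.nan
    return RatioProfile(
        sample_id=rp.sample_id,
        grid=out_grid,
        log2_ratios=means,
        noise_mapd=mapd(means, out_grid.chroms),
        qc_pass=rp.qc_pass,
    )


def _plain_grid(genome, bin_size) -> BinGrid:
    """Annotation-free grid (GC/mappability unused downstream of aggregation)."""
    g = build_bin_grid(genome, bin_size, rng=np.random.default_rng(0),
                       blacklist_fraction=0.0, low_mappability_fraction=0.0)
    g.gc[:] = np.nan
    g.mappability[:] = 1.0
    return g


def _location_average(profiles) -> np.ndarray:
    mat = np.vstack([p.log2_ratios for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mat, axis=0)


def fit_calibration(training_profiles, current_profiles) -> CalibrationModel:
    """OLS of the sorted per-bin training average on the sorted per-bin
    current average; the resulting (alpha, beta) maps current data onto the
    training scale."""
    if len(training_profiles) < 2 or len(current_profiles) < 2:
        raise ValueError("need at least 2 samples per set")
    t_avg = _location_average(training_profiles)
    c_avg = _location_average(current_profiles)
    ok = np.isfinite(t_avg) & np.isfinite(c_avg)
    if ok.sum() < 3:
        raise ValueError("calibration underdetermined")
    x = np.sort(c_avg[ok])
    y = np.sort(t_avg[ok])
    if np.ptp(x) < 1e-12:
        raise ValueError("calibration underdetermined")
    beta, alpha = np.polyfit(x, y, 1)
    return CalibrationModel(alpha=float(alpha), beta=float(beta))


def apply_calibration(rp: RatioProfile, model: CalibrationModel) -> RatioProfile:
    return replace(rp, log2_ratios=model.alpha + model.beta * rp.log2_ratios)
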