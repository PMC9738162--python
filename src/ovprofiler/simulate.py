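"""Synthetic cohort generator.

Produces cohorts with the statistical structure the downstream pipeline
assumes: piecewise-constant integer copy-number genomes (quiet vs. an
HRD-like scattered-alteration signature vs. focal amplicons at a designated
cyclin-E locus), GC- and mappability-biased negative-binomial read counts
over a bin grid, profile-dependent immune counts over four cores, and
profile- and density-dependent exponential survival with uniform
administrative censoring.

Everything is deterministic under a fixed seed; per-patient child seeds are
derived as ``(config.seed, crc32(patient_id))`` so subsetting a cohort is
reproducible.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BinGrid, build_bin_grid

__all__ = [
    "PROFILES",
    "MARKERS",
    "SimConfig",
    "TruthRecord",
    "CohortData",
    "default_genome",
    "simulate_copy_states",
    "simulate_read_counts",
    "simulate_immune_counts",
    "simulate_survival",
    "simulate_cohort",
    "simulate_roster",
    "child_rng",
]

PROFILES = ("BRCAm", "nonBRCAmutHRD", "CCNE1", "double", "NSMP")
MARKERS = ("CD8", "CD20", "CD68", "CD103")

#: dichotomization cutoffs (count strictly above => high stratum)
BINARY_CUTOFFS = {"CD8": 100, "CD20": 50, "CD68": 100, "CD103": 100}

# Immune model: per-profile per-marker (mean, gamma shape).  A patient draws a
# latent per-core mean from Gamma(shape, mean/shape); the four cores are
# Poisson around it.  Values calibrated so that the max-of-4-cores category
# fractions match the reference cohort's printed low/high margins.
DEFAULT_IMMUNE_MEANS = {
    "CD8": {"BRCAm": 78.6, "nonBRCAmutHRD": 54.3, "CCNE1": 55.4, "double": 62.1, "NSMP": 93.5},
    "CD103": {"BRCAm": 71.8, "nonBRCAmutHRD": 53.6, "CCNE1": 37.6, "double": 50.7, "NSMP": 51.1},
    "CD20": {"BRCAm": 27.4, "nonBRCAmutHRD": 18.9, "CCNE1": 13.3, "double": 22.1, "NSMP": 27.5},
    "CD68": {"BRCAm": 159.9, "nonBRCAmutHRD": 62.4, "CCNE1": 56.2, "double": 71.0, "NSMP": 46.6},
}
DEFAULT_IMMUNE_SHAPES = {
    "CD8": {"BRCAm": 1.33, "nonBRCAmutHRD": 1.30, "CCNE1": 0.82, "double": 1.09, "NSMP": 0.72},
    "CD103": {"BRCAm": 0.73, "nonBRCAmutHRD": 0.55, "CCNE1": 0.66, "double": 0.83, "NSMP": 0.82},
    "CD20": {"BRCAm": 0.57, "nonBRCAmutHRD": 0.92, "CCNE1": 0.90, "double": 0.56, "NSMP": 0.66},
    "CD68": {"BRCAm": 0.49, "nonBRCAmutHRD": 0.43, "CCNE1": 1.00, "double": 0.30, "NSMP": 0.60},
}

# Exponential OS hazards (1/month) per profile and the conditional hazard
# multiplier for CD103-high patients.  Calibrated (jointly with the immune
# model above) so that crude Cox hazard ratios and the BRCAm-arm KM median on
# default cohorts land on the reference cohort's reported survival statistics.
DEFAULT_BASE_HAZARD = {
    "BRCAm": 0.014818,
    "nonBRCAmutHRD": 0.018552,
    "CCNE1": 0.029772,
    "double": 0.025087,
    "NSMP": 0.023742,
}
DEFAULT_DENSITY_MULTIPLIERS = {"CD8": 1.0, "CD20": 1.0, "CD68": 1.0, "CD103": 0.6367}


def default_genome() -> list:
    """22 toy chromosomes, linearly decreasing lengths, ~308 Mb total."""
    return [(f"chr{i}", 22_000_000 - (i - 1) * 760_000) for i in range(1, 23)]


@dataclass
class ImmuneModel:
    means: dict = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_IMMUNE_MEANS.items()})
    shapes: dict = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_IMMUNE_SHAPES.items()})
    n_cores: int = 4


@dataclass
class SurvivalModel:
    base_hazard: dict = field(default_factory=lambda: dict(DEFAULT_BASE_HAZARD))
    density_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_DENSITY_MULTIPLIERS))
    density_cutoffs: dict = field(default_factory=lambda: dict(BINARY_CUTOFFS))
    pfs_factor: float = 2.3          # PFS hazard = pfs_factor * OS hazard (>= 1)
    censor_horizon_months: float = 120.0


@dataclass
class HRDSignature:
    """Scattered-alteration phenotype with recurrent hotspots.

    Most segments land in fixed per-chromosome hotspot windows with a
    consistent loss/gain direction (recurrent alterations are what make the
    phenotype learnable from centroids); the rest are placed uniformly with
    a random direction.
    """

    n_segments: tuple = (8, 16)          # inclusive uniform-integer range
    segment_length: tuple = (1_000_000.0, 8_000_000.0)  # uniform bp range
    copies: tuple = (1, 3)
    hotspot_fraction: float = 0.8
    hotspot_length: float = 8_000_000.0
    hotspot_position: float = 0.3        # window start as a fraction of chrom length
    hotspot_min_chrom: float = 12_000_000.0


def hotspot_windows(genome, sig: "HRDSignature") -> list:
    """Deterministic (chrom, start, end, copy) windows, alternating loss/gain."""
    out = []
    for i, (chrom, length) in enumerate(genome):
        if length < sig.hotspot_min_chrom:
            continue
        start = int(sig.hotspot_position * length)
        end = start + int(sig.hotspot_length)
        if end > length:
            continue
        copy = sig.copies[i % len(sig.copies)]
        out.append((chrom, start, end, int(copy)))
    return out


@dataclass
class SimConfig:
    n_patients: int = 348
    profile_proportions: tuple = (0.302, 0.193, 0.129, 0.198, 0.178)
    genome: list = field(default_factory=default_genome)
    bin_size: int = 20_000
    mean_depth: float = 60.0
    gc_bias_strength: float = 0.3
    dispersion: float = 0.05
    ccne1_locus: tuple = ("chr17", 8_000_000, 8_400_000)
    hrd_signature: HRDSignature = field(default_factory=HRDSignature)
    immune_model: ImmuneModel = field(default_factory=ImmuneModel)
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    nsmp_alteration_rate: float = 0.7    # expected altered segments, capped at 2
    brca_hrd_fraction: float = 0.9       # BRCAm genomes also carrying the HRD signature
    ccne1_amp_fraction: float = 17.0 / 45.0  # amplification (vs gain) among amplicon carriers
    amplicon_length: tuple = (300_000.0, 3_000_000.0)
    quality_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.profile_proportions, dtype=float)
        if len(p) != len(PROFILES) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("profile_proportions must be a 5-vector summing to 1")
        if any(l <= 0 for _, l in self.genome):
            raise ValueError("all chromosome lengths must be > 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    def build_grid(self, bin_size: int | None = None) -> BinGrid:
        """The grid is a property of the synthetic genome, keyed off the seed."""
        bs = self.bin_size if bin_size is None else bin_size
        return build_bin_grid(self.genome, bs, rng=np.random.default_rng([self.seed, bs]))


@dataclass
class TruthRecord:
    patient_id: str
    true_profile: str
    brca_mutation: str = "none"      # germline/somatic BRCA1/2 subtype or "none"
    brca1_methylation: bool = False
    has_hrd_signature: bool = False
    cn_segments: list = field(default_factory=list)   # (chrom, start, end, copy) non-neutral
    ccne1_truth: str = "none"        # none / gain / amplification
    immune_truth: dict = field(default_factory=dict)  # marker -> latent per-core mean
    true_hazard: float = float("nan")

    def copy_states(self, grid: BinGrid) -> np.ndarray:
        return project_segments(self.cn_segments, grid)


@dataclass
class CohortData:
    roster: pd.DataFrame
    truths: list
    grids: dict          # name -> BinGrid
    counts: dict         # name -> ndarray (n_bins x n_patients)

    def counts_frame(self, name: str) -> pd.DataFrame:
        g = self.grids[name]
        df = pd.DataFrame(self.counts[name], columns=list(self.roster["patient_id"]))
        df.insert(0, "chrom", g.chroms)
        df.insert(1, "start", g.starts)
        df.insert(2, "end", g.ends)
        return df


def child_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Deterministic per-patient generator: seed + stable CRC32 of the id."""
    return np.random.default_rng([int(seed), zlib.crc32(patient_id.encode())])


def project_segments(segments: list, grid: BinGrid) -> np.ndarray:
    """Per-bin integer copy states from bp-level non-neutral segments.

    A bin takes a segment's copy number when the segment covers the majority
    of the bin (ties broken toward the segment); background is 2.
    """
    states = np.full(grid.n_bins, 2, dtype=np.int64)
    for chrom, start, end, copy in segments:
        idx = grid.overlapping_bins(chrom, int(start), int(end))
        if idx.size == 0:
            continue
        ov = np.minimum(grid.ends[idx], end) - np.maximum(grid.starts[idx], start)
        keep = ov >= 0.5 * grid.widths[idx]
        states[idx[keep]] = int(copy)
    return states


def _place_segment(rng, genome, length, occupied, max_tries=40):
    total = sum(l for _, l in genome)
    for _ in range(max_tries):
        pos = rng.uniform(0, total)
        acc = 0.0
        for chrom, l in genome:
            if pos < acc + l:
                start = int(pos - acc)
                break
            acc += l
        end = min(start + int(length), dict(genome)[chrom])
        if all(not (chrom == c and start < e and end > s) for c, s, e in occupied):
            occupied.append((chrom, start, end))
            return chrom, start, end
    return None


def _simulate_cn_segments(true_profile, config, rng):
    """bp-level non-neutral segments plus the truth CCNE1 sub-label."""
    if true_profile not in PROFILES:
        raise ValueError(f"unknown profile {true_profile!r}")
    chrom_l, start_l, end_l = config.ccne1_locus
    lengths = dict(config.genome)
    if chrom_l not in lengths or end_l > lengths[chrom_l]:
        raise ValueError("ccne1_locus outside the configured genome")
    segments, occupied, ccne1_truth = [], [], "none"

    hrd_like = true_profile in ("nonBRCAmutHRD", "double") or (
        true_profile == "BRCAm" and rng.random() < config.brca_hrd_fraction
    )
    if true_profile in ("CCNE1", "double"):
        amp = rng.random() < config.ccne1_amp_fraction
        copy = int(rng.integers(5, 9)) if amp else int(rng.integers(3, 5))
        ccne1_truth = "amplification" if amp else "gain"
        length = rng.uniform(*config.amplicon_length)
        anchor = rng.uniform(start_l, end_l)            # amplicon overlaps the locus
        start = int(max(0, anchor - rng.uniform(0.2, 0.8) * length))
        end = int(min(start + length, lengths[chrom_l]))
        segments.append((chrom_l, start, end, copy))
        occupied.append((chrom_l, start, end))
    if hrd_like:
        sig = config.hrd_signature
        windows = hotspot_windows(config.genome, sig)
        lo, hi = sig.n_segments
        n_seg = int(rng.integers(lo, hi + 1))
        for _ in range(n_seg):
            length = rng.uniform(*sig.segment_length)
            if windows and rng.random() < sig.hotspot_fraction:
                placed = None
                for _ in range(40):
                    wc, ws, we, wcopy = windows[rng.integers(len(windows))]
                    L = min(int(length), we - ws)
                    start = int(rng.uniform(ws, we - L))
                    end = start + L
                    if all(not (wc == c and start < e and end > s)
                           for c, s, e in occupied):
                        occupied.append((wc, start, end))
                        placed = (wc, start, end)
                        copy = wcopy
                        break
            else:
                placed = _place_segment(rng, config.genome, length, occupied)
                copy = int(rng.choice(sig.copies))
            if placed is None:
                continue
            chrom, start, end = placed
            segments.append((chrom, start, end, copy))
    if true_profile == "NSMP":
        n_seg = min(2, rng.poisson(config.nsmp_alteration_rate))
        for _ in range(n_seg):
            length = rng.uniform(*config.hrd_signature.segment_length)
            placed = _place_segment(rng, config.genome, length, occupied)
            if placed is None:
                continue
            chrom, start, end = placed
            segments.append((chrom, start, end, int(rng.choice((1, 3)))))
    return segments, ccne1_truth, hrd_like


def simulate_copy_states(true_profile, grid, config, rng) -> np.ndarray:
    """Per-bin integer copy states for one genome of the given truth profile."""
    segments, _, _ = _simulate_cn_segments(true_profile, config, rng)
    return project_segments(segments, grid)


def gc_bias_curve(gc, strength, center=0.45, width=0.15):
    """Smooth unimodal multiplicative bias; identically 1 at strength 0."""
    return np.exp(-strength * ((np.asarray(gc, dtype=float) - center) / width) ** 2 / 2.0)


def simulate_read_counts(copy_states, grid, config, rng) -> np.ndarray:
    """Negative-binomial counts per bin.

    mean_b = mean_depth * (width_b / bin_size) * mappability_b * (copy_b / 2)
             * g(GC_b); var = mean * (1 + dispersion * mean).  Blacklisted
    bins are emitted (and flagged in the grid), not dropped.
    """
    copy_states = np.asarray(copy_states)
    if len(copy_states) != grid.n_bins:
        raise ValueError("copy_states not aligned to grid")
    if config.mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    mu = (
        config.mean_depth
        * (grid.widths / config.bin_size)
        * grid.mappability
        * (copy_states / 2.0)
        * gc_bias_curve(grid.gc, config.gc_bias_strength)
    )
    mu = np.maximum(mu, 1e-12)
    if config.dispersion <= 1e-12:
        return rng.poisson(mu).astype(np.int64)
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam).astype(np.int64)


def simulate_immune_counts(true_profile, config, rng) -> dict:
    """Per-marker integer counts over the four cores (all tumor-bearing)."""
    im = config.immune_model
    out = {}
    for marker in MARKERS:
        if marker not in im.means:
            raise ValueError(f"unknown marker {marker!r}")
        try:
            mean = im.means[marker][true_profile]
            shape = im.shapes[marker][true_profile]
        except KeyError as e:
            raise ValueError(f"immune model undefined for {true_profile!r}") from e
        if mean <= 0:
            out[marker] = np.zeros(im.n_cores, dtype=np.int64)
            continue
        lam = rng.gamma(shape, mean / shape)
        out[marker] = rng.poisson(lam, size=im.n_cores).astype(np.int64)
    return out


def patient_hazard(true_profile, immune_high, config) -> float:
    """OS hazard: profile baseline times the density multipliers that apply."""
    sm = config.survival_model
    h = sm.base_hazard[true_profile]
    for marker, is_high in immune_high.items():
        if is_high:
            h *= sm.density_multipliers.get(marker, 1.0)
    if h <= 0:
        raise ValueError("hazard must be positive")
    return h


def simulate_survival(true_profile, immune_category, config, rng):
    """(os_months, os_event, pfs_months, pfs_event) for one patient.

    ``immune_category`` maps marker -> bool (high density).  Latent OS is
    exponential at the patient hazard; latent PFS is the minimum of latent OS
    and an independent progression time, so PFS <= OS always.  Censoring is
    uniform on (0, horizon), shared between the two endpoints.
    """
    sm = config.survival_model
    if sm.censor_horizon_months <= 0:
        raise ValueError("censoring horizon must be > 0")
    h = patient_hazard(true_profile, immune_category, config)
    t_os = rng.exponential(1.0 / h)
    extra = sm.pfs_factor - 1.0
    t_pfs = min(t_os, rng.exponential(1.0 / (extra * h))) if extra > 1e-12 else t_os
    c = rng.uniform(0.0, sm.censor_horizon_months)
    os_event = t_os <= c
    pfs_event = t_pfs <= c
    eps = 1e-3
    return (
        max(min(t_os, c), eps),
        bool(os_event),
        max(min(t_pfs, c), eps),
        bool(pfs_event),
    )


_BRCA_SUBTYPES = ("germline_BRCA1", "somatic_BRCA1", "germline_BRCA2", "somatic_BRCA2")
# within-BRCAm composition: 25/25/18/10 mutation subtypes + 27 methylation-only
_BRCAM_SPLIT = np.array([25, 25, 18, 10, 27], dtype=float) / 105.0

_AGE_P = (0.42, 0.37, 0.21)
_FIGO_P = (0.05, 0.62, 0.33)
_PDS_P = 0.41
_DEBULK_P = (0.55, 0.33, 0.12)


def _simulate_patient(pid, true_profile, config, grids):
    rng = child_rng(config.seed, pid)
    segments, ccne1_truth, hrd_like = _simulate_cn_segments(true_profile, config, rng)
    counts = {
        name: simulate_read_counts(project_segments(segments, g), g, config, rng)
        for name, g in grids.items()
    }
    immune = simulate_immune_counts(true_profile, config, rng)
    immune_max = {m: int(immune[m].max()) for m in MARKERS}
    immune_high = {
        m: immune_max[m] > config.survival_model.density_cutoffs[m] for m in MARKERS
    }
    os_m, os_e, pfs_m, pfs_e = simulate_survival(true_profile, immune_high, config, rng)

    mutation, methylation = "none", False
    if true_profile == "BRCAm":
        k = rng.choice(5, p=_BRCAM_SPLIT)
        if k < 4:
            mutation = _BRCA_SUBTYPES[k]
        else:
            methylation = True
    truth = TruthRecord(
        patient_id=pid,
        true_profile=true_profile,
        brca_mutation=mutation,
        brca1_methylation=methylation,
        has_hrd_signature=hrd_like,
        cn_segments=segments,
        ccne1_truth=ccne1_truth,
        immune_truth={m: float(np.mean(immune[m])) for m in MARKERS},
        true_hazard=patient_hazard(true_profile, immune_high, config),
    )
    row = {
        "patient_id": pid,
        "age_group": ("<65", "65-75", ">75")[rng.choice(3, p=_AGE_P)],
        "figo_stage": ("II", "III", "IV")[rng.choice(3, p=_FIGO_P)],
        "therapy_sequence": "PDS" if rng.random() < _PDS_P else "NACT_IDS",
        "debulking": ("complete", "optimal", "suboptimal")[rng.choice(3, p=_DEBULK_P)],
        "brca_mutation": mutation,
        "brca1_methylation": methylation,
        "dna_quality_pass": bool(rng.random() >= config.quality_fail_rate),
        "os_months": os_m,
        "os_event": int(os_e),
        "pfs_months": pfs_m,
        "pfs_event": int(pfs_e),
        "true_profile": true_profile,
    }
    for m in MARKERS:
        for c in range(config.immune_model.n_cores):
            row[f"{m}_core{c + 1}"] = int(immune[m][c])
    return row, truth, counts


def simulate_cohort(config: SimConfig, grid_bin_sizes=(20_000,)) -> CohortData:
    """Simulate a full cohort: roster, truth records, and count matrices on
    one grid per requested bin size."""
    grids = {f"{bs // 1000}kb": config.build_grid(bs) for bs in grid_bin_sizes}
    rng = np.random.default_rng([config.seed, 0xC0F0])
    labels = rng.choice(
        len(PROFILES), size=config.n_patients, p=np.asarray(config.profile_proportions)
    )
    rows, truths = [], []
    count_cols = {name: [] for name in grids}
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        row, truth, counts = _simulate_patient(pid, PROFILES[labels[i]], config, grids)
        rows.append(row)
        truths.append(truth)
        for name in grids:
            count_cols[name].append(counts[name])
    roster = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["patient_id", "true_profile"]
    )
    counts = {
        name: (np.column_stack(cols) if cols else np.empty((grids[name].n_bins, 0), dtype=np.int64))
        for name, cols in count_cols.items()
    }
    return CohortData(roster=roster, truths=truths, grids=grids, counts=counts)


def simulate_roster(config: SimConfig) -> pd.DataFrame:
    """Roster-only fast path: truth labels, immune counts, covariates and
    survival — no read-count matrices.  Used for survival-calibration runs."""
    rng = np.random.default_rng([config.seed, 0xC0F0])
    labels = rng.choice(
        len(PROFILES), size=config.n_patients, p=np.asarray(config.profile_proportions)
    )
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        prng = child_rng(config.seed, pid)
        profile = PROFILES[labels[i]]
        immune = simulate_immune_counts(profile, config, prng)
        immune_max = {m: int(immune[m].max()) for m in MARKERS}
        immune_high = {
            m: immune_max[m] > config.survival_model.density_cutoffs[m] for m in MARKERS
        }
        os_m, os_e, pfs_m, pfs_e = simulate_survival(profile, immune_high, config, prng)
        row = {
            "patient_id": pid,
            "true_profile": profile,
            "os_months": os_m,
            "os_event": int(os_e),
            "pfs_months": pfs_m,
            "pfs_event": int(pfs_e),
        }
        for m in MARKERS:
            row[f"{m}_max"] = immune_max[m]
            row[f"{m}_high"] = int(immune_high[m])
        rows.append(row)
    return pd.DataFrame(rows)
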