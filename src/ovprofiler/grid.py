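"""Genome bin grids: fixed-width, half-open bins with per-bin GC, mappability
and blacklist annotations.

Coordinates are 0-based, half-open everywhere; on disk the grid is a BED-like
TSV (chrom, start, end, gc, mappability, blacklist).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinGrid", "build_bin_grid"]


@dataclass
class BinGrid:
    """A partition of a genome into fixed-width bins (last bin may be short)."""

    chroms: np.ndarray          # per-bin chromosome name (object dtype)
    starts: np.ndarray          # per-bin start, 0-based inclusive
    ends: np.ndarray            # per-bin end, exclusive
    gc: np.ndarray              # GC fraction in [0, 1]
    mappability: np.ndarray     # in [0, 1]
    blacklist: np.ndarray       # bool
    bin_size: int = 0           # nominal width used to build the grid
    genome: list = field(default_factory=list)  # [(chrom, length), ...]

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def __len__(self) -> int:
        return self.n_bins

    def chrom_slices(self) -> dict:
        """Mapping chrom -> slice of contiguous bin indices."""
        out = {}
        i = 0
        while i < self.n_bins:
            c = self.chroms[i]
            j = i
            while j < self.n_bins and self.chroms[j] == c:
                j += 1
            out[c] = slice(i, j)
            i = j
        return out

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the bin containing (chrom, pos); -1 if chrom unknown."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            return -1
        idx = sl.start + int(pos) // self.bin_size
        if idx >= sl.stop or pos >= self.ends[sl.stop - 1]:
            return -1
        return idx

    def overlapping_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of bins overlapping the half-open interval [start, end)."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            return np.empty(0, dtype=int)
        idx = np.arange(sl.start, sl.stop)
        hit = (self.starts[sl] < end) & (self.ends[sl] > start)
        return idx[hit]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "gc": self.gc,
                "mappability": self.mappability,
                "blacklist": self.blacklist.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, bin_size: int | None = None) -> "BinGrid":
        df = pd.read_csv(path, sep="\t")
        starts = df["start"].to_numpy(dtype=np.int64)
        ends = df["end"].to_numpy(dtype=np.int64)
        if bin_size is None:
            bin_size = int((ends - starts).max())
        genome = [
            (c, int(sub["end"].max())) for c, sub in df.groupby("chrom", sort=False)
        ]
        return cls(
            chroms=df["chrom"].to_numpy(dtype=object),
            starts=starts,
            ends=ends,
            gc=df["gc"].to_numpy(dtype=float),
            mappability=df["mappability"].to_numpy(dtype=float),
            blacklist=df["blacklist"].to_numpy().astype(bool),
            bin_size=bin_size,
            genome=genome,
        )


def build_bin_grid(
    genome: list,
    bin_size: int,
    rng: np.random.Generator | int | None = 0,
    gc_beta: tuple = (42.0, 58.0),
    blacklist_fraction: float = 0.01,
    low_mappability_fraction: float = 0.01,
) -> BinGrid:
    """Tile each chromosome with half-open bins of ``bin_size`` bp.

    The last bin of each chromosome is truncated to the chromosome end.  GC is
    Beta-distributed, mappability is near 1 with a small low-mappability
    subset, and ~``blacklist_fraction`` of bins are flagged blacklisted.
    """
    if not genome:
        raise ValueError("empty genome")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chroms, starts, ends = [], [], []
    for name, length in genome:
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length")
        pos = np.arange(0, length, bin_size, dtype=np.int64)
        chroms.extend([name] * len(pos))
        starts.append(pos)
        ends.append(np.minimum(pos + bin_size, length))
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    n = len(starts)
    gc = rng.beta(gc_beta[0], gc_beta[1], size=n)
    mappability = 1.0 - rng.beta(0.9, 9.0, size=n)
    low = rng.random(n) < low_mappability_fraction
    mappability[low] = rng.uniform(0.0, 0.3, size=low.sum())
    blacklist = rng.random(n) < blacklist_fraction
    return BinGrid(
        chroms=np.asarray(chroms, dtype=object),
        starts=starts,
        ends=ends,
        gc=gc,
        mappability=mappability,
        blacklist=blacklist,
        bin_size=int(bin_size),
        genome=list(genome),
    )
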