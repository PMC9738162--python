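"""Tabular readers/writers for the on-disk formats (all plain TSV)."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import BinGrid

__all__ = ["write_counts_tsv", "read_counts_tsv", "write_roster_tsv",
           "read_roster_tsv"]

_COORD_COLS = ["chrom", "start", "end"]


def write_counts_tsv(path, grid: BinGrid, counts: np.ndarray, sample_ids) -> None:
    """bins x samples count matrix with a leading BED-like coordinate block."""
    df = pd.DataFrame(np.asarray(counts), columns=list(sample_ids))
    df.insert(0, "chrom", grid.chroms)
    df.insert(1, "start", grid.starts)
    df.insert(2, "end", grid.ends)
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> tuple:
    """Returns (coords DataFrame, counts ndarray, sample ids)."""
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in _COORD_COLS]
    return df[_COORD_COLS], df[samples].to_numpy(), samples


def write_roster_tsv(path, roster: pd.DataFrame) -> None:
    roster.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_roster_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
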