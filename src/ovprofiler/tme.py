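"""Immune-cell density scoring and profile-association statistics.

Per-tumor score = highest count over tumor-bearing cores; ordinal score bins
0 / 1-5 / 6-19 / 20-49 / 50-100 / >100; three-level categories use the fixed
published cutpoints by default (a quartile-based mode is available); binary
high/low strata use the published dichotomies (strictly above the cutoff).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "DensityScore",
    "aggregate_cores",
    "ordinal_bin",
    "tri_categorize",
    "binary_high",
    "score_patient",
    "association_test",
    "ordinal_logistic",
    "ORDINAL_BINS",
    "TRI_CUTPOINTS",
    "BINARY_CUTOFFS",
]

ORDINAL_BINS = ("0", "1-5", "6-19", "20-49", "50-100", ">100")
_ORDINAL_EDGES = (0, 5, 19, 49, 100)  # upper edge of each bin but the last

#: fixed (low_upper, high_lower) cutpoints: low < first, high > second
TRI_CUTPOINTS = {
    "CD8": (20, 100),    # <20 / 20-100 / >100
    "CD103": (20, 100),
    "CD20": (20, 50),    # <20 / 20-50 / >50
    "CD68": (50, 100),   # <50 / 50-100 / >100
}

#: binary high strata: strictly above the cutoff
BINARY_CUTOFFS = {"CD8": 100, "CD20": 50, "CD68": 100, "CD103": 100}


@dataclass
class DensityScore:
    patient_id: str
    marker: str
    max_count: int | None
    ordinal: str | None
    tri_category: str | None
    binary_high: bool | None


def aggregate_cores(core_counts, core_has_tumor=None):
    """Highest count over tumor-bearing cores; None when no core has tumor."""
    counts = list(core_counts)
    if len(counts) == 0:
        raise ValueError("no cores supplied")
    if core_has_tumor is None:
        core_has_tumor = [True] * len(counts)
    kept = [c for c, t in zip(counts, core_has_tumor) if t]
    if not kept:
        return None
    return max(kept)


def ordinal_bin(count: int) -> str:
    if count < 0:
        raise ValueError("count must be non-negative")
    for edge, name in zip(_ORDINAL_EDGES, ORDINAL_BINS):
        if count <= edge:
            return name
    return ">100"


def tri_categorize(max_count, marker, mode="fixed", cohort_counts=None) -> str:
    """low / medium / high.

    ``fixed`` applies the published marker cutpoints; ``quartile`` derives
    cutpoints from the 25th/75th percentiles of ``cohort_counts``.
    """
    if mode == "fixed":
        if marker not in TRI_CUTPOINTS:
            raise ValueError(f"unknown marker {marker!r}")
        lo, hi = TRI_CUTPOINTS[marker]
    elif mode == "quartile":
        if cohort_counts is None:
            raise ValueError("quartile mode needs cohort_counts")
        lo, hi = np.percentile(np.asarray(cohort_counts, dtype=float), [25, 75])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if max_count < lo:
        return "low"
    if max_count <= hi:
        return "medium"
    return "high"


def binary_high(max_count, marker) -> bool:
    if marker not in BINARY_CUTOFFS:
        raise ValueError(f"unknown marker {marker!r}")
    return max_count > BINARY_CUTOFFS[marker]


def score_patient(patient_id, marker, core_counts, core_has_tumor=None,
                  mode="fixed", cohort_counts=None) -> DensityScore:
    mx = aggregate_cores(core_counts, core_has_tumor)
    if mx is None:
        return DensityScore(patient_id, marker, None, None, None, None)
    return DensityScore(
        patient_id=patient_id,
        marker=marker,
        max_count=int(mx),
        ordinal=ordinal_bin(int(mx)),
        tri_category=tri_categorize(int(mx), marker, mode, cohort_counts),
        binary_high=binary_high(int(mx), marker),
    )


def association_test(table):
    """Pearson chi-square (no continuity correction) on a categories x groups
    count table (DataFrame or 2-D array); zero-margin rows/columns dropped."""
    t = pd.DataFrame(table).astype(float)
    zero_rows = t.sum(axis=1) == 0
    zero_cols = t.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn("dropping zero-margin rows/columns from chi-square table")
        t = t.loc[~zero_rows, ~zero_cols]
    res = stats.chi2_contingency(t.to_numpy(), correction=False)
    expected = res.expected_freq
    if (expected < 5).any():
        warnings.warn("chi-square expected counts below 5")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def ordinal_logistic(ordinal, profile, reference="BRCAm"):
    """Proportional-odds logit of an ordered density outcome on profile.

    Returns a coefficient table (log-odds vs the reference profile) and a
    separation flag.
    """
    y = pd.Series(ordinal)
    if isinstance(y.dtype, pd.CategoricalDtype) and y.cat.ordered:
        y_cat = y
    else:
        levels = sorted(pd.unique(y))
        y_cat = pd.Categorical(y, categories=levels, ordered=True)
    if len(pd.unique(np.asarray(ordinal))) < 2:
        raise ValueError("outcome has a single level")
    X = pd.get_dummies(pd.Series(profile), dtype=float)
    if reference in X.columns:
        X = X.drop(columns=reference)
    model = OrderedModel(pd.Series(y_cat), X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", maxiter=500, disp=False)
    coefs = fit.params[X.columns]
    se = fit.bse[X.columns]
    separation = bool((np.abs(coefs) > 15).any())
    if separation:
        warnings.warn("possible separation in ordinal logistic fit")
    out = pd.DataFrame(
        {
            "coef": coefs,
            "se": se,
            "odds_ratio": np.exp(coefs),
            "p": 2 * stats.norm.sf(np.abs(coefs / se)),
        }
    )
    out.attrs["separation"] = separation
    return out
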