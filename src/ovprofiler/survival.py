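"""Kaplan-Meier estimation, logrank tests and Cox proportional-hazards
models (lifelines-backed), with the univariable p < 0.10 screen and
backward-selection multivariable workflow used in the analyses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMEstimate",
    "CoxFit",
    "km_estimate",
    "logrank",
    "cox_fit",
    "multivariable_select",
    "encode_covariates",
]


@dataclass
class KMEstimate:
    times: np.ndarray         # event/censor times (step-function support)
    survival: np.ndarray      # S(t) just after each time
    median: float             # earliest t with S <= 0.5; NaN if never reached
    q25: float                # earliest t with S <= 0.75
    q75: float                # earliest t with S <= 0.25
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _quantile_time(times, survival, q):
    hit = np.flatnonzero(survival <= q + 1e-12)
    return float(times[hit[0]]) if len(hit) else float("nan")


def km_estimate(times, events) -> KMEstimate:
    """Product-limit estimator with median and quartile times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(times) == 0:
        raise ValueError("no samples")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    t, s = t[keep], s[keep]
    return KMEstimate(
        times=t,
        survival=s,
        median=_quantile_time(t, s, 0.5),
        q25=_quantile_time(t, s, 0.75),
        q75=_quantile_time(t, s, 0.25),
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank(times, events, groups):
    """(statistic, df, p) for the k-sample logrank test."""
    df_in = pd.DataFrame({"t": times, "e": np.asarray(events).astype(int),
                          "g": groups})
    sizes = df_in.groupby("g").size()
    if (sizes == 0).any():
        warnings.warn("dropping empty groups from logrank test")
        df_in = df_in[df_in["g"].isin(sizes[sizes > 0].index)]
    if df_in["g"].nunique() < 2:
        raise ValueError("need at least 2 non-empty groups")
    if df_in["e"].sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(df_in["t"], df_in["g"], df_in["e"])
    df = df_in["g"].nunique() - 1
    return float(res.test_statistic), int(df), float(res.p_value)


@dataclass
class CoxFit:
    summary: pd.DataFrame     # coef, se, hr, hr_lower, hr_upper, p per term
    log_likelihood: float
    included: list
    reference_levels: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p_value(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


def encode_covariates(df: pd.DataFrame, spec: dict) -> tuple:
    """Expand categorical covariates to dummies against stated references.

    ``spec`` maps column -> reference level (None for numeric pass-through).
    Returns (design DataFrame, term->source-column map, reference levels).
    """
    cols, terms, refs = [], {}, {}
    for col, ref in spec.items():
        if ref is None:
            cols.append(df[col].astype(float).rename(col))
            terms[col] = col
        else:
            d = pd.get_dummies(df[col], prefix=col, dtype=float)
            refcol = f"{col}_{ref}"
            if refcol in d.columns:
                d = d.drop(columns=refcol)
            refs[col] = ref
            for c in d.columns:
                terms[c] = col
            cols.append(d)
    X = pd.concat(cols, axis=1)
    return X, terms, refs


def cox_fit(times, events, X: pd.DataFrame, max_iter: int = 100) -> CoxFit:
    """Cox PH fit (Efron tie handling) of the supplied design matrix."""
    X = pd.DataFrame(X).astype(float).reset_index(drop=True)
    if int(np.asarray(events).sum()) == 0:
        raise ValueError("no events observed")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    data = X.copy()
    data["_t"] = np.asarray(times, dtype=float)
    data["_e"] = np.asarray(events).astype(int)
    cph = CoxPHFitter()
    flags = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col="_t", event_col="_e")
        except Exception as e:  # convergence / collinearity diagnostics
            raise RuntimeError(f"Cox fit failed: {e}") from e
        for w in caught:
            if "convergence" in str(w.message).lower() or "collinear" in str(w.message).lower():
                flags.append(str(w.message))
    s = cph.summary
    if (np.abs(s["coef"]) > 15).any():
        flags.append("possible monotone likelihood / separation")
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "hr_lower": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "hr_upper": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        included=list(X.columns),
        flags=flags,
    )


def multivariable_select(df: pd.DataFrame, time_col: str, event_col: str,
                         candidates: dict, adjust_set: dict,
                         entry_p: float = 0.10, stay_p: float = 0.05) -> CoxFit:
    """Univariable screen at ``entry_p``, then a joint model with the adjust
    set, with backward elimination of screened candidates above ``stay_p``.

    ``candidates`` and ``adjust_set`` map column -> reference level (None for
    numeric).  Adjust-set covariates are always retained.
    """
    if not candidates:
        raise ValueError("no candidate covariates")
    screened = []
    for col, ref in candidates.items():
        X, terms, _ = encode_covariates(df, {col: ref})
        fit = cox_fit(df[time_col], df[event_col], X)
        if (fit.summary["p"] < entry_p).any():
            screened.append(col)
    flags = []
    while True:
        spec = {c: candidates[c] for c in screened}
        spec.update(adjust_set)
        if not spec:
            raise ValueError("empty model: no adjust set and nothing screened in")
        X, terms, refs = encode_covariates(df, spec)
        fit = cox_fit(df[time_col], df[event_col], X)
        fit.reference_levels = refs
        if not screened:
            fit.flags.append("no candidate passed the univariable screen; adjust-set-only model")
            return fit
        cand_p = {
            c: min(fit.summary.loc[t, "p"] for t in fit.summary.index if terms[t] == c)
            for c in screened
        }
        worst = max(cand_p, key=cand_p.get)
        if cand_p[worst] <= stay_p:
            fit.flags.extend(flags)
            return fit
        screened.remove(worst)
        flags.append(f"removed {worst} (p={cand_p[worst]:.3g})")
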