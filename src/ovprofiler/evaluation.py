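"""Parameter-recovery and worked-example evaluations.

These functions recompute the quantities used as acceptance anchors by
running the package end to end: stepwise assignment on the printed reference
roster, percentage arithmetic on the printed density table, and
replicate-based recovery of the survival generator's calibrated parameters.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import nsc, profiles, reference, segmentation, simulate, survival
from .config import RunConfig
from .pipeline import counts_to_ratio_1mb, train_hrd_classifier

__all__ = [
    "reference_assignment_counts",
    "density_percent_high",
    "survival_recovery",
    "ccne1_sensitivity",
    "hrd_recovery",
]


def reference_assignment_counts() -> dict:
    """Run quality exclusion + stepwise assignment on the reference roster.

    Returns counts keyed by profile plus 'kept', 'excluded' and 'mutation'
    (records flagged with any germline/somatic BRCA1/2 mutation).
    """
    roster = reference.build_reference_roster()
    kept, excluded = assign_mod.assign_all(roster)
    out = {p: 0 for p in simulate.PROFILES}
    for r in kept:
        out[r.profile] += 1
    out["kept"] = len(kept)
    out["excluded"] = len(excluded)
    out["mutation"] = sum(
        1 for r in kept if r.brca_mutation in assign_mod.BRCA_SUBTYPES
    )
    return out


def density_percent_high(marker: str, profile: str) -> float:
    """Percentage of a profile's tumors in the marker's highest density
    category, from the printed table counts, rounded to one decimal."""
    table = reference.DENSITY_TABLE[marker]
    total = sum(table[cat][profile] for cat in table)
    return round(100.0 * table["high"][profile] / total, 1)


def survival_recovery(n_reps: int = 200, n: int = 348, seed: int = 0) -> dict:
    """Replicate-based recovery of the survival generator's calibration.

    Per replicate: crude Cox HRs of OS on molecular profile (BRCAm
    reference), the BRCAm-arm KM median, and the crude Cox HR of OS on the
    binary CD103 stratum.  Returns means over replicates.
    """
    from lifelines import CoxPHFitter

    hr_ccne1, med_brcam, hr_cd103 = [], [], []
    for r in range(n_reps):
        cfg = simulate.SimConfig(n_patients=n, seed=seed * 1_000_003 + r)
        df = simulate.simulate_roster(cfg)
        X = pd.get_dummies(df["true_profile"]).drop(columns="BRCAm").astype(float)
        X["_t"], X["_e"] = df["os_months"], df["os_event"]
        cph = CoxPHFitter().fit(X, "_t", "_e")
        hr_ccne1.append(float(np.exp(cph.params_["CCNE1"])))
        X2 = pd.DataFrame(
            {"hi": df["CD103_high"].astype(float), "_t": df["os_months"], "_e": df["os_event"]}
        )
        hr_cd103.append(float(np.exp(CoxPHFitter().fit(X2, "_t", "_e").params_["hi"])))
        sub = df[df["true_profile"] == "BRCAm"]
        med_brcam.append(survival.km_estimate(sub["os_months"], sub["os_event"]).median)
    return {
        "mean_hr_ccne1": float(np.mean(hr_ccne1)),
        "mean_km_median_brcam": float(np.nanmean(med_brcam)),
        "mean_hr_cd103_high": float(np.mean(hr_cd103)),
        "n_reps": n_reps,
        "n": n,
    }


def ccne1_sensitivity(seed: int = 0, max_samples: int = 60,
                      n_perm: int = 200, alpha: float = 0.01) -> dict:
    """End-to-end amplicon recovery: simulate a default cohort, run the
    30 kb arm on truth-amplification samples (capped for runtime), and score
    the fraction recovered as 'amplification' at the locus."""
    cfg = simulate.SimConfig(seed=seed)
    cohort = simulate.simulate_cohort(cfg, grid_bin_sizes=(30_000,))
    g30 = cohort.grids["30kb"]
    idx = [
        i for i, t in enumerate(cohort.truths)
        if t.ccne1_truth == "amplification"
        and any(
            c == cfg.ccne1_locus[0] and (e - s) >= 300_000 and cp >= 5
            for c, s, e, cp in t.cn_segments
        )
    ][:max_samples]
    seg_profiles = []
    for i in idx:
        cp = profiles.CountProfile(
            sample_id=cohort.truths[i].patient_id, grid=g30,
            counts=cohort.counts["30kb"][:, i],
        )
        rp = segmentation.preprocess_30kb(cp)
        rp = segmentation.smooth_if_noisy(rp)
        seg_profiles.append(
            segmentation.segment_cbs(rp, alpha=alpha, n_perm=n_perm, seed=seed)
        )
    segmentation.call_states(seg_profiles, rng=np.random.default_rng(seed))
    hits = sum(
        segmentation.ccne1_status(sp, cfg.ccne1_locus).status == "amplification"
        for sp in seg_profiles
    )
    return {"sensitivity": hits / len(idx) if idx else float("nan"), "n": len(idx)}


def hrd_recovery(seed: int = 0, n_train: int = 200, n_test: int = 348) -> dict:
    """Train the NSC on a labeled synthetic cohort, calibrate, classify a
    fresh cohort, and score sensitivity/specificity against truth."""
    cfg = RunConfig(seed=seed)
    cfg.classifier.n_train = n_train
    model, train_rps = train_hrd_classifier(cfg)
    test_cfg = simulate.SimConfig(n_patients=n_test, seed=seed + 7919)
    cohort = simulate.simulate_cohort(test_cfg, grid_bin_sizes=(test_cfg.bin_size,))
    g = cohort.grids[f"{test_cfg.bin_size // 1000}kb"]
    rps = [
        counts_to_ratio_1mb(cohort.counts[f"{test_cfg.bin_size // 1000}kb"][:, i],
                            g, cohort.truths[i].patient_id, cfg.profile)
        for i in range(n_test)
    ]
    calib = profiles.fit_calibration(train_rps, rps)
    tp = fp = tn = fn = 0
    for i, rp in enumerate(rps):
        call = nsc.classify(model, profiles.apply_calibration(rp, calib))
        truth = cohort.truths[i].has_hrd_signature
        pred = call.label == "nonBRCAmutHRD"
        tp += pred and truth
        fp += pred and not truth
        tn += (not pred) and (not truth)
        fn += (not pred) and truth
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "n_train": n_train,
        "n_test": n_test,
    }
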