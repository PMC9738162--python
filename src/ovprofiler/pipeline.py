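"""End-to-end orchestration: simulate -> profile -> classify -> segment/call
-> assign -> immune densities -> survival, emitting a structured report.

The stepwise logic mirrors the clinical workup: patients with a BRCA event
(mutation or promoter methylation) skip copy-number classification; everyone
else is scored by the 1 MB shrunken-centroids classifier and the 30 kb
segmentation/calling arm.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import nsc, profiles, segmentation, simulate, survival, tme
from .config import RunConfig
from .io import write_counts_tsv, write_roster_tsv

log = logging.getLogger(__name__)

ADJUST_SET = {
    "age_group": "<65",
    "figo_stage": "III",
    "therapy_sequence": "PDS",
    "debulking": "complete",
}


def counts_to_ratio_1mb(counts_col, grid, sample_id, params):
    """20 kb counts -> corrected ratios -> 1 MB profile."""
    cp = profiles.CountProfile(sample_id=sample_id, grid=grid, counts=counts_col)
    cp = profiles.correct_mappability(profiles.correct_gc(cp, span=params.lowess_span))
    rp = profiles.to_log2_ratios(cp, qc_threshold=params.qc_mapd)
    return profiles.aggregate_to_1mb(rp, agg_size=params.aggregate_size)


def train_hrd_classifier(config: RunConfig):
    """Fit the BRCA-like NSC on a freshly simulated labeled training cohort.

    Returns (model, training 1 MB RatioProfiles).
    """
    sim_cfg = config.simulation
    train_cfg = simulate.SimConfig(
        n_patients=config.classifier.n_train,
        genome=sim_cfg.genome,
        bin_size=sim_cfg.bin_size,
        mean_depth=sim_cfg.mean_depth,
        gc_bias_strength=sim_cfg.gc_bias_strength,
        dispersion=sim_cfg.dispersion,
        ccne1_locus=sim_cfg.ccne1_locus,
        hrd_signature=sim_cfg.hrd_signature,
        seed=sim_cfg.seed + 1,
    )
    cohort = simulate.simulate_cohort(train_cfg, grid_bin_sizes=(sim_cfg.bin_size,))
    gname = f"{sim_cfg.bin_size // 1000}kb"
    grid = cohort.grids[gname]
    rps, labels = [], []
    for i, truth in enumerate(cohort.truths):
        rp = counts_to_ratio_1mb(cohort.counts[gname][:, i], grid,
                                 truth.patient_id, config.profile)
        rps.append(rp)
        labels.append(nsc.BRCA_LIKE if truth.has_hrd_signature else nsc.NON_BRCA_LIKE)
    X = np.vstack([rp.log2_ratios for rp in rps])
    y = np.asarray(labels)
    delta = config.classifier.delta
    if delta is None:
        delta = nsc.choose_delta(
            X, y, folds=config.classifier.folds,
            delta_grid=config.classifier.delta_grid,
            rng=np.random.default_rng(sim_cfg.seed + 2),
        )
    feature_ids = [f"{c}:{s}" for c, s in zip(rps[0].grid.chroms, rps[0].grid.starts)]
    model = nsc.train_nsc(X, y, delta, feature_ids=feature_ids)
    return model, rps


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    sim_cfg = config.simulation
    seg_par = config.segmentation
    bs20 = sim_cfg.bin_size
    bs30 = 30_000
    log.info("simulating cohort: n=%d seed=%d", sim_cfg.n_patients, sim_cfg.seed)
    cohort = simulate.simulate_cohort(sim_cfg, grid_bin_sizes=(bs20, bs30))
    g20name, g30name = f"{bs20 // 1000}kb", f"{bs30 // 1000}kb"
    g20, g30 = cohort.grids[g20name], cohort.grids[g30name]

    log.info("training HRD classifier (n_train=%d)", config.classifier.n_train)
    model, train_rps = train_hrd_classifier(config)

    roster_df = cohort.roster
    brca_event = (
        roster_df["brca_mutation"].isin(assign_mod.BRCA_SUBTYPES)
        | roster_df["brca1_methylation"].astype(bool)
    ).to_numpy()

    # 1 MB profiles + cross-dataset calibration for the classifier arm
    current_rps = [
        counts_to_ratio_1mb(cohort.counts[g20name][:, i], g20,
                            roster_df["patient_id"].iloc[i], config.profile)
        for i in range(len(roster_df))
    ]
    calib = profiles.fit_calibration(train_rps, current_rps)
    log.info("calibration: alpha=%.4g beta=%.4g", calib.alpha, calib.beta)

    hrd_calls, seg_profiles = {}, {}
    to_segment = [i for i in range(len(roster_df)) if not brca_event[i]]
    log.info("segmenting %d non-BRCA-event samples", len(to_segment))
    for i in to_segment:
        pid = roster_df["patient_id"].iloc[i]
        call = nsc.classify(model, profiles.apply_calibration(current_rps[i], calib))
        hrd_calls[pid] = call
        cp30 = profiles.CountProfile(sample_id=pid, grid=g30,
                                     counts=cohort.counts[g30name][:, i])
        rp30 = segmentation.preprocess_30kb(cp30)
        rp30 = segmentation.smooth_if_noisy(rp30, seg_par.smooth_mapd)
        seg_profiles[pid] = segmentation.segment_cbs(
            rp30, alpha=seg_par.alpha, n_perm=seg_par.n_perm,
            min_width=seg_par.min_width, seed=sim_cfg.seed,
            merge_threshold=seg_par.merge_threshold,
        )
    if seg_profiles:
        segmentation.call_states(list(seg_profiles.values()),
                                 rng=np.random.default_rng(sim_cfg.seed + 3))
    ccne1_calls = {
        pid: segmentation.ccne1_status(sp, sim_cfg.ccne1_locus)
        for pid, sp in seg_profiles.items()
    }

    # patient records and stepwise assignment
    records = []
    for i, row in roster_df.iterrows():
        pid = row["patient_id"]
        hrd = hrd_calls.get(pid)
        rec = assign_mod.PatientRecord(
            patient_id=pid,
            age_group=row["age_group"],
            figo_stage=row["figo_stage"],
            therapy_sequence=row["therapy_sequence"],
            debulking=row["debulking"],
            brca_mutation=row["brca_mutation"],
            brca1_methylation="yes" if row["brca1_methylation"] else "no",
            hrd_call=(
                "not_tested" if hrd is None
                else "HRD" if hrd.label == "nonBRCAmutHRD"
                else "non_BRCA_like"
            ),
            ccne1=ccne1_calls[pid].status if pid in ccne1_calls else "not_tested",
            dna_quality_pass=bool(row["dna_quality_pass"]),
            immune={
                m: [row[f"{m}_core{c + 1}"] for c in range(sim_cfg.immune_model.n_cores)]
                for m in simulate.MARKERS
            },
            os_months=row["os_months"],
            os_event=int(row["os_event"]),
            pfs_months=row["pfs_months"],
            pfs_event=int(row["pfs_event"]),
        )
        records.append(rec)
    kept, excluded = assign_mod.assign_all(records)
    summary = assign_mod.profile_summary(kept)

    # analysis table
    adf = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in kept],
            "profile": [r.profile for r in kept],
            "age_group": [r.age_group for r in kept],
            "figo_stage": [r.figo_stage for r in kept],
            "therapy_sequence": [r.therapy_sequence for r in kept],
            "debulking": [r.debulking for r in kept],
            "os_months": [r.os_months for r in kept],
            "os_event": [r.os_event for r in kept],
            "pfs_months": [r.pfs_months for r in kept],
            "pfs_event": [r.pfs_event for r in kept],
        }
    )
    density_tables, density_assoc = {}, {}
    for m in simulate.MARKERS:
        scores = [tme.score_patient(r.patient_id, m, r.immune[m], mode=config.tme.mode,
                                    cohort_counts=[max(r.immune[m]) for r in kept])
                  for r in kept]
        adf[f"{m}_max"] = [s.max_count for s in scores]
        adf[f"{m}_tri"] = [s.tri_category for s in scores]
        adf[f"{m}_high"] = [int(bool(s.binary_high)) for s in scores]
        table = pd.crosstab(adf[f"{m}_tri"], adf["profile"])
        density_tables[m] = table
        stat, dof, p = tme.association_test(table)
        density_assoc[m] = {"chi2": stat, "df": dof, "p": p}

    # survival analyses
    surv = {}
    for outcome in ("os", "pfs"):
        t, e = adf[f"{outcome}_months"], adf[f"{outcome}_event"]
        km_medians = {
            prof: survival.km_estimate(t[adf["profile"] == prof],
                                       e[adf["profile"] == prof]).median
            for prof in summary["profile"]
            if (adf["profile"] == prof).any()
        }
        lr_stat, lr_df, lr_p = survival.logrank(t, e, adf["profile"])
        Xc, terms, _ = survival.encode_covariates(adf, {"profile": "BRCAm"})
        crude = survival.cox_fit(t, e, Xc)
        Xa, _, _ = survival.encode_covariates(adf, {"profile": "BRCAm", **ADJUST_SET})
        adjusted = survival.cox_fit(t, e, Xa)
        markers = {}
        for m in simulate.MARKERS:
            fitm = survival.cox_fit(t, e, adf[[f"{m}_high"]])
            Xma, _, _ = survival.encode_covariates(adf, ADJUST_SET)
            Xma[f"{m}_high"] = adf[f"{m}_high"].to_numpy(dtype=float)
            fitma = survival.cox_fit(t, e, Xma)
            markers[m] = {
                "crude_hr": fitm.hazard_ratio(f"{m}_high"),
                "adjusted_hr": fitma.hazard_ratio(f"{m}_high"),
            }
        surv[outcome] = {
            "km_median_months": km_medians,
            "logrank": {"stat": lr_stat, "df": lr_df, "p": lr_p},
            "profile_crude_hr": {k: crude.hazard_ratio(k) for k in crude.summary.index},
            "profile_adjusted_hr": {
                k: adjusted.hazard_ratio(k)
                for k in adjusted.summary.index if k.startswith("profile_")
            },
            "density_hr": markers,
        }

    report = {
        "seed": sim_cfg.seed,
        "n_total": len(records),
        "n_excluded_quality": len(excluded),
        "profiles": summary.to_dict(orient="records"),
        "calibration": {"alpha": calib.alpha, "beta": calib.beta},
        "classifier_delta": model.delta,
        "density_association": density_assoc,
        "survival": surv,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        g20.to_tsv(outdir / "grid_20kb.tsv")
        write_counts_tsv(outdir / "counts_20kb.tsv", g20, cohort.counts[g20name],
                         roster_df["patient_id"])
        write_roster_tsv(outdir / "roster.tsv", roster_df)
        write_roster_tsv(outdir / "analysis_table.tsv", adf)
        summary.to_csv(outdir / "profile_summary.tsv", sep="\t", index=False)
        model.to_json(outdir / "nsc_model.json")
        if seg_profiles:
            pd.concat([sp.to_frame() for sp in seg_profiles.values()]).to_csv(
                outdir / "segments.seg", sep="\t", index=False, float_format="%.6g")
        for m, tab in density_tables.items():
            tab.to_csv(outdir / f"density_{m}.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
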