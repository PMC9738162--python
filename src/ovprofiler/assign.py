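"""Stepwise, mutually exclusive molecular-profile assignment.

Precedence: any germline/somatic BRCA1/2 mutation, then BRCA1 promoter
methylation (both -> BRCAm); then HRD call combined with a CCNE1 gain or
amplification (-> double); HRD alone (-> nonBRCAmutHRD); CCNE1 alone
(-> CCNE1); otherwise NSMP.  Fields marked not_tested count as absent
evidence, mirroring the short-circuit of the stepwise workup.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PatientRecord", "assign_profile", "exclude_for_quality"]

BRCA_SUBTYPES = ("germline_BRCA1", "somatic_BRCA1", "germline_BRCA2", "somatic_BRCA2")


@dataclass
class PatientRecord:
    patient_id: str
    age_group: str = "unknown"               # <65 / 65-75 / >75 / unknown
    figo_stage: str = "unknown"              # II / III / IV / unknown
    therapy_sequence: str = "unknown"        # PDS / NACT_IDS
    debulking: str = "unknown"               # complete / optimal / suboptimal
    brca_mutation: str = "none"              # subtype, "none", or "not_tested"
    brca1_methylation: str = "no"            # yes / no / not_tested
    hrd_call: str = "not_tested"             # HRD / non_BRCA_like / not_tested
    ccne1: str = "not_tested"                # none / gain / amplification / not_tested
    dna_quality_pass: bool = True
    immune: dict = field(default_factory=dict)  # marker -> per-core counts
    os_months: float = float("nan")
    os_event: int = 0
    pfs_months: float = float("nan")
    pfs_event: int = 0
    profile: str | None = None


def assign_profile(record: PatientRecord) -> str:
    """One of BRCAm / nonBRCAmutHRD / CCNE1 / double / NSMP."""
    if not record.dna_quality_pass:
        raise ValueError("excluded: insufficient DNA")
    if record.brca_mutation in BRCA_SUBTYPES:
        return "BRCAm"
    if record.brca1_methylation == "yes":
        return "BRCAm"
    hrd = record.hrd_call == "HRD"
    ccne1 = record.ccne1 in ("gain", "amplification")
    if hrd and ccne1:
        return "double"
    if hrd:
        return "nonBRCAmutHRD"
    if ccne1:
        return "CCNE1"
    return "NSMP"


def exclude_for_quality(roster):
    """Partition a roster (list of PatientRecord) by the DNA-quality flag."""
    kept = [r for r in roster if r.dna_quality_pass]
    excluded = [r for r in roster if not r.dna_quality_pass]
    return kept, excluded


def assign_all(roster):
    """Assign every quality-passing record in place; returns (kept, excluded)."""
    kept, excluded = exclude_for_quality(roster)
    for r in kept:
        r.profile = assign_profile(r)
    return kept, excluded


def profile_summary(records) -> pd.DataFrame:
    """Per-profile counts and one-decimal percentages."""
    counts = pd.Series([r.profile for r in records]).value_counts()
    order = ["BRCAm", "nonBRCAmutHRD", "CCNE1", "double", "NSMP"]
    counts = counts.reindex(order).fillna(0).astype(int)
    pct = (100.0 * counts / max(counts.sum(), 1)).round(1)
    return pd.DataFrame({"profile": order, "n": counts.values, "percent": pct.values})
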