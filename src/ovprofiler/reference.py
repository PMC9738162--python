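"""Printed composition of the reference HGSOC cohort, used as worked-example
input: 360 enrolled patients, 12 excluded for insufficient DNA, and the
molecular and immune-density breakdown of the remaining 348.

These tables are data (inputs to the worked examples), not outputs of the
pipeline; the pipeline recomputes everything downstream of them.
"""
from __future__ import annotations

import pandas as pd

from .assign import PatientRecord

__all__ = [
    "COHORT_SIZE",
    "QUALITY_FAILURES",
    "PROFILE_COUNTS",
    "MUTATION_COUNTS",
    "METHYLATION_ONLY",
    "CCNE1_ONLY_SPLIT",
    "DENSITY_TABLE",
    "build_reference_roster",
    "density_table_frame",
]

COHORT_SIZE = 360
QUALITY_FAILURES = 12

#: assigned-profile counts among the 348 profiled patients
PROFILE_COUNTS = {
    "BRCAm": 105,
    "nonBRCAmutHRD": 67,
    "CCNE1": 45,
    "double": 69,
    "NSMP": 62,
}

#: germline/somatic BRCA1/2 mutation carriers within the BRCAm group
MUTATION_COUNTS = {
    "germline_BRCA1": 25,
    "somatic_BRCA1": 25,
    "germline_BRCA2": 18,
    "somatic_BRCA2": 10,
}
METHYLATION_ONLY = 27

#: gain vs amplification split within the CCNE1-only group
CCNE1_ONLY_SPLIT = {"gain": 28, "amplification": 17}

#: immune-density three-category counts per profile (rows: category)
DENSITY_TABLE = {
    "CD8": {
        "low": {"BRCAm": 13, "nonBRCAmutHRD": 13, "CCNE1": 13, "double": 14, "NSMP": 14},
        "medium": {"BRCAm": 58, "nonBRCAmutHRD": 42, "CCNE1": 23, "double": 39, "NSMP": 26},
        "high": {"BRCAm": 34, "nonBRCAmutHRD": 12, "CCNE1": 9, "double": 16, "NSMP": 22},
    },
    "CD103": {
        "low": {"BRCAm": 28, "nonBRCAmutHRD": 26, "CCNE1": 19, "double": 21, "NSMP": 19},
        "medium": {"BRCAm": 48, "nonBRCAmutHRD": 28, "CCNE1": 21, "double": 36, "NSMP": 32},
        "high": {"BRCAm": 29, "nonBRCAmutHRD": 13, "CCNE1": 5, "double": 12, "NSMP": 11},
    },
    "CD20": {
        "low": {"BRCAm": 55, "nonBRCAmutHRD": 38, "CCNE1": 31, "double": 40, "NSMP": 31},
        "medium": {"BRCAm": 28, "nonBRCAmutHRD": 22, "CCNE1": 12, "double": 18, "NSMP": 18},
        "high": {"BRCAm": 22, "nonBRCAmutHRD": 7, "CCNE1": 2, "double": 11, "NSMP": 13},
    },
    "CD68": {
        "low": {"BRCAm": 42, "nonBRCAmutHRD": 41, "CCNE1": 24, "double": 44, "NSMP": 40},
        "medium": {"BRCAm": 16, "nonBRCAmutHRD": 11, "CCNE1": 12, "double": 9, "NSMP": 12},
        "high": {"BRCAm": 47, "nonBRCAmutHRD": 15, "CCNE1": 9, "double": 16, "NSMP": 10},
    },
}


def density_table_frame(marker: str) -> pd.DataFrame:
    return pd.DataFrame(DENSITY_TABLE[marker]).T  # categories x profiles


def build_reference_roster() -> list:
    """The 360-patient roster implied by the printed subgroup counts.

    Mutation carriers short-circuit downstream testing (fields left
    not_tested); the 12 DNA-quality failures carry no molecular results.
    """
    roster = []
    i = 0

    def add(**kw):
        nonlocal i
        i += 1
        roster.append(PatientRecord(patient_id=f"R{i:04d}", **kw))

    for subtype, n in MUTATION_COUNTS.items():
        for _ in range(n):
            add(brca_mutation=subtype, brca1_methylation="not_tested",
                hrd_call="not_tested", ccne1="not_tested")
    for _ in range(METHYLATION_ONLY):
        add(brca_mutation="none", brca1_methylation="yes",
            hrd_call="not_tested", ccne1="not_tested")
    for _ in range(PROFILE_COUNTS["nonBRCAmutHRD"]):
        add(brca_mutation="none", brca1_methylation="no",
            hrd_call="HRD", ccne1="none")
    for state, n in CCNE1_ONLY_SPLIT.items():
        for _ in range(n):
            add(brca_mutation="none", brca1_methylation="no",
                hrd_call="non_BRCA_like", ccne1=state)
    for _ in range(PROFILE_COUNTS["double"]):
        add(brca_mutation="none", brca1_methylation="no",
            hrd_call="HRD", ccne1="gain")
    for _ in range(PROFILE_COUNTS["NSMP"]):
        add(brca_mutation="none", brca1_methylation="no",
            hrd_call="non_BRCA_like", ccne1="none")
    for _ in range(QUALITY_FAILURES):
        add(dna_quality_pass=False, brca_mutation="not_tested",
            brca1_methylation="not_tested")
    assert len(roster) == COHORT_SIZE
    return roster
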