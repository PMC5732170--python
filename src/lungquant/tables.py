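"""Packaged worked-example fixtures: the published cohort's demographic and
mutation contingency tables.

These are the printed counts of a 118-subject surgical lung-adenocarcinoma
cohort: overall demographics, and the characteristics of EGFR- and
KRAS-mutant subgroups (gender, smoking status and texture-based prognosis
group, mutant versus wild type).  They serve as inputs for the contingency
statistics and as ground truth for percentage computations; no network
access is needed.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_printed_tables", "COHORT_N"]

COHORT_N = 118


def load_printed_tables() -> dict[str, pd.DataFrame]:
    """Return the packaged contingency tables.

    Keys
    ----
    ``demographics``
        Single-column counts for the full cohort (n = 118).
    ``egfr_gender`` / ``egfr_smoking`` / ``egfr_prognosis``
        Rows = category, columns = ``EGFR+`` (n = 15) and ``WT`` (n = 103).
    ``kras_gender`` / ``kras_smoking`` / ``kras_prognosis``
        Rows = category, columns = ``KRAS+`` (n = 47) and ``WT`` (n = 71).
    """
    demographics = pd.DataFrame(
        {"count": [65, 53, 27, 77, 14, 94, 12, 11, 1]},
        index=["women", "men", "smoking_current", "smoking_former", "smoking_never",
               "stage_I", "stage_II", "stage_III", "stage_IV"],
    )
    egfr_gender = pd.DataFrame(
        {"EGFR+": [4, 11], "WT": [49, 54]}, index=["male", "female"]
    )
    egfr_smoking = pd.DataFrame(
        {"EGFR+": [8, 7, 0], "WT": [6, 70, 27]}, index=["never", "former", "current"]
    )
    egfr_prognosis = pd.DataFrame(
        {"EGFR+": [2, 12, 1], "WT": [9, 65, 29]}, index=["G", "I", "P"]
    )
    kras_gender = pd.DataFrame(
        {"KRAS+": [19, 28], "WT": [34, 37]}, index=["male", "female"]
    )
    kras_smoking = pd.DataFrame(
        {"KRAS+": [1, 36, 10], "WT": [13, 41, 17]}, index=["never", "former", "current"]
    )
    kras_prognosis = pd.DataFrame(
        {"KRAS+": [7, 25, 15], "WT": [4, 52, 15]}, index=["G", "I", "P"]
    )
    return {
        "demographics": demographics,
        "egfr_gender": egfr_gender,
        "egfr_smoking": egfr_smoking,
        "egfr_prognosis": egfr_prognosis,
        "kras_gender": kras_gender,
        "kras_smoking": kras_smoking,
        "kras_prognosis": kras_prognosis,
    }
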