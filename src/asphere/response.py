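"""Lesion eligibility, selection, and per-lesion RECIST 1.1 response.

RECIST 1.1 is defined on sums of target-lesion diameters; this package
applies the same rules *per lesion* (the study design it follows reads
each lesion separately): CR is disappearance (for lymph nodes,
normalization to < 10 mm short axis); PR is a relative diameter change of
-30% or more; PD requires both >= +20% relative and >= +5 mm absolute
increase; SD is anything in between. Diameters are the short axis for
lymph nodes and the long transverse-plane diameter for liver, pancreatic
and bone metastases. Thresholds are inclusive on the response side they
state (-30% is PR, +20% with +5 mm is PD).

Classes are cumulated into responding lesions (RL = CR/PR/SD) and
non-responding lesions (NRL = PD) — the binary endpoint of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

RECIST_CLASSES = ("CR", "PR", "SD", "PD")
ORGANS = ("liver", "lymph_node", "bone", "pancreas")

#: Minimum baseline diameter (mm) for a lesion to enter the analysis;
#: smaller lesions are excluded to avoid partial-volume effects.
#: Exclusion is strict-less-than, so the threshold itself is eligible.
ELIGIBILITY_MM = {"liver": 10.0, "pancreas": 10.0, "bone": 10.0, "lymph_node": 15.0}

#: Lymph nodes below this short axis count as normalized (CR) under RECIST 1.1.
NODE_NORMALIZED_MM = 10.0


@dataclass(frozen=True)
class ResponseLabel:
    recist: str
    group: str

    def __post_init__(self) -> None:
        if self.recist not in RECIST_CLASSES:
            raise ValueError(f"unknown RECIST class '{self.recist}'")
        expected = "NRL" if self.recist == "PD" else "RL"
        if self.group != expected:
            raise ValueError(f"{self.recist} must map to {expected}, got {self.group}")


def _check_organ(organ: str) -> str:
    if organ not in ORGANS:
        raise ValueError(f"unknown organ '{organ}'; expected one of {ORGANS}")
    return organ


def eligible_target(organ: str, baseline_mm: float) -> bool:
    """True iff the baseline diameter meets the organ's minimum size."""
    return baseline_mm >= ELIGIBILITY_MM[_check_organ(organ)]


def select_lesions(records: pd.DataFrame, max_per_organ: int = 2, max_per_patient: int = 5) -> pd.DataFrame:
    """Target-lesion selection for one patient: <= 2 per organ, <= 5 total.

    When over-subscribed, lesions are ranked by functional tumor volume
    (descending) as a quantitative proxy for "most representative uptake",
    with a deterministic lesion_id tie-break.
    """
    if records["patient_id"].nunique() > 1:
        raise ValueError("select_lesions operates on one patient's records")
    ranked = records.sort_values(
        ["ftv_ml", "lesion_id"], ascending=[False, True], kind="mergesort"
    )
    kept_idx = []
    organ_counts: dict[str, int] = {}
    for idx, row in ranked.iterrows():
        if len(kept_idx) >= max_per_patient:
            break
        if organ_counts.get(row["organ"], 0) >= max_per_organ:
            continue
        organ_counts[row["organ"]] = organ_counts.get(row["organ"], 0) + 1
        kept_idx.append(idx)
    return records.loc[sorted(kept_idx)]


def classify_lesion(baseline_mm: float, followup_mm: float, organ: str) -> ResponseLabel:
    """Per-lesion RECIST 1.1 label from baseline and follow-up diameters."""
    _check_organ(organ)
    if baseline_mm <= 0:
        raise ValueError("baseline diameter must be positive")
    if followup_mm < 0:
        raise ValueError("follow-up diameter must be >= 0")
    if followup_mm == 0 or (organ == "lymph_node" and followup_mm < NODE_NORMALIZED_MM):
        return ResponseLabel("CR", "RL")
    change = (followup_mm - baseline_mm) / baseline_mm
    if change <= -0.30:
        return ResponseLabel("PR", "RL")
    if change >= 0.20 and (followup_mm - baseline_mm) >= 5.0:
        return ResponseLabel("PD", "NRL")
    return ResponseLabel("SD", "RL")


def group_response(recist: str) -> str:
    """RL/NRL dichotomy: PD is non-responding, everything else responds."""
    if recist not in RECIST_CLASSES:
        raise ValueError(f"unknown RECIST class '{recist}'")
    return "NRL" if recist == "PD" else "RL"


def classify_table(table: pd.DataFrame, timepoint: str = "12m") -> pd.DataFrame:
    """Classify every row of a lesion table at the given follow-up timepoint.

    Adds ``recist_<timepoint>`` and ``group_<timepoint>`` columns.
    """
    col = {"4m": "diameter_4m_mm", "12m": "diameter_12m_mm"}.get(timepoint)
    if col is None:
        raise ValueError(f"timepoint must be '4m' or '12m', got '{timepoint}'")
    labels = [
        classify_lesion(row["diameter_baseline_mm"], row[col], row["organ"])
        for _, row in table.iterrows()
    ]
    out = table.copy()
    out[f"recist_{timepoint}"] = [lab.recist for lab in labels]
    out[f"group_{timepoint}"] = [lab.group for lab in labels]
    return out


def sum_of_diameters_response(baseline_sum_mm: float, followup_sum_mm: float) -> ResponseLabel:
    """Patient-level RECIST 1.1 on sums of target-lesion diameters (off by default)."""
    if baseline_sum_mm <= 0:
        raise ValueError("baseline sum must be positive")
    if followup_sum_mm == 0:
        return ResponseLabel("CR", "RL")
    change = (followup_sum_mm - baseline_sum_mm) / baseline_sum_mm
    if change <= -0.30:
        return ResponseLabel("PR", "RL")
    if change >= 0.20 and (followup_sum_mm - baseline_sum_mm) >= 5.0:
        return ResponseLabel("PD", "NRL")
    return ResponseLabel("SD", "RL")
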