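"""Synthetic per-lesion cohorts emulating a published PRRT response study.

The generator draws, per RECIST class, asphericity (ASP) values and
baseline diameters from five-number-summary quantile models, assigns each
lesion one of four metastatic sites, and then draws follow-up diameters
*inside the RECIST-consistent interval* for the assigned class, so that
re-classifying the generated diameters recovers the class labels exactly
(closed loop). Lesions are packed into synthetic patients honoring the
study's selection rules (at most two lesions per organ, five per patient),
so no generated lesion is dropped downstream.

The module-level default summaries are the per-class ASP and per-group
diameter distributions of a 131-lesion [177Lu]DOTATATE cohort
(104 responding / 27 non-responding lesions; liver 59, lymph node 48,
bone 19, pancreas 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..grids import split_seed
from ..response import ELIGIBILITY_MM, RECIST_CLASSES
from .quantiles import FiveNumberSummary, sample_from_summary

#: Per-RECIST-class ASP (%) five-number summaries (min, q1, median, q3, max).
ASP_SUMMARIES: dict[str, FiveNumberSummary] = {
    "CR": FiveNumberSummary(0.0, 0.0, 0.5, 1.3, 2.8),
    "PR": FiveNumberSummary(0.0, 0.9, 1.7, 2.8, 5.5),
    "SD": FiveNumberSummary(0.2, 2.1, 3.4, 4.5, 18.0),
    "PD": FiveNumberSummary(2.4, 8.5, 11.3, 15.5, 21.3),
}

#: Group-level ASP (%) summaries: responding (CR/PR/SD) vs non-responding (PD).
RL_ASP_SUMMARY = FiveNumberSummary(0.0, 0.9, 2.9, 3.9, 18.0)
NRL_ASP_SUMMARY = ASP_SUMMARIES["PD"]

#: Baseline diameter (mm) summaries per response group.
BASELINE_DIAMETER_SUMMARIES: dict[str, FiveNumberSummary] = {
    "RL": FiveNumberSummary(10.0, 13.7, 19.2, 33.3, 100.0),
    "NRL": FiveNumberSummary(12.0, 14.2, 19.6, 35.0, 104.6),
}

#: Organ mix of the default cohort (fractions of 131 lesions).
ORGAN_MIX: dict[str, float] = {
    "liver": 59 / 131,
    "lymph_node": 48 / 131,
    "bone": 19 / 131,
    "pancreas": 5 / 131,
}

#: Default class sizes. The responding split CR/PR/SD is a package choice
#: consistent with the group total of 104; PD is the reported 27.
DEFAULT_N_PER_CLASS: dict[str, int] = {"CR": 6, "PR": 33, "SD": 65, "PD": 27}

# Functional tumor volume (ml): identical lognormal across classes (the
# groups showed no FTV difference before therapy); median ~12 ml, clipped
# to a delineable range.
_FTV_LOG_MEDIAN = np.log(12.0)
_FTV_LOG_SIGMA = 0.7
_FTV_RANGE_ML = (2.5, 150.0)

# Uniform sampling windows for the RECIST-consistent relative follow-up
# change per class; PR/PD windows are further clipped per lesion so the
# absolute rules (node CR normalization, +5 mm PD minimum) hold.
_PR_RATIO = (0.35, 0.70)
_SD_RATIO = (0.705, 1.195)
_PD_RATIO_SPAN = 0.40


@dataclass(frozen=True)
class CohortSpec:
    n_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    asp_summary_per_class: dict[str, FiveNumberSummary] = field(
        default_factory=lambda: dict(ASP_SUMMARIES)
    )
    baseline_diameter_summary: dict[str, FiveNumberSummary] = field(
        default_factory=lambda: dict(BASELINE_DIAMETER_SUMMARIES)
    )
    organ_mix: dict[str, float] = field(default_factory=lambda: dict(ORGAN_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in RECIST_CLASSES:
                raise ValueError(f"unknown RECIST class '{cls}'")
            if n < 0:
                raise ValueError("class counts must be >= 0")
        if not np.isclose(sum(self.organ_mix.values()), 1.0):
            raise ValueError("organ proportions must sum to 1")
        if any(p < 0 for p in self.organ_mix.values()):
            raise ValueError("organ proportions must be non-negative")


def _followup_for_class(cls: str, baseline: float, organ: str, rng: np.random.Generator) -> float:
    """Draw one follow-up diameter consistent with the assigned RECIST class."""
    if cls == "CR":
        return 0.0
    if cls == "PR":
        lo, hi = _PR_RATIO
        if organ == "lymph_node":
            # shrinking a node below 10 mm short axis would normalize it (CR)
            lo = max(lo, 10.05 / baseline)
            if lo >= hi:
                lo = hi - 1e-6
        return baseline * rng.uniform(lo, hi)
    if cls == "SD":
        lo, hi = _SD_RATIO
        # stay clear of the +5 mm PD gate for small lesions (ratio cap irrelevant
        # below baseline 25 mm, where the absolute rule dominates anyway)
        return baseline * rng.uniform(lo, hi)
    # PD: >= +20% and >= +5 mm
    lo = max(1.205, 1.0 + 5.05 / baseline)
    return baseline * rng.uniform(lo, lo + _PD_RATIO_SPAN)


def _assign_patients(organs: list[str], rng: np.random.Generator) -> list[str]:
    """Greedy packing into patients: <= 2 lesions/organ and <= 5 lesions/patient."""
    patients: list[dict] = []
    ids = []
    order = rng.permutation(len(organs))
    assigned = [""] * len(organs)
    for idx in order:
        organ = organs[idx]
        home = None
        for p in patients:
            if p["total"] < 5 and p["organs"].get(organ, 0) < 2:
                home = p
                break
        if home is None:
            home = {"name": f"P{len(patients) + 1:02d}", "total": 0, "organs": {}}
            patients.append(home)
        home["total"] += 1
        home["organs"][organ] = home["organs"].get(organ, 0) + 1
        assigned[idx] = home["name"]
    return assigned


def sample_agreement_table(
    n: int = 77,
    diff_sd_pp: float = 3.1,
    seed: int = 0,
    nrl_fraction: float = 27 / 131,
) -> pd.DataFrame:
    """Paired pre-/intra-therapeutic ASP readings for the agreement sub-study.

    A latent per-lesion ASP is drawn from the RL/NRL quantile mixture;
    each of the two readings adds independent zero-mean Gaussian
    inter-scan noise with SD ``diff_sd_pp / sqrt(2)``, so the paired
    *difference* has SD ``diff_sd_pp`` (default 3.1 pp, which puts the
    1.96-SD limits of agreement near +/-6 pp and makes roughly
    2*Phi(-5/3.1) ~ 10% of pairs exceed the 5 pp concordance limit).
    """
    rng = split_seed(seed, "agreement")
    n_nrl = int(round(n * nrl_fraction))
    latent = np.concatenate(
        [
            sample_from_summary(RL_ASP_SUMMARY, n - n_nrl, rng),
            sample_from_summary(NRL_ASP_SUMMARY, max(n_nrl, 1), rng)[: n_nrl],
        ]
    )
    sd = diff_sd_pp / np.sqrt(2.0)
    a = latent + rng.normal(0.0, sd, size=n)
    b = latent + rng.normal(0.0, sd, size=n)
    return pd.DataFrame(
        {
            "lesion_id": [f"A{i + 1:03d}" for i in range(n)],
            "asp_in_percent": a,
            "asp_lu_percent": b,
        }
    )


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one lesion table (one row per lesion) from a cohort spec."""
    rows = []
    organs_all = sorted(spec.organ_mix)
    probs = np.array([spec.organ_mix[o] for o in organs_all])
    rng_organ = split_seed(spec.seed, "cohort", "organ")
    rng_ftv = split_seed(spec.seed, "cohort", "ftv")
    for cls in RECIST_CLASSES:
        n = int(spec.n_per_class.get(cls, 0))
        if n == 0:
            continue
        group = "NRL" if cls == "PD" else "RL"
        rng_asp = split_seed(spec.seed, "cohort", "asp", cls)
        rng_diam = split_seed(spec.seed, "cohort", "diam", cls)
        asp = sample_from_summary(spec.asp_summary_per_class[cls], n, rng_asp)
        organs = rng_organ.choice(organs_all, size=n, p=probs)
        base_summary = spec.baseline_diameter_summary[group]
        for i in range(n):
            organ = str(organs[i])
            baseline = float(
                sample_from_summary(
                    base_summary, 1, rng_diam, lower_bound=ELIGIBILITY_MM[organ]
                )[0]
            )
            d4 = _followup_for_class(cls, baseline, organ, rng_diam)
            d12 = _followup_for_class(cls, baseline, organ, rng_diam)
            ftv = float(
                np.clip(
                    np.exp(rng_ftv.normal(_FTV_LOG_MEDIAN, _FTV_LOG_SIGMA)), *_FTV_RANGE_ML
                )
            )
            rows.append(
                {
                    "organ": organ,
                    "asp_percent": float(asp[i]),
                    "ftv_ml": ftv,
                    "diameter_baseline_mm": baseline,
                    "diameter_4m_mm": float(d4),
                    "diameter_12m_mm": float(d12),
                    "true_class": cls,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=["patient_id", "lesion_id"] + list(table.columns))
    rng_pat = split_seed(spec.seed, "cohort", "patients")
    table["patient_id"] = _assign_patients(list(table["organ"]), rng_pat)
    table["lesion_id"] = [f"L{i + 1:03d}" for i in range(len(table))]
    cols = ["patient_id", "lesion_id"] + [c for c in table.columns if c not in ("patient_id", "lesion_id")]
    return table[cols].reset_index(drop=True)
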