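"""End-to-end study orchestration: delineate -> ASP -> classify -> statistics.

A study runs in one of three modes:

* ``synthetic`` — generate a lesion cohort from a :class:`CohortSpec`
  (seed mandatory), classify it, and run the statistics;
* ``tables`` — load an existing lesion CSV and do the same;
* ``volumes`` — delineate and measure a list of NIfTI image/seed pairs,
  producing a lesion table fragment (ASP + FTV per volume).

Outputs are a labeled CSV, a JSON report mirroring a clinical results
section (per-class ASP summaries, lesion counts, Kruskal-Wallis,
Mann-Whitney, ROC block per timepoint, agreement block when paired
scores are provided), and optional ROC / boxplot / Bland-Altman figures.
The report is deterministic given the seed and carries the config hash,
seed and package version for provenance; no timestamps are embedded, so
repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import LesionVOI
from .io import read_volume, write_lesion_table
from .response import RECIST_CLASSES, eligible_target, select_lesions, classify_table
from .segmentation import DelineationParams, delineate
from .shape import measure_voi
from .stats import (
    AgreementResult,
    ROCResult,
    bland_altman,
    five_number_summary,
    kruskal_wallis,
    mann_whitney_u,
    roc,
)
from .synthetic.cohort import CohortSpec, sample_cohort

log = logging.getLogger("asphere")


@dataclass
class StudyConfig:
    mode: str = "synthetic"
    table_path: str | None = None
    volumes: list[dict] = field(default_factory=list)  # [{"image":…, "seed_point":[x,y,z]}]
    cohort: CohortSpec | None = None
    delineation: DelineationParams = field(default_factory=DelineationParams)
    timepoints: tuple[str, ...] = ("4m", "12m")
    seed: int | None = None
    out_dir: str = "study_out"
    make_plots: bool = False
    score_column: str = "asp_percent"
    paired_column: str | None = None  # second ASP reading for the agreement block

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "tables", "volumes"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if self.mode == "tables" and not self.table_path:
            raise ValueError("tables mode requires table_path")
        if self.mode == "volumes" and not self.volumes:
            raise ValueError("volumes mode requires a volume list")


def config_from_yaml(path: str | os.PathLike) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "cohort" in raw and raw["cohort"] is not None:
        raw["cohort"] = CohortSpec(**raw["cohort"])
    if "delineation" in raw and raw["delineation"] is not None:
        raw["delineation"] = DelineationParams(**raw["delineation"])
    if "timepoints" in raw:
        raw["timepoints"] = tuple(raw["timepoints"])
    return StudyConfig(**raw)


def _config_hash(config: StudyConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    payload = dataclasses.asdict(config)
    # output location and plot toggles do not affect the computed numbers
    payload.pop("out_dir", None)
    payload.pop("make_plots", None)
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _roc_block(r: ROCResult) -> dict:
    return {
        "auc": r.auc,
        "cutoff": r.cutoff,
        "cutoff_convention": "predict non-responding iff score > cutoff",
        "youden_j": r.youden_j,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "n_positive_NRL": r.n_positive,
        "n_negative_RL": r.n_negative,
    }


def _agreement_block(a: AgreementResult) -> dict:
    return {
        "mean_diff": a.mean_diff,
        "loa_low": a.loa_low,
        "loa_high": a.loa_high,
        "rho": a.rho,
        "rho_p": a.rho_p,
        "n_discordant": a.n_discordant,
        "n_total": a.n_total,
    }


def measure_volumes(entries: list[dict], params: DelineationParams) -> pd.DataFrame:
    """Delineate + measure each {'image': path, 'seed_point': [x,y,z]} entry."""
    rows = []
    for i, entry in enumerate(entries):
        grid = read_volume(entry["image"])
        voi = delineate(grid, tuple(entry["seed_point"]), params)
        metrics = measure_voi(voi, grid)
        rows.append(
            {
                "lesion_id": entry.get("lesion_id", f"V{i + 1:03d}"),
                "image": str(entry["image"]),
                "asp_percent": metrics.ASP_percent,
                "ftv_ml": metrics.V_ml,
                "surface_mm2": metrics.S_mm2,
                "converged": voi.converged,
            }
        )
        log.info("measured %s: V=%.2f ml ASP=%.2f%%", entry["image"], metrics.V_ml, metrics.ASP_percent)
    return pd.DataFrame(rows)


def apply_study_filters(table: pd.DataFrame) -> pd.DataFrame:
    """Eligibility (size) exclusion, then per-patient target-lesion selection."""
    eligible = table.apply(
        lambda r: eligible_target(r["organ"], r["diameter_baseline_mm"]), axis=1
    )
    for _, row in table[~eligible].iterrows():
        log.info(
            "excluded %s/%s: %s baseline %.1f mm below eligibility",
            row["patient_id"], row["lesion_id"], row["organ"], row["diameter_baseline_mm"],
        )
    kept = table[eligible]
    selected = kept.groupby("patient_id", group_keys=False)[kept.columns].apply(select_lesions)
    for lid in sorted(set(kept["lesion_id"]) - set(selected["lesion_id"])):
        log.info("dropped %s in target-lesion selection", lid)
    return selected.reset_index(drop=True)


def run_study(config: StudyConfig) -> dict:
    """Run the configured study end to end; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "volumes":
        table = measure_volumes(config.volumes, config.delineation)
        table.to_csv(out / "volumes_measured.csv", index=False)
        return {
            "provenance": _provenance(config),
            "volumes": table.to_dict(orient="records"),
        }

    if config.mode == "synthetic":
        spec = config.cohort or CohortSpec(seed=config.seed)
        if spec.seed != config.seed and config.seed is not None:
            spec = dataclasses.replace(spec, seed=config.seed)
        table = sample_cohort(spec)
    else:
        from .io import read_lesion_table

        table = read_lesion_table(config.table_path)

    table = apply_study_filters(table)
    for tp in config.timepoints:
        table = classify_table(table, tp)
    write_lesion_table(table, out / "labeled.csv")

    score = table[config.score_column].to_numpy(float)
    report: dict = {"provenance": _provenance(config)}
    report["lesion_counts"] = {
        "total": int(len(table)),
        "by_organ": {k: int(v) for k, v in table["organ"].value_counts().items()},
    }
    for tp in config.timepoints:
        recist = table[f"recist_{tp}"]
        group = table[f"group_{tp}"].to_numpy()
        classes_present = [c for c in RECIST_CLASSES if (recist == c).any()]
        block: dict = {
            "n_per_class": {c: int((recist == c).sum()) for c in RECIST_CLASSES},
            "n_RL": int((group == "RL").sum()),
            "n_NRL": int((group == "NRL").sum()),
            "asp_summary_per_class": {
                c: list(five_number_summary(score[recist == c]).points)
                for c in classes_present
            },
        }
        if len(classes_present) >= 2:
            kw = kruskal_wallis(*[score[recist == c] for c in classes_present])
            block["kruskal_wallis"] = {"H": kw.statistic, "p": kw.p_value}
        if (group == "RL").any() and (group == "NRL").any():
            mwu = mann_whitney_u(score[group == "RL"], score[group == "NRL"])
            block["mann_whitney"] = {"U": mwu.statistic, "p": mwu.p_value}
            r = roc(score, group, positive="NRL")
            block["roc"] = _roc_block(r)
            if config.make_plots:
                _plot_roc(r, out / f"roc_{tp}.png", tp)
        report[f"timepoint_{tp}"] = block
        if config.make_plots:
            _plot_boxes(score, recist, out / f"asp_by_class_{tp}.png", tp)
    if config.paired_column and config.paired_column in table.columns:
        agreement = paired_agreement_study(table, config.score_column, config.paired_column)
        report["agreement"] = _agreement_block(agreement)
        if config.make_plots:
            _plot_bland_altman(
                table[config.score_column], table[config.paired_column], out / "bland_altman.png"
            )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _provenance(config: StudyConfig) -> dict:
    return {"config_hash": _config_hash(config), "seed": config.seed, "version": __version__}


def paired_agreement_study(
    table: pd.DataFrame, col_a: str, col_b: str, concordance_limit_pp: float = 5.0
) -> AgreementResult:
    """Spearman + Bland-Altman + discordance for two paired ASP readings."""
    for col in (col_a, col_b):
        if col not in table.columns:
            raise ValueError(f"paired agreement: column '{col}' missing")
    unpaired = table.index[table[col_a].isna() | table[col_b].isna()].tolist()
    if unpaired:
        raise ValueError(f"paired agreement: unpaired rows {unpaired}")
    return bland_altman(
        table[col_a].to_numpy(float),
        table[col_b].to_numpy(float),
        concordance_limit_pp=concordance_limit_pp,
    )


# ----------------------------------------------------------------- plotting

def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _plot_roc(r: ROCResult, path: Path, tp: str) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(r.points[:, 0], r.points[:, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ASP ROC, {tp} (AUC {r.auc:.2f}, cutoff >{r.cutoff:.2f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_boxes(score, recist, path: Path, tp: str) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    present = [c for c in RECIST_CLASSES if (recist == c).any()]
    ax.boxplot([score[recist == c] for c in present], tick_labels=present)
    ax.set_ylabel("ASP (%)")
    ax.set_title(f"ASP by RECIST class, {tp}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_bland_altman(a, b, path: Path) -> None:
    plt = _mpl()
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter((a + b) / 2, a - b, s=12)
    for y, style in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, ls=style, c="gray", lw=0.9)
    ax.set_xlabel("mean of readings (%)")
    ax.set_ylabel("difference (pp)")
    ax.set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
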