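"""Run the full synthetic cohort study and read off the ROC block.

Generates a 131-lesion cohort (104 responding / 27 non-responding) whose
per-class ASP distributions follow the published five-number summaries,
classifies it with the RECIST rules, and prints the 12-month separation
statistics.
"""

import json

from asphere.pipeline import StudyConfig, run_study

report = run_study(StudyConfig(mode="synthetic", seed=1, out_dir="scratch/example_study"))

block = report["timepoint_12m"]
print(f"lesions analyzed : {report['lesion_counts']['total']} "
      f"({block['n_RL']} RL / {block['n_NRL']} NRL)")
print(f"Kruskal-Wallis H : {block['kruskal_wallis']['H']:.1f} "
      f"(p = {block['kruskal_wallis']['p']:.2g}) across CR/PR/SD/PD")
roc = block["roc"]
print(f"ROC AUC          : {roc['auc']:.3f}")
print(f"Youden cutoff    : ASP > {roc['cutoff']:.2f} %  "
      f"(sens {100 * roc['sensitivity']:.0f} %, spec {100 * roc['specificity']:.0f} %)")
print("High ASP separates non-responding from responding lesions; the model-")
print("implied AUC of the generating quantile summaries is ~0.876, and any")
print("single 131-lesion draw scatters around it.")
print("full report: scratch/example_study/report.json")
print(json.dumps(report["provenance"], indent=2))
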