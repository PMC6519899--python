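"""Per-lesion RECIST 1.1 classification of diameter changes.

Classifies three liver-lesion diameter pairs typical of PRRT follow-up:
one clear responder and two progressing lesions.
"""

from asphere.response import classify_lesion

cases = [(39.0, 23.0), (35.0, 42.0), (46.0, 70.0)]
for baseline, followup in cases:
    label = classify_lesion(baseline, followup, organ="liver")
    change = 100 * (followup - baseline) / baseline
    print(f"{baseline:5.1f} mm -> {followup:5.1f} mm  ({change:+6.1f} %)  "
          f"=> {label.recist} ({label.group})")
print("PR needs a >=30% decrease; PD needs both >=20% and >=5 mm increase;")
print("PD lesions form the non-responding (NRL) group, the rest respond (RL).")
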