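"""Simulate a two-group phantom cohort and summarize its structure.

Generates the default study conditions — 20 complete-response (CR) and 10
non-CR patients whose tumors are larger, hotter, and more heterogeneous in
the non-CR group — and prints per-group medians of the semiquantitative PET
metrics. The printed medians should differ in the clinical direction:
higher SUVmax, MTV, and volume in the non-CR group.
"""

import numpy as np

from pettex import CohortConfig, generate_cohort, metabolic_tumor_volume, roi_volume, suv_max

records = generate_cohort(CohortConfig(seed=1))
print(f"{len(records)} patients: "
      f"{sum(r.response == 'CR' for r in records)} CR, "
      f"{sum(r.response == 'nonCR' for r in records)} non-CR\n")

rows = {"CR": [], "nonCR": []}
for rec in records:
    rows[rec.response].append(
        (suv_max(rec.pet, rec.pet_mask),
         metabolic_tumor_volume(rec.pet, rec.pet_mask) / 1000.0,
         roi_volume(rec.pet_mask) / 1000.0)
    )

print(f"{'group':<8s}{'SUVmax (grey)':>16s}{'MTV (cm^3)':>14s}{'volume (cm^3)':>16s}")
for group, vals in rows.items():
    med = np.median(np.array(vals), axis=0)
    print(f"{group:<8s}{med[0]:>16.0f}{med[1]:>14.1f}{med[2]:>16.1f}")
print("\nNon-CR medians exceed CR medians on every metric: the generator's"
      "\neffect multipliers reproduce the direction of the clinical contrast.")
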