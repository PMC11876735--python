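"""Sphere-model lesion doses and dose-threshold frequencies.

Interpolates Lu-177 unit-density-sphere dose factors by lesion mass,
computes per-administration and cumulative course doses under the
constant-uptake assumption, and counts lesions above 100 and 50 Gy.
"""

from prrtdose import (
    AdministrationRecord,
    cumulative_lesion_dose,
    default_sphere_table,
    fractions_at_thresholds,
    interp_df,
    lesion_dose,
)

table = default_sphere_table()
admin = AdministrationRecord(cycle_activities=(7.4,) * 4)

lesions = [  # (id, mass g, TIAC h)
    ("liver-1", 5.0, 1.8),
    ("liver-2", 120.0, 2.5),
    ("node-1", 12.0, 0.15),
    ("bone-1", 30.0, 0.9),
]
print(f"{'lesion':9s} {'mass g':>7s} {'df Gy/(MBq.h)':>14s} {'per admin Gy':>13s} {'course Gy':>10s}")
cum = []
for lid, mass, tiac in lesions:
    d1 = lesion_dose(tiac, mass, table, administered=7.4e3)
    dc = cumulative_lesion_dose(d1, admin)
    cum.append(dc)
    print(f"{lid:9s} {mass:7.1f} {interp_df(table, mass):14.5f} {d1:13.1f} {dc:10.1f}")

freq = fractions_at_thresholds(cum, (100.0, 50.0))
print(f"\nlesions >= 100 Gy: {freq[100.0]:.1f}%   >= 50 Gy: {freq[50.0]:.1f}%")
print("\nDose factors fall roughly as 1/mass (electrons dominate for Lu-177),")
print("so at equal TIAC a small lesion absorbs a far higher dose; cumulative")
print("doses scale the measured cycle by total over reference-cycle activity.")
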