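"""Odor-activity screening of the bundled volatile panel.

Computes OAV = concentration / odor threshold in water for every
(compound, grade) cell and tallies the odor-active compounds (OAV > 1):
these are the volatiles present above their human detection threshold and
hence contributing to the perceived aroma of each tea grade.
"""

from flavorgrade import datasets, oav_table, odor_active_counts, top_oav

volatiles = datasets.load_volatiles()
thresholds = datasets.load_thresholds()

oavs = oav_table(volatiles, thresholds)
counts = odor_active_counts(oavs)

print("odor-active compounds (OAV > 1) per grade:", counts["per_group"])
print("odor-active in every grade:", counts["active_in_all"])
print("odor-active in at least one grade:", counts["active_in_any"])

for grade in volatiles.group_ids:
    top = top_oav(oavs, grade, k=5)
    names = [volatiles.get(c).name for c in top["compound_id"]]
    print(f"\ntop-5 OAV in {grade}:")
    for name, oav in zip(names, top["oav"]):
        print(f"  {name:<28s} OAV = {oav:8.2f}")

print("\nA higher OAV means a stronger expected contribution to aroma; "
      "the per-grade top-5 lists show which compounds dominate each grade.")
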