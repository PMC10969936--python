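"""The multi-criteria differential-marker screen.

Combines the published VIP scores and ANOVA p-values with recomputed OAVs:
stage 1 keeps compounds with VIP > 1 and p < 0.05 (statistically
discriminating between grades); stage 2 additionally requires OAV > 1 in
at least one grade (sensorially relevant).  The non-volatile panel is
screened on VIP > 1 alone.
"""

import pandas as pd

from flavorgrade import (datasets, oav_table, screen_markers,
                         screen_nonvolatile_markers)

volatiles = datasets.load_volatiles()
thresholds = datasets.load_thresholds()
nonvolatiles = datasets.load_nonvolatiles()

oavs = oav_table(volatiles, thresholds)
vip = pd.Series({r.compound_id: r.vip for r in volatiles.records})
p = pd.Series({r.compound_id: r.p_value for r in volatiles.records})

rep = screen_markers(vip, p, oavs)
print(f"stage 1 (VIP > 1 and p < 0.05): {int(rep['stage1'].sum())} "
      "volatile compounds")
print(f"stage 2 (+ OAV > 1 in >= 1 grade): {int(rep['stage2'].sum())} "
      "odor-active differential markers")

nv = screen_nonvolatile_markers(nonvolatiles)
print(f"non-volatile markers (VIP > 1): {int(nv['marker'].sum())}")

print("\nThe three counts (80, 43, 22) are the compound lists a taster "
      "would watch to tell the grades apart by aroma and by taste.")
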