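"""Odor activity values (OAV) and odor-active compound ranking.

OAV = concentration / odor threshold in water, both in ug/kg.  A compound
with OAV > 1 is considered odor-active: present above its human detection
threshold and hence contributing to the perceived aroma.  The OAV is
undefined (NaN) when the compound was not detected or no literature
threshold exists ("n.f."); undefined OAVs are excluded from — not failed
by — OAV-based filters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .tables import CompoundTable


def compute_oav(concentration: float | None,
                threshold: float | None) -> float:
    """Single OAV; NaN when the threshold is absent or the compound undetected."""
    if threshold is None or (isinstance(threshold, float) and math.isnan(threshold)):
        return math.nan
    if threshold <= 0:
        raise ValueError("threshold must be strictly positive")
    if concentration is None or (isinstance(concentration, float)
                                 and math.isnan(concentration)):
        return math.nan
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return concentration / threshold


def oav_table(compounds: CompoundTable, thresholds: pd.DataFrame
              ) -> pd.DataFrame:
    """Long-format OAV records: one row per (compound, group).

    ``thresholds`` is indexed by compound_id with a ``threshold_ugkg``
    column (NaN = not found).  Output columns: compound_id, name, group,
    concentration, threshold, oav, odor_active.
    """
    rows = []
    for r in compounds.records:
        thr = thresholds["threshold_ugkg"].get(r.compound_id, np.nan)
        for g in compounds.group_ids:
            st = r.per_group[g]
            conc = st.mean if st.detected else np.nan
            oav = compute_oav(conc, thr)
            rows.append({"compound_id": r.compound_id, "name": r.name,
                         "group": g, "concentration": conc,
                         "threshold": thr, "oav": oav,
                         "odor_active": bool(oav > 1)
                         if not math.isnan(oav) else np.nan})
    return pd.DataFrame(rows)


def odor_active_counts(oavs: pd.DataFrame) -> dict:
    """Per-group OAV>1 counts plus the all-group and any-group tallies."""
    act = oavs[oavs["oav"] > 1]
    per_group = {g: int((act["group"] == g).sum())
                 for g in oavs["group"].unique()}
    by_compound = act.groupby("compound_id")["group"].nunique()
    n_groups = oavs["group"].nunique()
    return {"per_group": per_group,
            "active_in_all": int((by_compound == n_groups).sum()),
            "active_in_any": int(by_compound.size)}


def odor_active_set(oavs: pd.DataFrame, scope: str = "any") -> set[str]:
    """Compound ids with OAV > 1 in at least one ("any") or every ("all") group."""
    act = oavs[oavs["oav"] > 1].groupby("compound_id")["group"].nunique()
    if scope == "any":
        return set(act.index)
    if scope == "all":
        return set(act.index[act == oavs["group"].nunique()])
    raise ValueError("scope must be 'any' or 'all'")


def top_oav(oavs: pd.DataFrame, group: str, k: int = 5) -> pd.DataFrame:
    """The k compounds with the highest OAV in one group.

    Undefined OAVs are excluded; ties break on compound_id for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = oavs[(oavs["group"] == group) & oavs["oav"].notna()]
    sub = sub.sort_values(["oav", "compound_id"],
                          ascending=[False, True], kind="mergesort")
    return sub.head(k).reset_index(drop=True)
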