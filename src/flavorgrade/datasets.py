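"""Bundled reference tables for the three-grade Tuo tea study.

Four CSV fixtures ship with the package, transcribed from the published
quantification tables of a GC-MS / HPLC flavoromics survey of Chongqing Tuo
tea at three commercial grades (SG = special, 1G = first, 2G = second;
triplicate measurements, mean ± sd):

* ``volatiles.csv``     — 112 volatile compounds: retention time, calculated
  and literature retention index, per-grade concentration (ug/kg) with
  ``n.d.`` for grade-specific absences and Duncan letters as printed.
* ``thresholds.csv``    — odor thresholds in water (ug/kg, ``n.f.`` = no
  literature value), the published per-grade OAVs, PLS-DA VIP scores and
  ANOVA p-values for the same 112 compounds.
* ``nonvolatiles.csv``  — 49 non-volatile rows (44 compounds plus 5 derived
  aggregates such as total catechins, flagged ``derived``), mg/g or %, with
  VIP scores.
* ``categories.csv``    — curated chemical class per volatile compound
  (29 ketones, 26 aldehydes, 22 alcohols, 17 hydrocarbons, 8 esters,
  4 phenolics, 4 methoxy-phenolics, 2 lactones).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables import CompoundTable, CompoundRecord, GroupDesign, \
    read_compound_table, read_threshold_table

GRADES = ("SG", "1G", "2G")

DESIGN = GroupDesign(group_ids=GRADES, replicates_per_group=3, alpha=0.05)


def _path(name: str):
    return resources.files("flavorgrade.data").joinpath(name)


def load_volatiles() -> CompoundTable:
    """The 112-compound volatile panel (ug/kg), category annotations attached."""
    with resources.as_file(_path("volatiles.csv")) as p:
        table = read_compound_table(p, group_ids=list(GRADES), unit="ug/kg")
    cats = load_categories()
    thr = load_thresholds()
    records = []
    for r in table.records:
        records.append(CompoundRecord(
            compound_id=r.compound_id, name=r.name, cas=r.cas,
            rt_min=r.rt_min, ri_cal=r.ri_cal, ri_lit=r.ri_lit,
            category=cats[r.compound_id], derived=False,
            vip=float(thr.loc[r.compound_id, "vip"]),
            p_value=float(thr.loc[r.compound_id, "p_value"]),
            per_group=r.per_group))
    return CompoundTable(records, list(GRADES), unit="ug/kg")


def load_thresholds() -> pd.DataFrame:
    """Odor thresholds plus published OAV / VIP / p columns, indexed by id."""
    with resources.as_file(_path("thresholds.csv")) as p:
        return read_threshold_table(p)


def load_nonvolatiles() -> CompoundTable:
    """The non-volatile panel (catechins, amino acids, flavonol glycosides...).

    Units are mixed (mg/g for compounds, % for the bulk assays); the
    ``derived`` flag marks aggregate rows that are sums of other rows.
    """
    with resources.as_file(_path("nonvolatiles.csv")) as p:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    df.insert(0, "no", df["name"])
    import io
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_compound_table(buf, group_ids=list(GRADES), unit="mg/g")


def load_categories() -> dict[str, str]:
    """Curated chemical class per volatile compound id."""
    with resources.as_file(_path("categories.csv")) as p:
        df = pd.read_csv(p, dtype=str)
    return dict(zip(df["no"], df["category"]))
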