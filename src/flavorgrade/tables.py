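"""Tabular data model and CSV I/O for compound quantification tables.

The central container is :class:`CompoundTable`: one row per compound, one
``(mean, sd, n, detected)`` record per sample group.  Cells may be written
either as the compact ``"21.18 ± 0.92 a"`` style used in published tables
(optionally carrying a Duncan letter) or as separate ``<group>_mean`` /
``<group>_sd`` columns.  The literal sentinels ``n.d.`` (not detected) and
``n.f.`` (not found) are preserved on round-trip.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ND = "n.d."
NF = "n.f."

_PM_RE = re.compile(r"^\s*([0-9.]+)\s*±\s*([0-9.]+)\s*([A-Za-z]*)\s*$")


class TableParseError(ValueError):
    """Raised when a cell or column cannot be interpreted."""


@dataclass(frozen=True)
class GroupStat:
    """Per-group quantification: mean ± sd over n replicates.

    ``detected=False`` encodes the ``n.d.`` state; mean and sd are then None.
    ``letter`` optionally carries a compact-letter-display label.
    """

    mean: float | None
    sd: float | None
    n: int = 3
    detected: bool = True
    letter: str | None = None

    def __post_init__(self):
        if self.detected:
            if self.mean is None or self.sd is None:
                raise ValueError("detected record requires mean and sd")
            if self.sd < 0:
                raise ValueError("sd must be >= 0")
        else:
            if self.mean is not None or self.sd is not None:
                raise ValueError("n.d. record must not carry mean/sd")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    per_group: dict[str, GroupStat]
    cas: str | None = None
    rt_min: float | None = None
    ri_cal: float | None = None
    ri_lit: float | None = None
    category: str | None = None
    unit: str | None = None
    derived: bool = False
    vip: float | None = None
    p_value: float | None = None

    def detected_in(self, group: str) -> bool:
        return self.per_group[group].detected


@dataclass
class CompoundTable:
    """Ordered collection of :class:`CompoundRecord` sharing one unit."""

    records: list[CompoundRecord]
    group_ids: list[str]
    unit: str = "ug/kg"

    def __post_init__(self):
        ids = [r.compound_id for r in self.records]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise TableParseError(f"duplicate compound_id(s): {sorted(dups)}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, compound_id: str) -> CompoundRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def compounds(self) -> "CompoundTable":
        """Table restricted to individual compounds (derived rows dropped)."""
        t = CompoundTable([r for r in self.records if not r.derived],
                          list(self.group_ids), self.unit)
        return t

    def mean_frame(self, fill_nd: float | None = None) -> pd.DataFrame:
        """Compounds x groups matrix of means; n.d. becomes NaN or ``fill_nd``."""
        nd = np.nan if fill_nd is None else float(fill_nd)
        data = {g: [r.per_group[g].mean if r.per_group[g].detected else nd
                    for r in self.records] for g in self.group_ids}
        return pd.DataFrame(data, index=self.compound_ids)

    def sd_frame(self) -> pd.DataFrame:
        data = {g: [r.per_group[g].sd if r.per_group[g].detected else np.nan
                    for r in self.records] for g in self.group_ids}
        return pd.DataFrame(data, index=self.compound_ids)

    def detected_frame(self) -> pd.DataFrame:
        data = {g: [r.per_group[g].detected for r in self.records]
                for g in self.group_ids}
        return pd.DataFrame(data, index=self.compound_ids)


@dataclass(frozen=True)
class GroupDesign:
    """Experimental design: ordered groups, replication, significance level."""

    group_ids: tuple[str, ...]
    replicates_per_group: int = 3
    alpha: float = 0.05

    def __post_init__(self):
        if len(self.group_ids) < 2:
            raise ValueError("need at least 2 groups")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ReplicateMatrix:
    """Samples x variables numeric matrix with one group label per sample."""

    values: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self):
        if len(self.group_labels) != len(self.values):
            raise ValueError("one group label required per sample row")
        if self.values.columns.duplicated().any():
            raise ValueError("variable_ids must be unique")
        self.group_labels = pd.Series(
            np.asarray(self.group_labels), index=self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def variable_ids(self):
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen


# ---------------------------------------------------------------------------
# cell parsing / formatting


def parse_measurement(cell: str) -> GroupStat:
    """Parse one ``"mean ± sd [letter]"`` or ``"n.d."`` cell."""
    cell = str(cell).strip()
    if cell == ND or cell.startswith(ND):
        return GroupStat(None, None, detected=False)
    m = _PM_RE.match(cell)
    if not m:
        raise TableParseError(f"malformed measurement cell: {cell!r}")
    letter = m.group(3) or None
    return GroupStat(float(m.group(1)), float(m.group(2)), letter=letter)


def format_measurement(stat: GroupStat, decimals: int = 2) -> str:
    if not stat.detected:
        return ND
    s = f"{stat.mean:.{decimals}f} ± {stat.sd:.{decimals}f}"
    return f"{s} {stat.letter}" if stat.letter else s


# ---------------------------------------------------------------------------
# readers / writers


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    if s in ("", NF, ND, "nan"):
        return None
    return float(s)


def read_compound_table(path, group_ids: list[str] | None = None,
                        dialect: str = "pm", unit: str = "ug/kg",
                        n: int = 3, id_column: str = "no") -> CompoundTable:
    """Read a compound quantification CSV.

    dialect="pm"    : one cell per group, ``"mean ± sd [letter]"`` / ``"n.d."``
    dialect="split" : ``<group>_mean`` and ``<group>_sd`` columns, blank = n.d.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise TableParseError(f"missing id column {id_column!r} in {path}")
    if group_ids is None:
        if dialect == "pm":
            known = {id_column, "name", "cas", "rt_min", "ri_cal", "ri_lit",
                     "id_method", "category", "unit", "derived", "vip",
                     "p_value"}
            group_ids = [c for c in df.columns if c not in known]
        else:
            group_ids = sorted({c[:-5] for c in df.columns
                                if c.endswith("_mean")})
    records = []
    for i, row in df.iterrows():
        per_group = {}
        for g in group_ids:
            try:
                if dialect == "pm":
                    stat = parse_measurement(row[g])
                elif dialect == "split":
                    mean = _opt_float(row.get(f"{g}_mean"))
                    sd = _opt_float(row.get(f"{g}_sd"))
                    if mean is None:
                        stat = GroupStat(None, None, detected=False)
                    else:
                        stat = GroupStat(mean, 0.0 if sd is None else sd)
                else:
                    raise TableParseError(f"unknown dialect {dialect!r}")
            except (TableParseError, ValueError) as e:
                raise TableParseError(
                    f"row {i + 2} ({row[id_column]}), column {g!r}: {e}"
                ) from e
            stat = replace(stat, n=n)
            per_group[g] = stat
        records.append(CompoundRecord(
            compound_id=str(row[id_column]),
            name=str(row.get("name", row[id_column])),
            cas=str(row["cas"]) if "cas" in df.columns and row["cas"] else None,
            rt_min=_opt_float(row.get("rt_min")),
            ri_cal=_opt_float(row.get("ri_cal")),
            ri_lit=_opt_float(row.get("ri_lit")),
            category=(row["category"] or None) if "category" in df.columns else None,
            unit=(row["unit"] or None) if "unit" in df.columns else unit,
            derived=str(row.get("derived", "false")).lower() == "true",
            vip=_opt_float(row.get("vip")),
            p_value=_opt_float(row.get("p_value")),
            per_group=per_group,
        ))
    return CompoundTable(records, list(group_ids), unit=unit)


def write_compound_table(table: CompoundTable, path, decimals: int = 2) -> None:
    rows = []
    for r in table.records:
        row = {"no": r.compound_id, "name": r.name}
        if r.cas is not None:
            row["cas"] = r.cas
        for col, v in (("rt_min", r.rt_min), ("ri_cal", r.ri_cal),
                       ("ri_lit", r.ri_lit)):
            if v is not None:
                row[col] = v
        for g in table.group_ids:
            row[g] = format_measurement(r.per_group[g], decimals)
        if r.category is not None:
            row["category"] = r.category
        if r.derived:
            row["derived"] = "true"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_threshold_table(path, id_column: str = "no") -> pd.DataFrame:
    """Read odor thresholds (ug/kg in water). ``n.f.`` becomes NaN.

    Returns a DataFrame indexed by compound_id with at least a
    ``threshold_ugkg`` column; any extra columns are carried through.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise TableParseError(f"missing id column {id_column!r} in {path}")
    out = df.set_index(df[id_column].astype(str)).drop(columns=[id_column])
    out.index.name = "compound_id"

    def conv(v):
        s = str(v).strip().replace(",", "")
        if s in (NF, ND, ""):
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    for col in out.columns:
        if col in ("name", "id_method"):
            continue
        out[col] = out[col].map(conv)
    thr = out["threshold_ugkg"]
    bad = thr[(thr <= 0) & thr.notna()]
    if len(bad):
        raise TableParseError(
            f"non-positive threshold for compound(s): {list(bad.index)}")
    return out


def join_tables(compounds: CompoundTable, thresholds: pd.DataFrame,
                key: str = "compound_id") -> tuple[pd.DataFrame, dict]:
    """Left-join compound means onto thresholds.

    Join keys: ``compound_id`` (default), ``cas`` or ``name`` (normalized,
    case/space-insensitive).  Returns (joined frame, report); unmatched
    compounds keep a NaN threshold.  Ambiguous keys raise.
    """
    def norm(s):
        return re.sub(r"\s+", " ", str(s)).strip().lower()

    if key == "compound_id":
        left_keys = [r.compound_id for r in compounds.records]
        right = thresholds.copy()
        right_keys = [str(i) for i in thresholds.index]
    elif key in ("cas", "name"):
        left_keys = [norm(getattr(r, key)) for r in compounds.records]
        right = thresholds.copy()
        if key not in right.columns:
            raise TableParseError(f"threshold table lacks column {key!r}")
        right_keys = [norm(v) for v in right[key]]
    else:
        raise ValueError(f"unsupported join key {key!r}")

    for side, keys in (("compound", left_keys), ("threshold", right_keys)):
        dups = sorted({k for k in keys if keys.count(k) > 1})
        if dups:
            raise TableParseError(f"ambiguous {side} join key(s): {dups}")

    thr_map = dict(zip(right_keys, right["threshold_ugkg"]))
    mean = compounds.mean_frame()
    rows, unmatched = [], []
    for r, k in zip(compounds.records, left_keys):
        thr = thr_map.get(k, np.nan)
        if k not in thr_map:
            unmatched.append(r.compound_id)
        row = {"compound_id": r.compound_id, "name": r.name,
               "threshold_ugkg": thr}
        for g in compounds.group_ids:
            row[g] = mean.loc[r.compound_id, g]
        rows.append(row)
    joined = pd.DataFrame(rows).set_index("compound_id")
    report = {"n_rows": len(joined), "n_unmatched": len(unmatched),
              "unmatched": unmatched}
    return joined, report


MARKER_COLUMNS = ["compound_id", "name", "category", "vip", "p_value",
                  "max_oav", "stage1", "stage2"]


def write_marker_report(report: pd.DataFrame, path) -> None:
    """Write a marker screening report with a deterministic column order."""
    cols = [c for c in MARKER_COLUMNS if c in report.columns]
    cols += [c for c in report.columns if c not in cols]
    report.loc[:, cols].to_csv(path, index=False)


def read_marker_report(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("stage1", "stage2"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
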