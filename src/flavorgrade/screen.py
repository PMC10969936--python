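"""Detection sets, content summaries, marker screening, HCA, sensory score.

The differential-marker screen combines three lines of evidence:

* stage 1 — multivariate + univariate: VIP > 1 (contribution to the PLS-DA
  class separation) and ANOVA p < 0.05;
* stage 2 (volatiles only) — sensory relevance: OAV > 1 in at least one
  grade, i.e. the compound is present above its odor threshold somewhere.

All thresholds are strict inequalities.  Compounds with undefined OAV
(no literature threshold) pass through stage 1 but cannot enter stage 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tables import CompoundTable, ReplicateMatrix


# ---------------------------------------------------------------------------
# detection (Venn) sets


@dataclass
class DetectionSets:
    per_group: dict[str, set[str]]
    all_compounds: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.per_group.items()}

    @property
    def common(self) -> set[str]:
        sets = list(self.per_group.values())
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out

    def unique_to(self, group: str) -> set[str]:
        out = set(self.per_group[group])
        for g, s in self.per_group.items():
            if g != group:
                out -= s
        return out

    @property
    def never_detected(self) -> set[str]:
        return self.all_compounds - set().union(*self.per_group.values())

    def regions(self) -> dict[str, int]:
        """Cardinality of every disjoint Venn region, keyed by group subset."""
        groups = list(self.per_group)
        out: dict[str, int] = {}
        for mask in range(1, 2 ** len(groups)):
            inside = [g for i, g in enumerate(groups) if mask >> i & 1]
            outside = [g for g in groups if g not in inside]
            region = set(self.all_compounds)
            for g in inside:
                region &= self.per_group[g]
            for g in outside:
                region -= self.per_group[g]
            out["&".join(inside)] = len(region)
        out["none"] = len(self.never_detected)
        return out


def detection_sets(table: CompoundTable) -> DetectionSets:
    per_group = {g: {r.compound_id for r in table.records if r.detected_in(g)}
                 for g in table.group_ids}
    return DetectionSets(per_group=per_group,
                         all_compounds=set(table.compound_ids))


# ---------------------------------------------------------------------------
# content summaries


def content_summaries(table: CompoundTable,
                      category_map: dict[str, str] | None = None,
                      scale: float = 1e-3) -> dict:
    """Per-group totals and per-category counts / sums / proportions.

    Totals sum the detected means per group; ``scale`` converts units for
    the reported totals (default 1e-3: ug/kg -> mg/kg).  Compounds missing
    from ``category_map`` are listed and excluded from category sums.
    """
    if category_map is None:
        category_map = {r.compound_id: r.category for r in table.records
                        if r.category is not None}
    means = table.mean_frame(fill_nd=0.0)
    totals = {g: float(means[g].sum()) * scale for g in table.group_ids}
    uncategorized = [c for c in table.compound_ids if c not in category_map]
    cat = pd.Series({c: category_map[c] for c in table.compound_ids
                     if c in category_map})
    counts = cat.value_counts().to_dict()
    sums, props = {}, {}
    for g in table.group_ids:
        by_cat = means.loc[cat.index, g].groupby(cat).sum() * scale
        sums[g] = by_cat.to_dict()
        total = by_cat.sum()
        props[g] = (by_cat / total).to_dict() if total > 0 else {}
    return {"totals": totals, "category_counts": counts,
            "category_sums": sums, "category_proportions": props,
            "uncategorized": uncategorized}


# ---------------------------------------------------------------------------
# marker screening


@dataclass(frozen=True)
class MarkerCriteria:
    vip_min: float = 1.0
    p_max: float = 0.05
    oav_min: float = 1.0
    oav_scope: str = "any"  # "any" or "all" grades

    def __post_init__(self):
        if self.vip_min <= 0 or self.p_max <= 0 or self.oav_min <= 0:
            raise ValueError("all thresholds must be positive")


def screen_markers(vip: pd.Series, p_values: pd.Series,
                   oavs: pd.DataFrame,
                   criteria: MarkerCriteria = MarkerCriteria()
                   ) -> pd.DataFrame:
    """Two-stage volatile marker screen.

    stage 1: VIP > vip_min and p < p_max; stage 2: additionally OAV >
    oav_min in at least one grade (``oav_scope="any"``) or every grade
    (``"all"``).  Compounds missing a VIP or p-value are excluded and
    reported via the ``excluded`` attribute of the returned frame.
    """
    ids = sorted(set(vip.index) | set(p_values.index),
                 key=lambda c: (len(str(c)), str(c)))
    excluded = [c for c in ids
                if c not in vip.index or c not in p_values.index
                or pd.isna(vip.get(c)) or pd.isna(p_values.get(c))]
    kept = [c for c in ids if c not in excluded]
    active = _active_at(oavs, criteria.oav_min, criteria.oav_scope)
    max_oav = oavs.groupby("compound_id")["oav"].max()
    rows = []
    for c in kept:
        s1 = bool(vip[c] > criteria.vip_min and p_values[c] < criteria.p_max)
        s2 = bool(s1 and c in active)
        rows.append({"compound_id": c, "vip": float(vip[c]),
                     "p_value": float(p_values[c]),
                     "max_oav": float(max_oav.get(c, np.nan)),
                     "stage1": s1, "stage2": s2})
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    out.attrs["criteria"] = criteria
    return out


def _active_at(oavs: pd.DataFrame, oav_min: float, scope: str) -> set[str]:
    act = oavs[oavs["oav"] > oav_min].groupby("compound_id")["group"].nunique()
    if scope == "any":
        return set(act.index)
    return set(act.index[act == oavs["group"].nunique()])


def screen_nonvolatile_markers(table: CompoundTable,
                               criteria: MarkerCriteria = MarkerCriteria()
                               ) -> pd.DataFrame:
    """Non-volatile marker screen: VIP > vip_min over non-aggregate rows."""
    rows = [{"compound_id": r.compound_id, "name": r.name,
             "vip": r.vip, "marker": bool(r.vip is not None
                                          and r.vip > criteria.vip_min)}
            for r in table.records if not r.derived]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class HcaResult:
    linkage: np.ndarray
    labels: dict[int, np.ndarray] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def cut(self, k: int) -> np.ndarray:
        if k not in self.labels:
            self.labels[k] = hierarchy.fcluster(self.linkage, k,
                                                criterion="maxclust")
        return self.labels[k]

    def cophenetic(self) -> np.ndarray:
        return hierarchy.cophenet(self.linkage)


def hca(matrix, metric: str = "euclidean", method: str = "ward",
        autoscale: bool = True, k: int | None = None) -> HcaResult:
    """Agglomerative clustering of samples (rows).

    Defaults follow common chemometrics practice: Euclidean distance and
    Ward linkage on autoscaled columns.  NaNs are rejected with the
    offending cell named.
    """
    if isinstance(matrix, ReplicateMatrix):
        df = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix, dtype=float))
    if df.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    nan = np.argwhere(df.isna().to_numpy())
    if len(nan):
        i, j = nan[0]
        raise ValueError(
            f"NaN at row {df.index[i]!r}, column {df.columns[j]!r}")
    X = df.to_numpy(dtype=float)
    if autoscale:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    res = HcaResult(linkage=Z, sample_ids=[str(i) for i in df.index])
    if k is not None:
        res.cut(k)
    return res


# ---------------------------------------------------------------------------
# weighted sensory score


#: Weights of the 100-point tea quality grading system: dry-leaf
#: appearance, liquor color, aroma, taste, infused leaves.
SENSORY_WEIGHTS = {"appearance": 0.20, "liquor_color": 0.10, "aroma": 0.30,
                   "taste": 0.35, "infused_leaves": 0.05}


def sensory_total(subscores: dict[str, float],
                  weights: dict[str, float] | None = None) -> float:
    """Weighted total sensory score on the 0-100 scale."""
    weights = SENSORY_WEIGHTS if weights is None else weights
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    missing = set(weights) - set(subscores)
    if missing:
        raise ValueError(f"missing subscores: {sorted(missing)}")
    for k, v in subscores.items():
        if not 0 <= v <= 100:
            raise ValueError(f"subscore {k!r} outside [0, 100]")
    return float(sum(weights[k] * subscores[k] for k in weights))
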