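"""One-way ANOVA and Duncan's multiple range test with compact letters.

Both tests are computable from raw replicates or from per-group
``(mean, sd, n)`` summaries — the two routes are algebraically identical
because the one-way decomposition depends on the data only through those
summaries.

Duncan's test ranks the k group means and compares the gap between any two
means spanning r ranked positions against a critical range built from the
studentized range distribution at the "special protection level"
1 - (1 - alpha)^(r-1).  A pair differs only if its gap exceeds the critical
range for its span and no enclosing stretch of means was already declared
homogeneous.  Results are rendered as compact letter displays: groups
sharing a letter are not significantly different.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import CompoundTable, GroupDesign, ReplicateMatrix


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("variance-based tests need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    mse: float
    degenerate: bool = False


def summaries_from_replicates(values: np.ndarray, labels) -> list[GroupSummary]:
    """Per-group (mean, sd, n) with the sample (ddof=1) standard deviation."""
    labels = np.asarray(labels)
    out = []
    for g in pd.unique(labels):
        x = np.asarray(values)[labels == g]
        out.append(GroupSummary(str(g), float(np.mean(x)),
                                float(np.std(x, ddof=1)), len(x)))
    return out


def anova_oneway(groups: list[GroupSummary]) -> AnovaResult:
    """One-way fixed-effects ANOVA from per-group summaries.

    SSB = sum n_i (m_i - grand)^2, MSE = pooled within-group variance,
    F = MSB / MSE with (k-1, sum(n_i-1)) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    grand = float(np.sum(ns * means) / ns.sum())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    sse = float(np.sum((ns - 1) * sds ** 2))
    mse = sse / df_w
    if mse == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, math.nan, 0.0, degenerate=True)
        return AnovaResult(math.inf, df_b, df_w, 0.0, 0.0, degenerate=True)
    f = (ssb / df_b) / mse
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f, df_b, df_w, p, mse)


@lru_cache(maxsize=4096)
def _q_cached(p: float, span: int, df: int) -> float:
    # studentized-range quantiles are costly; Duncan reuses few (p, span, df)
    return float(sps.studentized_range.ppf(p, span, df))


def duncan_critical_range(alpha: float, span: int, df: int, n: float,
                          mse: float) -> float:
    """Critical range for a stretch of ``span`` ranked means.

    Uses the studentized range quantile at Duncan's protection level
    alpha_r = 1 - (1 - alpha)^(span - 1).
    """
    alpha_r = 1.0 - (1.0 - alpha) ** (span - 1)
    q = _q_cached(round(1.0 - alpha_r, 12), span, df)
    if not np.isfinite(q):
        raise ValueError(f"studentized range quantile unavailable for df={df}")
    return float(q * math.sqrt(mse / n))


@dataclass
class DuncanResult:
    letters: dict[str, str]
    different: dict[frozenset, bool]
    order: list[str]  # group ids in the ranking used for lettering


def duncan_mrt(groups: list[GroupSummary], alpha: float = 0.05,
               mse: float | None = None, df_within: int | None = None,
               letter_order: str = "descending") -> DuncanResult:
    """Duncan's multiple range test with a compact letter display.

    ``mse``/``df_within`` default to the pooled values from the same
    summaries.  Unequal group sizes use the harmonic mean n (Kramer).
    ``letter_order`` fixes which end of the ranking receives the letter
    "a": "descending" labels the largest mean first (the convention used
    for quality scores), "ascending" the smallest.
    """
    if mse is None or df_within is None:
        a = anova_oneway(groups)
        mse = a.mse if mse is None else mse
        df_within = a.df_within if df_within is None else df_within
    k = len(groups)
    n_h = k / np.sum([1.0 / g.n for g in groups])  # harmonic mean n
    ranked = sorted(groups, key=lambda g: g.mean,
                    reverse=(letter_order == "descending"))
    means = [g.mean for g in ranked]

    # Stepwise range procedure, largest spans first.  A span found
    # homogeneous protects every stretch nested inside it.
    homogeneous: list[tuple[int, int]] = []
    different: dict[frozenset, bool] = {}
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            pair = frozenset({ranked[i].group_id, ranked[j].group_id})
            if any(a <= i and j <= b for a, b in homogeneous):
                different[pair] = False
                continue
            if mse == 0.0:
                diff = means[i] != means[j]
            else:
                crit = duncan_critical_range(alpha, span, df_within, n_h, mse)
                diff = abs(means[i] - means[j]) > crit
            different[pair] = diff
            if not diff:
                homogeneous.append((i, j))

    # Compact letter display from the maximal homogeneous stretches.
    ranges = [(a, b) for a, b in homogeneous
              if not any((c <= a and b <= d) and (c, d) != (a, b)
                         for c, d in homogeneous)]
    covered = {i for a, b in ranges for i in range(a, b + 1)}
    for i in range(k):
        if i not in covered:
            ranges.append((i, i))
    ranges.sort()
    letters = {g.group_id: "" for g in ranked}
    for idx, (a, b) in enumerate(ranges):
        lab = chr(ord("a") + idx)
        for i in range(a, b + 1):
            letters[ranked[i].group_id] += lab
    return DuncanResult(letters=letters, different=different,
                        order=[g.group_id for g in ranked])


def per_variable_tests(data: CompoundTable | ReplicateMatrix,
                       design: GroupDesign | None = None,
                       alpha: float | None = None,
                       letter_order: str = "descending") -> pd.DataFrame:
    """ANOVA p-value and Duncan letters for every compound / variable.

    Accepts either a summary table (mean, sd, n per group) or a replicate
    matrix.  Variables observed in fewer than two groups are marked
    untestable; variables missing in exactly one group are tested across
    the remaining groups and flagged ``partial``.
    """
    if design is None:
        if isinstance(data, CompoundTable):
            design = GroupDesign(tuple(data.group_ids))
        else:
            design = GroupDesign(tuple(data.groups))
    if alpha is None:
        alpha = design.alpha

    def summary_iter():
        if isinstance(data, CompoundTable):
            for r in data.records:
                gs = [GroupSummary(g, r.per_group[g].mean, r.per_group[g].sd,
                                   r.per_group[g].n)
                      for g in design.group_ids if r.per_group[g].detected]
                yield r.compound_id, gs
        else:
            labels = np.asarray(data.group_labels)
            for var in data.variable_ids:
                x = data.values[var].to_numpy(dtype=float)
                gs = []
                for g in design.group_ids:
                    xi = x[labels == g]
                    xi = xi[~np.isnan(xi)]
                    if len(xi) >= 2:
                        gs.append(GroupSummary(g, float(xi.mean()),
                                               float(xi.std(ddof=1)), len(xi)))
                yield var, gs

    rows = []
    for var, gs in summary_iter():
        row: dict = {"variable": var,
                     "n_groups_tested": len(gs),
                     "partial": 2 <= len(gs) < len(design.group_ids),
                     "untestable": len(gs) < 2}
        for g in design.group_ids:
            row[f"letter_{g}"] = ""
        if len(gs) >= 2:
            a = anova_oneway(gs)
            row.update(f_stat=a.f_stat, p_value=a.p_value,
                       degenerate=a.degenerate)
            if a.degenerate and math.isnan(a.p_value):
                for g in gs:
                    row[f"letter_{g.group_id}"] = "a"
            else:
                d = duncan_mrt(gs, alpha=alpha, mse=a.mse,
                               df_within=a.df_within,
                               letter_order=letter_order)
                for gid, lab in d.letters.items():
                    row[f"letter_{gid}"] = lab
        else:
            row.update(f_stat=math.nan, p_value=math.nan, degenerate=False)
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
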