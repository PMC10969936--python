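"""Kovats retention indices and internal-standard semi-quantification.

The Kovats retention index places an analyte on a dimensionless scale
anchored to n-alkanes: the alkane with k carbons has RI = 100k, and an
analyte eluting between the C_n and C_{n+1} alkanes is interpolated linearly
in retention time,

    RI = 100 n + 100 (RT_x - RT_n) / (RT_{n+1} - RT_n).

No extrapolation is performed by default: the formula is defined only for
analytes bracketed by the ladder.

Semi-quantification divides the analyte peak area by the internal-standard
area and scales by the amount of standard added per mass of sample, with a
configurable response factor (1.0 = pure IS-relative semi-quantification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CompoundTable


class LadderError(ValueError):
    pass


class OutOfLadderError(ValueError):
    """Analyte retention time falls outside the alkane ladder span."""


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon count, retention time) pairs.

    Carbon numbers and retention times must both be strictly increasing.
    Bracketing an analyte requires consecutive carbon numbers n, n+1 in the
    ladder; gaps are allowed elsewhere.
    """

    carbons: tuple[int, ...]
    rts: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.carbons)
        t = np.asarray(self.rts, dtype=float)
        if len(c) != len(t) or len(c) < 2:
            raise LadderError("ladder needs >= 2 (carbon, rt) pairs")
        if not (np.diff(c) > 0).all():
            raise LadderError("carbon numbers must be strictly increasing")
        if not (np.diff(t) > 0).all():
            raise LadderError("retention times must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "AlkaneLadder":
        df = pd.read_csv(path)
        return cls(tuple(int(x) for x in df["carbon_n"]),
                   tuple(float(x) for x in df["rt_min"]))

    def span(self) -> tuple[float, float]:
        return self.rts[0], self.rts[-1]


def kovats_ri(rt_x: float, ladder: AlkaneLadder,
              extrapolate: bool = False) -> float:
    """Kovats retention index of an analyte at retention time ``rt_x``.

    Raises :class:`OutOfLadderError` outside the ladder span unless
    ``extrapolate=True``, in which case the first/last bracket is extended
    linearly.
    """
    if rt_x <= 0:
        raise ValueError("rt_x must be positive")
    c = np.asarray(ladder.carbons)
    t = np.asarray(ladder.rts, dtype=float)
    if not extrapolate and not (t[0] <= rt_x <= t[-1]):
        raise OutOfLadderError(
            f"rt {rt_x} outside ladder span [{t[0]}, {t[-1]}]")
    i = int(np.clip(np.searchsorted(t, rt_x, side="right") - 1, 0, len(t) - 2))
    n, n_next = c[i], c[i + 1]
    if n_next != n + 1:
        raise LadderError(
            f"bracketing requires consecutive alkanes; have C{n} and C{n_next}")
    return 100.0 * n + 100.0 * (rt_x - t[i]) / (t[i + 1] - t[i])


@dataclass(frozen=True)
class QuantSpec:
    """Internal-standard quantification parameters.

    is_peak_area   : chromatographic area of the internal-standard peak
    is_amount_ug   : micrograms of internal standard added to the extraction
    sample_mass_kg : mass of sample (tea) extracted, kg
    response_factor: analyte/IS response ratio; 1.0 for semi-quantification
    """

    is_peak_area: float
    is_amount_ug: float
    sample_mass_kg: float
    response_factor: float = 1.0

    def __post_init__(self):
        for name in ("is_peak_area", "is_amount_ug", "sample_mass_kg",
                     "response_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def quantify_by_internal_standard(peak_area: float,
                                  spec: QuantSpec) -> float:
    """Concentration in ug/kg from a peak area, relative to the IS peak."""
    if peak_area < 0:
        raise ValueError("peak_area must be >= 0")
    return (peak_area / spec.is_peak_area) * spec.is_amount_ug \
        / spec.sample_mass_kg / spec.response_factor


def ri_match_report(table: CompoundTable, tolerance: float = 20.0
                    ) -> pd.DataFrame:
    """Compare calculated vs literature retention indices per compound.

    Rows lacking a literature RI are skipped.  Returns a frame with the
    absolute deviation and a ``flagged`` column for deviations exceeding
    ``tolerance`` RI units.
    """
    rows = []
    for r in table.records:
        if r.ri_cal is None or r.ri_lit is None:
            continue
        delta = abs(r.ri_cal - r.ri_lit)
        rows.append({"compound_id": r.compound_id, "name": r.name,
                     "ri_cal": r.ri_cal, "ri_lit": r.ri_lit,
                     "delta": delta, "flagged": delta > tolerance})
    return pd.DataFrame(rows,
                        columns=["compound_id", "name", "ri_cal", "ri_lit",
                                 "delta", "flagged"])
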