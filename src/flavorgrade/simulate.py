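"""Replicate-level data simulation with the structure the analysis assumes.

The published quantification tables report only per-grade mean ± sd over
triplicates; the raw replicate matrices are not deposited.  This module
generates replicate-level datasets that honour a template table's group
means, standard deviations and detection (n.d.) patterns so every
downstream stage — ANOVA/Duncan, PLS-DA, HCA — can be exercised and
validated end to end.

Design points:

* concentrations are non-negative: the default noise model is a normal
  truncated at zero (printed SDs are small relative to means, so the
  truncation bias is negligible); a moment-matched lognormal is available
  for stress testing;
* n.d. cells are exactly 0 in every replicate;
* one global seed expands to independent per-compound substreams keyed by
  compound id, so adding or removing a compound never perturbs the draws
  of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import CompoundTable, ReplicateMatrix


@dataclass(frozen=True)
class SensorSpec:
    """Synthetic e-nose / e-tongue panel: per-group mean response vectors.

    ``effect_size`` scales the between-group separation of the mean
    vectors relative to the within-group sd; 0 collapses all groups onto
    a common mean (a null panel).
    """

    n_sensors: int = 10
    group_ids: tuple[str, ...] = ("SG", "1G", "2G")
    n_reps: int = 3
    within_sd: float = 1.0
    effect_size: float = 5.0
    group_means: np.ndarray | None = None  # groups x sensors, optional

    def resolved_means(self, rng: np.random.Generator) -> np.ndarray:
        if self.group_means is not None:
            m = np.asarray(self.group_means, dtype=float)
            if m.shape != (len(self.group_ids), self.n_sensors):
                raise ValueError("group_means must be groups x sensors")
            return m
        base = rng.normal(0.0, 1.0, self.n_sensors)
        directions = rng.normal(0.0, 1.0,
                                (len(self.group_ids), self.n_sensors))
        directions -= directions.mean(axis=0)
        return base + self.effect_size * self.within_sd * directions


@dataclass(frozen=True)
class SimulationSpec:
    template: CompoundTable
    n_reps: int = 3
    seed: int = 0
    noise_model: str = "truncnorm"  # or "lognormal"

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 for variance-based stages")
        if self.noise_model not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _compound_rng(seed: int, compound_id: str) -> np.random.Generator:
    key = zlib.crc32(str(compound_id).encode())
    return np.random.default_rng(np.random.SeedSequence((seed, key)))


def _draw(rng, mean: float, sd: float, size: int, model: str) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    if model == "truncnorm":
        a = (0.0 - mean) / sd
        return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                 size=size, random_state=rng)
    # lognormal matched to the target mean and sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_grade_dataset(spec: SimulationSpec) -> ReplicateMatrix:
    """Draw replicate concentrations per (compound, group) from the template.

    Returns a samples x compounds matrix; samples are ordered group-major
    (``<group>_r<rep>``).  Undetected cells are exactly 0 in all replicates.
    """
    t = spec.template
    sample_ids = [f"{g}_r{i + 1}" for g in t.group_ids
                  for i in range(spec.n_reps)]
    labels = [g for g in t.group_ids for _ in range(spec.n_reps)]
    data = np.zeros((len(sample_ids), len(t.records)))
    for j, r in enumerate(t.records):
        rng = _compound_rng(spec.seed, r.compound_id)
        for gi, g in enumerate(t.group_ids):
            st = r.per_group[g]
            block = slice(gi * spec.n_reps, (gi + 1) * spec.n_reps)
            if st.detected:
                if st.sd < 0:
                    raise ValueError(f"negative sd for {r.compound_id}/{g}")
                data[block, j] = _draw(rng, st.mean, st.sd, spec.n_reps,
                                       spec.noise_model)
    values = pd.DataFrame(data, index=sample_ids,
                          columns=[r.compound_id for r in t.records])
    return ReplicateMatrix(values=values, group_labels=pd.Series(labels))


def simulate_alkane_ladder(c_min: int = 8, c_max: int = 32,
                           rt_model=None, seed: int | None = None,
                           analyte_ris: list[float] | None = None):
    """Build an n-alkane retention ladder, optionally with planted analytes.

    ``rt_model`` maps carbon number to retention time (callable or dict);
    the default is a mildly convex, strictly increasing curve.  When
    ``analyte_ris`` is given, analyte retention times are placed by exact
    inverse interpolation so that the true retention indices are known —
    a plant-and-recover oracle for the RI computation.

    Returns ``(ladder, analyte_rts)`` where ladder is a list of
    ``(carbon, rt)`` pairs.
    """
    from .retention import AlkaneLadder, LadderError

    if c_min >= c_max:
        raise ValueError("c_min must be < c_max")
    carbons = list(range(c_min, c_max + 1))
    if rt_model is None:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(0.0, 0.2, len(carbons)) if seed is not None \
            else np.zeros(len(carbons))
        rts = [2.0 * n + 0.01 * n ** 2 + j for n, j in zip(carbons, jitter)]
    elif callable(rt_model):
        rts = [float(rt_model(n)) for n in carbons]
    else:
        rts = [float(rt_model[n]) for n in carbons]
    if not all(b > a for a, b in zip(rts, rts[1:])):
        raise LadderError("rt model is not strictly increasing in carbons")
    ladder = AlkaneLadder(tuple(carbons), tuple(rts))

    analyte_rts = None
    if analyte_ris is not None:
        analyte_rts = []
        for ri in analyte_ris:
            n = int(ri // 100)
            if not (c_min <= n < c_max):
                raise ValueError(f"true RI {ri} not bracketed by ladder")
            frac = (ri - 100 * n) / 100.0
            i = carbons.index(n)
            analyte_rts.append(rts[i] + frac * (rts[i + 1] - rts[i]))
    return ladder, analyte_rts


def simulate_sensor_panel(spec: SensorSpec, seed: int = 0) -> ReplicateMatrix:
    """Samples x sensors response matrix with controllable group separation."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5E25)))
    means = spec.resolved_means(rng)
    if spec.effect_size > 0 and spec.group_means is None:
        pass  # distinctness guaranteed by construction
    elif spec.group_means is not None and spec.effect_size > 0:
        if any(np.allclose(means[i], means[j])
               for i in range(len(means)) for j in range(i)):
            raise ValueError("group mean vectors must be distinct "
                             "when separation is requested")
    rows, labels, ids = [], [], []
    for gi, g in enumerate(spec.group_ids):
        noise = rng.normal(0.0, spec.within_sd,
                           (spec.n_reps, spec.n_sensors))
        rows.append(means[gi] + noise)
        labels += [g] * spec.n_reps
        ids += [f"{g}_r{i + 1}" for i in range(spec.n_reps)]
    values = pd.DataFrame(np.vstack(rows), index=ids,
                          columns=[f"S{i + 1}" for i in range(spec.n_sensors)])
    return ReplicateMatrix(values=values, group_labels=pd.Series(labels))
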