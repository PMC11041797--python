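"""Random-effects pooling of per-protocol effect sizes.

DerSimonian-Laird moment estimation: with study effects d_i and sampling
variances se_i^2, fixed weights w_i = 1/se_i^2 give Cochran's
Q = sum w_i (d_i - d_fixed)^2; the between-protocol variance is
tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)), random-effects
weights are w*_i = 1/(se_i^2 + tau^2), and the pooled effect, its standard
error, the normal z test, and the I^2 heterogeneity percentage follow.
Multiplicity is controlled by Bonferroni over the measure family.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MEASURES, CohortTable, PATIENT_GROUPS
from .effects import LI_MEASURES, EffectSize, per_protocol_effects

__all__ = ["MetaSummary", "dersimonian_laird", "bonferroni", "meta_table"]

ALPHA = 0.05


@dataclasses.dataclass
class MetaSummary:
    measure: str
    diagnosis: str
    k: int
    d_pooled: float
    se_pooled: float
    z_stat: float
    p_value: float
    q_stat: float
    tau2: float
    i2: float
    single_study: bool = False
    p_bonferroni_significant: bool | None = None
    p_uncorrected_significant: bool | None = None


def dersimonian_laird(
    effects: Sequence[tuple[float, float]] | Sequence[EffectSize],
    measure: str = "",
    diagnosis: str = "",
) -> MetaSummary:
    """Pool (d, se) study pairs with the DerSimonian-Laird estimator.

    ``effects`` may be (d, se) tuples or :class:`EffectSize` records.
    With a single study the pooled estimate is that study, tau^2 = I^2 = 0,
    and ``single_study`` is flagged.
    """
    if len(effects) == 0:
        raise ValueError("need at least one study to pool")
    if isinstance(effects[0], EffectSize):
        d = np.array([e.d for e in effects])
        se = np.array([e.se_d for e in effects])
    else:
        d = np.array([e[0] for e in effects], dtype=float)
        se = np.array([e[1] for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    k = len(d)
    w = 1.0 / se**2
    d_fixed = float(np.sum(w * d) / np.sum(w))
    q = float(np.sum(w * (d - d_fixed) ** 2))
    if k == 1:
        tau2 = 0.0
        i2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
        i2 = 0.0 if q == 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    w_star = 1.0 / (se**2 + tau2)
    d_pooled = float(np.sum(w_star * d) / np.sum(w_star))
    se_pooled = float(np.sum(w_star) ** -0.5)
    z = d_pooled / se_pooled
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaSummary(
        measure=measure,
        diagnosis=diagnosis,
        k=k,
        d_pooled=d_pooled,
        se_pooled=se_pooled,
        z_stat=float(z),
        p_value=p,
        q_stat=q,
        tau2=float(tau2),
        i2=float(i2),
        single_study=(k == 1),
    )


def bonferroni(p_values: Iterable[float], m: int) -> tuple[list[bool], list[bool]]:
    """Two-sided Bonferroni flags at family size ``m`` and alpha = 0.05.

    Returns (corrected_significant, uncorrected_significant) boolean lists.
    """
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError("family size m must be >= number of tests")
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    corrected = [p < ALPHA / m for p in p_values]
    uncorrected = [p < ALPHA for p in p_values]
    return corrected, uncorrected


def meta_table(
    cohort: CohortTable,
    diagnoses: Sequence[str] = PATIENT_GROUPS,
    measures: str = "volumes",
    min_group_n: int = 2,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Pooled summary per diagnosis x measure (forest-plot top rows).

    The Bonferroni family defaults to the number of measures per diagnosis:
    17 for volumes (16 regions + ICV), 8 for laterality indices. Diagnoses
    with no eligible protocol are omitted with a warning.
    """
    names = list(MEASURES) if measures == "volumes" else list(LI_MEASURES)
    m = bonferroni_m if bonferroni_m is not None else len(names)
    rows: list[dict] = []
    for diagnosis in diagnoses:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            effects = per_protocol_effects(cohort, diagnosis, measures, min_group_n)
        if not effects:
            warnings.warn(f"no eligible protocol for {diagnosis}; omitted", UserWarning)
            continue
        by_measure: dict[str, list[EffectSize]] = {}
        for e in effects:
            by_measure.setdefault(e.measure, []).append(e)
        summaries = [
            dersimonian_laird(by_measure[name], measure=name, diagnosis=diagnosis)
            for name in names
            if name in by_measure
        ]
        corrected, uncorrected = bonferroni([s.p_value for s in summaries], m)
        for s, c, u in zip(summaries, corrected, uncorrected):
            s.p_bonferroni_significant = c
            s.p_uncorrected_significant = u
            rows.append(dataclasses.asdict(s))
    table = pd.DataFrame(rows)
    if len(table):
        table.attrs["bonferroni_m"] = m
    return table
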