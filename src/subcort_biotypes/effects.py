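"""Per-protocol covariate-adjusted group differences and effect sizes.

Within each protocol, a patient-vs-control difference in a measure is
estimated by ordinary least squares of the measure on an intercept, a case
indicator, and nuisance covariates (sex, age, ICV for regional volumes;
sex and age only for ICV itself and for laterality indices). The case
coefficient's t statistic is converted to a Cohen's d on the pooled-SD scale,

    d = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df)),
    se(d) = sqrt((n1 + n2)/(n1 * n2) + d^2 / (2 * (n1 + n2 - 2))),

which folds the covariate adjustment into the standardized difference. The
laterality index of a structure is (left - right) / (left + right); positive
values are leftward.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cohort import MEASURES, REGION_PAIRS, STRUCTURES, CohortTable

__all__ = [
    "AdjustedDifference",
    "EffectSize",
    "SingularDesignError",
    "DegenerateFitWarning",
    "fit_adjusted_group_difference",
    "cohens_d",
    "laterality_index",
    "li_columns",
    "per_protocol_effects",
]

LI_MEASURES: tuple[str, ...] = tuple(f"LI-{s}" for s in STRUCTURES)


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


class DegenerateFitWarning(UserWarning):
    """Residual variance is (numerically) zero; t statistics are unstable."""


@dataclasses.dataclass
class AdjustedDifference:
    measure: str
    protocol_id: str
    diagnosis: str
    beta: float
    t_stat: float
    df: int
    n_case: int
    n_control: int


@dataclasses.dataclass
class EffectSize:
    measure: str
    protocol_id: str
    diagnosis: str
    d: float
    se_d: float
    n_case: int
    n_control: int


def fit_adjusted_group_difference(
    y: np.ndarray,
    is_case: np.ndarray,
    covariates: np.ndarray | None = None,
    measure: str = "",
    protocol_id: str = "",
    diagnosis: str = "",
) -> AdjustedDifference:
    """OLS of ``y`` on intercept + case indicator + covariates.

    Returns the case coefficient, its t statistic and the residual degrees
    of freedom. Raises :class:`SingularDesignError` on a rank-deficient
    design; warns :class:`DegenerateFitWarning` when the residual variance
    vanishes (t is then reported as +/-inf, or 0 for a zero coefficient).
    """
    y = np.asarray(y, dtype=float)
    is_case = np.asarray(is_case, dtype=float)
    n = len(y)
    cols = [np.ones(n), is_case]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n:
            cov = cov.T
        cols.extend(list(cov))
    X = np.column_stack(cols)
    p = X.shape[1]
    n_case = int(is_case.sum())
    n_control = int(n - n_case)
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise SingularDesignError(
            f"design matrix rank {rank} < {p} columns for measure {measure!r}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss <= 1e-12 * tss or tss == 0.0:
        warnings.warn(
            f"degenerate fit (zero residual variance) for measure {measure!r}",
            DegenerateFitWarning,
            stacklevel=2,
        )
        t = 0.0 if np.isclose(beta[1], 0.0) else float(np.sign(beta[1]) * np.inf)
    else:
        se = np.sqrt(rss / df * xtx_inv[1, 1])
        t = float(beta[1] / se)
    return AdjustedDifference(
        measure=measure,
        protocol_id=protocol_id,
        diagnosis=diagnosis,
        beta=float(beta[1]),
        t_stat=t,
        df=df,
        n_case=n_case,
        n_control=n_control,
    )


def cohens_d(adj: AdjustedDifference) -> EffectSize:
    """Convert an adjusted difference into Cohen's d with standard error."""
    if adj.df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    n1, n2 = adj.n_case, adj.n_control
    d = adj.t_stat * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(adj.df))
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2 - 2)))
    return EffectSize(
        measure=adj.measure,
        protocol_id=adj.protocol_id,
        diagnosis=adj.diagnosis,
        d=float(d),
        se_d=float(se_d),
        n_case=n1,
        n_control=n2,
    )


def laterality_index(left, right):
    """Hemispheric dominance ratio (L - R) / (L + R), in [-1, 1].

    Accepts scalars or arrays; positive values indicate leftward dominance.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("hemisphere volumes must be non-negative")
    total = left + right
    if np.any(total == 0):
        raise ValueError("laterality index undefined: left + right = 0")
    li = (left - right) / total
    if li.ndim == 0:
        return float(li)
    return li


def li_columns(cohort: CohortTable) -> pd.DataFrame:
    """Per-subject laterality indices for the 8 structures."""
    out = pd.DataFrame(index=cohort.df.index)
    for (left, right), name in zip(REGION_PAIRS, LI_MEASURES):
        out[name] = laterality_index(cohort.df[left].to_numpy(), cohort.df[right].to_numpy())
    return out


def _measure_frame(cohort: CohortTable, measures: str) -> tuple[pd.DataFrame, list[str]]:
    if measures == "volumes":
        return cohort.df[list(MEASURES)], list(MEASURES)
    if measures == "li":
        li = li_columns(cohort)
        return li, list(LI_MEASURES)
    raise ValueError(f"unknown measure family {measures!r}; use 'volumes' or 'li'")


def per_protocol_effects(
    cohort: CohortTable,
    diagnosis: str,
    measures: str = "volumes",
    min_group_n: int = 2,
) -> list[EffectSize]:
    """One :class:`EffectSize` per (protocol, measure) for one diagnosis.

    Protocols with fewer than ``min_group_n`` cases or controls are skipped
    (the published per-protocol tables have such gaps). Laterality indices
    are computed per subject first and modelled with sex and age only; the
    ICV covariate is likewise dropped when the outcome is ICV itself.
    """
    if diagnosis == "HC":
        raise ValueError("diagnosis must be a patient group, not 'HC'")
    values, names = _measure_frame(cohort, measures)
    df = cohort.df
    results: list[EffectSize] = []
    for pid in cohort.protocols():
        in_protocol = (df["protocol_id"] == pid).to_numpy()
        case_mask = in_protocol & (df["diagnosis"] == diagnosis).to_numpy()
        hc_mask = in_protocol & (df["diagnosis"] == "HC").to_numpy()
        if case_mask.sum() < min_group_n or hc_mask.sum() < min_group_n:
            continue
        keep = case_mask | hc_mask
        is_case = case_mask[keep].astype(float)
        sex = df.loc[keep, "sex"].to_numpy()
        age = df.loc[keep, "age"].to_numpy()
        icv = df.loc[keep, "ICV"].to_numpy()
        for name in names:
            y = values.loc[keep, name].to_numpy()
            if measures == "li" or name == "ICV":
                cov = np.column_stack([sex, age])
            else:
                cov = np.column_stack([sex, age, icv])
            adj = fit_adjusted_group_difference(
                y, is_case, cov, measure=name, protocol_id=pid, diagnosis=diagnosis
            )
            results.append(cohens_d(adj))
    if not results:
        warnings.warn(
            f"no protocol meets the minimum group size for {diagnosis}", UserWarning
        )
    return results
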