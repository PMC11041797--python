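"""Healthy-control-referenced normative z-scoring, per protocol.

For each protocol and each of the 16 regional volumes, an OLS model
(intercept + sex + age + ICV) is fitted on that protocol's healthy controls
only; every subject of the protocol (patients and controls alike) is then
scored as

    z = (observed - predicted) / residual SD,

with the residual SD computed on n_hc - 4 degrees of freedom (the fitted
model's df). By the least-squares residual identity the controls' z-columns
have mean exactly 0 within each protocol; their sample SD is
sqrt((n_hc - 4) / (n_hc - 1)) under the n-1 convention.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .cohort import REGIONS, CohortTable

__all__ = [
    "NormativeModel",
    "ProtocolUnusableError",
    "fit_normative_model",
    "fit_all_normative_models",
    "zscore_cohort",
    "save_models",
    "load_models",
]

_PREDICTORS = ("intercept", "sex", "age", "ICV")


class ProtocolUnusableError(ValueError):
    """Too few healthy controls (or a degenerate design) to reference against."""


@dataclasses.dataclass
class NormativeModel:
    """Per-protocol HC regression coefficients and residual SDs."""

    protocol_id: str
    n_hc: int
    coefficients: dict[str, np.ndarray]  # region -> (intercept, sex, age, ICV)
    residual_sd: dict[str, float]
    degenerate_regions: list[str] = dataclasses.field(default_factory=list)

    def predict(self, region: str, sex, age, icv) -> np.ndarray:
        b = self.coefficients[region]
        return b[0] + b[1] * np.asarray(sex) + b[2] * np.asarray(age) + b[3] * np.asarray(icv)


def fit_normative_model(
    cohort: CohortTable, protocol_id: str, min_hc: int = 10
) -> NormativeModel:
    """Fit the 16 per-region HC reference regressions for one protocol.

    Raises :class:`ProtocolUnusableError` when the protocol has fewer than
    ``min_hc`` controls or a rank-deficient HC design. Regions with zero
    residual variance are flagged as degenerate (their z-scores would be
    unusable) but retained.
    """
    df = cohort.df
    hc = df[(df["protocol_id"] == protocol_id) & (df["diagnosis"] == "HC")]
    n_hc = len(hc)
    if n_hc < min_hc:
        raise ProtocolUnusableError(
            f"protocol {protocol_id!r} has {n_hc} HCs; minimum is {min_hc}"
        )
    X = np.column_stack(
        [np.ones(n_hc), hc["sex"].to_numpy(), hc["age"].to_numpy(), hc["ICV"].to_numpy()]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ProtocolUnusableError(
            f"rank-deficient HC design for protocol {protocol_id!r}"
        )
    df_resid = n_hc - X.shape[1]
    if df_resid <= 0:
        raise ProtocolUnusableError(
            f"protocol {protocol_id!r}: no residual df with {n_hc} HCs"
        )
    coefficients: dict[str, np.ndarray] = {}
    residual_sd: dict[str, float] = {}
    degenerate: list[str] = []
    for region in REGIONS:
        y = hc[region].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = float(np.sqrt(resid @ resid / df_resid))
        coefficients[region] = beta
        residual_sd[region] = sd
        if sd <= np.sqrt(np.finfo(float).eps) * max(1.0, float(np.abs(y).max())):
            degenerate.append(region)
    if degenerate:
        warnings.warn(
            f"protocol {protocol_id!r}: zero residual variance in {degenerate}",
            UserWarning,
        )
    return NormativeModel(
        protocol_id=protocol_id,
        n_hc=n_hc,
        coefficients=coefficients,
        residual_sd=residual_sd,
        degenerate_regions=degenerate,
    )


def fit_all_normative_models(
    cohort: CohortTable, min_hc: int = 10
) -> dict[str, NormativeModel]:
    """Fit models for every protocol; unusable protocols are skipped with a
    warning (their subjects will be excluded from z-scoring)."""
    models: dict[str, NormativeModel] = {}
    for pid in cohort.protocols():
        try:
            models[pid] = fit_normative_model(cohort, pid, min_hc=min_hc)
        except ProtocolUnusableError as err:
            warnings.warn(str(err), UserWarning)
    return models


def zscore_cohort(
    cohort: CohortTable, models: dict[str, NormativeModel]
) -> pd.DataFrame:
    """Standardize all subjects against their own protocol's HC model.

    Returns a frame with ``subject_id``, ``protocol_id``, ``diagnosis`` and
    the 16 z-columns in region order. Subjects whose protocol has no model
    are excluded with a warning.
    """
    df = cohort.df
    has_model = df["protocol_id"].isin(models.keys())
    if not has_model.all():
        dropped = sorted(df.loc[~has_model, "protocol_id"].unique())
        warnings.warn(
            f"excluding subjects of protocols without a normative model: {dropped}",
            UserWarning,
        )
    df = df[has_model]
    blocks: list[pd.DataFrame] = []
    for pid, sub in df.groupby("protocol_id", sort=False):
        model = models[pid]
        block = sub[["subject_id", "protocol_id", "diagnosis"]].copy()
        sex, age, icv = (sub[c].to_numpy() for c in ("sex", "age", "ICV"))
        for region in REGIONS:
            pred = model.predict(region, sex, age, icv)
            sd = model.residual_sd[region]
            block[region] = (sub[region].to_numpy() - pred) / sd if sd > 0 else np.nan
        blocks.append(block)
    out = pd.concat(blocks, ignore_index=True)
    # restore cohort row order
    order = pd.Index(cohort.df.loc[has_model, "subject_id"])
    return out.set_index("subject_id").loc[order].reset_index()


def save_models(models: dict[str, NormativeModel], path) -> None:
    payload = {
        pid: {
            "n_hc": m.n_hc,
            "coefficients": {r: list(map(float, b)) for r, b in m.coefficients.items()},
            "residual_sd": m.residual_sd,
            "degenerate_regions": m.degenerate_regions,
        }
        for pid, m in models.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_models(path) -> dict[str, NormativeModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        pid: NormativeModel(
            protocol_id=pid,
            n_hc=entry["n_hc"],
            coefficients={r: np.asarray(b) for r, b in entry["coefficients"].items()},
            residual_sd={r: float(v) for r, v in entry["residual_sd"].items()},
            degenerate_regions=list(entry.get("degenerate_regions", [])),
        )
        for pid, entry in payload.items()
    }
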