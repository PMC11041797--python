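"""Discriminant classification of biotypes, medication contrasts, and the
end-to-end pipeline.

Classical linear discriminant analysis (class means, pooled within-class
covariance, empirical priors) separates biotypes in z-score space; its
leave-one-out cross-validated accuracy measures how reliably a new subject's
normative profile maps back to a biotype. Medication-dose differences across
biotypes are assessed with Kruskal-Wallis rank tests followed by Dunn's
pairwise post hoc with Bonferroni correction. ``run_pipeline`` binds all
stages in analysis order: per-protocol effects -> random-effects pooling ->
normative z-scoring -> X-means -> singleton removal -> association tests ->
functionally-normal merging -> LDA -> medication contrasts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DOSE_COLUMNS, FUNCTIONING_SCALES, REGIONS, CohortTable
from .clustering import (
    UNASSIGNED,
    BiotypeModel,
    ClusterSolution,
    FunctioningSummary,
    cluster_diagnosis_association,
    drop_singletons,
    functioning_association,
    merge_functionally_normal,
    xmeans,
)
from .meta import meta_table
from .normative import fit_all_normative_models, zscore_cohort
from .simulate import HC_FUNCTIONING_REFERENCE

__all__ = [
    "DiscriminantModel",
    "PipelineConfig",
    "PipelineReport",
    "lda_fit",
    "lda_predict",
    "lda_loocv_accuracy",
    "kruskal_wallis",
    "dunn_posthoc",
    "run_pipeline",
]


@dataclasses.dataclass
class DiscriminantModel:
    classes: list
    means: np.ndarray            # k x dims
    covariance: np.ndarray       # pooled within-class, dims x dims
    priors: np.ndarray
    ridged: bool = False


def _pooled_scatter(z: np.ndarray, labels: np.ndarray, classes: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = np.stack([z[labels == c].mean(axis=0) for c in classes])
    scatter = np.zeros((z.shape[1], z.shape[1]))
    for i, c in enumerate(classes):
        resid = z[labels == c] - means[i]
        scatter += resid.T @ resid
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    return means, scatter, counts


def lda_fit(
    z: np.ndarray,
    labels: Sequence,
    priors: str = "empirical",
    ridge: float | None = None,
) -> DiscriminantModel:
    """Classical LDA: class means, pooled covariance, class priors.

    ``priors`` is ``"empirical"`` (class frequencies) or ``"uniform"``. If
    the pooled covariance is singular, a ridge of eps * trace/dim is added
    and flagged (``ridge`` overrides eps; default 1e-6).
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    means, scatter, counts = _pooled_scatter(z, labels, classes)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    cov = scatter / (len(z) - len(classes))
    ridged = False
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eps = ridge if ridge is not None else 1e-6
        cov = cov + eps * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        ridged = True
        warnings.warn("singular pooled covariance; ridge added", UserWarning)
        np.linalg.cholesky(cov)  # still singular -> raise
    if priors == "empirical":
        pri = counts / counts.sum()
    elif priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError("priors must be 'empirical' or 'uniform'")
    return DiscriminantModel(classes=classes, means=means, covariance=cov,
                             priors=pri, ridged=ridged)


def _discriminant_scores(model: DiscriminantModel, z: np.ndarray) -> np.ndarray:
    solve = np.linalg.solve(model.covariance, model.means.T)  # dims x k
    linear = z @ solve
    const = -0.5 * np.sum(model.means.T * solve, axis=0) + np.log(model.priors)
    return linear + const


def lda_predict(model: DiscriminantModel, z: np.ndarray) -> np.ndarray:
    """Assign each row to the class with the largest discriminant score."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    scores = _discriminant_scores(model, z)
    return np.asarray(model.classes, dtype=object)[np.argmax(scores, axis=1)]


def lda_loocv_accuracy(z: np.ndarray, labels: Sequence, priors: str = "empirical") -> float:
    """Leave-one-out accuracy of LDA reclassification.

    Each subject is predicted from a model fitted on the remaining n-1; the
    per-fold model is obtained by downdating the class mean and the pooled
    scatter (rank-one), so the loop is exact and fast. A fold in which the
    held-out subject's class vanishes is predicted from the remaining
    classes (flagged via warning).
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    class_index = {c: i for i, c in enumerate(classes)}
    idx = np.array([class_index[l] for l in labels])
    n, dims = z.shape
    k = len(classes)
    means, scatter, counts = _pooled_scatter(z, labels, classes)
    sums = means * counts[:, None]
    vanished = 0
    correct = 0
    for i in range(n):
        c = idx[i]
        nc = counts[c]
        if nc <= 1:
            vanished += 1
            fold_classes = [j for j in range(k) if j != c]
        else:
            fold_classes = list(range(k))
        fold_counts = counts.copy()
        fold_sums = sums.copy()
        fold_counts[c] -= 1
        fold_sums[c] -= z[i]
        # scatter downdate: removing x from class c changes its scatter by
        # -(nc/(nc-1)) (x - mean_c)(x - mean_c)^T
        if nc > 1:
            dev = z[i] - means[c]
            fold_scatter = scatter - (nc / (nc - 1.0)) * np.outer(dev, dev)
        else:
            fold_scatter = scatter
        fold_means = fold_sums[fold_classes] / fold_counts[fold_classes][:, None]
        cov = fold_scatter / max(1.0, (n - 1) - len(fold_classes))
        pri = fold_counts[fold_classes] / fold_counts[fold_classes].sum()
        if priors == "uniform":
            pri = np.full(len(fold_classes), 1.0 / len(fold_classes))
        solve = np.linalg.solve(cov, fold_means.T)
        scores = z[i] @ solve - 0.5 * np.sum(fold_means.T * solve, axis=0) + np.log(pri)
        pred = fold_classes[int(np.argmax(scores))]
        correct += int(pred == c)
    if vanished:
        warnings.warn(
            f"{vanished} folds lost their class entirely; predicted from the rest",
            UserWarning,
        )
    return correct / n


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; chi-squared reference, k-1 df.

    Identical values across all groups give H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    df = len(levels) - 1
    if np.all(values == values[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


def dunn_posthoc(
    values: Sequence[float], groups: Sequence, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-based pairwise post hoc after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values are
    Bonferroni-corrected over the k(k-1)/2 pairs.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = sorted(pd.unique(groups).tolist())
    n_total = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in levels}
    sizes = {g: int((groups == g).sum()) for g in levels}
    m = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            gi, gj = levels[a], levels[b]
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = 0.0 if se == 0 else (mean_ranks[gi] - mean_ranks[gj]) / se
            p_raw = float(2.0 * stats.norm.sf(abs(z)))
            p_adj = min(1.0, p_raw * m) if correction == "bonferroni" else p_raw
            rows.append({"group_i": gi, "group_j": gj, "z": float(z),
                         "p_raw": p_raw, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class PipelineConfig:
    """Stage parameters for :func:`run_pipeline` (all recorded in the report)."""

    min_group_n: int = 2
    min_hc: int = 10
    kmin: int = 1
    kmax: int = 20
    n_init: int = 10
    max_singleton_size: int = 1
    lda_priors: str = "empirical"
    hc_reference: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(HC_FUNCTIONING_REFERENCE)
    )
    functioning_scales: tuple[str, ...] = FUNCTIONING_SCALES


@dataclasses.dataclass
class PipelineReport:
    config: PipelineConfig
    seed: int
    meta_volumes: pd.DataFrame
    meta_li: pd.DataFrame
    cluster_solution: ClusterSolution
    diagnosis_association: object
    functioning_summary: FunctioningSummary | None
    biotype_model: BiotypeModel | None
    biotype_labels: np.ndarray | None
    loocv_accuracy: float | None
    medication_tests: pd.DataFrame | None
    medication_posthoc: pd.DataFrame | None
    zscores: pd.DataFrame

    def n_biotypes(self) -> int | None:
        return None if self.biotype_model is None else len(self.biotype_model.biotype_ids)

    def to_json_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "k_clusters": int(self.cluster_solution.k),
            "dropped_singletons": list(map(int, self.cluster_solution.dropped_singletons)),
            "chi2": float(self.diagnosis_association.chi2),
            "chi2_p": float(self.diagnosis_association.p_value),
            "n_biotypes": self.n_biotypes(),
            "loocv_accuracy": self.loocv_accuracy,
            "meta_volumes": self.meta_volumes.to_dict(orient="records"),
            "meta_li": self.meta_li.to_dict(orient="records"),
        }
        if self.functioning_summary is not None:
            out["anova"] = self.functioning_summary.anova.to_dict(orient="records")
        if self.biotype_model is not None:
            out["cluster_to_biotype"] = {
                str(k): v for k, v in self.biotype_model.cluster_to_biotype.items()
            }
        if self.medication_tests is not None:
            out["medication_tests"] = self.medication_tests.to_dict(orient="records")
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=float)


def run_pipeline(
    cohort: CohortTable, config: PipelineConfig | None = None, seed: int = 0
) -> PipelineReport:
    """Run the full cross-disorder analysis on a cohort.

    Deterministic given (cohort, config, seed). Functioning-dependent stages
    (biotype merging, medication contrasts) are skipped with a warning when
    the cohort carries no functioning or dose columns.
    """
    config = config or PipelineConfig()
    meta_volumes = meta_table(cohort, measures="volumes", min_group_n=config.min_group_n)
    meta_li = meta_table(cohort, measures="li", min_group_n=config.min_group_n)

    models = fit_all_normative_models(cohort, min_hc=config.min_hc)
    if not models:
        raise RuntimeError("normative stage: no usable protocol")
    zmat = zscore_cohort(cohort, models)
    z = zmat[list(REGIONS)].to_numpy()

    solution = xmeans(z, kmin=config.kmin, kmax=config.kmax, seed=seed,
                      n_init=config.n_init)
    solution = drop_singletons(solution, config.max_singleton_size)
    association = cluster_diagnosis_association(
        solution.labels, zmat["diagnosis"].to_numpy()
    )

    functioning_summary = None
    biotype_model = None
    biotype_labels = None
    loocv = None
    med_tests = None
    med_posthoc = None

    scored = cohort.df.set_index("subject_id").loc[zmat["subject_id"]]
    if cohort.has_functioning:
        available = [s for s in config.functioning_scales if s in scored.columns]
        functioning_summary = functioning_association(
            solution.labels, scored[available].reset_index(drop=True), available
        )
        biotype_model = merge_functionally_normal(
            solution, functioning_summary, config.hc_reference, on_missing="exclude"
        )
        biotype_labels = biotype_model.biotype_labels(solution.labels)
        assigned = (solution.labels != UNASSIGNED) & (biotype_labels != "unassigned")
        loocv = lda_loocv_accuracy(
            z[assigned], biotype_labels[assigned], priors=config.lda_priors
        )
        if cohort.has_medications:
            rows = []
            posthoc_frames = []
            for col in DOSE_COLUMNS:
                if col not in scored.columns:
                    continue
                doses = scored[col].to_numpy(dtype=float)
                mask = assigned & ~np.isnan(doses)
                if mask.sum() == 0 or len(pd.unique(biotype_labels[mask])) < 2:
                    continue
                h, dfree, p = kruskal_wallis(doses[mask], biotype_labels[mask])
                rows.append({"drug": col, "H": h, "df": dfree, "p": p})
                ph = dunn_posthoc(doses[mask], biotype_labels[mask])
                ph.insert(0, "drug", col)
                posthoc_frames.append(ph)
            med_tests = pd.DataFrame(rows)
            med_posthoc = (
                pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else None
            )
    else:
        warnings.warn("cohort has no functioning columns; biotype merge skipped",
                      UserWarning)

    return PipelineReport(
        config=config,
        seed=seed,
        meta_volumes=meta_volumes,
        meta_li=meta_li,
        cluster_solution=solution,
        diagnosis_association=association,
        functioning_summary=functioning_summary,
        biotype_model=biotype_model,
        biotype_labels=biotype_labels,
        loocv_accuracy=loocv,
        medication_tests=med_tests,
        medication_posthoc=med_posthoc,
        zscores=zmat,
    )
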