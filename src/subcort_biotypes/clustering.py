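"""X-means clustering of normative z-scores and biotype construction.

The subject-by-16 z-score matrix is clustered with X-means: k-means
(k-means++ initialisation, Lloyd iterations, best of ``n_init`` restarts)
combined with recursive two-way splits that are accepted when they improve a
spherical-Gaussian Bayesian Information Criterion evaluated locally on the
parent cluster's points. Clusters of size one are discarded. Retained
clusters are tested for association with diagnosis (Pearson chi-squared with
adjusted standardized residuals) and with cognitive/social functioning
(per-scale one-way ANOVA plus Games-Howell pairwise post hocs). Finally,
clusters whose mean functioning exceeds the healthy-control mean minus one SD
on every scale are merged into a single functionally normal biotype; the
remaining clusters become impaired biotypes ordered by severity.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FUNCTIONING_SCALES

__all__ = [
    "ClusterSolution",
    "FunctioningSummary",
    "BiotypeModel",
    "DegenerateScoreWarning",
    "kmeans",
    "bic_score",
    "xmeans",
    "drop_singletons",
    "cluster_diagnosis_association",
    "ChiSquareResult",
    "functioning_association",
    "merge_functionally_normal",
]

UNASSIGNED = -1


class DegenerateScoreWarning(UserWarning):
    """Zero pooled variance: the BIC model likelihood is unbounded."""


@dataclasses.dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    bic: float
    dropped_singletons: list[int] = dataclasses.field(default_factory=list)

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels != UNASSIGNED], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(points)
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    closest = np.sum((points - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = closest.sum()
        if total <= 0:
            centroids[j:] = points[rng.integers(n, size=k - j)]
            break
        probs = closest / total
        centroids[j] = points[rng.choice(n, p=probs)]
        closest = np.minimum(closest, np.sum((points - centroids[j]) ** 2, axis=1))
    return centroids


def _assign(points: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = (
        np.sum(points**2, axis=1)[:, None]
        - 2.0 * points @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    labels = np.argmin(d2, axis=1)
    return labels, np.maximum(d2[np.arange(len(points)), labels], 0.0)


def _lloyd(
    points: np.ndarray, centroids: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations from given centroids until the assignment is stable.

    An emptied cluster is re-seeded at the point farthest from its centroid.
    Returns (labels, centroids, within-cluster sum of squared distances).
    """
    centroids = centroids.copy()
    k = len(centroids)
    labels = np.full(len(points), -1)
    for _ in range(max_iter):
        new_labels, closest = _assign(points, centroids)
        for j in range(k):
            mask = new_labels == j
            if mask.any():
                centroids[j] = points[mask].mean(axis=0)
            else:
                far = int(np.argmax(closest))
                centroids[j] = points[far]
                new_labels[far] = j
                closest[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    _, closest = _assign(points, centroids)
    return labels, centroids, float(closest.sum())


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm from k-means++ starts; best of ``n_init`` restarts.

    Returns (labels, centroids, within-cluster sum of squared distances).
    Deterministic given ``seed``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_init):
        result = _lloyd(points, _kmeans_pp_init(points, k, rng), max_iter)
        if best is None or result[2] < best[2]:
            best = result
    return best


def _split_in_two(
    members: np.ndarray, rng: np.random.Generator, n_init: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best candidate 2-way split of one cluster's points, by BIC.

    Candidates are ``n_init`` k-means++ Lloyd runs plus a deterministic start
    seeded at the centroid +/- one SD along the first principal component
    (the dominant elongation is where real substructure lies). Selection is
    by the split criterion itself - the local BIC - rather than inertia,
    because distinct local optima (e.g. an outlier-peeling split vs. a
    balanced geometric cut) can order differently under the two scores.
    """
    candidates = [
        _lloyd(members, _kmeans_pp_init(members, 2, rng)) for _ in range(n_init)
    ]
    center = members.mean(axis=0)
    centered = members - center
    # first right singular vector = principal axis
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0] * (s[0] / np.sqrt(len(members)))
    candidates.append(_lloyd(members, np.stack([center + direction, center - direction])))
    best_bic = -np.inf
    best = candidates[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateScoreWarning)
        for cand in candidates:
            labels, centroids, _ = cand
            score = bic_score(members, labels, centroids)
            if score > best_bic:
                best_bic = score
                best = cand
    return best[0], best[1], best_bic


def bic_score(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Spherical-Gaussian BIC of a hard clustering (larger is better).

    Identical per-dimension variance pooled over clusters (MLE with n - k
    mean parameters subtracted); parameter count p = k*(dims+1) + 1; score is
    log-likelihood - (p/2) log n. Zero pooled variance yields -inf with a
    :class:`DegenerateScoreWarning`.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n, dims = points.shape
    k = len(centroids)
    if n <= k:
        warnings.warn("BIC undefined: n <= k", DegenerateScoreWarning, stacklevel=2)
        return -np.inf
    sq = float(np.sum((points - centroids[labels]) ** 2))
    sigma2 = sq / (dims * (n - k))
    if sigma2 <= 0:
        warnings.warn(
            "degenerate clustering: zero pooled variance", DegenerateScoreWarning,
            stacklevel=2,
        )
        return -np.inf
    sizes = np.bincount(labels, minlength=k).astype(float)
    sizes = sizes[sizes > 0]
    loglik = (
        float(np.sum(sizes * np.log(sizes / n)))
        - 0.5 * n * dims * np.log(2.0 * np.pi * sigma2)
        - 0.5 * dims * (n - k)
    )
    p = k * (dims + 1) + 1
    return loglik - 0.5 * p * np.log(n)


def xmeans(
    points: np.ndarray,
    kmin: int = 1,
    kmax: int = 20,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterSolution:
    """X-means: BIC-guided recursive splitting between ``kmin`` and ``kmax``.

    Starting from a k-means solution at ``kmin``, the algorithm alternates a
    global Lloyd refinement of the current centroids with a structure pass in
    which each cluster is tentatively split in two; a split is kept when the
    local BIC of the two children on the cluster's own points exceeds the
    local BIC of the parent. The alternation repeats until a structure pass
    accepts no split (so at convergence no cluster locally prefers to split)
    or k would exceed ``kmax``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < kmin:
        raise ValueError("fewer points than kmin")
    rng = np.random.default_rng(seed)
    labels, centroids, _ = kmeans(points, kmin, rng, n_init=n_init)
    centroid_list = [c for c in centroids]

    def refine(centroid_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        k = len(centroid_list)
        centroids = np.asarray(centroid_list)
        labels = np.full(len(points), -1)
        for _ in range(300):
            new_labels, closest = _assign(points, centroids)
            for j in range(k):
                mask = new_labels == j
                if mask.any():
                    centroids[j] = points[mask].mean(axis=0)
                else:
                    far = int(np.argmax(closest))
                    centroids[j] = points[far]
                    new_labels[far] = j
                    closest[far] = 0.0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        return labels, centroids

    improved = True
    while improved:
        labels, centroids = refine(centroid_list)
        centroid_list = [c for c in centroids]
        improved = False
        new_centroids: list[np.ndarray] = []
        k_now = len(centroid_list)
        for j, centroid in enumerate(centroid_list):
            members = points[labels == j]
            # need headroom under kmax and enough points for a 2-way split
            if k_now >= kmax or len(members) < 4:
                new_centroids.append(centroid)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateScoreWarning)
                parent_bic = bic_score(members, np.zeros(len(members), dtype=int),
                                       centroid[None, :])
                child_labels, child_centroids, child_bic = _split_in_two(
                    members, rng, n_init
                )
            if child_bic > parent_bic:
                new_centroids.extend([child_centroids[0], child_centroids[1]])
                improved = True
                k_now += 1
            else:
                new_centroids.append(centroid)
        centroid_list = new_centroids

    labels, centroids = refine(centroid_list)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateScoreWarning)
        final_bic = bic_score(points, labels, centroids)
    return ClusterSolution(k=len(centroid_list), labels=labels, centroids=centroids,
                           bic=final_bic)


def drop_singletons(
    solution: ClusterSolution, max_singleton_size: int = 1
) -> ClusterSolution:
    """Remove clusters of size <= ``max_singleton_size``.

    Members of dropped clusters are flagged unassigned (label -1) and the
    remaining clusters are renumbered consecutively. Raises when every
    cluster would be dropped.
    """
    sizes = np.bincount(solution.labels[solution.labels != UNASSIGNED],
                        minlength=solution.k)
    keep = [j for j in range(solution.k) if sizes[j] > max_singleton_size]
    dropped = [j for j in range(solution.k) if sizes[j] <= max_singleton_size]
    if not keep:
        raise ValueError("all clusters are singletons; nothing to retain")
    if not dropped:
        return ClusterSolution(
            k=solution.k,
            labels=solution.labels.copy(),
            centroids=solution.centroids.copy(),
            bic=solution.bic,
            dropped_singletons=list(solution.dropped_singletons),
        )
    remap = {old: new for new, old in enumerate(keep)}
    labels = np.array(
        [remap.get(l, UNASSIGNED) if l != UNASSIGNED else UNASSIGNED
         for l in solution.labels]
    )
    return ClusterSolution(
        k=len(keep),
        labels=labels,
        centroids=solution.centroids[keep],
        bic=solution.bic,
        dropped_singletons=solution.dropped_singletons + dropped,
    )


@dataclasses.dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    adjusted_residuals: pd.DataFrame
    flags: pd.DataFrame  # +1 over-represented, -1 under-represented, 0 neither
    alpha_per_cell: float


def cluster_diagnosis_association(
    labels: np.ndarray,
    diagnoses: Sequence[str],
    alpha: float = 0.05,
    bonferroni_cells: bool = True,
) -> ChiSquareResult:
    """Pearson chi-squared test of cluster x diagnosis with residual post hoc.

    Unassigned subjects (label -1) are excluded. Adjusted standardized
    residuals r = (O - E) / sqrt(E (1 - row/N) (1 - col/N)) are compared
    two-sidedly against the normal critical value at alpha / (#cells) by
    default (the per-cell correction is configurable).
    """
    labels = np.asarray(labels)
    diagnoses = np.asarray(diagnoses)
    mask = labels != UNASSIGNED
    table = pd.crosstab(pd.Series(labels[mask], name="cluster"),
                        pd.Series(diagnoses[mask], name="diagnosis"))
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 clusters and 2 diagnosis levels")
    obs = table.to_numpy(dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    denom = np.sqrt(expected * (1.0 - row / n) * (1.0 - col / n))
    residuals = (obs - expected) / denom
    cells = obs.size
    alpha_cell = alpha / cells if bonferroni_cells else alpha
    crit = stats.norm.isf(alpha_cell / 2.0)
    flags = np.where(residuals > crit, 1, np.where(residuals < -crit, -1, 0))
    wrap = lambda a: pd.DataFrame(a, index=table.index, columns=table.columns)
    return ChiSquareResult(
        chi2=chi2,
        df=df,
        p_value=p,
        observed=wrap(obs),
        expected=wrap(expected),
        adjusted_residuals=wrap(residuals),
        flags=wrap(flags),
        alpha_per_cell=alpha_cell,
    )


@dataclasses.dataclass
class FunctioningSummary:
    cluster_stats: pd.DataFrame  # cluster x scale: n, mean, sd
    anova: pd.DataFrame          # per scale: k_groups, F, p
    games_howell: pd.DataFrame   # scale, cluster_i, cluster_j, t, df, p

    def cluster_means(self, scale: str) -> pd.Series:
        sub = self.cluster_stats[self.cluster_stats["scale"] == scale]
        return sub.set_index("cluster")["mean"]


def _games_howell(groups: dict[int, np.ndarray], scale: str) -> list[dict]:
    """Pairwise Games-Howell comparisons via the studentized range.

    t_ij = (m_i - m_j) / sqrt(s_i^2/n_i + s_j^2/n_j) with Welch-Satterthwaite
    degrees of freedom; p from the studentized-range distribution with
    q = t * sqrt(2) and the number of compared groups.
    """
    ids = sorted(groups)
    k = len(ids)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            xi, xj = groups[ids[a]], groups[ids[b]]
            ni, nj = len(xi), len(xj)
            vi, vj = xi.var(ddof=1), xj.var(ddof=1)
            vi_n, vj_n = vi / ni, vj / nj
            se = np.sqrt(vi_n + vj_n)
            if se == 0:
                t, df_w, p = 0.0, float(ni + nj - 2), 1.0
            else:
                t = float((xi.mean() - xj.mean()) / se)
                df_w = float(
                    (vi_n + vj_n) ** 2
                    / (vi_n**2 / (ni - 1) + vj_n**2 / (nj - 1))
                )
                p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_w))
            rows.append(
                {"scale": scale, "cluster_i": ids[a], "cluster_j": ids[b],
                 "t": t, "df": df_w, "p": p}
            )
    return rows


def functioning_association(
    labels: np.ndarray,
    functioning: pd.DataFrame,
    scales: Sequence[str] = FUNCTIONING_SCALES,
    min_cluster_n: int = 2,
) -> FunctioningSummary:
    """Per-scale one-way ANOVA across clusters plus Games-Howell post hocs.

    ``functioning`` is row-aligned with ``labels``; only rows with a
    non-missing value for a scale enter that scale's test, and clusters with
    fewer than ``min_cluster_n`` such rows are excluded per scale.
    """
    labels = np.asarray(labels)
    stats_rows, anova_rows, gh_rows = [], [], []
    for scale in scales:
        if scale not in functioning.columns:
            continue
        values = functioning[scale].to_numpy(dtype=float)
        ok = ~np.isnan(values) & (labels != UNASSIGNED)
        groups: dict[int, np.ndarray] = {}
        for j in np.unique(labels[ok]):
            x = values[ok & (labels == j)]
            if len(x) >= min_cluster_n:
                groups[int(j)] = x
        for j, x in groups.items():
            stats_rows.append(
                {"scale": scale, "cluster": j, "n": len(x),
                 "mean": float(x.mean()), "sd": float(x.std(ddof=1))}
            )
        if len(groups) < 2:
            raise ValueError(f"fewer than 2 usable clusters for scale {scale!r}")
        if all(np.allclose(x, next(iter(groups.values()))[0]) for x in groups.values()):
            warnings.warn(f"constant data for scale {scale!r}; F undefined", UserWarning)
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups.values())
        anova_rows.append(
            {"scale": scale, "k_groups": len(groups), "F": float(f_stat),
             "p": float(p)}
        )
        gh_rows.extend(_games_howell(groups, scale))
    return FunctioningSummary(
        cluster_stats=pd.DataFrame(stats_rows),
        anova=pd.DataFrame(anova_rows),
        games_howell=pd.DataFrame(gh_rows),
    )


@dataclasses.dataclass
class BiotypeModel:
    cluster_to_biotype: dict[int, str]
    biotype_ids: list[str]
    normal_biotype: str
    hc_reference: dict[str, tuple[float, float]]
    thresholds: dict[str, float]

    def biotype_labels(self, cluster_labels: np.ndarray) -> np.ndarray:
        return np.array(
            [self.cluster_to_biotype.get(int(l), "unassigned") for l in cluster_labels]
        )


def merge_functionally_normal(
    solution: ClusterSolution,
    summary: FunctioningSummary,
    hc_reference: Mapping[str, tuple[float, float]],
    severity_scale: str = "FIQ",
    on_missing: str = "error",
) -> BiotypeModel:
    """Merge clusters that look functionally normal into one biotype.

    A cluster joins the normal group iff its mean exceeds (HC mean - 1 SD) on
    *every* functioning scale. Impaired clusters become biotypes ordered by
    ascending mean on ``severity_scale`` (worst first; ties broken by cluster
    size, larger first); the merged normal group is the last-numbered biotype.

    A retained cluster with no functioning observations cannot be classified;
    with ``on_missing="error"`` this raises, with ``"exclude"`` the cluster is
    left out of the biotype mapping (its members are later unassigned).
    """
    if on_missing not in ("error", "exclude"):
        raise ValueError("on_missing must be 'error' or 'exclude'")
    thresholds = {s: mean - sd for s, (mean, sd) in hc_reference.items()}
    clusters = sorted(solution.sizes())
    sizes = solution.sizes()
    means = {
        s: summary.cluster_means(s) for s in thresholds
        if s in set(summary.cluster_stats["scale"])
    }
    if not means:
        raise ValueError("no functioning scales with cluster means available")
    normal, impaired = [], []
    for j in clusters:
        missing = [s for s, mean_series in means.items() if j not in mean_series.index]
        if missing:
            if on_missing == "error":
                raise ValueError(f"cluster {j} lacks a mean for scale {missing[0]!r}")
            warnings.warn(
                f"cluster {j} (n={sizes[j]}) has no functioning data; "
                "excluded from biotype assignment",
                UserWarning,
            )
            continue
        if any(means[s][j] <= thresholds[s] for s in means):
            impaired.append(j)
        else:
            normal.append(j)
    if not normal:
        warnings.warn("no cluster qualifies as functionally normal", UserWarning)
    severity = means.get(severity_scale, next(iter(means.values())))
    impaired.sort(key=lambda j: (severity[j], -sizes[j]))
    mapping: dict[int, str] = {}
    for rank, j in enumerate(impaired, start=1):
        mapping[j] = f"BB{rank}"
    normal_id = f"BB{len(impaired) + 1}"
    for j in normal:
        mapping[j] = normal_id
    biotype_ids = [f"BB{r}" for r in range(1, len(impaired) + 2)]
    return BiotypeModel(
        cluster_to_biotype=mapping,
        biotype_ids=biotype_ids,
        normal_biotype=normal_id,
        hc_reference={s: tuple(v) for s, v in hc_reference.items()},
        thresholds=thresholds,
    )
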