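"""k-means/X-means, BIC splitting, association tests, biotype merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

from subcort_biotypes import (
    ClusterSolution,
    DegenerateScoreWarning,
    bic_score,
    cluster_diagnosis_association,
    drop_singletons,
    functioning_association,
    kmeans,
    merge_functionally_normal,
    xmeans,
)


def _blobs(rng, centers, n_each, sd=1.0):
    points = np.concatenate(
        [rng.normal(c, sd, size=(n_each, len(c))) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_each)
    return points, labels


def test_kmeans_two_points_two_clusters():
    points = np.array([[0.0, 0.0], [5.0, 5.0]])
    labels, centroids, inertia = kmeans(points, 2, seed=0)
    assert inertia == 0.0
    assert len(set(labels)) == 2
    assert sorted(map(tuple, centroids)) == sorted(map(tuple, points))


def test_kmeans_recovers_separated_blobs():
    rng = np.random.default_rng(3)
    centers = [(0, 0), (10, 0), (0, 10), (10, 10)]
    points, true = _blobs(rng, centers, 50, sd=1.0)
    labels, _, _ = kmeans(points, 4, seed=1)
    assert adjusted_rand_score(true, labels) == 1.0


def test_kmeans_identical_points_degenerate_but_stable():
    points = np.zeros((10, 3))
    labels_a, _, inertia = kmeans(points, 2, seed=7)
    labels_b, _, _ = kmeans(points, 2, seed=7)
    assert inertia == 0.0
    np.testing.assert_array_equal(labels_a, labels_b)
    with pytest.raises(ValueError):
        kmeans(points, 11, seed=0)


def test_bic_prefers_true_number_of_components():
    rng = np.random.default_rng(12)
    single = rng.normal(0.0, 1.0, size=(300, 4))
    labels2, cents2, _ = kmeans(single, 2, seed=0)
    one = bic_score(single, np.zeros(300, dtype=int), single.mean(0)[None, :])
    two = bic_score(single, labels2, cents2)
    assert one > two

    blobs, _ = _blobs(rng, [(0.0,) * 4, (10.0,) * 4], 150, sd=1.0)
    labels2, cents2, _ = kmeans(blobs, 2, seed=0)
    one = bic_score(blobs, np.zeros(300, dtype=int), blobs.mean(0)[None, :])
    two = bic_score(blobs, labels2, cents2)
    assert two > one


def test_bic_degenerate_flag():
    points = np.zeros((2, 3))
    with pytest.warns(DegenerateScoreWarning):
        score = bic_score(points, np.zeros(2, dtype=int), np.zeros((1, 3)))
    assert score == -np.inf


def test_xmeans_single_blob_stays_at_kmin():
    rng = np.random.default_rng(5)
    points = rng.normal(0.0, 1.0, size=(400, 6))
    solution = xmeans(points, kmin=1, kmax=10, seed=2)
    assert solution.k == 1


def test_xmeans_recovers_planted_four_profile_structure():
    # 4 planted profiles on 16 z-features (impaired shifts >= 1.5)
    rng = np.random.default_rng(8)
    profiles = np.zeros((4, 16))
    profiles[0, :6] = [3.0, 3.0, -3.0, -3.0, -3.0, -3.0]   # extreme
    profiles[1, :6] = [1.5, 1.5, -1.5, -1.5, -1.5, -1.5]   # moderate
    profiles[2, 6:12] = 2.0                                # basal-ganglia-like
    counts = [180, 240, 180, 600]                          # normal majority
    points = np.concatenate(
        [rng.normal(profiles[i], 1.0, size=(n, 16)) for i, n in enumerate(counts)]
    )
    true = np.repeat(np.arange(4), counts)
    solution = xmeans(points, kmin=1, kmax=20, seed=4)
    assert solution.k >= 4
    assert adjusted_rand_score(true, solution.labels) > 0.8


def test_xmeans_kmax_equals_kmin_is_forced():
    rng = np.random.default_rng(2)
    points, _ = _blobs(rng, [(0, 0), (8, 8)], 100)
    solution = xmeans(points, kmin=3, kmax=3, seed=0)
    assert solution.k == 3


def test_xmeans_partition_invariant_to_row_permutation():
    rng = np.random.default_rng(23)
    points, _ = _blobs(rng, [(0.0,) * 5, (9.0,) * 5, (0.0, 9.0, 0.0, 9.0, 0.0)], 80)
    perm = rng.permutation(len(points))
    a = xmeans(points, 1, 10, seed=3)
    b = xmeans(points[perm], 1, 10, seed=3)
    assert a.k == b.k
    assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0


def test_drop_singletons_cases():
    labels = np.array([0] * 100 + [1] * 50 + [2] + [3])
    solution = ClusterSolution(
        k=4, labels=labels, centroids=np.zeros((4, 2)), bic=0.0
    )
    out = drop_singletons(solution)
    assert out.k == 2
    assert out.dropped_singletons == [2, 3]
    assert (out.labels[:150] >= 0).all()
    assert (out.labels[150:] == -1).all()

    untouched = drop_singletons(out)
    assert untouched.k == 2 and untouched.dropped_singletons == [2, 3]

    only_singletons = ClusterSolution(
        k=2, labels=np.array([0, 1]), centroids=np.zeros((2, 2)), bic=0.0
    )
    with pytest.raises(ValueError):
        drop_singletons(only_singletons)


def test_chi2_worked_example_and_residuals():
    labels = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
    diagnoses = np.array(
        ["HC"] * 30 + ["SZ"] * 10 + ["HC"] * 10 + ["SZ"] * 30
    )
    res = cluster_diagnosis_association(labels, diagnoses)
    # hand formula: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2) = 80*(900-100)^2/40^4
    assert res.chi2 == pytest.approx(20.0)
    assert res.df == 1
    assert res.adjusted_residuals.loc[0, "HC"] == pytest.approx(
        10.0 / np.sqrt(20 * 0.5 * 0.5)
    )
    assert res.adjusted_residuals.loc[0, "HC"] == pytest.approx(4.472, abs=5e-4)
    # residual matrix rows/columns of O-E sum to zero
    diff = res.observed - res.expected
    np.testing.assert_allclose(diff.sum(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(diff.sum(axis=1), 0.0, atol=1e-9)


def test_chi2_matches_scipy():
    from scipy.stats import chi2_contingency

    rng = np.random.default_rng(44)
    labels = rng.integers(0, 3, 400)
    diagnoses = rng.choice(["HC", "SZ", "MDD"], 400, p=[0.5, 0.3, 0.2])
    res = cluster_diagnosis_association(labels, diagnoses)
    ref_chi2, ref_p, ref_df, _ = chi2_contingency(res.observed.to_numpy(),
                                                  correction=False)
    assert res.chi2 == pytest.approx(ref_chi2, rel=1e-10)
    assert res.p_value == pytest.approx(ref_p, rel=1e-8)
    assert res.df == ref_df


def test_residual_flag_rate_under_independence():
    # independent labels: per-cell flag rate ~ alpha/(cells) summed over cells
    rng = np.random.default_rng(10)
    flagged = 0
    tables = 0
    for _ in range(200):
        labels = rng.integers(0, 2, 300)
        diagnoses = rng.choice(["HC", "SZ"], 300)
        res = cluster_diagnosis_association(labels, diagnoses)
        flagged += int((res.flags.to_numpy() != 0).any())
        tables += 1
    # with Bonferroni over cells, any-flag rate stays around alpha
    assert flagged / tables < 0.12


def test_unassigned_subjects_excluded_from_association():
    labels = np.array([0] * 40 + [1] * 40 + [-1] * 20)
    diagnoses = np.array(["HC", "SZ"] * 50)
    res = cluster_diagnosis_association(labels, diagnoses)
    assert res.observed.to_numpy().sum() == 80


def _functioning_frame(labels, means, sd, rng, scale="FIQ"):
    values = rng.normal([means[l] for l in labels], sd)
    return pd.DataFrame({scale: values})


def test_functioning_association_detects_separation_and_matches_welch():
    rng = np.random.default_rng(31)
    labels = np.repeat([0, 1], 200)
    table = _functioning_frame(labels, {0: 100.0, 1: 85.0}, 10.0, rng)
    summary = functioning_association(labels, table, scales=("FIQ",))
    assert summary.anova.loc[0, "F"] > 50
    gh = summary.games_howell
    assert len(gh) == 1
    assert gh.loc[0, "p"] < 1e-6
    # two groups: Games-Howell t equals Welch's t
    from scipy.stats import ttest_ind

    x, y = table["FIQ"][labels == 0], table["FIQ"][labels == 1]
    welch = ttest_ind(x, y, equal_var=False)
    assert gh.loc[0, "t"] == pytest.approx(welch.statistic, rel=1e-10)


def test_games_howell_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(17)
    labels = np.repeat([0, 1, 2], [50, 80, 120])
    table = _functioning_frame(labels, {0: 100.0, 1: 96.0, 2: 90.0}, 12.0, rng)
    summary = functioning_association(labels, table, scales=("FIQ",))
    ref = pg.pairwise_gameshowell(
        data=table.assign(g=labels), dv="FIQ", between="g"
    ).set_index(["A", "B"])
    for _, row in summary.games_howell.iterrows():
        r = ref.loc[(row["cluster_i"], row["cluster_j"])]
        assert abs(row["t"]) == pytest.approx(abs(r["T"]), rel=1e-6)
        assert row["df"] == pytest.approx(r["df"], rel=1e-6)
        assert row["p"] == pytest.approx(r["pval"], rel=1e-4, abs=1e-10)


def test_functioning_association_null_is_calm():
    rng = np.random.default_rng(77)
    labels = np.repeat([0, 1, 2], 100)
    table = _functioning_frame(labels, {0: 100.0, 1: 100.0, 2: 100.0}, 10.0, rng)
    summary = functioning_association(labels, table, scales=("FIQ",))
    assert summary.anova.loc[0, "p"] > 0.01
    assert (summary.games_howell["p"] > 0.01).all()


def test_merge_rule_all_means_at_hc_mean_merges_everything():
    stats = pd.DataFrame(
        {
            "scale": ["FIQ"] * 3,
            "cluster": [0, 1, 2],
            "n": [50, 50, 50],
            "mean": [112.7, 112.7, 112.7],
            "sd": [10.0] * 3,
        }
    )
    summary_obj = _summary_from(stats)
    solution = _solution_with_sizes({0: 50, 1: 50, 2: 50})
    model = merge_functionally_normal(solution, summary_obj, {"FIQ": (112.7, 12.2)})
    assert model.biotype_ids == ["BB1"]
    assert set(model.cluster_to_biotype.values()) == {"BB1"}


def test_merge_rule_single_scale_below_threshold_excludes():
    stats = pd.DataFrame(
        {
            "scale": ["FIQ", "SFS", "FIQ", "SFS"],
            "cluster": [0, 0, 1, 1],
            "n": [50] * 4,
            "mean": [112.7 - 1.5 * 12.2, 144.5, 112.7, 144.5],
            "sd": [10.0] * 4,
        }
    )
    summary_obj = _summary_from(stats)
    solution = _solution_with_sizes({0: 50, 1: 50})
    model = merge_functionally_normal(
        solution, summary_obj, {"FIQ": (112.7, 12.2), "SFS": (144.5, 17.4)}
    )
    assert model.cluster_to_biotype == {0: "BB1", 1: "BB2"}
    assert model.normal_biotype == "BB2"


def test_merge_severity_ordering_by_fiq():
    stats = pd.DataFrame(
        {
            "scale": ["FIQ"] * 4,
            "cluster": [0, 1, 2, 3],
            "n": [50] * 4,
            "mean": [95.0, 85.0, 90.0, 113.0],
            "sd": [10.0] * 4,
        }
    )
    summary_obj = _summary_from(stats)
    solution = _solution_with_sizes({0: 50, 1: 50, 2: 50, 3: 500})
    model = merge_functionally_normal(solution, summary_obj, {"FIQ": (112.7, 12.2)})
    assert model.cluster_to_biotype == {1: "BB1", 2: "BB2", 0: "BB3", 3: "BB4"}
    assert model.normal_biotype == "BB4"


def test_merge_no_normal_cluster_warns():
    stats = pd.DataFrame(
        {"scale": ["FIQ"] * 2, "cluster": [0, 1], "n": [50, 50],
         "mean": [80.0, 85.0], "sd": [10.0, 10.0]}
    )
    summary_obj = _summary_from(stats)
    solution = _solution_with_sizes({0: 50, 1: 50})
    with pytest.warns(UserWarning, match="normal"):
        model = merge_functionally_normal(solution, summary_obj, {"FIQ": (112.7, 12.2)})
    assert model.normal_biotype == "BB3"
    assert set(model.cluster_to_biotype.values()) == {"BB1", "BB2"}


def _summary_from(stats: pd.DataFrame):
    from subcort_biotypes import FunctioningSummary

    return FunctioningSummary(
        cluster_stats=stats, anova=pd.DataFrame(), games_howell=pd.DataFrame()
    )


def _solution_with_sizes(sizes: dict[int, int]) -> ClusterSolution:
    labels = np.concatenate([[j] * n for j, n in sizes.items()])
    return ClusterSolution(
        k=len(sizes), labels=labels, centroids=np.zeros((len(sizes), 16)), bic=0.0
    )
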