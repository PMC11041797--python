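"""LDA, LOOCV, rank-based medication tests, and the pipeline driver."""

import numpy as np
import pandas as pd
import pytest

from subcort_biotypes import (
    default_config,
    dunn_posthoc,
    kruskal_wallis,
    lda_fit,
    lda_loocv_accuracy,
    lda_predict,
    run_pipeline,
    simulate_cohort,
)


def _two_class_data(rng, n=100, dims=16, shift=5.0):
    a = rng.normal(0.0, 1.0, size=(n, dims))
    b = rng.normal(0.0, 1.0, size=(n, dims))
    a[:, 0] -= shift / 2
    b[:, 0] += shift / 2
    z = np.concatenate([a, b])
    labels = np.array(["A"] * n + ["B"] * n)
    return z, labels


def test_lda_decision_boundary_symmetric_case():
    rng = np.random.default_rng(0)
    z, labels = _two_class_data(rng, shift=10.0)
    model = lda_fit(z, labels)
    probes = np.zeros((2, 16))
    probes[0, 0] = -1.0
    probes[1, 0] = +1.0
    assert list(lda_predict(model, probes)) == ["A", "B"]


def test_lda_single_class_errors():
    z = np.random.default_rng(1).normal(size=(10, 4))
    with pytest.raises(ValueError):
        lda_fit(z, ["A"] * 10)


def test_lda_matches_sklearn():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(5)
    z = rng.normal(size=(300, 6))
    z[:100, 0] += 2.5
    z[100:200, 1] -= 2.0
    labels = np.repeat(["a", "b", "c"], 100)
    ours = lda_predict(lda_fit(z, labels), z)
    ref = LinearDiscriminantAnalysis(solver="lsqr").fit(z, labels).predict(z)
    assert (ours == ref).mean() > 0.995


def test_resubstitution_accuracy_on_planted_biotypes(paper_cohort):
    cohort, truth = paper_cohort
    from subcort_biotypes import REGIONS, fit_all_normative_models, zscore_cohort

    models = fit_all_normative_models(cohort)
    z = zscore_cohort(cohort, models)
    bt = truth.biotype_of().loc[z["subject_id"]].to_numpy()
    model = lda_fit(z[list(REGIONS)].to_numpy(), bt)
    acc = (lda_predict(model, z[list(REGIONS)].to_numpy()) == bt).mean()
    assert acc > 0.9


def test_loocv_perfect_separation_and_agrees_with_refit():
    rng = np.random.default_rng(2)
    z, labels = _two_class_data(rng, n=60, shift=12.0)
    assert lda_loocv_accuracy(z, labels) == 1.0
    # the rank-one downdate must equal brute-force refitting
    z_small, labels_small = _two_class_data(rng, n=15, dims=4, shift=1.0)
    fast = lda_loocv_accuracy(z_small, labels_small)
    correct = 0
    for i in range(len(z_small)):
        mask = np.arange(len(z_small)) != i
        model = lda_fit(z_small[mask], labels_small[mask])
        correct += int(lda_predict(model, z_small[i]) [0] == labels_small[i])
    assert fast == pytest.approx(correct / len(z_small))


def test_loocv_permuted_labels_near_chance():
    rng = np.random.default_rng(9)
    n, k = 400, 4
    z = rng.normal(size=(n, 16))
    labels = rng.permutation(np.repeat(np.arange(k), n // k))
    acc = lda_loocv_accuracy(z, labels)
    band = 3.0 * np.sqrt(k - 1) / (k * np.sqrt(n))
    assert abs(acc - 1.0 / k) < band + 0.05


def test_kruskal_wallis_worked_example_and_degenerate():
    h, df, p = kruskal_wallis([1, 2, 3, 10, 20, 30], ["a"] * 3 + ["b"] * 3)
    assert h == pytest.approx(3.857, abs=5e-4)
    assert df == 1
    h, df, p = kruskal_wallis([5.0] * 8, ["a"] * 4 + ["b"] * 4)
    assert h == 0.0 and p == 1.0
    with pytest.raises(ValueError):
        kruskal_wallis([1.0, 2.0], ["a", "a"])


def test_kruskal_wallis_invariant_to_monotone_transform():
    rng = np.random.default_rng(3)
    doses = rng.gamma(2.0, 100.0, 200)
    groups = rng.integers(0, 3, 200)
    h0, _, _ = kruskal_wallis(doses, groups)
    h1, _, _ = kruskal_wallis(np.log1p(doses), groups)
    h2, _, _ = kruskal_wallis(doses**3, groups)
    assert h0 == pytest.approx(h1, rel=1e-12)
    assert h0 == pytest.approx(h2, rel=1e-12)


def test_kruskal_wallis_null_mean_is_df():
    rng = np.random.default_rng(4)
    hs = []
    for _ in range(300):
        values = rng.normal(size=60)
        groups = np.repeat([0, 1, 2], 20)
        h, df, _ = kruskal_wallis(values, groups)
        hs.append(h)
    assert np.mean(hs) == pytest.approx(2.0, abs=0.3)


def test_dunn_identity_and_two_group_reduction():
    rng = np.random.default_rng(6)
    values = rng.normal(size=80)
    groups = np.repeat([0, 1], 40)
    out = dunn_posthoc(values, groups)
    assert len(out) == 1
    assert out.loc[0, "p_adjusted"] == pytest.approx(out.loc[0, "p_raw"])

    same = dunn_posthoc(np.ones(60), np.repeat([0, 1, 2], 20))
    assert (same["p_adjusted"] == 1.0).all()


def test_dunn_flags_only_truly_shifted_group():
    rng = np.random.default_rng(8)
    values = np.concatenate(
        [rng.normal(0, 1, 80), rng.normal(0, 1, 80),
         rng.normal(0, 1, 80), rng.normal(3.0, 1, 80)]
    )
    groups = np.repeat([0, 1, 2, 3], 80)
    out = dunn_posthoc(values, groups)
    hit = out[out["p_adjusted"] < 0.05]
    assert set(map(tuple, hit[["group_i", "group_j"]].to_numpy())) == {
        (0, 3), (1, 3), (2, 3)
    }


def test_pipeline_smoke_and_determinism(toy_cohort):
    cohort, _ = toy_cohort
    a = run_pipeline(cohort, seed=5)
    b = run_pipeline(cohort, seed=5)
    assert a.cluster_solution.k == b.cluster_solution.k
    np.testing.assert_array_equal(a.cluster_solution.labels, b.cluster_solution.labels)
    assert a.loocv_accuracy == b.loocv_accuracy
    assert a.to_json_dict() == b.to_json_dict()
    assert len(a.meta_volumes) == 4 * 17
    assert len(a.meta_li) == 4 * 8
    assert a.medication_tests is not None and len(a.medication_tests) == 4
    assert a.n_biotypes() is not None and a.n_biotypes() >= 1


def test_pipeline_report_serializes(tmp_path, toy_cohort):
    cohort, _ = toy_cohort
    report = run_pipeline(cohort, seed=1)
    path = tmp_path / "report.json"
    report.save(path)
    import json

    payload = json.loads(path.read_text())
    assert payload["k_clusters"] == report.cluster_solution.k
    assert payload["seed"] == 1
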