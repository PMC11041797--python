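"""Synthetic-cohort generator: bookkeeping, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from subcort_biotypes import (
    DIAGNOSES,
    REGION_PAIRS,
    TABLE1_DEMOGRAPHICS,
    default_config,
    dersimonian_laird,
    make_protocols,
    per_protocol_effects,
    simulate_cohort,
    simulate_medications,
)
from conftest import null_config, planted_config


def test_paper_like_counts_match_published_totals():
    cfg = default_config("paper-like")
    totals = {d: 0 for d in DIAGNOSES}
    for spec in cfg.protocols:
        for diag, cell in spec.groups.items():
            totals[diag] += cell.n
    assert len(cfg.protocols) == 30
    assert totals["HC"] == 3078
    assert totals == {"HC": 3078, "SZ": 1500, "BP": 235, "MDD": 598, "ASD": 193}
    assert sum(totals.values()) == 5604


def test_toy_config_structure():
    cfg = default_config("toy")
    assert len(cfg.protocols) == 4
    for diag, mix in cfg.biotype_mixing.items():
        assert np.isclose(sum(mix.values()), 1.0)
    with pytest.raises(ValueError):
        default_config("huge")


def test_same_seed_reproduces_cohort_exactly():
    a, truth_a = simulate_cohort(default_config("toy", seed=42))
    b, truth_b = simulate_cohort(default_config("toy", seed=42))
    assert a.df.equals(b.df)
    assert truth_a.subjects.equals(truth_b.subjects)
    c, _ = simulate_cohort(default_config("toy", seed=43))
    assert not a.df.equals(c.df)


def test_null_config_gives_near_zero_effects():
    cfg = null_config(n_protocols=4, n_per_diagnosis={"HC": 150, "SZ": 150}, seed=3)
    cohort, _ = simulate_cohort(cfg)
    effects = per_protocol_effects(cohort, "SZ", "volumes")
    by_measure = {}
    for e in effects:
        by_measure.setdefault(e.measure, []).append(e)
    for name, es in by_measure.items():
        pooled = dersimonian_laird(es)
        assert abs(pooled.d_pooled) < 3.0 * pooled.se_pooled + 1e-12, name


def test_planted_effect_recovered_by_pipeline():
    cfg = planted_config({("SZ", "Left-Pallidum"): 0.40}, seed=7)
    cohort, _ = simulate_cohort(cfg)
    effects = [
        e for e in per_protocol_effects(cohort, "SZ", "volumes")
        if e.measure == "Left-Pallidum"
    ]
    pooled = dersimonian_laird(effects)
    assert abs(pooled.d_pooled - 0.40) < 0.1


def test_laterality_shift_conserves_structure_totals():
    groups = {"HC": 100, "SZ": 100}
    base = null_config(n_protocols=2, n_per_diagnosis=groups, seed=5)
    shifted = null_config(n_protocols=2, n_per_diagnosis=groups, seed=5)
    shifted.laterality_shift = {("SZ", "Pallidum"): 0.05}
    a, _ = simulate_cohort(base)
    b, _ = simulate_cohort(shifted)
    # same seed and structure: only the pallidum L/R split of SZ subjects moves
    sz = a.df["diagnosis"] == "SZ"
    for left, right in REGION_PAIRS:
        tot_a = a.df.loc[sz, left] + a.df.loc[sz, right]
        tot_b = b.df.loc[sz, left] + b.df.loc[sz, right]
        np.testing.assert_allclose(tot_a, tot_b, rtol=1e-12)
    pall = (a.df.loc[sz, "Left-Pallidum"] != b.df.loc[sz, "Left-Pallidum"])
    assert pall.all()


def test_hc_fiq_matches_reference_at_scale():
    cfg = default_config("paper-like", seed=123)
    cohort, _ = simulate_cohort(cfg)
    df = cohort.df
    hc = df[(df["diagnosis"] == "HC") & df["FIQ"].notna()]
    # marginal HC mean is calibrated to the reference 112.7 +/- 12.2
    assert abs(hc["FIQ"].mean() - 112.7) < 3.0 * 12.2 / np.sqrt(len(hc))
    assert abs(hc["FIQ"].std() / 12.2 - 1.0) < 0.1


def test_functioning_restricted_to_designated_sites():
    cohort, _ = simulate_cohort(default_config("paper-like", seed=1))
    df = cohort.df
    osaka = df["protocol_id"].isin(["Osaka A", "Osaka B", "Osaka C"])
    assert df.loc[osaka, "FIQ"].notna().all()
    assert df.loc[~osaka, "FIQ"].isna().all()
    assert df.loc[~osaka, "dose_antipsychotics"].isna().all()


def test_medication_doses_ordered_by_biotype():
    cfg = default_config("toy", seed=9)
    cfg.protocols = make_protocols(2, {"HC": 400, "SZ": 1200})
    cfg.functioning_protocols = [p.protocol_id for p in cfg.protocols]
    cohort, truth = simulate_cohort(cfg)
    doses = cohort.df.set_index("subject_id")["dose_antipsychotics"]
    bt = truth.biotype_of()
    med_bb1 = doses[bt == "BB1"].median()
    med_bb4 = doses[bt == "BB4"].median()
    assert med_bb1 > med_bb4
    assert (doses.dropna() >= 0).all()


def test_all_bb4_cohort_uses_only_bb4_dose_model():
    cfg = null_config(n_protocols=1, n_per_diagnosis={"HC": 200}, seed=2)
    cohort, truth = simulate_cohort(cfg)
    assert (truth.subjects["biotype"] == "BB4").all()
    treated = cohort.df["dose_antipsychotics"] > 0
    # BB4 treatment probability is 0.15 under the defaults
    assert 0.05 < treated.mean() < 0.30


def test_zero_dose_config_gives_all_zero_doses():
    from subcort_biotypes import DoseModel

    cfg = null_config(n_protocols=1, n_per_diagnosis={"HC": 50}, seed=4)
    cfg.medication_model = {
        drug: {b: DoseModel(0.0, 0.0, 0.1) for b in per}
        for drug, per in cfg.medication_model.items()
    }
    cohort, _ = simulate_cohort(cfg)
    assert (cohort.df["dose_antipsychotics"].dropna() == 0).all()


def test_config_round_trips_through_plain_mapping():
    import json

    from subcort_biotypes import GeneratorConfig

    cfg = default_config("toy", seed=13)
    payload = json.loads(json.dumps(cfg.to_dict()))  # force plain-JSON types
    back = GeneratorConfig.from_dict(payload)
    a, _ = simulate_cohort(cfg)
    b, _ = simulate_cohort(back)
    assert a.df.equals(b.df)


def test_table1_cells_are_internally_consistent():
    for pid, groups in TABLE1_DEMOGRAPHICS.items():
        for diag, (n, m, age_mean, age_sd) in groups.items():
            assert 0 <= m <= n, (pid, diag)
            assert 0 < age_mean < 90 and age_sd > 0
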