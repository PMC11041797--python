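"""Shared fixtures: small simulated cohorts and planted-effect configs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from subcort_biotypes import (
    DIAGNOSES,
    GeneratorConfig,
    default_config,
    make_protocols,
    simulate_cohort,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def null_config(
    n_protocols: int = 4,
    n_per_diagnosis: dict[str, int] | None = None,
    seed: int = 0,
) -> GeneratorConfig:
    """A generator config with every planted effect switched off.

    No diagnosis shifts, no laterality shift, and a single (normal) biotype,
    so case and control volumes differ only by covariates and noise.
    """
    cfg = default_config("toy", seed=seed)
    cfg.protocols = make_protocols(
        n_protocols, n_per_diagnosis or {d: 30 for d in DIAGNOSES}
    )
    cfg.functioning_protocols = [p.protocol_id for p in cfg.protocols]
    cfg.effect_profile = {}
    cfg.laterality_shift = {}
    cfg.biotype_mixing = {d: {"BB4": 1.0} for d in DIAGNOSES}
    cfg.seed = seed
    return cfg


def planted_config(
    effect_profile: dict[tuple[str, str], float],
    laterality_shift: dict[tuple[str, str], float] | None = None,
    n_protocols: int = 10,
    n_case: int = 100,
    n_control: int = 100,
    seed: int = 0,
) -> GeneratorConfig:
    """A config planting only the given diagnosis effects (single biotype)."""
    cfg = null_config(seed=seed)
    diagnoses = {diag for diag, _ in effect_profile}
    if laterality_shift:
        diagnoses |= {diag for diag, _ in laterality_shift}
    counts = {"HC": n_control}
    counts.update({d: n_case for d in diagnoses})
    cfg.protocols = make_protocols(n_protocols, counts)
    cfg.functioning_protocols = [p.protocol_id for p in cfg.protocols]
    cfg.effect_profile = dict(effect_profile)
    cfg.laterality_shift = dict(laterality_shift or {})
    return cfg


@pytest.fixture(scope="session")
def toy_cohort():
    cohort, truth = simulate_cohort(default_config("toy", seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def paper_cohort():
    cohort, truth = simulate_cohort(default_config("paper-like", seed=0))
    return cohort, truth
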