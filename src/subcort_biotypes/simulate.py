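"""Synthetic multi-site cohort generator with planted ground truth.

Emulates the statistical structure the analysis pipeline assumes in a
multi-protocol case-control volumetry study: protocol-specific additive and
multiplicative scanner effects, sex/age/ICV covariate structure, per-diagnosis
volume shifts expressed in Cohen's-d units, a schizophrenia-specific leftward
pallidum laterality shift, latent brain-biotype profiles expressed as z-shifts
on the 16 regional volumes, and cognitive/social-functioning scores and
medication doses tied to biotype and collected at designated sites only.

The ``paper-like`` configuration reproduces the published cohort bookkeeping
(30 protocols; 3078 healthy controls and 2526 patients across SZ/BP/MDD/ASD)
and the published healthy-control functioning means/SDs (e.g. WAIS-III FIQ
112.7 +/- 12.2). Effect magnitudes that the source tables do not print are
configuration choices, documented in the methods note, not literature values.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    DIAGNOSES,
    DOSE_COLUMNS,
    FUNCTIONING_SCALES,
    REGIONS,
    REGION_PAIRS,
    STRUCTURES,
    CohortTable,
)

__all__ = [
    "DiagnosisCell",
    "ProtocolSpec",
    "FunctioningScaleModel",
    "DoseModel",
    "GeneratorConfig",
    "GroundTruth",
    "BIOTYPES",
    "TABLE1_DEMOGRAPHICS",
    "HC_FUNCTIONING_REFERENCE",
    "default_config",
    "simulate_cohort",
    "simulate_medications",
]

BIOTYPES: tuple[str, ...] = ("BB1", "BB2", "BB3", "BB4")

# Per-protocol demographics of the published overall cohort:
# {protocol: {diagnosis: (n, n_male, age_mean, age_sd)}}. Column sums equal the
# published totals (HC 3078, SZ 1500, BP 235, MDD 598, ASD 193; 5604 subjects).
TABLE1_DEMOGRAPHICS: dict[str, dict[str, tuple[int, int, float, float]]] = {
    "Osaka A": {"HC": (413, 193, 35.8, 12.7), "SZ": (174, 102, 36.6, 12.9),
                "MDD": (14, 9, 27.6, 10.2), "ASD": (45, 29, 24.4, 10.2)},
    "Osaka C": {"HC": (419, 226, 32.6, 15.2), "SZ": (94, 50, 34.3, 12.2),
                "BP": (5, 5, 50.0, 19.8), "MDD": (19, 9, 48.6, 13.0),
                "ASD": (18, 10, 27.8, 9.8)},
    "Nippon Med": {"HC": (194, 41, 47.9, 9.0), "SZ": (213, 121, 44.1, 13.6)},
    "Hokkaido A": {"HC": (35, 14, 47.8, 12.9), "SZ": (113, 43, 34.8, 12.5),
                   "BP": (78, 41, 45.5, 16.3), "MDD": (175, 85, 47.2, 17.3)},
    "Tokyo A": {"HC": (232, 142, 34.4, 11.9), "SZ": (99, 55, 33.3, 9.6)},
    "Osaka B": {"HC": (227, 125, 30.8, 12.9), "SZ": (57, 22, 34.0, 13.2),
                "MDD": (9, 4, 58.3, 19.4), "ASD": (12, 8, 25.8, 10.0)},
    "Kanazawa Med": {"HC": (114, 72, 35.3, 11.5), "SZ": (109, 41, 40.3, 12.7),
                     "BP": (34, 18, 45.6, 15.4), "MDD": (43, 27, 43.2, 13.8)},
    "Toyama A": {"HC": (118, 63, 25.9, 6.3), "SZ": (114, 57, 26.4, 6.2)},
    "Nagoya A": {"HC": (121, 74, 36.5, 9.8), "SZ": (54, 30, 43.3, 10.0),
                 "BP": (19, 8, 49.0, 14.0), "ASD": (12, 12, 30.7, 9.5)},
    "Kyoto B": {"HC": (148, 90, 36.5, 11.4), "SZ": (43, 22, 40.4, 9.2)},
    "Kyoto A": {"HC": (111, 63, 31.9, 10.6), "SZ": (77, 41, 36.4, 9.1)},
    "Yamaguchi B": {"HC": (113, 46, 44.4, 19.0), "BP": (15, 9, 40.9, 13.6),
                    "MDD": (55, 24, 51.6, 12.7)},
    "Tokyo B": {"HC": (80, 54, 28.6, 5.6), "SZ": (41, 27, 31.4, 9.2),
                "ASD": (34, 34, 30.2, 6.8)},
    "Kyushu A": {"HC": (78, 36, 33.2, 11.9), "SZ": (41, 11, 38.2, 9.6),
                 "BP": (18, 7, 48.4, 14.7), "MDD": (9, 5, 49.0, 11.6)},
    "Yamaguchi A": {"HC": (90, 18, 49.3, 16.1), "SZ": (27, 5, 55.4, 8.2),
                    "BP": (8, 0, 50.3, 11.2), "MDD": (21, 9, 50.2, 12.1)},
    "Tokyo E": {"HC": (41, 17, 37.3, 7.7), "SZ": (28, 19, 30.3, 10.4),
                "BP": (23, 15, 34.4, 9.5), "MDD": (43, 24, 37.7, 11.3),
                "ASD": (6, 6, 36.8, 8.4)},
    "Hiroshima D": {"HC": (53, 28, 56.0, 14.2), "BP": (26, 10, 52.7, 15.7),
                    "MDD": (61, 23, 49.2, 14.2)},
    "Hiroshima A": {"HC": (64, 29, 34.5, 12.9), "MDD": (71, 36, 42.5, 11.5)},
    "Showa": {"HC": (68, 55, 26.9, 5.9), "ASD": (66, 57, 30.1, 6.5)},
    "Toyama B": {"HC": (56, 32, 25.7, 3.3), "SZ": (61, 31, 27.7, 9.2)},
    "UOEH": {"HC": (54, 36, 36.6, 12.0), "SZ": (15, 6, 28.0, 13.4),
             "MDD": (23, 10, 43.3, 13.7)},
    "Kyushu B": {"HC": (27, 11, 34.6, 13.8), "SZ": (31, 15, 35.5, 11.9),
                 "BP": (9, 5, 48.8, 7.9)},
    "Hiroshima B": {"HC": (19, 8, 42.4, 9.4), "MDD": (47, 25, 44.5, 10.5)},
    "Tokyo D": {"HC": (47, 17, 38.8, 9.0), "SZ": (11, 6, 38.4, 4.2)},
    "Tokyo C": {"HC": (41, 25, 28.8, 7.5), "SZ": (12, 6, 27.4, 9.4)},
    "Hokkaido B": {"HC": (21, 14, 33.2, 7.7), "SZ": (28, 11, 37.9, 9.7)},
    "Hiroshima C": {"HC": (41, 11, 42.7, 11.6), "MDD": (8, 1, 37.5, 9.4)},
    "Tokushima B": {"HC": (19, 10, 41.6, 10.7), "SZ": (21, 11, 42.9, 10.3)},
    "Tokushima A": {"HC": (21, 16, 34.3, 8.4), "SZ": (18, 9, 34.8, 9.4)},
    "Nagoya B": {"HC": (13, 8, 66.8, 4.3), "SZ": (19, 9, 40.4, 11.5)},
}

# Published healthy-control functioning reference: {scale: (mean, SD)}.
HC_FUNCTIONING_REFERENCE: dict[str, tuple[float, float]] = {
    "FIQ": (112.7, 12.2),
    "VC": (111.4, 13.1),
    "PO": (108.2, 13.2),
    "WM": (110.7, 15.5),
    "PS": (110.1, 14.0),
    "UPSAB_Financial": (48.7, 3.3),
    "UPSAB_Communication": (32.1, 8.3),
    "SFS": (144.5, 17.4),
    "WHW": (36.3, 18.5),
}

# Healthy baseline volume distributions, mm^3 per hemisphere (typical adult
# FreeSurfer aseg values): {structure: (mean, SD)}.
_BASELINES: dict[str, tuple[float, float]] = {
    "Lateral-Ventricle": (7700.0, 2500.0),
    "Thalamus": (7500.0, 700.0),
    "Caudate": (3700.0, 450.0),
    "Putamen": (5300.0, 600.0),
    "Pallidum": (1600.0, 250.0),
    "Hippocampus": (4200.0, 450.0),
    "Amygdala": (1600.0, 250.0),
    "Accumbens": (600.0, 120.0),
}

_ICV_REF = 1.5e6  # mm^3, reference point for the ICV covariate term
_AGE_REF = 40.0   # years, centring point for the age covariate term


@dataclasses.dataclass(frozen=True)
class DiagnosisCell:
    """Sample-size and demographics cell for one protocol x diagnosis."""

    n: int
    male_frac: float
    age_mean: float
    age_sd: float


@dataclasses.dataclass(frozen=True)
class ProtocolSpec:
    """One scanner/imaging-protocol combination.

    ``offset``/``scale`` are the scanner's additive (mm^3) and multiplicative
    location/scale effects per region.
    """

    protocol_id: str
    groups: dict[str, DiagnosisCell]
    offset: dict[str, float]
    scale: dict[str, float]


@dataclasses.dataclass(frozen=True)
class FunctioningScaleModel:
    """HC reference and per-biotype shift (in HC-SD units) for one scale."""

    hc_mean: float
    hc_sd: float
    biotype_shift_sd: dict[str, float]


@dataclasses.dataclass(frozen=True)
class DoseModel:
    """Zero-inflated log-normal daily-dose model for one drug x biotype."""

    p_treated: float
    median_dose: float
    log_sd: float


@dataclasses.dataclass
class GeneratorConfig:
    protocols: list[ProtocolSpec]
    region_baselines: dict[str, tuple[float, float]]
    covariate_effects: dict[str, tuple[float, float, float]]  # sex, age, ICV coefs
    effect_profile: dict[tuple[str, str], float]  # (diagnosis, measure) -> d
    laterality_shift: dict[tuple[str, str], float]  # (diagnosis, structure) -> dLI
    biotype_profiles: dict[str, np.ndarray]  # biotype -> 16 z-shifts
    biotype_mixing: dict[str, dict[str, float]]  # diagnosis -> biotype -> prob
    functioning_model: dict[str, FunctioningScaleModel]
    medication_model: dict[str, dict[str, DoseModel]]
    functioning_protocols: list[str]
    icv_log_mean: float = float(np.log(_ICV_REF))
    icv_log_sd: float = 0.08
    icv_sex_log_shift: float = 0.09  # males ~9% larger ICV
    seed: int = 0

    def to_dict(self) -> dict:
        """Plain-mapping form suitable for YAML/JSON serialization."""
        return {
            "seed": self.seed,
            "icv_log_mean": self.icv_log_mean,
            "icv_log_sd": self.icv_log_sd,
            "icv_sex_log_shift": self.icv_sex_log_shift,
            "protocols": [
                {
                    "protocol_id": p.protocol_id,
                    "groups": {
                        d: dataclasses.asdict(c) for d, c in p.groups.items()
                    },
                    "offset": dict(p.offset),
                    "scale": dict(p.scale),
                }
                for p in self.protocols
            ],
            "region_baselines": {r: list(v) for r, v in self.region_baselines.items()},
            "covariate_effects": {r: list(v) for r, v in self.covariate_effects.items()},
            "effect_profile": {f"{d}|{m}": v for (d, m), v in self.effect_profile.items()},
            "laterality_shift": {f"{d}|{s}": v for (d, s), v in self.laterality_shift.items()},
            "biotype_profiles": {
                b: [float(x) for x in p] for b, p in self.biotype_profiles.items()
            },
            "biotype_mixing": {d: dict(m) for d, m in self.biotype_mixing.items()},
            "functioning_model": {
                s: {
                    "hc_mean": m.hc_mean,
                    "hc_sd": m.hc_sd,
                    "biotype_shift_sd": dict(m.biotype_shift_sd),
                }
                for s, m in self.functioning_model.items()
            },
            "medication_model": {
                drug: {b: dataclasses.asdict(m) for b, m in per.items()}
                for drug, per in self.medication_model.items()
            },
            "functioning_protocols": list(self.functioning_protocols),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneratorConfig":
        def split_key(key: str) -> tuple[str, str]:
            a, b = key.split("|", 1)
            return a, b

        cfg = cls(
            protocols=[
                ProtocolSpec(
                    protocol_id=p["protocol_id"],
                    groups={
                        d: DiagnosisCell(**c) for d, c in p["groups"].items()
                    },
                    offset=dict(p["offset"]),
                    scale=dict(p["scale"]),
                )
                for p in payload["protocols"]
            ],
            region_baselines={r: tuple(v) for r, v in payload["region_baselines"].items()},
            covariate_effects={r: tuple(v) for r, v in payload["covariate_effects"].items()},
            effect_profile={split_key(k): v for k, v in payload["effect_profile"].items()},
            laterality_shift={split_key(k): v for k, v in payload["laterality_shift"].items()},
            biotype_profiles={
                b: np.asarray(p, dtype=float) for b, p in payload["biotype_profiles"].items()
            },
            biotype_mixing={d: dict(m) for d, m in payload["biotype_mixing"].items()},
            functioning_model={
                s: FunctioningScaleModel(
                    hc_mean=m["hc_mean"], hc_sd=m["hc_sd"],
                    biotype_shift_sd=dict(m["biotype_shift_sd"]),
                )
                for s, m in payload["functioning_model"].items()
            },
            medication_model={
                drug: {b: DoseModel(**m) for b, m in per.items()}
                for drug, per in payload["medication_model"].items()
            },
            functioning_protocols=list(payload["functioning_protocols"]),
            icv_log_mean=payload.get("icv_log_mean", float(np.log(_ICV_REF))),
            icv_log_sd=payload.get("icv_log_sd", 0.08),
            icv_sex_log_shift=payload.get("icv_sex_log_shift", 0.09),
            seed=payload.get("seed", 0),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for diag, mix in self.biotype_mixing.items():
            total = sum(mix.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"biotype proportions for {diag} sum to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"negative biotype proportion for {diag}")
        for region, (_, sd) in self.region_baselines.items():
            if sd <= 0:
                raise ValueError(f"non-positive baseline SD for {region}")
        for spec in self.protocols:
            if any(s <= 0 for s in spec.scale.values()):
                raise ValueError(f"non-positive protocol scale in {spec.protocol_id}")
        for b, prof in self.biotype_profiles.items():
            if np.asarray(prof).shape != (16,):
                raise ValueError(f"biotype profile {b} must have 16 entries")


@dataclasses.dataclass
class GroundTruth:
    """Latent labels and realized generator parameters for one simulation."""

    subjects: pd.DataFrame  # subject_id, protocol_id, diagnosis, biotype
    effect_profile: dict[tuple[str, str], float]
    laterality_shift: dict[tuple[str, str], float]
    functioning_model: dict[str, FunctioningScaleModel]
    biotype_profiles: dict[str, np.ndarray]
    n_floored_volumes: int = 0

    def biotype_of(self) -> pd.Series:
        return self.subjects.set_index("subject_id")["biotype"]

    def to_json(self, path) -> None:
        payload = {
            "subjects": self.subjects.to_dict(orient="records"),
            "effect_profile": {f"{d}|{m}": v for (d, m), v in self.effect_profile.items()},
            "laterality_shift": {f"{d}|{s}": v for (d, s), v in self.laterality_shift.items()},
            "biotype_profiles": {b: list(map(float, p)) for b, p in self.biotype_profiles.items()},
            "functioning_model": {
                s: {
                    "hc_mean": m.hc_mean,
                    "hc_sd": m.hc_sd,
                    "biotype_shift_sd": dict(m.biotype_shift_sd),
                }
                for s, m in self.functioning_model.items()
            },
            "n_floored_volumes": int(self.n_floored_volumes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _pattern(**structure_d: float) -> dict[str, float]:
    """Expand {structure or 'Left-X'/'Right-X': d} into per-region d values."""
    out: dict[str, float] = {}
    for key, d in structure_d.items():
        name = key.replace("_", "-")
        if name in STRUCTURES:
            out[f"Left-{name}"] = d
            out[f"Right-{name}"] = d
        else:
            out[name] = d
    return out


def _default_effect_profile() -> dict[tuple[str, str], float]:
    """Per-diagnosis Cohen's-d shifts mirroring the published direction
    pattern (magnitudes are generator choices)."""
    profile: dict[str, dict[str, float]] = {
        "SZ": _pattern(
            Lateral_Ventricle=+0.40, Thalamus=-0.30, Caudate=+0.25,
            Putamen=+0.30, Pallidum=+0.40, Hippocampus=-0.45,
            Amygdala=-0.30, Accumbens=-0.30,
        ),
        "BP": _pattern(
            Lateral_Ventricle=+0.30, Hippocampus=-0.30,
            **{"Right-Thalamus": -0.15, "Right-Accumbens": -0.15,
               "Left-Caudate": +0.12, "Right-Caudate": +0.12,
               "Left-Pallidum": +0.12},
        ),
        "MDD": _pattern(
            Lateral_Ventricle=+0.15, Hippocampus=-0.15,
            **{"Right-Thalamus": -0.10, "Right-Accumbens": -0.10},
        ),
        "ASD": _pattern(Lateral_Ventricle=+0.15, Thalamus=-0.10),
    }
    flat = {(diag, region): d for diag, per in profile.items() for region, d in per.items()}
    flat[("SZ", "ICV")] = -0.10
    return flat


def _default_biotype_profiles() -> dict[str, np.ndarray]:
    def vec(**kw: float) -> np.ndarray:
        per = _pattern(**kw)
        return np.array([per.get(r, 0.0) for r in REGIONS])

    # impaired profiles load their signature regions at >= 1.5 z so the
    # planted 4-cluster structure is resolvable by BIC-guided clustering
    return {
        # extreme limbic reduction with ventricular enlargement
        "BB1": vec(Lateral_Ventricle=+2.6, Thalamus=-2.0, Hippocampus=-2.8,
                   Amygdala=-2.8, Accumbens=-2.0),
        # moderate version of the same profile
        "BB2": vec(Lateral_Ventricle=+1.5, Thalamus=-1.5, Hippocampus=-1.6,
                   Amygdala=-1.6, Accumbens=-1.5),
        # basal-ganglia enlargement
        "BB3": vec(Caudate=+2.0, Putamen=+2.0, Pallidum=+2.0),
        # normal volumes
        "BB4": vec(),
    }


_DEFAULT_MIXING: dict[str, dict[str, float]] = {
    "HC": {"BB1": 0.01, "BB2": 0.02, "BB3": 0.02, "BB4": 0.95},
    "SZ": {"BB1": 0.25, "BB2": 0.25, "BB3": 0.20, "BB4": 0.30},
    "BP": {"BB1": 0.12, "BB2": 0.25, "BB3": 0.10, "BB4": 0.53},
    "MDD": {"BB1": 0.08, "BB2": 0.22, "BB3": 0.10, "BB4": 0.60},
    "ASD": {"BB1": 0.05, "BB2": 0.15, "BB3": 0.08, "BB4": 0.72},
}

# Biotype shifts on functioning, HC-SD units, identical across scales. The
# impaired biotypes must sit decisively below the -1 SD normality cutoff so
# that cluster-level means remain below it despite assignment contamination;
# BB1 is severe, BB2/BB3 mild.
_FUNCTIONING_SHIFTS: dict[str, float] = {"BB1": -2.4, "BB2": -1.8, "BB3": -1.6, "BB4": 0.0}

_DEFAULT_MEDICATION: dict[str, dict[str, DoseModel]] = {
    "antipsychotics": {
        "BB1": DoseModel(0.75, 400.0, 0.8), "BB2": DoseModel(0.70, 350.0, 0.8),
        "BB3": DoseModel(0.70, 400.0, 0.8), "BB4": DoseModel(0.15, 150.0, 0.9),
    },
    "antidepressants": {
        "BB1": DoseModel(0.30, 100.0, 0.7), "BB2": DoseModel(0.40, 120.0, 0.7),
        "BB3": DoseModel(0.25, 80.0, 0.7), "BB4": DoseModel(0.12, 60.0, 0.8),
    },
    "lithium": {
        "BB1": DoseModel(0.25, 600.0, 0.5), "BB2": DoseModel(0.30, 600.0, 0.5),
        "BB3": DoseModel(0.20, 600.0, 0.5), "BB4": DoseModel(0.04, 400.0, 0.5),
    },
    "valproate": {
        "BB1": DoseModel(0.30, 600.0, 0.5), "BB2": DoseModel(0.30, 600.0, 0.5),
        "BB3": DoseModel(0.15, 500.0, 0.5), "BB4": DoseModel(0.03, 400.0, 0.5),
    },
}

_DRUG_TO_COLUMN = {
    "antipsychotics": "dose_antipsychotics",
    "antidepressants": "dose_antidepressants",
    "lithium": "dose_lithium",
    "valproate": "dose_valproate",
}


def _region_baselines() -> dict[str, tuple[float, float]]:
    return {
        f"{side}-{s}": _BASELINES[s] for s in STRUCTURES for side in ("Left", "Right")
    }


def _covariate_effects() -> dict[str, tuple[float, float, float]]:
    """(sex, age, ICV) coefficients per region: small direct sex effect, age
    atrophy for tissue / age expansion for ventricles, partial ICV scaling."""
    out: dict[str, tuple[float, float, float]] = {}
    for region, (mean, _) in _region_baselines().items():
        if "Lateral-Ventricle" in region:
            age_coef = +0.025 * mean
        else:
            age_coef = -0.004 * mean
        out[region] = (0.02 * mean, age_coef, 0.4 * mean / _ICV_REF)
    return out


def _protocol_effects(protocol_ids: list[str]) -> dict[str, tuple[dict, dict]]:
    """Deterministic scanner location/scale effects (fixed internal stream so
    the default configs are identical across calls)."""
    rng = np.random.default_rng(20230804)
    baselines = _region_baselines()
    out = {}
    for pid in protocol_ids:
        offset = {r: float(rng.normal(0.0, 0.04 * m)) for r, (m, _) in baselines.items()}
        scale = {r: float(np.exp(rng.normal(0.0, 0.04))) for r in baselines}
        out[pid] = (offset, scale)
    return out


def make_protocols(
    n_protocols: int,
    n_per_diagnosis: Mapping[str, int],
    male_frac: float = 0.5,
    age_mean: float = 40.0,
    age_sd: float = 12.0,
) -> list[ProtocolSpec]:
    """Build a custom homogeneous-demographics protocol list.

    Scanner offsets/scales are drawn from the same fixed internal stream as
    the default configurations, so the result is identical across calls.
    """
    ids = [f"P{i + 1:02d}" for i in range(n_protocols)]
    effects = _protocol_effects(ids)
    cells = {
        diag: DiagnosisCell(n, male_frac, age_mean, age_sd)
        for diag, n in n_per_diagnosis.items()
        if n > 0
    }
    return [
        ProtocolSpec(pid, dict(cells), offset=effects[pid][0], scale=effects[pid][1])
        for pid in ids
    ]


def default_config(scale: str = "toy", seed: int = 0) -> GeneratorConfig:
    """Build a fully specified generator configuration.

    ``"toy"`` gives 4 protocols of ~50 subjects each with functioning
    collected everywhere (fast, self-contained exercises); ``"paper-like"``
    reproduces the published 30-protocol cohort bookkeeping with functioning
    and medications collected at the three Osaka protocols only.
    """
    if scale == "toy":
        cells = {
            "HC": DiagnosisCell(20, 0.5, 35.0, 12.0),
            "SZ": DiagnosisCell(12, 0.5, 36.0, 12.0),
            "BP": DiagnosisCell(6, 0.5, 42.0, 13.0),
            "MDD": DiagnosisCell(8, 0.5, 44.0, 13.0),
            "ASD": DiagnosisCell(4, 0.8, 30.0, 9.0),
        }
        table = {f"Site-{i}": dict(cells) for i in range(1, 5)}
        functioning_protocols = list(table)
    elif scale == "paper-like":
        table = {
            pid: {
                diag: DiagnosisCell(n, m / n, age_mean, age_sd)
                for diag, (n, m, age_mean, age_sd) in groups.items()
            }
            for pid, groups in TABLE1_DEMOGRAPHICS.items()
        }
        functioning_protocols = ["Osaka A", "Osaka B", "Osaka C"]
    else:
        raise ValueError(f"unknown scale {scale!r}; use 'toy' or 'paper-like'")

    effects = _protocol_effects(list(table))
    protocols = [
        ProtocolSpec(pid, groups, offset=effects[pid][0], scale=effects[pid][1])
        for pid, groups in table.items()
    ]
    functioning_model = {
        name: FunctioningScaleModel(mean, sd, dict(_FUNCTIONING_SHIFTS))
        for name, (mean, sd) in HC_FUNCTIONING_REFERENCE.items()
    }
    cfg = GeneratorConfig(
        protocols=protocols,
        region_baselines=_region_baselines(),
        covariate_effects=_covariate_effects(),
        effect_profile=_default_effect_profile(),
        laterality_shift={("SZ", "Pallidum"): +0.03},
        biotype_profiles=_default_biotype_profiles(),
        biotype_mixing={d: dict(_DEFAULT_MIXING[d]) for d in DIAGNOSES},
        functioning_model=functioning_model,
        medication_model={d: dict(m) for d, m in _DEFAULT_MEDICATION.items()},
        functioning_protocols=functioning_protocols,
        seed=seed,
    )
    cfg.validate()
    return cfg


def simulate_cohort(config: GeneratorConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort (volumes, covariates, functioning, doses) plus ground truth.

    Volumes are generated per subject as

        scale_p * (baseline + covariate terms + d_diag * SD + z_biotype * SD
                   + Gaussian noise) + offset_p,

    after which any configured laterality shift is applied by transferring
    volume between hemispheres at fixed structure total. Identical seeds give
    byte-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    biotype_names = list(config.biotype_profiles)
    frames: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    n_floored = 0

    for spec in config.protocols:
        for diag in DIAGNOSES:
            cell = spec.groups.get(diag)
            if cell is None or cell.n == 0:
                continue
            n = cell.n
            sex = (rng.random(n) < cell.male_frac).astype(float)
            age = np.clip(rng.normal(cell.age_mean, cell.age_sd, n), 15.0, 90.0)
            log_icv = rng.normal(
                config.icv_log_mean + config.icv_sex_log_shift * sex,
                config.icv_log_sd,
            )
            d_icv = config.effect_profile.get((diag, "ICV"), 0.0)
            log_icv = log_icv + d_icv * config.icv_log_sd
            icv = np.exp(log_icv)

            mix = config.biotype_mixing[diag]
            probs = np.array([mix.get(b, 0.0) for b in biotype_names])
            biotype_idx = rng.choice(len(biotype_names), size=n, p=probs / probs.sum())
            biotypes = np.array(biotype_names)[biotype_idx]
            profile_matrix = np.stack(
                [np.asarray(config.biotype_profiles[b], dtype=float) for b in biotype_names]
            )
            z_shift = profile_matrix[biotype_idx]  # n x 16

            vols = np.empty((n, len(REGIONS)))
            for j, region in enumerate(REGIONS):
                mean_r, sd_r = config.region_baselines[region]
                sex_c, age_c, icv_c = config.covariate_effects[region]
                core = (
                    mean_r
                    + sex_c * sex
                    + age_c * (age - _AGE_REF)
                    + icv_c * (icv - _ICV_REF)
                    + config.effect_profile.get((diag, region), 0.0) * sd_r
                    + z_shift[:, j] * sd_r
                    + rng.normal(0.0, sd_r, n)
                )
                vols[:, j] = spec.scale[region] * core + spec.offset[region]

            # laterality shift: within-structure transfer, left+right conserved
            for (shift_diag, structure), delta in config.laterality_shift.items():
                if shift_diag != diag:
                    continue
                li_, ri_ = REGIONS.index(f"Left-{structure}"), REGIONS.index(f"Right-{structure}")
                total = vols[:, li_] + vols[:, ri_]
                li_val = (vols[:, li_] - vols[:, ri_]) / total
                li_val = np.clip(li_val + delta, -1.0, 1.0)
                vols[:, li_] = total * (1.0 + li_val) / 2.0
                vols[:, ri_] = total * (1.0 - li_val) / 2.0

            n_floored += int((vols < 1.0).sum())
            vols = np.maximum(vols, 1.0)

            pid_tag = spec.protocol_id.replace(" ", "_")
            ids = [f"{pid_tag}-{diag}-{i:04d}" for i in range(n)]
            block = pd.DataFrame(
                {
                    "subject_id": ids,
                    "protocol_id": spec.protocol_id,
                    "diagnosis": diag,
                    "sex": sex,
                    "age": age,
                    "ICV": icv,
                }
            )
            for j, region in enumerate(REGIONS):
                block[region] = vols[:, j]

            if spec.protocol_id in config.functioning_protocols:
                hc_adjust = _hc_mean_biotype_shift_from(config)
                for scale_name, model in config.functioning_model.items():
                    base = model.hc_mean - hc_adjust(model) * model.hc_sd
                    shift = np.array(
                        [model.biotype_shift_sd.get(b, 0.0) for b in biotypes]
                    )
                    block[scale_name] = (
                        base + shift * model.hc_sd + rng.normal(0.0, model.hc_sd, n)
                    )

            frames.append(block)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": ids,
                        "protocol_id": spec.protocol_id,
                        "diagnosis": diag,
                        "biotype": biotypes,
                    }
                )
            )

    df = pd.concat(frames, ignore_index=True)
    truth_df = pd.concat(truth_rows, ignore_index=True)
    truth = GroundTruth(
        subjects=truth_df,
        effect_profile=dict(config.effect_profile),
        laterality_shift=dict(config.laterality_shift),
        functioning_model=dict(config.functioning_model),
        biotype_profiles={b: np.asarray(p) for b, p in config.biotype_profiles.items()},
        n_floored_volumes=n_floored,
    )

    doses = simulate_medications(truth, config, rng=rng)
    df = df.merge(doses, on="subject_id", how="left")
    return CohortTable(df), truth


def _hc_mean_biotype_shift_from(config: GeneratorConfig):
    """Per-scale HC-mixture-weighted mean biotype shift, in SD units.

    Subtracted from each scale's base level so the HC *marginal* mean equals
    the configured HC reference exactly despite the small HC leakage into
    impaired biotypes.
    """
    mix = config.biotype_mixing["HC"]

    def adjust(model: FunctioningScaleModel) -> float:
        return sum(mix.get(b, 0.0) * s for b, s in model.biotype_shift_sd.items())

    return adjust


def simulate_medications(
    ground_truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw biotype-dependent daily doses for functioning-site subjects.

    Doses are zero-inflated log-normal; under the defaults the functionally
    normal biotype's distribution is stochastically dominated by the impaired
    ones. Returns a frame with ``subject_id`` and the four dose columns
    (NaN for subjects outside the designated sites).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    subjects = ground_truth.subjects
    at_site = subjects["protocol_id"].isin(config.functioning_protocols).to_numpy()
    n = len(subjects)
    out = pd.DataFrame({"subject_id": subjects["subject_id"]})
    for drug, per_biotype in config.medication_model.items():
        col = _DRUG_TO_COLUMN.get(drug, f"dose_{drug}")
        values = np.full(n, np.nan)
        biotypes = subjects["biotype"].to_numpy()
        treated = rng.random(n)
        noise = rng.normal(0.0, 1.0, n)
        for b, model in per_biotype.items():
            mask = at_site & (biotypes == b)
            dose = np.where(
                treated[mask] < model.p_treated,
                model.median_dose * np.exp(model.log_sd * noise[mask]),
                0.0,
            )
            values[mask] = dose
        out[col] = values
    return out
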