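"""Cohort data model and delimited-text I/O.

A cohort is a flat subject table: one row per subject carrying identity
(``subject_id``), acquisition protocol (``protocol_id``, one scanner +
imaging-protocol combination), a five-level diagnosis label, nuisance
covariates (sex, age, intracranial volume), the 16 FreeSurfer-style
subcortical volumes (left/right lateral ventricle, thalamus, caudate,
putamen, pallidum, hippocampus, amygdala, accumbens) in mm^3, and optional
cognitive/social-functioning scores and daily medication doses that only a
subset of sites collect.

All downstream stages consume :class:`CohortTable`; the region ordering
exposed by :class:`RegionSet` is fixed and shared by every module.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRUCTURES",
    "REGIONS",
    "MEASURES",
    "REGION_PAIRS",
    "DIAGNOSES",
    "PATIENT_GROUPS",
    "FUNCTIONING_SCALES",
    "DOSE_COLUMNS",
    "RegionSet",
    "CohortTable",
    "ValidationReport",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

# Bilateral subcortical structures in fixed order; this order is load-bearing:
# effect tables, z-score columns and cluster centroids all follow it.
STRUCTURES: tuple[str, ...] = (
    "Lateral-Ventricle",
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
)

REGIONS: tuple[str, ...] = tuple(
    f"{side}-{structure}" for structure in STRUCTURES for side in ("Left", "Right")
)
#: The 17 measures modelled in the case-control stage: 16 volumes + ICV.
MEASURES: tuple[str, ...] = REGIONS + ("ICV",)
REGION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (f"Left-{s}", f"Right-{s}") for s in STRUCTURES
)

DIAGNOSES: tuple[str, ...] = ("HC", "SZ", "BP", "MDD", "ASD")
PATIENT_GROUPS: tuple[str, ...] = ("SZ", "BP", "MDD", "ASD")

FUNCTIONING_SCALES: tuple[str, ...] = (
    "FIQ",
    "VC",
    "PO",
    "WM",
    "PS",
    "UPSAB_Financial",
    "UPSAB_Communication",
    "SFS",
    "WHW",
)
DOSE_COLUMNS: tuple[str, ...] = (
    "dose_antipsychotics",
    "dose_antidepressants",
    "dose_lithium",
    "dose_valproate",
)

ID_COLUMNS: tuple[str, ...] = ("subject_id", "protocol_id", "diagnosis")
COVARIATE_COLUMNS: tuple[str, ...] = ("sex", "age")
REQUIRED_COLUMNS: tuple[str, ...] = ID_COLUMNS + COVARIATE_COLUMNS + MEASURES
OPTIONAL_COLUMNS: tuple[str, ...] = FUNCTIONING_SCALES + DOSE_COLUMNS


def _alias_map() -> dict[str, str]:
    """Accepted spellings for measure columns.

    FreeSurfer's aseg table and its common exports disagree on separators
    and suffixes ("Left-Thalamus-Proper", "Left.Lateral.Ventricle",
    "Left_Accumbens_area", "EstimatedTotalIntraCranialVol", ...); all are
    mapped onto the canonical hyphenated names.
    """
    aliases: dict[str, str] = {}
    for canon in MEASURES:
        variants = {canon, canon.replace("-", "."), canon.replace("-", "_")}
        aliases.update({v: canon for v in variants})
    for side in ("Left", "Right"):
        for fs_name, canon_struct in (
            (f"{side}-Thalamus-Proper", f"{side}-Thalamus"),
            (f"{side}-Accumbens-area", f"{side}-Accumbens"),
        ):
            for v in (fs_name, fs_name.replace("-", "."), fs_name.replace("-", "_")):
                aliases[v] = canon_struct
    for v in ("EstimatedTotalIntraCranialVol", "eTIV", "IntraCranialVol", "icv"):
        aliases[v] = "ICV"
    return aliases


COLUMN_ALIASES: dict[str, str] = _alias_map()


class CohortSchemaError(ValueError):
    """A required column is missing or mistyped."""


class CohortValidationError(ValueError):
    """A row violates the cohort invariants (range, label, uniqueness)."""


@dataclasses.dataclass(frozen=True)
class RegionSet:
    """Fixed, ordered set of the 17 measures and the 8 hemisphere pairs."""

    names: tuple[str, ...] = MEASURES
    pairs: tuple[tuple[str, str], ...] = REGION_PAIRS

    @property
    def volumes(self) -> tuple[str, ...]:
        """The 16 bilateral volume names (ICV excluded)."""
        return tuple(n for n in self.names if n != "ICV")

    def __post_init__(self) -> None:
        if len(self.pairs) != 8 or len(self.names) != 17:
            raise ValueError("region set must hold 8 L/R pairs plus ICV")
        lefts = {l for l, _ in self.pairs}
        rights = {r for _, r in self.pairs}
        if len(lefts) != 8 or len(rights) != 8:
            raise ValueError("hemisphere pairs must be unique")


@dataclasses.dataclass
class ValidationReport:
    ok: bool
    issues: list[str] = dataclasses.field(default_factory=list)
    protocols_below_hc_minimum: list[str] = dataclasses.field(default_factory=list)
    duplicate_subject_ids: list[str] = dataclasses.field(default_factory=list)


class CohortTable:
    """Validated per-subject table plus the shared region set.

    Thin wrapper around a :class:`pandas.DataFrame`; the frame is exposed as
    ``.df`` and uses canonical column names and a RangeIndex in file order.
    """

    def __init__(self, df: pd.DataFrame, region_set: RegionSet | None = None):
        self.region_set = region_set or RegionSet()
        self.df = _validate_frame(df.reset_index(drop=True), self.region_set)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        if set(self.df.columns) != set(other.df.columns):
            return False
        return self.df.equals(other.df[self.df.columns])

    @property
    def has_functioning(self) -> bool:
        return any(c in self.df.columns for c in FUNCTIONING_SCALES)

    @property
    def has_medications(self) -> bool:
        return any(c in self.df.columns for c in DOSE_COLUMNS)

    def protocols(self) -> list[str]:
        return list(pd.unique(self.df["protocol_id"]))

    def subset(self, mask: Sequence[bool] | pd.Series) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask)].copy(), self.region_set)


def _validate_frame(df: pd.DataFrame, region_set: RegionSet) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CohortSchemaError(f"missing required column: {col!r}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["protocol_id"] = df["protocol_id"].astype(str)
    df["diagnosis"] = df["diagnosis"].astype(str)

    bad_dx = sorted(set(df["diagnosis"]) - set(DIAGNOSES))
    if bad_dx:
        raise CohortValidationError(f"unknown diagnosis label(s): {bad_dx}")

    numeric = list(COVARIATE_COLUMNS) + list(region_set.names)
    for col in numeric + [c for c in OPTIONAL_COLUMNS if c in df.columns]:
        # float64 throughout so written/re-read cohorts compare equal
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)

    for col in region_set.names:
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            sid = df.loc[bad[0], "subject_id"]
            raise CohortValidationError(
                f"non-positive volume in column {col!r} for subject {sid!r}"
            )
    if (df["age"] < 0).any():
        sid = df.loc[df.index[df["age"] < 0][0], "subject_id"]
        raise CohortValidationError(f"negative age for subject {sid!r}")
    return df


def read_cohort(path, dialect: str = "csv") -> CohortTable:
    """Read a delimited cohort table.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with a header row.
    dialect : {"csv", "tsv"}
        Field separator convention.

    Returns
    -------
    CohortTable
        Validated cohort; optional functioning/dose columns are kept when
        present, row order is preserved. Header names are canonicalised via
        the documented alias map (e.g. ``Left.Lateral.Ventricle``).
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"subject_id": str, "protocol_id": str},
        float_precision="round_trip",
    )
    df = df.rename(columns=COLUMN_ALIASES)
    keep = [c for c in df.columns if c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    return CohortTable(df[keep])


def write_cohort(cohort: CohortTable, path, dialect: str = "csv") -> None:
    """Write a cohort table; round-trips through :func:`read_cohort`.

    Floats are written with 17 significant digits so that the round trip is
    exact at double precision; missing optional cells are written empty.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    cols = [c for c in REQUIRED_COLUMNS if c in cohort.df.columns] + [
        c for c in OPTIONAL_COLUMNS if c in cohort.df.columns
    ]
    cohort.df[cols].to_csv(path, sep=sep, index=False, float_format="%.17g")


def validate_cohort(cohort: CohortTable, min_hc_per_protocol: int = 1) -> ValidationReport:
    """Report-only checks beyond the hard constructor invariants.

    Flags protocols with fewer healthy controls than the downstream
    normative stage needs, duplicated subject IDs, and out-of-range
    optional values (negative doses). Never raises.
    """
    report = ValidationReport(ok=True)
    df = cohort.df
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        report.duplicate_subject_ids = dupes
        report.issues.append(f"duplicate subject_id values: {dupes}")
    hc_counts = (
        df[df["diagnosis"] == "HC"].groupby("protocol_id").size().reindex(
            cohort.protocols(), fill_value=0
        )
    )
    low = hc_counts[hc_counts < min_hc_per_protocol].index.tolist()
    if low:
        report.protocols_below_hc_minimum = low
        report.issues.append(
            f"protocols below the HC minimum of {min_hc_per_protocol}: {low}"
        )
    for col in DOSE_COLUMNS:
        if col in df.columns and (df[col].dropna() < 0).any():
            report.issues.append(f"negative values in {col}")
    report.ok = not report.issues
    return report
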