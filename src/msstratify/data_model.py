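"""Tabular data model for the stratification pipeline.

Two table kinds flow through the pipeline:

* a per-visit biomarker table (one row per MRI visit, one column per
  volumetric biomarker, raw millilitres or dimensionless z-scores), and
* a per-subject clinical table (baseline EDSS, long-term ordinal outcomes,
  secondary-progressive transition, therapy code).

Both are thin, validated wrappers around :class:`pandas.DataFrame` so that
every downstream stage can rely on the keying and monotonicity invariants
being checked exactly once, at the boundary.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

KEY_COLUMNS = ("subject_id", "visit_index")
META_COLUMNS = ("subject_id", "visit_index", "years_from_baseline", "age_years", "sex")

#: internal sex coding (documented, arbitrary but fixed)
SEX_CODES = {"F": 0, "M": 1}


class ValidationError(ValueError):
    """A table violates one of the structural invariants."""


@dataclasses.dataclass
class BiomarkerTable:
    """Per-visit biomarker values keyed by ``(subject_id, visit_index)``.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain the meta columns ``subject_id``, ``visit_index``,
        ``years_from_baseline``, ``age_years``, ``sex`` plus at least one
        numeric biomarker column.
    scale : {"raw", "zscore"}
        Table-level marker: raw volumes (mL) or dimensionless z-scores.
    """

    df: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "zscore"):
            raise ValidationError(f"scale must be 'raw' or 'zscore', got {self.scale!r}")
        self.df = _validate_biomarker_frame(self.df)

    # -- accessors ---------------------------------------------------------
    @property
    def biomarkers(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def subjects(self) -> list:
        return list(self.df["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.df)

    def baseline(self) -> "BiomarkerTable":
        """Visit-0 rows only (the training slice)."""
        return BiomarkerTable(self.df[self.df["visit_index"] == 0].copy(), scale=self.scale)

    def values(self, biomarkers: Sequence[str] | None = None) -> np.ndarray:
        """Biomarker matrix (visits x biomarkers), NaN for missing."""
        cols = list(biomarkers) if biomarkers is not None else self.biomarkers
        return self.df[cols].to_numpy(dtype=float)

    def with_values(self, values: np.ndarray, biomarkers: Sequence[str], scale: str) -> "BiomarkerTable":
        out = self.df[list(META_COLUMNS)].copy()
        for j, name in enumerate(biomarkers):
            out[name] = values[:, j]
        return BiomarkerTable(out, scale=scale)


def _validate_biomarker_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    biomarkers = [c for c in df.columns if c not in META_COLUMNS]
    if not biomarkers:
        raise ValidationError("table has no biomarker columns")

    df = df.copy()
    df["visit_index"] = df["visit_index"].astype(int)
    if (df["visit_index"] < 0).any():
        raise ValidationError("visit_index must be >= 0")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        keys = df.loc[dup, list(KEY_COLUMNS)].drop_duplicates().to_records(index=False)
        raise ValidationError(f"duplicate (subject_id, visit_index) keys: {list(keys)[:5]}")

    for col in ("years_from_baseline", "age_years"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"non-numeric value in column {col!r}")
        df[col] = vals.astype(float)

    bad_sex = ~df["sex"].isin(list(SEX_CODES))
    if bad_sex.any():
        raise ValidationError(f"sex must be one of {sorted(SEX_CODES)}; offending rows: {df.index[bad_sex][:5].tolist()}")

    for col in biomarkers:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            raise ValidationError(f"non-numeric biomarker cell in column {col!r}")
        df[col] = coerced.astype(float)

    df = df.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)
    for sid, grp in df.groupby("subject_id", sort=False):
        if 0 not in grp["visit_index"].values:
            raise ValidationError(f"subject {sid!r} has no baseline visit (visit_index 0)")
        t = grp["years_from_baseline"].to_numpy()
        v = grp["visit_index"].to_numpy()
        if t[v == 0][0] != 0.0:
            raise ValidationError(f"subject {sid!r}: years_from_baseline must be 0 at visit_index 0")
        if np.any(np.diff(t) <= 0) and len(t) > 1:
            raise ValidationError(
                f"subject {sid!r}: years_from_baseline must be strictly increasing in visit_index"
            )
        if np.any((t == 0) & (v != 0)):
            raise ValidationError(f"subject {sid!r}: years_from_baseline is 0 at a non-baseline visit")
    return df


@dataclasses.dataclass
class ClinicalTable:
    """Per-subject clinical outcomes.

    ``motor_disability_lt`` and ``cognitive_disability_lt`` are ordinal 0-3;
    ``sp_transition`` is 0/1 (secondary-progressive transition, 1 = SP);
    ``dmt_code`` is 0-3 (0 = no therapy, 1 = interferon, 2 = glatiramer
    acetate, 3 = natalizumab); ``baseline_edss`` runs 0-10 in 0.5 steps.
    Missing long-term outcomes are allowed (NaN).
    """

    df: pd.DataFrame

    REQUIRED = (
        "subject_id",
        "baseline_edss",
        "motor_disability_lt",
        "cognitive_disability_lt",
        "sp_transition",
        "dmt_code",
        "fu_time_years",
    )

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"missing required clinical column {col!r}")
        if df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id in clinical table")
        edss = df["baseline_edss"].dropna()
        if ((edss < 0) | (edss > 10) | ((edss * 2) % 1 != 0)).any():
            raise ValidationError("baseline_edss must lie in 0..10 in 0.5 steps")
        for col in ("motor_disability_lt", "cognitive_disability_lt"):
            vals = df[col].dropna()
            if ~vals.isin([0, 1, 2, 3]).all():
                raise ValidationError(f"{col} levels must be in {{0,1,2,3}}")
        sp = df["sp_transition"].dropna()
        if ~sp.isin([0, 1]).all():
            raise ValidationError("sp_transition must be 0/1")
        dmt = df["dmt_code"].dropna()
        if ~dmt.isin([0, 1, 2, 3]).all():
            raise ValidationError("dmt_code must be in {0,1,2,3} (0 = no therapy)")
        self.df = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_biomarker_table(path, scale: str = "raw", sep: str = ",") -> BiomarkerTable:
    """Read a delimited per-visit biomarker table (UTF-8, '.' decimal).

    Raises :class:`ValidationError` with a descriptive message on duplicate
    keys, a missing baseline visit, non-monotone visit times, or a
    non-numeric biomarker cell.
    """
    df = pd.read_csv(path, sep=sep)
    return BiomarkerTable(df, scale=scale)


def write_biomarker_table(table: BiomarkerTable, path, sep: str = ",") -> None:
    table.df.to_csv(path, sep=sep, index=False)


def read_clinical_table(path, sep: str = ",") -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep=sep))


def write_clinical_table(table: ClinicalTable, path, sep: str = ",") -> None:
    table.df.to_csv(path, sep=sep, index=False)


def merge_assignments(
    biomarkers: BiomarkerTable,
    assignments: pd.DataFrame,
    clinical: ClinicalTable | None = None,
) -> pd.DataFrame:
    """Left-join per-visit subtype/stage assignments and per-subject clinical
    fields onto the visit table.

    The result has exactly one row per biomarker-table visit; visits without
    clinical data keep their biomarker fields with NaN clinical columns.
    Assignments for visit keys absent from the biomarker table raise.
    """
    visits = biomarkers.df
    required = {"subject_id", "visit_index", "ml_subtype", "subtype_probability", "ml_stage", "expected_stage"}
    missing = required - set(assignments.columns)
    if missing:
        raise ValidationError(f"assignment table missing columns: {sorted(missing)}")
    visit_keys = set(map(tuple, visits[["subject_id", "visit_index"]].itertuples(index=False)))
    assign_keys = set(map(tuple, assignments[["subject_id", "visit_index"]].itertuples(index=False)))
    unknown = assign_keys - visit_keys
    if unknown:
        raise ValidationError(f"assignments reference unknown visit keys: {sorted(unknown)[:5]}")

    out = visits.merge(assignments, on=["subject_id", "visit_index"], how="left", validate="one_to_one")
    if clinical is not None:
        if not (set(clinical.df["subject_id"]) & set(visits["subject_id"])):
            warnings.warn("clinical and biomarker tables share no subjects; clinical columns will be empty")
        out = out.merge(clinical.df, on="subject_id", how="left", validate="many_to_one")
    assert len(out) == len(visits), "merge must preserve visit-table row count"
    return out
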