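"""Participant-level cohort tables.

A cohort is a plain :class:`pandas.DataFrame` with one row per participant:

=================  =========================================================
column             contents
=================  =========================================================
participant_id     unique opaque identifier
age                age in years (continuous)
sex, race,
parental_education,
income, scanner    category labels
icv                intracranial volume, mm^3 (optional, > 0)
<outcome...>       any further numeric columns are brain-structure outcomes
=================  =========================================================

:func:`validate_cohort` enforces the schema and :func:`load_cohort` reads and
validates a CSV.
"""

from __future__ import annotations

import pandas as pd

DEMOGRAPHIC_VARIABLES = ["race", "sex", "parental_education", "income"]
REQUIRED_COLUMNS = ["participant_id", "age"] + DEMOGRAPHIC_VARIABLES + ["scanner"]
DEFAULT_AGE_RANGE = (3.0, 18.0)


def outcome_columns(cohort: pd.DataFrame) -> list[str]:
    """Names of the outcome columns (everything beyond the schema columns)."""
    known = set(REQUIRED_COLUMNS) | {"icv"}
    return [c for c in cohort.columns if c not in known]


def validate_cohort(
    cohort: pd.DataFrame,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    vocabulary: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Check schema, age range, id uniqueness and (optionally) category vocabulary.

    Returns the validated frame unchanged; raises ``ValueError`` naming the
    offending column/row otherwise.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing required columns: {missing}")
    if cohort["participant_id"].duplicated().any():
        dupes = cohort.loc[cohort["participant_id"].duplicated(), "participant_id"]
        raise ValueError(f"duplicated participant_id values: {list(dupes[:5])}")
    ages = pd.to_numeric(cohort["age"], errors="coerce")
    if ages.isna().any():
        row = int(ages.index[ages.isna()][0])
        raise ValueError(f"non-numeric age at row {row}")
    lo, hi = age_range
    bad = (ages < lo) | (ages > hi)
    if bad.any():
        row = int(ages.index[bad][0])
        raise ValueError(
            f"age {ages[row]} at row {row} outside configured range [{lo}, {hi}]"
        )
    if vocabulary is not None:
        for var, allowed in vocabulary.items():
            if var not in cohort.columns:
                continue
            unknown = set(cohort[var].astype(str)) - set(allowed)
            if unknown:
                raise ValueError(
                    f"unknown categories for {var!r}: {sorted(unknown)}"
                )
    if "icv" in cohort.columns:
        icv = pd.to_numeric(cohort["icv"], errors="coerce")
        if (icv <= 0).any() or icv.isna().any():
            row = int(icv.index[(icv <= 0) | icv.isna()][0])
            raise ValueError(f"icv must be positive and numeric (row {row})")
    for col in outcome_columns(cohort):
        vals = pd.to_numeric(cohort[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric outcome {col!r} at row {row}")
    return cohort


def load_cohort(
    path,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    vocabulary: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Read a cohort CSV and validate it (see :func:`validate_cohort`)."""
    cohort = pd.read_csv(path, dtype={"participant_id": str, "scanner": str})
    return validate_cohort(cohort, age_range=age_range, vocabulary=vocabulary)
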