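"""Cohort metadata: one row per metagenome sample.

The metadata table follows curatedMetagenomicData-style conventions: string
identifiers for sample, subject, dataset, household and village; parent links
(``mother_id`` / ``father_id``) as subject references; a per-study time axis in
integer days; ``body_site`` restricted to gut or oral. Missing values are empty
fields in TSV and NaN/None in memory.
"""

from __future__ import annotations

import pandas as pd

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "dataset_id",
    "body_site",
    "collection_day",
    "age_years",
    "household_id",
    "village_id",
    "mother_id",
    "father_id",
    "westernized",
]

BODY_SITES = {"gut", "oral"}

_STRING_COLUMNS = [
    "sample_id",
    "subject_id",
    "dataset_id",
    "body_site",
    "household_id",
    "village_id",
    "mother_id",
    "father_id",
]


class MetadataError(ValueError):
    """Raised when a metadata table violates a cohort invariant."""


def load_metadata(path) -> pd.DataFrame:
    """Read a cohort metadata TSV (empty fields = missing) and validate it."""
    df = pd.read_csv(path, sep="\t", dtype={c: "string" for c in _STRING_COLUMNS})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata is missing required columns: {missing}")
    df = df[METADATA_COLUMNS].copy()
    df["collection_day"] = pd.to_numeric(df["collection_day"]).astype("Int64")
    df["age_years"] = pd.to_numeric(df["age_years"])
    if df["westernized"].dtype == object or str(df["westernized"].dtype) == "string":
        df["westernized"] = df["westernized"].map(
            {"True": True, "False": False, "true": True, "false": False}
        )
    validate_metadata(df)
    return df


def save_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_metadata(df: pd.DataFrame) -> None:
    """Check cohort invariants; raise :class:`MetadataError` on violation."""
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MetadataError(f"duplicate sample_id: {dup!r}")
    bad_site = set(df["body_site"].dropna()) - BODY_SITES
    if bad_site:
        raise MetadataError(f"unknown body_site values: {sorted(bad_site)}")
    subjects = set(df["subject_id"].dropna())
    for col in ("mother_id", "father_id"):
        refs = set(df[col].dropna())
        unresolved = refs - subjects
        if unresolved:
            raise MetadataError(
                f"{col} references unknown subjects: {sorted(unresolved)[:5]}"
            )
    if (df["age_years"].dropna() < 0).any():
        raise MetadataError("age_years must be non-negative")
    # every subject with >1 sample needs collection_day on all of them
    counts = df.groupby("subject_id")["sample_id"].transform("count")
    multi = df[counts > 1]
    if multi["collection_day"].isna().any():
        subj = multi.loc[multi["collection_day"].isna(), "subject_id"].iloc[0]
        raise MetadataError(
            f"subject {subj!r} has multiple samples but missing collection_day"
        )


def subject_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Collapse sample metadata to one row per subject.

    Age is the minimum over the subject's samples (age at first sampling);
    identifier columns are taken from the first sample and are assumed
    constant per subject.
    """
    first = samples.sort_values(["subject_id", "collection_day", "sample_id"]).groupby(
        "subject_id", as_index=False
    )
    out = first.agg(
        dataset_id=("dataset_id", "first"),
        body_site=("body_site", "first"),
        household_id=("household_id", "first"),
        village_id=("village_id", "first"),
        mother_id=("mother_id", "first"),
        father_id=("father_id", "first"),
        westernized=("westernized", "first"),
        age_years=("age_years", "min"),
        n_samples=("sample_id", "count"),
    )
    return out
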