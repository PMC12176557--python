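"""Tabular containers and I/O for lesion and clinical records.

A cohort is represented by two tidy tables:

* a **lesion table** with one row per individual lesion (connected
  component) per patient, timepoint and anatomical site, carrying its
  volume in mm^3 and centroid in physical scanner coordinates (mm);
* a **clinical table** in long format with one row per response
  assessment, carrying the RECIST category per assessment week together
  with the patient-level progression-free-survival and enrolment times.

Both are plain :class:`pandas.DataFrame` objects validated against the
schemas below; CSV is the on-disk format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .taxonomy import DEFAULT_TAXONOMY, TIMEPOINTS, SiteTaxonomy

LESION_COLUMNS = [
    "patient_id",
    "timepoint",
    "site_code",
    "lesion_index",
    "volume_mm3",
    "x_mm",
    "y_mm",
    "z_mm",
]

CLINICAL_COLUMNS = ["patient_id", "week", "recist", "pfs_weeks", "enrollment_weeks"]

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")


class ValidationError(ValueError):
    """Raised when a cohort table violates its schema or invariants."""


def validate_lesion_table(
    df: pd.DataFrame, taxonomy: SiteTaxonomy = DEFAULT_TAXONOMY
) -> pd.DataFrame:
    """Validate and normalise a lesion table.

    Enforces column presence and dtypes, taxonomy membership of site
    codes, the timepoint enum, strictly positive volumes, lesion indices
    >= 1, and uniqueness of (patient_id, timepoint, site_code,
    lesion_index). Returns a normalised copy.
    """
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"lesion table missing columns: {missing}")
    out = df.loc[:, LESION_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["timepoint"] = out["timepoint"].astype(str)
    out["site_code"] = out["site_code"].astype(int)
    out["lesion_index"] = out["lesion_index"].astype(int)
    for col in ("volume_mm3", "x_mm", "y_mm", "z_mm"):
        out[col] = out[col].astype(float)

    bad_tp = sorted(set(out["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(f"unknown timepoint(s) {bad_tp}; expected {TIMEPOINTS}")
    bad_codes = sorted({c for c in out["site_code"].unique() if c not in taxonomy})
    if bad_codes:
        raise ValidationError(
            "unknown site code " + ", ".join(str(c) for c in bad_codes)
        )
    if (out["volume_mm3"] <= 0).any():
        raise ValidationError("volume_mm3 must be > 0 for every lesion")
    if (out["lesion_index"] < 1).any():
        raise ValidationError("lesion_index must be >= 1")
    key = ["patient_id", "timepoint", "site_code", "lesion_index"]
    dup = out.duplicated(subset=key)
    if dup.any():
        first = out.loc[dup, key].iloc[0].tolist()
        raise ValidationError(f"duplicate lesion key {tuple(first)}")
    return out.reset_index(drop=True)


def read_lesion_table(path, taxonomy: SiteTaxonomy = DEFAULT_TAXONOMY) -> pd.DataFrame:
    """Read and validate a lesion CSV."""
    return validate_lesion_table(pd.read_csv(path), taxonomy)


def write_lesion_table(df: pd.DataFrame, path) -> None:
    validate_lesion_table(df).to_csv(path, index=False)


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format clinical table.

    Each patient must have strictly increasing assessment weeks including
    a week-4 assessment, RECIST categories in {CR, PR, SD, PD}, and
    positive, per-patient-constant PFS and enrolment times.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    out = df.loc[:, CLINICAL_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["week"] = out["week"].astype(int)
    out["recist"] = out["recist"].astype(str)
    out["pfs_weeks"] = out["pfs_weeks"].astype(float)
    out["enrollment_weeks"] = out["enrollment_weeks"].astype(float)

    bad = sorted(set(out["recist"]) - set(RECIST_CATEGORIES))
    if bad:
        raise ValidationError(f"unknown RECIST category {bad}")
    if (out["pfs_weeks"] <= 0).any() or (out["enrollment_weeks"] <= 0).any():
        raise ValidationError("pfs_weeks and enrollment_weeks must be > 0")
    for pid, grp in out.groupby("patient_id"):
        weeks = grp["week"].to_numpy()
        if not np.all(np.diff(weeks) > 0):
            raise ValidationError(f"assessment weeks not strictly increasing for {pid}")
        if 4 not in weeks:
            raise ValidationError(f"patient {pid} has no week-4 assessment")
        if grp["pfs_weeks"].nunique() != 1 or grp["enrollment_weeks"].nunique() != 1:
            raise ValidationError(f"patient-level times not constant for {pid}")
    return out.reset_index(drop=True)


def read_clinical_table(path) -> pd.DataFrame:
    return validate_clinical_table(pd.read_csv(path))


def write_clinical_table(df: pd.DataFrame, path) -> None:
    validate_clinical_table(df).to_csv(path, index=False)


def site_observations(lesions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate lesions into one observation per (patient, timepoint, site).

    The observation carries the total volume, the lesion count, and the
    site's centre of mass: the volume-weighted mean of the member lesion
    centroids. Volume is conserved exactly (sum of totals equals the sum
    of lesion volumes). An empty table yields an empty result.
    """
    cols = [
        "patient_id",
        "timepoint",
        "site_code",
        "total_volume_mm3",
        "n_lesions",
        "com_x_mm",
        "com_y_mm",
        "com_z_mm",
    ]
    if len(lesions) == 0:
        return pd.DataFrame(columns=cols)
    df = validate_lesion_table(lesions)
    rows = []
    for (pid, tp, code), grp in df.groupby(
        ["patient_id", "timepoint", "site_code"], sort=True
    ):
        v = grp["volume_mm3"].to_numpy()
        xyz = grp[["x_mm", "y_mm", "z_mm"]].to_numpy()
        com = (v[:, None] * xyz).sum(axis=0) / v.sum()
        rows.append((pid, tp, code, float(v.sum()), len(grp), *com))
    return pd.DataFrame(rows, columns=cols)
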