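"""Volumetric tumour burden and treatment-arm response tables.

Total volumetric burden is the sum of all segmented lesion volumes per
patient and timepoint. Relative changes are reported per treatment arm
(t0->t1: four weeks of PARP-inhibitor monotherapy; t1->t2: eight weeks
of combination therapy) and over the whole window (t0->t2), each as
100 x (V_b - V_a) / V_a with the interval's own starting volume as the
denominator (undefined when it is zero). Because the second arm lasts
twice as long, per-week-normalised changes are reported alongside.

An alternative convention normalising both arms by the baseline (t0)
volume — which, unlike the default, can fall below -100% for disease
that grew in arm 1 and vanished in arm 2 — is available via
``denominator='baseline'``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import site_observations, validate_lesion_table
from .taxonomy import DEFAULT_TAXONOMY, TIMEPOINTS

ARM_WEEKS = {"t0_t1": 4.0, "t1_t2": 8.0, "t0_t2": 12.0}


def _change_pct(v_from: float, v_to: float, denom: float) -> float:
    return 100.0 * (v_to - v_from) / denom if denom > 0 else np.nan


def volumetric_summary(
    lesion_df: pd.DataFrame, denominator: str = "interval"
) -> pd.DataFrame:
    """Per-patient volumetric burden, peritoneal fraction, and changes.

    One row per patient with total volume (mm^3) per timepoint (0 when
    the patient has no lesions then), the percentage of burden in
    peritoneal sites (undefined at zero volume), the three relative
    changes, and their per-week-normalised counterparts. ``denominator``
    selects the interval's starting volume ('interval', default) or the
    baseline volume ('baseline') for arm changes.
    """
    if denominator not in ("interval", "baseline"):
        raise ValueError("denominator must be 'interval' or 'baseline'")
    df = validate_lesion_table(lesion_df)
    obs = site_observations(df)
    patients = sorted(df["patient_id"].unique())
    peritoneal = set(DEFAULT_TAXONOMY.codes_in_region("peritoneal"))

    rows = []
    for pid in patients:
        sub = obs[obs["patient_id"] == pid]
        vol = {tp: 0.0 for tp in TIMEPOINTS}
        perit = {tp: np.nan for tp in TIMEPOINTS}
        for tp in TIMEPOINTS:
            s = sub[sub["timepoint"] == tp]
            total = float(s["total_volume_mm3"].sum())
            vol[tp] = total
            if total > 0:
                pv = float(
                    s.loc[s["site_code"].isin(peritoneal), "total_volume_mm3"].sum()
                )
                perit[tp] = 100.0 * pv / total
        denoms = {
            "t0_t1": vol["t0"],
            "t1_t2": vol["t0"] if denominator == "baseline" else vol["t1"],
            "t0_t2": vol["t0"],
        }
        row = {
            "patient_id": pid,
            "volume_t0_mm3": vol["t0"],
            "volume_t1_mm3": vol["t1"],
            "volume_t2_mm3": vol["t2"],
            "peritoneal_pct_t0": perit["t0"],
            "peritoneal_pct_t1": perit["t1"],
            "peritoneal_pct_t2": perit["t2"],
            "change_pct_t0_t1": _change_pct(vol["t0"], vol["t1"], denoms["t0_t1"]),
            "change_pct_t1_t2": _change_pct(vol["t1"], vol["t2"], denoms["t1_t2"]),
            "change_pct_t0_t2": _change_pct(vol["t0"], vol["t2"], denoms["t0_t2"]),
        }
        for key, weeks in ARM_WEEKS.items():
            row[f"change_pct_per_week_{key}"] = row[f"change_pct_{key}"] / weeks
        rows.append(row)
    return pd.DataFrame(rows)


def waterfall_table(summaries: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Waterfall data: week-4 volume change per patient, sorted descending.

    Patients with an undefined t0->t1 change are dropped with a warning.
    Response labels are joined 1:1 on patient id.
    """
    merged = summaries.merge(labels, on="patient_id", how="left", validate="1:1")
    undefined = merged["change_pct_t0_t1"].isna()
    if undefined.any():
        warnings.warn(
            "excluding patient(s) with undefined t0->t1 change: "
            + ", ".join(merged.loc[undefined, "patient_id"])
        )
        merged = merged[~undefined]
    cols = ["patient_id", "change_pct_t0_t1"] + [
        c for c in ("er_4wk", "bor_responder", "lte", "lr", "vol_responder")
        if c in merged.columns
    ]
    out = merged[cols].sort_values(
        ["change_pct_t0_t1", "patient_id"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def scatterpie_table(
    lesion_df: pd.DataFrame, denominator: str = "interval"
) -> pd.DataFrame:
    """Per-patient arm-1 vs arm-2 changes with per-site components.

    One row per (patient, arm, site). ``change_pct_t0_t1`` (x) and
    ``change_pct_t1_t2`` (y) repeat across a patient's rows;
    ``delta_mm3`` is the site's signed volume change over the arm (the
    sites' deltas sum exactly to the patient's total change) and
    ``share`` the site's fraction of the total absolute change, summing
    to 1 per arm. Each site also carries its region so peritoneal vs
    other components can be split. Patients with an undefined change in
    either arm are omitted with a warning.
    """
    df = validate_lesion_table(lesion_df)
    obs = site_observations(df)
    summ = volumetric_summary(df, denominator=denominator)
    rows = []
    skipped = []
    for _, srow in summ.iterrows():
        pid = srow["patient_id"]
        if np.isnan(srow["change_pct_t0_t1"]) or np.isnan(srow["change_pct_t1_t2"]):
            skipped.append(pid)
            continue
        sub = obs[obs["patient_id"] == pid]
        pivot = (
            sub.pivot_table(
                index="site_code", columns="timepoint", values="total_volume_mm3",
                aggfunc="sum", fill_value=0.0,
            )
            .reindex(columns=list(TIMEPOINTS), fill_value=0.0)
        )
        for arm, (a, b) in (("arm1", ("t0", "t1")), ("arm2", ("t1", "t2"))):
            deltas = pivot[b] - pivot[a]
            total_abs = float(deltas.abs().sum())
            for code, delta in deltas.items():
                rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "site_code": int(code),
                        "region": DEFAULT_TAXONOMY.region_of(int(code)),
                        "change_pct_t0_t1": srow["change_pct_t0_t1"],
                        "change_pct_t1_t2": srow["change_pct_t1_t2"],
                        "delta_mm3": float(delta),
                        "share": abs(float(delta)) / total_abs if total_abs > 0 else np.nan,
                    }
                )
    if skipped:
        warnings.warn(
            "excluding patient(s) with undefined arm change: " + ", ".join(skipped)
        )
    return pd.DataFrame(rows)
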