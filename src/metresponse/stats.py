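"""Nonparametric comparison layer for cohort imaging metrics.

Paired longitudinal contrasts use two-sided Wilcoxon signed-rank tests
on complete pairs (patients missing either value — e.g. no lesions left
at a timepoint — are excluded and listed); between-group contrasts use
Kruskal-Wallis (also for two groups); association uses Pearson
correlation. Raw p-values are flagged significant at p <= 0.05 without
multiplicity adjustment; a Benjamini-Hochberg-adjusted column is emitted
alongside for transparency but does not drive the flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .taxonomy import TIMEPOINTS

SIGNIFICANCE_LEVEL = 0.05

TIMEPOINT_PAIRS = (("t0", "t1"), ("t1", "t2"), ("t0", "t2"))


@dataclass
class ComparisonResult:
    metric: str
    test: str
    statistic: float
    p_value: float
    n_used: int
    grouping: str | None = None
    interval: tuple[str, str] | None = None
    excluded_patients: list = field(default_factory=list)
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= SIGNIFICANCE_LEVEL)


def paired_longitudinal_test(
    values_a: pd.Series, values_b: pd.Series, metric: str = "", interval=None
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on per-patient paired values.

    Inputs are Series indexed by patient id; patients missing either
    value are excluded and listed. Zero differences are discarded
    (signed-rank zero-handling); the exact null distribution is used for
    up to 25 informative pairs, the normal approximation beyond. If
    every difference is zero the result is degenerate with p = 1.
    """
    a = pd.Series(values_a).astype(float)
    b = pd.Series(values_b).astype(float)
    patients = sorted(set(a.index) | set(b.index))
    a = a.reindex(patients)
    b = b.reindex(patients)
    complete = a.notna() & b.notna()
    excluded = [p for p in patients if not complete[p]]
    x = a[complete].to_numpy()
    y = b[complete].to_numpy()
    if len(x) < 2:
        raise ValueError("need >= 2 complete pairs")
    d = x - y
    if np.all(d == 0):
        return ComparisonResult(
            metric, "wilcoxon_paired", 0.0, 1.0, len(x), interval=interval,
            excluded_patients=excluded, degenerate=True,
        )
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= 25 and not _has_ties(d) else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return ComparisonResult(
        metric, "wilcoxon_paired", float(res.statistic), float(res.pvalue),
        len(x), interval=interval, excluded_patients=excluded,
    )


def _has_ties(d: np.ndarray) -> bool:
    nz = np.abs(d[d != 0])
    return len(np.unique(nz)) < len(nz)


def group_test(
    values: pd.Series, labels: pd.Series, metric: str = "", grouping: str | None = None
) -> ComparisonResult:
    """Kruskal-Wallis test of a metric between labelled groups.

    ``labels`` may be boolean or categorical with k >= 2 levels; every
    level must be non-empty after dropping patients with missing metric
    values. Identical group distributions give H = 0.
    """
    v = pd.Series(values).astype(float)
    lab = pd.Series(labels)
    patients = sorted(set(v.index) & set(lab.index))
    v = v.reindex(patients)
    lab = lab.reindex(patients)
    keep = v.notna() & lab.notna()
    excluded = [p for p in patients if not keep[p]]
    v, lab = v[keep], lab[keep]
    levels = sorted(lab.unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"need >= 2 groups, got levels {levels}")
    groups = []
    for lev in levels:
        g = v[lab == lev].to_numpy()
        if len(g) == 0:
            raise ValueError(f"empty group {lev!r}")
        groups.append(g)
    if np.ptp(np.concatenate(groups)) == 0:
        # all observations identical: no evidence of a difference
        return ComparisonResult(
            metric, "kruskal_wallis", 0.0, 1.0, len(v), grouping=grouping,
            excluded_patients=excluded, degenerate=True,
        )
    h, p = sps.kruskal(*groups)
    return ComparisonResult(
        metric, "kruskal_wallis", float(h), float(p), len(v),
        grouping=grouping, excluded_patients=excluded,
    )


def correlate(x: pd.Series, y: pd.Series, metric: str = "") -> ComparisonResult:
    """Pearson correlation over complete pairs (>= 3 required).

    Zero variance in either variable leaves r undefined (NaN, flagged
    degenerate) rather than raising.
    """
    xs = pd.Series(x).astype(float)
    ys = pd.Series(y).astype(float)
    patients = sorted(set(xs.index) & set(ys.index))
    xs = xs.reindex(patients)
    ys = ys.reindex(patients)
    keep = xs.notna() & ys.notna()
    excluded = [p for p in patients if not keep[p]]
    xs, ys = xs[keep].to_numpy(), ys[keep].to_numpy()
    if len(xs) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return ComparisonResult(
            metric, "pearson", np.nan, np.nan, len(xs),
            excluded_patients=excluded, degenerate=True,
        )
    r, p = sps.pearsonr(xs, ys)
    return ComparisonResult(
        metric, "pearson", float(r), float(p), len(xs), excluded_patients=excluded
    )


def _result_row(res: ComparisonResult, error: str | None = None) -> dict:
    return {
        "metric": res.metric,
        "test": res.test,
        "grouping": res.grouping,
        "timepoint": None,
        "interval": "->".join(res.interval) if res.interval else None,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n_used": res.n_used,
        "excluded": ";".join(map(str, res.excluded_patients)),
        "degenerate": res.degenerate,
        "significant": res.significant,
        "error": error,
    }


def run_comparison_suite(metrics: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Full comparison table: group tests and paired longitudinal tests.

    ``metrics`` is long format (patient_id, timepoint, metric, value);
    ``labels`` has one row per patient with boolean assessment columns
    (any non-identifier column is treated as an assessment). For every
    metric x assessment x timepoint a Kruskal-Wallis row is produced,
    and for every metric x timepoint pair a Wilcoxon row. Rows that fail
    (e.g. an assessment with a single class) carry an error note and the
    suite continues. A Benjamini-Hochberg column ``p_bh`` is appended;
    the ``significant`` flag remains based on the raw p-value.
    """
    required = {"patient_id", "timepoint", "metric", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    lab = labels.set_index("patient_id")
    assessments = [c for c in lab.columns if c != "patient_id"]
    metric_names = sorted(metrics["metric"].unique())

    rows = []
    for name in metric_names:
        sub = metrics[metrics["metric"] == name]
        by_tp = {
            tp: sub[sub["timepoint"] == tp].set_index("patient_id")["value"]
            for tp in TIMEPOINTS
        }
        for assessment in assessments:
            for tp in TIMEPOINTS:
                try:
                    res = group_test(
                        by_tp[tp], lab[assessment], metric=name, grouping=assessment
                    )
                    row = _result_row(res)
                except Exception as e:  # noqa: BLE001 - suite keeps going per row
                    row = {
                        "metric": name, "test": "kruskal_wallis", "grouping": assessment,
                        "timepoint": tp, "interval": None, "statistic": np.nan,
                        "p_value": np.nan, "n_used": 0, "excluded": "",
                        "degenerate": False, "significant": False, "error": str(e),
                    }
                row["timepoint"] = tp
                rows.append(row)
        for pair in TIMEPOINT_PAIRS:
            try:
                res = paired_longitudinal_test(
                    by_tp[pair[0]], by_tp[pair[1]], metric=name, interval=pair
                )
                row = _result_row(res)
            except Exception as e:  # noqa: BLE001
                row = {
                    "metric": name, "test": "wilcoxon_paired", "grouping": None,
                    "timepoint": None, "interval": "->".join(pair), "statistic": np.nan,
                    "p_value": np.nan, "n_used": 0, "excluded": "",
                    "degenerate": False, "significant": False, "error": str(e),
                }
            rows.append(row)

    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = sps.false_discovery_control(
            out.loc[ok, "p_value"].to_numpy(), method="bh"
        )
    return out


def metrics_long_table(
    dissemination: pd.DataFrame,
    edge_counts: pd.DataFrame | None = None,
    volumetrics: pd.DataFrame | None = None,
    feature_aggregates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the long-format metrics table the suite consumes.

    Pulls n_sites / n_lesions / ratio / distances from the dissemination
    table, edge counts, per-timepoint total volume and peritoneal
    percentage from the volumetric summary (wide -> long), and radiomic
    median/range/sum aggregates when provided. Patients with no disease
    at a timepoint get NaN for per-timepoint volume-derived metrics only
    where undefined (ratio, peritoneal fraction).
    """
    frames = []
    diss = dissemination.rename(columns={
        "total_intersite_distance_mm": "total_distance",
        "max_intersite_distance_mm": "max_distance",
    })
    for m in ("n_sites", "n_lesions", "lesion_site_ratio", "total_distance", "max_distance"):
        frames.append(
            diss[["patient_id", "timepoint", m]]
            .rename(columns={m: "value"})
            .assign(metric=m)
        )
    if edge_counts is not None:
        frames.append(
            edge_counts[["patient_id", "timepoint", "n_edges"]]
            .rename(columns={"n_edges": "value"})
            .assign(metric="edge_count")
        )
    if volumetrics is not None:
        for tp in TIMEPOINTS:
            frames.append(
                volumetrics[["patient_id", f"volume_{tp}_mm3"]]
                .rename(columns={f"volume_{tp}_mm3": "value"})
                .assign(timepoint=tp, metric="total_volume")
            )
            frames.append(
                volumetrics[["patient_id", f"peritoneal_pct_{tp}"]]
                .rename(columns={f"peritoneal_pct_{tp}": "value"})
                .assign(timepoint=tp, metric="peritoneal_pct")
            )
    if feature_aggregates is not None:
        for stat in ("median", "range", "sum"):
            frames.append(
                feature_aggregates[["patient_id", "timepoint", "feature", stat]]
                .rename(columns={stat: "value"})
                .assign(metric=lambda d, s=stat: d["feature"] + "_" + s)
                .drop(columns="feature")
            )
    out = pd.concat(frames, ignore_index=True)
    return out[["patient_id", "timepoint", "metric", "value"]]
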