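"""Cohort summary arithmetic and result-table export helpers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def proportion_pct(count: int, total: int, decimals: int = 0) -> float:
    """Percentage of ``count`` out of ``total``, rounded.

    The rounding convention used for printed cohort summaries (e.g.
    13 of 20 patients -> 65%).
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError("count must be between 0 and total")
    return float(round(100.0 * count / total, decimals))


def cohort_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Responder counts and percentages per assessment column."""
    rows = []
    n = len(labels)
    for col in labels.columns:
        if col == "patient_id":
            continue
        defined = labels[col].notna()
        k = int(labels.loc[defined, col].astype(bool).sum())
        d = int(defined.sum())
        rows.append(
            {
                "assessment": col,
                "n_responders": k,
                "n_defined": d,
                "n_total": n,
                "pct_responders": proportion_pct(k, d) if d else None,
            }
        )
    return pd.DataFrame(rows)


def write_confusion_matrices(matrices: dict, out_dir) -> None:
    """Write (counts, row-percentage) confusion-matrix pairs as CSVs."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    for name, (counts, pct) in matrices.items():
        counts.to_csv(root / f"confusion_{name}_counts.csv")
        pct.to_csv(root / f"confusion_{name}_rowpct.csv")
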