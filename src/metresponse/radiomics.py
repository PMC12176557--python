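"""First-order radiomic heterogeneity features per anatomical site.

Three intensity-histogram features are computed per site ROI (the union
of the site's lesion voxels on the resampled CT grid):

* Energy      = sum_i (X_i + c)^2          on raw (shifted) intensities
* Entropy     = -sum_k p_k log2 p_k        (bits) on discretised bins
* Uniformity  = sum_k p_k^2

Discretisation uses a fixed bin width (default 25 HU) with bin edges
anchored at floor(min / width) x width; the optional shift c (default 0)
only enters Energy. A constant ROI occupies one bin, giving entropy 0
and uniformity 1. Per patient and timepoint, each feature's site values
aggregate into median, range (max - min), and sum; a patient with no
sites at a timepoint has no aggregate (the paired-test exclusion rule
downstream). Feature values are reported raw — their known dependence
on ROI volume is not corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import STUDY_SPACING_MM, IntensityVolume, LabelVolume, resample

FEATURE_NAMES = ("energy", "entropy_bits", "uniformity")

DEFAULT_BIN_WIDTH = 25.0
DEFAULT_SHIFT = 0.0


def discretise(intensities, bin_width: float = DEFAULT_BIN_WIDTH):
    """Fixed-bin-width histogram of ROI intensities.

    Bins are anchored at floor(min / width) x width so the bin structure
    is shift-covariant: adding an exact multiple of the width to every
    value relabels bins without changing counts. Returns (counts,
    probabilities, edges); probabilities sum to 1.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo = np.floor(x.min() / bin_width) * bin_width
    n_bins = max(1, int(np.floor((x.max() - lo) / bin_width)) + 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.minimum(((x - lo) / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts, counts / x.size, edges


def first_order_features(
    intensities,
    bin_width: float = DEFAULT_BIN_WIDTH,
    shift: float = DEFAULT_SHIFT,
) -> dict:
    """Energy, entropy (bits) and uniformity of one ROI."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    if shift < 0:
        raise ValueError("shift must be >= 0")
    _, p, _ = discretise(x, bin_width)
    nz = p[p > 0]
    return {
        "energy": float(np.sum((x + shift) ** 2)),
        "entropy_bits": float(-np.sum(nz * np.log2(nz))),
        "uniformity": float(np.sum(nz**2)),
    }


def site_features(
    ct: IntensityVolume,
    mask: LabelVolume,
    patient_id: str,
    timepoint: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
    shift: float = DEFAULT_SHIFT,
    resample_spacing_mm=STUDY_SPACING_MM,
) -> pd.DataFrame:
    """First-order features per site of one CT + mask pair.

    Both volumes are resampled to ``resample_spacing_mm`` first (sinc
    for the CT, nearest neighbour for the mask); pass the volume's own
    spacing to stay on the native grid. One row per occupied site.
    """
    if ct.voxels.shape != mask.voxels.shape:
        raise ValueError("CT and mask grids differ")
    if resample_spacing_mm is not None:
        ct = resample(ct, resample_spacing_mm)
        mask = resample(mask, resample_spacing_mm)
        if ct.voxels.shape != mask.voxels.shape:
            raise ValueError("CT and mask disagree after resampling")
    rows = []
    for code in mask.site_codes_present():
        roi = ct.voxels[mask.voxels == code]
        feats = first_order_features(roi, bin_width, shift)
        rows.append(
            {"patient_id": patient_id, "timepoint": timepoint, "site_code": code, **feats}
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "timepoint", "site_code", *FEATURE_NAMES]
    )


def aggregate_patient(features: pd.DataFrame) -> pd.DataFrame:
    """Median / range / sum of each feature across a patient's sites.

    ``features`` holds per-site rows (site_features output, possibly for
    many patients and timepoints). Returns one row per (patient,
    timepoint, feature). Patients/timepoints with zero sites simply have
    no rows — the caller decides how to handle them (the comparison
    layer excludes such patients from paired tests).
    """
    rows = []
    for (pid, tp), grp in features.groupby(["patient_id", "timepoint"], sort=True):
        for feat in FEATURE_NAMES:
            v = grp[feat].to_numpy(dtype=float)
            rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "feature": feat,
                    "median": float(np.median(v)),
                    "range": float(v.max() - v.min()),
                    "sum": float(v.sum()),
                    "n_sites": len(v),
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "timepoint", "feature", "median", "range", "sum", "n_sites"]
    )


def cohort_features(
    rendered: dict,
    bin_width: float = DEFAULT_BIN_WIDTH,
    shift: float = DEFAULT_SHIFT,
    resample_spacing_mm=STUDY_SPACING_MM,
) -> pd.DataFrame:
    """Per-site features for a rendered cohort.

    ``rendered`` maps (patient_id, timepoint) -> (IntensityVolume,
    LabelVolume), as produced by the synthetic renderer or loaded from
    per-patient NIfTI directories.
    """
    frames = [
        site_features(ct, mask, pid, tp, bin_width, shift, resample_spacing_mm)
        for (pid, tp), (ct, mask) in sorted(rendered.items())
    ]
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "timepoint", "site_code", *FEATURE_NAMES]
        )
    return pd.concat(frames, ignore_index=True)
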