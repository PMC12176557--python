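"""Response stratifications, a simplified RECIST 1.1 evaluator, the
30% volumetric early-response rule, and confusion matrices.

Patients are classified as responder / non-responder under four
assessments:

* ``er_4wk`` — early responder: RECIST complete or partial response at
  the week-4 assessment;
* ``bor_responder`` — best overall response: CR or PR at any assessment;
* ``lte`` — long-term enrollee: enrolment time strictly over one year
  (52 weeks);
* ``lr`` — long responder: progression-free survival strictly over nine
  months (39 weeks);

plus the volume-based early call ``vol_responder``: total tumour volume
decreased by at least 30% between baseline and week 4 (inclusive at
exactly -30%, mirroring the 30% diameter rule it is modelled on);
undefined when the baseline volume is zero.

The RECIST evaluator covers target-lesion selection (max five lesions,
max two per organ, nodal short axis > 15 mm) and the CR/PR/SD/PD rules
on diameter sums. The PD rule (+20% versus the smallest sum on study and
an absolute +5 mm increase) is the standard RECIST 1.1 criterion,
imported here for completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import validate_clinical_table

RESPONSE_ASSESSMENTS = ("er_4wk", "bor_responder", "lte", "lr")

PFS_CUTOFF_WEEKS = 39.0  # nine months
ENROLLMENT_CUTOFF_WEEKS = 52.0  # one year
VOLUME_RESPONSE_CUTOFF_PCT = -30.0


@dataclass(frozen=True)
class LesionMeasurement:
    """One measurable lesion candidate for RECIST target selection."""

    lesion_id: str
    organ: str
    longest_diameter_mm: float
    is_node: bool = False
    short_axis_mm: float | None = None


@dataclass
class TargetLesionSet:
    lesions: list[LesionMeasurement] = field(default_factory=list)

    def __post_init__(self):
        if len(self.lesions) > 5:
            raise ValueError("at most five target lesions")
        organs = pd.Series([l.organ for l in self.lesions])
        if len(organs) and organs.value_counts().max() > 2:
            raise ValueError("at most two target lesions per organ")
        for l in self.lesions:
            if l.is_node and (l.short_axis_mm is None or l.short_axis_mm <= 15):
                raise ValueError("nodal targets need short axis > 15 mm")

    @property
    def sum_of_diameters_mm(self) -> float:
        return float(sum(l.longest_diameter_mm for l in self.lesions))


def select_target_lesions(candidates: list[LesionMeasurement]) -> TargetLesionSet:
    """Select RECIST 1.1 target lesions.

    Nodes with short axis <= 15 mm are not measurable and are excluded.
    Up to five lesions, at most two per organ, chosen by descending
    diameter but representing all involved organs: each organ's largest
    lesion is seated first, remaining slots then filled by diameter.
    Ties break on the lesion identifier.
    """
    measurable = [
        c
        for c in candidates
        if not c.is_node or (c.short_axis_mm is not None and c.short_axis_mm > 15)
    ]
    by_size = sorted(measurable, key=lambda c: (-c.longest_diameter_mm, c.lesion_id))
    first_of_organ: dict[str, LesionMeasurement] = {}
    for c in by_size:
        first_of_organ.setdefault(c.organ, c)
    # one per organ first (largest organs' representatives by diameter)
    primaries = sorted(
        first_of_organ.values(), key=lambda c: (-c.longest_diameter_mm, c.lesion_id)
    )
    selected = primaries[:5]
    chosen = {c.lesion_id for c in selected}
    per_organ = {c.organ: 1 for c in selected}
    for c in by_size:
        if len(selected) == 5:
            break
        if c.lesion_id in chosen or per_organ.get(c.organ, 0) >= 2:
            continue
        selected.append(c)
        chosen.add(c.lesion_id)
        per_organ[c.organ] = per_organ.get(c.organ, 0) + 1
    selected.sort(key=lambda c: (-c.longest_diameter_mm, c.lesion_id))
    return TargetLesionSet(selected)


def recist_category(
    baseline: TargetLesionSet,
    current_diameters_mm: dict[str, float],
    node_short_axes_mm: dict[str, float] | None = None,
    nadir_sum_mm: float | None = None,
) -> str:
    """RECIST 1.1 category from target-lesion diameters.

    ``current_diameters_mm`` maps lesion_id -> longest diameter (0 =
    disappeared) and must cover the baseline targets exactly. CR: all
    targets gone and every pathological node short axis < 10 mm. PR: sum
    of diameters down at least 30% from baseline. PD: sum up at least
    20% from the smallest sum on study (``nadir_sum_mm``, default the
    baseline sum) with an absolute increase of at least 5 mm. Else SD.
    """
    ids = {l.lesion_id for l in baseline.lesions}
    if set(current_diameters_mm) != ids:
        raise ValueError("current measurements must match baseline targets 1:1")
    base_sum = baseline.sum_of_diameters_mm
    cur_sum = float(sum(current_diameters_mm.values()))
    nadir = base_sum if nadir_sum_mm is None else min(float(nadir_sum_mm), base_sum)

    nodes_ok = all(
        sa < 10.0 for sa in (node_short_axes_mm or {}).values()
    )
    if cur_sum == 0.0 and nodes_ok:
        return "CR"
    if base_sum > 0 and (cur_sum - base_sum) / base_sum <= -0.30:
        return "PR"
    increase = cur_sum - nadir
    if increase >= 5.0 and (nadir == 0 or increase / nadir >= 0.20):
        return "PD"
    return "SD"


def classify_patient(
    clinical: pd.DataFrame, volume_change_pct_t0_t1: float | None
) -> dict:
    """Response labels for one patient from their clinical assessments.

    ``clinical`` holds the patient's rows of the clinical table (one per
    assessment); a week-4 assessment is required. The volumetric label
    is ``None`` when the week-4 volume change is undefined (zero
    baseline volume).
    """
    weeks = clinical["week"].to_numpy()
    if 4 not in weeks:
        raise ValueError("missing week-4 assessment")
    cats = clinical.set_index("week")["recist"]
    responder_cats = {"CR", "PR"}
    er = cats.loc[4] in responder_cats
    bor = bool(cats.isin(responder_cats).any())
    pfs = float(clinical["pfs_weeks"].iloc[0])
    enrol = float(clinical["enrollment_weeks"].iloc[0])
    vol = (
        None
        if volume_change_pct_t0_t1 is None or np.isnan(volume_change_pct_t0_t1)
        else bool(volume_change_pct_t0_t1 <= VOLUME_RESPONSE_CUTOFF_PCT)
    )
    return {
        "er_4wk": bool(er),
        "bor_responder": bor,
        "lr": pfs > PFS_CUTOFF_WEEKS,
        "lte": enrol > ENROLLMENT_CUTOFF_WEEKS,
        "vol_responder": vol,
    }


def classify_cohort(
    clinical_df: pd.DataFrame, volumetric_summary: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Response labels for every patient in a clinical table.

    When a volumetric summary (see :mod:`metresponse.burden`) is given,
    its ``change_pct_t0_t1`` column feeds the volume-based label.
    """
    clinical_df = validate_clinical_table(clinical_df)
    changes = {}
    if volumetric_summary is not None:
        changes = volumetric_summary.set_index("patient_id")["change_pct_t0_t1"].to_dict()
    rows = []
    for pid, grp in clinical_df.groupby("patient_id", sort=True):
        chg = changes.get(pid)
        if chg is not None and np.isnan(chg):
            chg = None
        labels = classify_patient(grp, chg)
        rows.append({"patient_id": pid, **labels})
    return pd.DataFrame(rows)


def confusion_matrix(labels_a: pd.Series, labels_b: pd.Series):
    """2x2 confusion counts and nearest-integer row percentages.

    Both inputs are boolean Series indexed by patient; indices must
    match exactly and entries must be defined. Rows are levels of
    ``labels_a`` (responder first), columns levels of ``labels_b``.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise ValueError("patient sets differ between the two labelings")
    if a.isna().any() or b.isna().any():
        raise ValueError("labels contain undefined entries")
    b = b.reindex(a.index)
    idx = pd.Index([True, False], name="a")
    cols = pd.Index([True, False], name="b")
    counts = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    for av in (True, False):
        for bv in (True, False):
            counts.loc[av, bv] = int(((a == av) & (b == bv)).sum())
    row_sums = counts.sum(axis=1)
    pct = counts.copy().astype(float)
    for av in (True, False):
        if row_sums[av] > 0:
            pct.loc[av] = np.rint(100.0 * counts.loc[av] / row_sums[av]).astype(int)
        else:
            pct.loc[av] = 0
    return counts, pct.astype(int)


def volume_confusion_matrices(labels: pd.DataFrame) -> dict:
    """Confusion matrices of ``vol_responder`` against each assessment.

    Patients with an undefined volumetric label are excluded with a
    warning, mirroring the exclusion of patients without measurable
    baseline volume.
    """
    lab = labels.set_index("patient_id")
    defined = lab["vol_responder"].notna()
    if (~defined).any():
        warnings.warn(
            f"excluding {int((~defined).sum())} patient(s) with undefined "
            "volumetric response from confusion matrices"
        )
        lab = lab.loc[defined]
    out = {}
    for assessment in RESPONSE_ASSESSMENTS:
        out[assessment] = confusion_matrix(
            lab["vol_responder"].astype(bool), lab[assessment].astype(bool)
        )
    return out
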