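"""Synthetic multi-site metastatic cohort generator.

The study data (a 20-patient, 3-timepoint contrast-enhanced CT cohort of
germline BRCA-mutated relapsed ovarian cancer) is licensed and cannot be
shipped, so this module generates cohorts with the statistical structure
the analysis assumes: per-patient metastatic site sets over the 15-code
taxonomy (median 4 sites, range 1-10), per-site lesion counts, baseline
lesion volumes, class- and arm-conditional multiplicative volume changes
(arm 1 = weeks 0-4, PARP-inhibitor monotherapy; arm 2 = weeks 4-12,
combination with an immune checkpoint inhibitor), stochastic site
disappearance, class-conditional progression-free-survival and enrolment
times, and RECIST categories at weeks 4 and 12.

Optionally, lesion tables can be rendered into small NIfTI volume pairs
(CT + site-labelled mask) with ellipsoidal lesions of the requested
volumes and Gaussian ROI texture, so the full imaging path (NIfTI I/O,
resampling, connected components, feature extraction) is exercisable
end-to-end. No attempt is made to simulate realistic CT anatomy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cohort import (
    CLINICAL_COLUMNS,
    LESION_COLUMNS,
    validate_clinical_table,
    validate_lesion_table,
)
from .imaging import IntensityVolume, LabelVolume, save_volume
from .taxonomy import DEFAULT_TAXONOMY

#: Approximate anatomical positions of the 15 sites in a body-centred
#: frame (mm; x right->left, y posterior->anterior, z feet->head). Only
#: the broad geometry matters: peritoneal sites abdominal/pelvic, lymph
#: node stations along the midline, thoracic sites high and lateral.
SITE_CENTERS_MM = {
    2: (-80.0, 40.0, 120.0),   # right upper quadrant
    3: (80.0, 40.0, 120.0),    # left upper quadrant
    5: (0.0, 40.0, 0.0),       # mesentery
    6: (105.0, 0.0, -20.0),    # left paracolic gutter
    7: (-105.0, 0.0, -20.0),   # right paracolic gutter
    9: (0.0, 0.0, -130.0),     # pelvis
    20: (45.0, 85.0, 40.0),    # peritoneum other
    21: (0.0, 70.0, 85.0),     # lesser sac / transverse mesocolon
    13: (0.0, -45.0, 25.0),    # infrarenal abdominal LN
    14: (0.0, -45.0, 95.0),    # suprarenal abdominal LN
    15: (0.0, -40.0, 185.0),   # supradiaphragmatic LN
    16: (25.0, 0.0, 230.0),    # other chest LN
    17: (45.0, 20.0, -185.0),  # inguinal LN
    11: (-115.0, 0.0, 200.0),  # pleura metastases
    19: (95.0, 0.0, 245.0),    # lung metastases
}

#: Default distribution of the number of metastatic sites per patient
#: over 1..10 (median 4, mirroring the study cohort's median of four
#: sites with range 1-10).
DEFAULT_SITES_PER_PATIENT_PROBS = (
    0.06, 0.10, 0.14, 0.25, 0.17, 0.10, 0.07, 0.05, 0.035, 0.025,
)

CLASSES = ("responder", "non_responder")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Volume-change entries are (mean, sigma) of the multiplicative factor
    applied to each site's volume over the arm, drawn independently per
    site and truncated at 0. PFS and enrolment entries are (mu, sigma)
    of a log-normal in weeks. ``site_disappearance_prob`` maps class ->
    (arm-1 prob, arm-2 prob) that a site's disease vanishes entirely.
    """

    n_patients: int = 20
    responder_fraction: float = 0.65
    seed: int = 0
    sites_per_patient_probs: tuple = DEFAULT_SITES_PER_PATIENT_PROBS
    lesions_per_site_poisson_mean: float = 2.5  # lesions = 1 + Poisson(mean)
    max_lesions_per_site: int = 10
    baseline_volume_log_mean: float = float(np.log(800.0))  # mm^3
    baseline_volume_log_sigma: float = 0.8
    volume_floor_mm3: float = 50.0
    volume_cap_mm3: float = 8000.0
    arm1_change: dict = field(
        default_factory=lambda: {"responder": (0.6, 0.1), "non_responder": (1.0, 0.1)}
    )
    arm2_change: dict = field(
        default_factory=lambda: {"responder": (0.55, 0.15), "non_responder": (1.0, 0.15)}
    )
    site_disappearance_prob: dict = field(
        default_factory=lambda: {"responder": (0.08, 0.25), "non_responder": (0.0, 0.03)}
    )
    pfs_weeks: dict = field(
        default_factory=lambda: {
            "responder": (float(np.log(70.0)), 0.4),
            "non_responder": (float(np.log(22.0)), 0.5),
        }
    )
    enrollment_weeks: dict = field(
        default_factory=lambda: {
            "responder": (float(np.log(75.0)), 0.4),
            "non_responder": (float(np.log(30.0)), 0.5),
        }
    )
    recist_week4: dict = field(
        default_factory=lambda: {
            # P(CR, PR, SD, PD) at the week-4 assessment
            "responder": (0.0, 0.35, 0.60, 0.05),
            "non_responder": (0.0, 0.05, 0.70, 0.25),
        }
    )
    recist_week12: dict = field(
        default_factory=lambda: {
            "responder": (0.10, 0.60, 0.25, 0.05),
            "non_responder": (0.0, 0.10, 0.55, 0.35),
        }
    )
    voxel_spacing_mm: tuple = (2.0, 2.0, 2.0)
    texture_mean_hu: float = 60.0
    texture_sigma_hu: float = 20.0
    background_hu: float = -1000.0
    site_center_jitter_mm: float = 15.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        probs = np.asarray(self.sites_per_patient_probs, dtype=float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("sites_per_patient_probs must be a distribution")
        if len(probs) > len(DEFAULT_TAXONOMY.codes):
            raise ValueError("more site slots than taxonomy codes")
        for d in (self.arm1_change, self.arm2_change):
            for cls in CLASSES:
                mean, sigma = d[cls]
                if mean < 0 or sigma < 0:
                    raise ValueError("volume-change parameters must be >= 0")
        for cls in CLASSES:
            for p in self.site_disappearance_prob[cls]:
                if not 0.0 <= p <= 1.0:
                    raise ValueError("site_disappearance_prob must be in [0, 1]")
            for cat_probs in (self.recist_week4[cls], self.recist_week12[cls]):
                arr = np.asarray(cat_probs, dtype=float)
                if arr.min() < 0 or not np.isclose(arr.sum(), 1.0):
                    raise ValueError("RECIST category probabilities must be a distribution")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be > 0")
        if self.texture_sigma_hu < 0:
            raise ValueError("texture_sigma_hu must be >= 0")
        if not 0 < self.volume_floor_mm3 < self.volume_cap_mm3:
            raise ValueError("need 0 < volume_floor_mm3 < volume_cap_mm3")

    def lr_probability(self, cutoff_weeks: float = 39.0) -> float:
        """Configured P(PFS > cutoff) under the class mixture (long-responder rate)."""
        p = 0.0
        for cls, w in (
            ("responder", self.responder_fraction),
            ("non_responder", 1.0 - self.responder_fraction),
        ):
            mu, sigma = self.pfs_weeks[cls]
            p += w * stats.lognorm.sf(cutoff_weeks, s=sigma, scale=np.exp(mu))
        return float(p)


def _lesion_bound_radius_mm(volume_mm3: float) -> float:
    # max semi-axis of the rendered ellipsoid is <= 1.35 x sphere radius
    # (axis log-ratios confined to [log 0.7, log 1.4]); add placement slack
    return 1.35 * (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def generate_cohort(config: CohortConfig):
    """Draw a full synthetic cohort.

    Returns ``(lesion_df, clinical_df, truth_df)``: a validated lesion
    table over the three timepoints, a validated long-format clinical
    table (assessments at weeks 4 and 12), and a ground-truth table with
    each patient's latent responder class and applied volume factors.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    codes = np.array(DEFAULT_TAXONOMY.codes)
    n_site_options = np.arange(1, len(config.sites_per_patient_probs) + 1)

    lesion_rows, clinical_rows, truth_rows = [], [], []
    for i in range(config.n_patients):
        pid = f"SYN{i:03d}"
        responder = bool(rng.random() < config.responder_fraction)
        cls = "responder" if responder else "non_responder"
        n_sites = int(rng.choice(n_site_options, p=config.sites_per_patient_probs))
        sites = rng.choice(codes, size=n_sites, replace=False)

        # geometry: anatomical site centres with patient-specific jitter,
        # lesions placed around them with pairwise clearance so rendered
        # ellipsoids never touch
        placed_centers: list[np.ndarray] = []
        placed_radii: list[float] = []
        margin = 3.0 * max(config.voxel_spacing_mm)

        patient_lesions = []  # (site, lesion_index, centroid, baseline_volume)
        for code in sites:
            center = np.asarray(SITE_CENTERS_MM[int(code)]) + rng.uniform(
                -config.site_center_jitter_mm, config.site_center_jitter_mm, size=3
            )
            n_lesions = 1 + int(rng.poisson(config.lesions_per_site_poisson_mean))
            n_lesions = min(n_lesions, config.max_lesions_per_site)
            for li in range(1, n_lesions + 1):
                vol = float(
                    np.clip(
                        rng.lognormal(
                            config.baseline_volume_log_mean,
                            config.baseline_volume_log_sigma,
                        ),
                        config.volume_floor_mm3,
                        config.volume_cap_mm3,
                    )
                )
                # bound uses the largest volume the lesion can reach over
                # follow-up (factors can exceed 1)
                rmax = _lesion_bound_radius_mm(vol * 2.0)
                spread = 35.0
                pos = None
                for attempt in range(400):
                    cand = center + rng.uniform(-spread, spread, size=3)
                    ok = all(
                        np.linalg.norm(cand - c) >= r + rmax + margin
                        for c, r in zip(placed_centers, placed_radii)
                    )
                    if ok:
                        pos = cand
                        break
                    if attempt % 100 == 99:
                        spread *= 1.5
                if pos is None:
                    raise RuntimeError(f"could not place lesion for {pid} site {code}")
                placed_centers.append(pos)
                placed_radii.append(rmax)
                patient_lesions.append((int(code), li, pos, vol))

        # longitudinal volumes: per-site multiplicative factors per arm
        m1, s1 = config.arm1_change[cls]
        m2, s2 = config.arm2_change[cls]
        p_dis1, p_dis2 = config.site_disappearance_prob[cls]
        site_f1 = {int(c): max(0.0, rng.normal(m1, s1)) for c in sites}
        site_f2 = {int(c): max(0.0, rng.normal(m2, s2)) for c in sites}
        site_gone_t1 = {int(c): rng.random() < p_dis1 for c in sites}
        site_gone_t2 = {
            int(c): site_gone_t1[int(c)] or rng.random() < p_dis2 for c in sites
        }

        min_vol = config.volume_floor_mm3 / 2.0
        for code, li, pos, v0 in patient_lesions:
            vols = {"t0": v0}
            if not site_gone_t1[code]:
                vols["t1"] = v0 * site_f1[code]
            if not site_gone_t2[code] and "t1" in vols:
                vols["t2"] = vols["t1"] * site_f2[code]
            for tp, v in vols.items():
                if v >= min_vol:
                    lesion_rows.append((pid, tp, code, li, v, *pos))

        # clinical outcomes, class-conditional
        mu_p, sg_p = config.pfs_weeks[cls]
        mu_e, sg_e = config.enrollment_weeks[cls]
        pfs = float(rng.lognormal(mu_p, sg_p))
        enrol = float(rng.lognormal(mu_e, sg_e))
        cats = np.array(["CR", "PR", "SD", "PD"])
        rec4 = str(rng.choice(cats, p=config.recist_week4[cls]))
        rec12 = str(rng.choice(cats, p=config.recist_week12[cls]))
        clinical_rows.append((pid, 4, rec4, pfs, enrol))
        clinical_rows.append((pid, 12, rec12, pfs, enrol))

        truth_rows.append(
            (
                pid,
                responder,
                float(np.mean([site_f1[int(c)] for c in sites])),
                float(np.mean([site_f2[int(c)] for c in sites])),
                n_sites,
            )
        )

    lesion_df = validate_lesion_table(pd.DataFrame(lesion_rows, columns=LESION_COLUMNS))
    clinical_df = validate_clinical_table(
        pd.DataFrame(clinical_rows, columns=CLINICAL_COLUMNS)
    )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "responder", "arm1_factor_mean", "arm2_factor_mean", "n_sites"],
    )
    return lesion_df, clinical_df, truth_df


class RenderError(RuntimeError):
    """Raised when lesions cannot be placed on the requested grid."""


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def render_patient_timepoint(
    lesions: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
):
    """Render one patient/timepoint lesion set into a (CT, mask) volume pair.

    Each lesion becomes a compact ellipsoidal blob: the N voxels closest
    to the centroid under a random anisotropic quadratic metric (axis
    ratios within [0.5, 2], random orientation), where N = volume /
    voxel volume rounded; the rendered volume is therefore within half a
    voxel volume of the request. ROI voxels get Gaussian texture, the
    background a distinct constant. Lesions that would overlap another
    site or 26-touch a same-site lesion raise :class:`RenderError`
    listing the offenders.
    """
    spacing = np.asarray(config.voxel_spacing_mm, dtype=float)
    voxvol = float(np.prod(spacing))
    cents = lesions[["x_mm", "y_mm", "z_mm"]].to_numpy()
    vols = lesions["volume_mm3"].to_numpy()
    bounds = np.array([_lesion_bound_radius_mm(v) for v in vols])
    pad = bounds + 4.0 * spacing.max()
    lo = (cents - pad[:, None]).min(axis=0)
    hi = (cents + pad[:, None]).max(axis=0)
    shape = np.maximum(1, np.ceil((hi - lo) / spacing).astype(int))
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = lo

    mask = np.zeros(shape, dtype=np.int32)
    ct = np.full(shape, config.background_hu, dtype=np.float64)
    offenders = []

    order = np.lexsort((lesions["lesion_index"], lesions["site_code"]))
    for row_i in order:
        code = int(lesions["site_code"].iloc[row_i])
        li = int(lesions["lesion_index"].iloc[row_i])
        center = cents[row_i]
        target_n = max(1, int(round(vols[row_i] / voxvol)))

        # anisotropic quadratic metric with bounded axis ratios
        r_sphere = (3.0 * vols[row_i] / (4.0 * np.pi)) ** (1.0 / 3.0)
        logr = rng.uniform(np.log(0.7), np.log(1.4), size=2)
        axes = np.array([1.0, np.exp(logr[0]), np.exp(logr[1])])
        axes = axes / np.prod(axes) ** (1.0 / 3.0) * r_sphere
        rot = _random_rotation(rng)
        metric = rot @ np.diag(1.0 / axes**2) @ rot.T

        half = bounds[row_i] + 2.0 * spacing.max()
        i0 = np.maximum(0, np.floor((center - half - lo) / spacing).astype(int))
        i1 = np.minimum(shape, np.ceil((center + half - lo) / spacing).astype(int))
        grid = np.stack(
            np.meshgrid(
                *[np.arange(a, b) for a, b in zip(i0, i1)], indexing="ij"
            ),
            axis=-1,
        ).reshape(-1, 3)
        pts = grid * spacing + lo - center
        q = np.einsum("ni,ij,nj->n", pts, metric, pts)
        sel = grid[np.lexsort((np.arange(len(q)), q))[:target_n]]

        sub = tuple(sel.T)
        if (mask[sub] != 0).any():
            offenders.append((code, li, "overlaps an existing lesion"))
            continue
        # same-site adjacency check on the local box (26-neighbourhood)
        box = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] == code
        if box.any():
            new = np.zeros(box.shape, dtype=bool)
            new[tuple((sel - i0).T)] = True
            if (ndimage.binary_dilation(new, np.ones((3, 3, 3))) & box).any():
                offenders.append((code, li, "touches a same-site lesion"))
                continue
        mask[sub] = code
        if config.texture_sigma_hu > 0:
            ct[sub] = rng.normal(config.texture_mean_hu, config.texture_sigma_hu, len(sel))
        else:
            ct[sub] = config.texture_mean_hu

    if offenders:
        raise RenderError(f"unplaceable lesions: {offenders}")
    return IntensityVolume(ct, affine), LabelVolume(mask, affine)


def render_volumes(lesion_df: pd.DataFrame, config: CohortConfig) -> dict:
    """Render every (patient, timepoint) in a lesion table.

    Returns ``{(patient_id, timepoint): (IntensityVolume, LabelVolume)}``.
    Deterministic given ``config.seed`` and independent of table order.
    """
    df = validate_lesion_table(lesion_df)
    out = {}
    for (pid, tp), grp in df.groupby(["patient_id", "timepoint"], sort=True):
        key_hash = zlib.crc32(f"{pid}|{tp}".encode())
        rng = np.random.default_rng([config.seed, key_hash])
        out[(pid, tp)] = render_patient_timepoint(grp.reset_index(drop=True), config, rng)
    return out


def write_rendered(rendered: dict, out_dir) -> None:
    """Write rendered volume pairs as ``<out>/<patient>/<timepoint>/{ct,mask}.nii.gz``."""
    from pathlib import Path

    root = Path(out_dir)
    for (pid, tp), (ct, mask) in rendered.items():
        d = root / str(pid) / str(tp)
        d.mkdir(parents=True, exist_ok=True)
        save_volume(ct, d / "ct.nii.gz")
        save_volume(mask, d / "mask.nii.gz")
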