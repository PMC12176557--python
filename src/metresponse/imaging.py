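"""NIfTI ingestion, resampling, and connected-component lesion extraction.

CT intensity volumes and their paired label masks (one integer site code
per segmented voxel, 0 = background) are held as lightweight containers
wrapping a 3D array plus the NIfTI affine. All physical quantities are in
millimetres; voxel indexing is 0-based and never leaks into reported
coordinates, which are always affine-mapped to scanner space.

Resampling follows the feature-extraction pre-processing convention of
the study: intensities with Welch-windowed sinc interpolation, label
masks with nearest neighbour, onto a grid covering the input extent at
the requested spacing (default: the cohort-average voxel size
0.801 x 0.801 x 3.764 mm). Lesions are the maximal 26-connected
components of a site's voxels (connectivity configurable: 6/18/26).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .cohort import LESION_COLUMNS, validate_lesion_table
from .taxonomy import DEFAULT_TAXONOMY, SiteTaxonomy

import pandas as pd

#: Cohort-average voxel size used as the default resampling target (mm).
STUDY_SPACING_MM = (0.801, 0.801, 3.764)


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class IntensityVolume:
    """A 3D CT intensity volume (HU) with its voxel->mm affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spacing_mm(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to physical mm coordinates."""
        ijk = np.atleast_2d(ijk).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class LabelVolume(IntensityVolume):
    """A segmentation mask: 0 = background, site codes elsewhere."""

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(np.int32)
        if (self.voxels < 0).any():
            raise ValueError("label volume must be non-negative")

    def validate_labels(self, taxonomy: SiteTaxonomy = DEFAULT_TAXONOMY) -> None:
        present = np.unique(self.voxels)
        bad = [int(v) for v in present if v != 0 and int(v) not in taxonomy]
        if bad:
            raise ValueError("unknown site code " + ", ".join(str(b) for b in bad))

    def site_codes_present(self) -> list[int]:
        return [int(v) for v in np.unique(self.voxels) if v != 0]


def load_volume(
    path, kind: str = "intensity", taxonomy: SiteTaxonomy = DEFAULT_TAXONOMY
) -> IntensityVolume | LabelVolume:
    """Load a NIfTI-1 file as an intensity or label volume.

    ``kind`` is 'intensity' or 'label'; label volumes are validated
    against the site taxonomy on load.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if kind == "label":
        vol = LabelVolume(np.rint(data).astype(np.int32), img.affine)
        vol.validate_labels(taxonomy)
        return vol
    if kind != "intensity":
        raise ValueError(f"kind must be 'intensity' or 'label', got {kind!r}")
    return IntensityVolume(data.astype(np.float64), img.affine)


def save_volume(volume: IntensityVolume, path) -> None:
    """Write a volume to NIfTI-1 (labels as int16, intensities as float32)."""
    if isinstance(volume, LabelVolume):
        data = volume.voxels.astype(np.int16)
    else:
        data = volume.voxels.astype(np.float32)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


def _to_sitk(volume: IntensityVolume) -> sitk.Image:
    # sitk image index (x,y,z) maps to voxels[i=x, j=y, k=z]
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.T))
    spacing = volume.spacing_mm
    direction = volume.affine[:3, :3] / spacing[None, :]
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in volume.affine[:3, 3]))
    img.SetDirection(tuple(direction.flatten()))
    return img


def resample(
    volume: IntensityVolume | LabelVolume,
    target_spacing_mm=STUDY_SPACING_MM,
) -> IntensityVolume | LabelVolume:
    """Resample a volume to a new spacing.

    Intensity volumes use Welch-windowed sinc interpolation; label
    volumes use nearest neighbour so the label set is preserved. The
    output grid shares the input origin and axis directions and covers
    the full input physical extent.
    """
    target = np.asarray(target_spacing_mm, dtype=float)
    if target.shape != (3,) or (target <= 0).any():
        raise ValueError("target spacing must be 3 strictly positive values")

    is_label = isinstance(volume, LabelVolume)
    src = _to_sitk(
        IntensityVolume(volume.voxels.astype(np.float64), volume.affine)
        if not is_label
        else volume
    )
    in_spacing = volume.spacing_mm
    in_size = np.array(volume.voxels.shape)
    out_size = np.maximum(1, np.ceil(in_size * in_spacing / target - 1e-9).astype(int))

    interp = sitk.sitkNearestNeighbor if is_label else sitk.sitkWelchWindowedSinc
    res = sitk.Resample(
        src,
        [int(s) for s in out_size],
        sitk.Transform(),
        interp,
        src.GetOrigin(),
        tuple(float(s) for s in target),
        src.GetDirection(),
        0.0 if is_label else float(np.min(volume.voxels)),
        sitk.sitkInt32 if is_label else sitk.sitkFloat64,
    )
    out = sitk.GetArrayFromImage(res).T  # back to (i,j,k)
    direction = volume.affine[:3, :3] / in_spacing[None, :]
    new_affine = np.eye(4)
    new_affine[:3, :3] = direction * target[None, :]
    new_affine[:3, 3] = volume.affine[:3, 3]
    cls = LabelVolume if is_label else IntensityVolume
    return cls(out, new_affine)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(
    mask: LabelVolume, site_code: int, connectivity: int = 26
) -> list[np.ndarray]:
    """Split one site's voxels into maximal connected components (lesions).

    Returns a list of (n,3) integer index arrays, ordered by descending
    voxel count with ties broken by the lexicographically smallest voxel
    index, so lesion numbering is independent of discovery order.
    """
    if site_code not in DEFAULT_TAXONOMY:
        raise KeyError(f"unknown site code {site_code}")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    binary = mask.voxels == site_code
    labelled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labelled == lab)
        # argwhere returns indices in C order -> already lexicographically sorted
        comps.append(idx)
    comps.sort(key=lambda a: (-len(a), tuple(a[0])))
    return comps


def lesion_table_from_masks(
    pairs, connectivity: int = 26, taxonomy: SiteTaxonomy = DEFAULT_TAXONOMY
) -> pd.DataFrame:
    """Build a validated lesion table from labelled masks.

    ``pairs`` is an iterable of (patient_id, timepoint, LabelVolume).
    Each connected component becomes one lesion; volume = voxel count x
    voxel volume (mm^3), centroid = mean of member voxel physical
    coordinates. Lesion indices follow the canonical component ordering.
    """
    rows = []
    for patient_id, timepoint, mask in pairs:
        mask.validate_labels(taxonomy)
        voxvol = mask.voxel_volume_mm3
        for code in mask.site_codes_present():
            for li, comp in enumerate(
                connected_components(mask, code, connectivity), start=1
            ):
                centroid = mask.index_to_mm(comp).mean(axis=0)
                rows.append(
                    (
                        str(patient_id),
                        str(timepoint),
                        int(code),
                        li,
                        len(comp) * voxvol,
                        *centroid,
                    )
                )
    df = pd.DataFrame(rows, columns=LESION_COLUMNS)
    return validate_lesion_table(df, taxonomy)
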