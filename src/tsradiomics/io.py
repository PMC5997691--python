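"""Image/mask/table input-output and lesion selection.

Images and masks travel as NIfTI-1 pairs on an identical grid; clinical
covariates and feature tables travel as CSV.  Per patient, at most five
lesions (always including the primary lung lesion) enter the analysis,
mirroring standard measurable-lesion caps.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AlignmentError",
    "EmptyROIError",
    "MissingPrimaryError",
    "SchemaError",
    "ImageVolume",
    "ROIMask",
    "LesionType",
    "LesionRecord",
    "read_lesion",
    "write_lesion",
    "select_lesions",
    "write_feature_table",
    "read_feature_table",
    "read_clinical_table",
    "CLINICAL_COLUMNS",
]

#: tolerance (mm) for declaring two voxel spacings identical
SPACING_ATOL = 1e-4


class AlignmentError(ValueError):
    """Image and mask do not share a voxel grid."""


class EmptyROIError(ValueError):
    """Mask has no foreground voxels."""


class MissingPrimaryError(ValueError):
    """A patient's lesion list has no (or more than one) primary lesion."""


class SchemaError(ValueError):
    """Feature vectors disagree on their key set."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid of CT intensities (HU) with physical geometry.

    Axes are ordered (x, y, z), x fastest-varying; ``spacing`` is the voxel
    edge length along each axis in mm and ``origin`` the physical position of
    voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={v.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite intensities")
        object.__setattr__(self, "voxels", v.astype(np.float64, copy=False))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class ROIMask:
    """Binary segmentation aligned with an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={v.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        v = (v > 0)
        if not v.any():
            raise EmptyROIError("mask has no foreground voxels")
        object.__setattr__(self, "voxels", v)

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


class LesionType(str, enum.Enum):
    PRIMARY = "primary"
    NODE = "node"
    LUNG_MET = "lung_met"
    PLEURAL = "pleural"
    DISTANT = "distant"


@dataclass
class LesionRecord:
    """One segmented lesion of one patient.

    ``size_mm`` is the longest axial diameter as measured at baseline; it
    drives the ranking used by :func:`select_lesions`.  ``image`` may be None
    for clinical-only workflows.
    """

    patient_id: str
    lesion_id: str
    lesion_type: LesionType
    size_mm: float
    image: ImageVolume | None = None
    mask: ROIMask | None = None


def _check_aligned(image: ImageVolume, mask: ROIMask) -> None:
    if image.voxels.shape != mask.voxels.shape:
        raise AlignmentError(
            f"image shape {image.voxels.shape} != mask shape {mask.voxels.shape}"
        )
    if not np.allclose(image.spacing, mask.spacing, atol=SPACING_ATOL, rtol=0.0):
        raise AlignmentError(
            f"image spacing {image.spacing} != mask spacing {mask.spacing}"
        )


def read_lesion(image_path, mask_path) -> tuple[ImageVolume, ROIMask]:
    """Load an aligned NIfTI image/mask pair.

    The mask is binarized at > 0.  Raises :class:`AlignmentError` when the
    grids disagree (shape, or spacing beyond 1e-4 mm) and
    :class:`EmptyROIError` when the mask is empty.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    image = ImageVolume(
        voxels=np.asarray(img.dataobj, dtype=np.float64),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        origin=tuple(float(t) for t in img.affine[:3, 3]),
    )
    mask = ROIMask(
        voxels=np.asarray(msk.dataobj),
        spacing=tuple(float(z) for z in msk.header.get_zooms()[:3]),
        origin=tuple(float(t) for t in msk.affine[:3, 3]),
    )
    _check_aligned(image, mask)
    return image, mask


def write_lesion(image: ImageVolume, mask: ROIMask, image_path, mask_path) -> None:
    """Write an image/mask pair as NIfTI-1 files (diagonal affine)."""
    _check_aligned(image, mask)

    def _affine(spacing, origin):
        a = np.diag(list(spacing) + [1.0])
        a[:3, 3] = origin
        return a

    nib.save(
        nib.Nifti1Image(image.voxels.astype(np.float32), _affine(image.spacing, image.origin)),
        str(image_path),
    )
    nib.save(
        nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing, mask.origin)),
        str(mask_path),
    )


def select_lesions(lesions: Sequence[LesionRecord]) -> list[LesionRecord]:
    """Apply the five-lesion cap: keep the primary plus the largest others.

    Non-primary lesions are ranked by ``size_mm`` descending with a
    deterministic lexicographic ``lesion_id`` tie-break.  Idempotent.
    """
    if not lesions:
        raise ValueError("empty lesion list")
    pids = {l.patient_id for l in lesions}
    if len(pids) != 1:
        raise ValueError(f"lesions span multiple patients: {sorted(pids)}")
    primaries = [l for l in lesions if l.lesion_type == LesionType.PRIMARY]
    if len(primaries) != 1:
        raise MissingPrimaryError(
            f"expected exactly one primary lesion, found {len(primaries)}"
        )
    others = [l for l in lesions if l.lesion_type != LesionType.PRIMARY]
    others.sort(key=lambda l: (-l.size_mm, l.lesion_id))
    return primaries + others[:4]


def write_feature_table(vectors, path) -> pd.DataFrame:
    """Write lesion- or patient-level feature vectors to CSV.

    ``vectors`` maps an id (lesion or patient) to an ordered mapping of
    feature name -> value.  All vectors must share one key set (SchemaError
    otherwise).  Values round-trip at 12 significant digits.
    """
    vectors = dict(vectors)
    if not vectors:
        raise SchemaError("no vectors to write")
    its = iter(vectors.values())
    ref_keys = list(next(its))
    for v in its:
        if list(v) != ref_keys:
            raise SchemaError("feature vectors disagree on feature names/order")
    df = pd.DataFrame.from_dict(
        {k: [v[name] for name in ref_keys] for k, v in vectors.items()},
        orient="index",
        columns=ref_keys,
    )
    df.index.name = "id"
    df.to_csv(path, float_format="%.12g")
    return df


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path, index_col="id")


#: canonical clinical-table columns; optional columns may be absent
CLINICAL_COLUMNS = {
    "required": [
        "patient_id", "age", "sex", "smoking", "egfr", "ts_label",
        "os_time", "os_event", "pfs_time", "pfs_event",
    ],
    "optional": ["suvmax", "opacity"],
}


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate a per-patient clinical covariate CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    for col in ("os_time", "pfs_time"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} contains negative times")
    for col in ("ts_label", "os_event", "pfs_event"):
        if not df[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be binary 0/1")
    return df.set_index("patient_id", drop=False)
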