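"""Volumes, masks and feature tables: domain types and NIfTI/CSV round-trips.

The interchange format is NIfTI-1 for scalar volumes and binary region
masks (voxel-index aligned, no resampling), and plain CSV for per-region
feature tables.  Masks and volumes must live on the same voxel grid; any
registration or resampling happens upstream of this package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .features.names import FEATURE_NAMES

#: Roles a binary region mask can play in the analysis.
MASK_ROLES = ("GTV", "GTVr", "GTVnr", "isodose95")


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing in millimetres.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary real units, e.g. MRI signal).
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm; all positive.
    id : str
        Subject label.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        bad = np.count_nonzero(~np.isfinite(self.data))
        if bad:
            raise ValueError(f"volume contains {bad} non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROIMask:
    """A binary mask on the grid of a companion :class:`ImageVolume`."""

    data: np.ndarray
    role: str = "GTV"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1)) | (np.abs(vals) < 1e-6) | (np.abs(vals - 1) < 1e-6)):
            raise ValueError("mask values must be binary (0/1)")
        self.data = arr.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class FeatureVector:
    """The 47 radiomic features for one region of one subject.

    ``values`` is an ordered mapping with exactly the canonical feature
    names (7 intensity-histogram, 9 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM).
    A feature may be NaN only if ``undefined`` records a reason for it
    (e.g. GLCM correlation on a constant region).
    """

    values: dict[str, float]
    subject_id: str
    roi_role: str
    undefined: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = list(self.values)
        if keys != list(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(keys)
            extra = set(keys) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must carry exactly the 47 canonical features "
                f"in canonical order (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for name, v in self.values.items():
            if not np.isfinite(v) and name not in self.undefined:
                raise ValueError(f"feature {name} is {v} but not flagged undefined")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI-1 scalar volume; spacing is taken from the header."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises ImageFileError subclasses
        raise ValueError(f"{path}: not a readable NIfTI volume ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar volume, got shape {data.shape}")
    bad = int(np.count_nonzero(~np.isfinite(data)))
    if bad:
        raise ValueError(f"{path}: volume contains {bad} NaN/Inf voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = os.path.basename(str(path)).split(".")[0]
    return ImageVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing, id=sid)


def read_mask(path: str | os.PathLike, reference: ImageVolume, role: str = "GTV") -> ROIMask:
    """Read a binary NIfTI mask on the grid of ``reference``.

    Values must be 0/1 within 1e-6; anything else is an error rather than
    being thresholded, so an accidentally-passed probability map fails loudly.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.shape != reference.shape:
        raise ValueError(
            f"{path}: mask shape {data.shape} does not match reference grid {reference.shape}"
        )
    near0 = np.abs(data) < 1e-6
    near1 = np.abs(data - 1.0) < 1e-6
    if not np.all(near0 | near1):
        nbad = int(np.count_nonzero(~(near0 | near1)))
        raise ValueError(f"{path}: mask is not binary ({nbad} voxels outside {{0,1}})")
    return ROIMask(data=near1, role=role)


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with spacing in the header."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: ROIMask, spacing: tuple[float, float, float], path: str | os.PathLike) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_feature_table(rows: list[FeatureVector], path: str | os.PathLike) -> None:
    """Write feature vectors as CSV: subject_id, roi_role, then the 47 features.

    Column order is the canonical Table-1 order so outputs are diffable;
    values are serialized with repr precision so read-back is exact.
    """
    key_sets = {tuple(r.values) for r in rows}
    if len(key_sets) > 1:
        raise ValueError("feature rows have inconsistent key sets")
    records = [
        {"subject_id": r.subject_id, "roi_role": r.roi_role, **r.values} for r in rows
    ]
    df = pd.DataFrame.from_records(records, columns=["subject_id", "roi_role", *FEATURE_NAMES])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature CSV back into a DataFrame (columns validated)."""
    df = pd.read_csv(path)
    expected = ["subject_id", "roi_role", *FEATURE_NAMES]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: unexpected feature table columns")
    return df


def feature_table(rows: list[FeatureVector]) -> pd.DataFrame:
    """In-memory equivalent of :func:`write_feature_table`."""
    records = [
        {"subject_id": r.subject_id, "roi_role": r.roi_role, **r.values} for r in rows
    ]
    return pd.DataFrame.from_records(records, columns=["subject_id", "roi_role", *FEATURE_NAMES])
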