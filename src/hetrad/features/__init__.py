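"""Radiomic feature extraction: 47 features per region of interest.

First-order features are computed on raw (unquantized) intensities; the
four texture families are computed on Lloyd-Max gray levels.
"""

from __future__ import annotations

import numpy as np

from ..io import FeatureVector, ImageVolume
from ..partition import HabitatPair
from ..quantize import lloyd_max_quantize
from .firstorder import FirstOrderStats, first_order_features
from .matrices import (
    DIRECTIONS,
    NGTDM,
    TextureMatrices,
    build_all,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
)
from .names import (
    FAMILY_COUNTS,
    FEATURE_NAMES,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    INTENSITY_FEATURES,
    NGTDM_FEATURES,
)
from .texture import glcm_features, glrlm_features, glszm_features, ngtdm_features

#: Habitats smaller than this cannot support texture statistics.
MIN_HABITAT_VOXELS = 8


class HabitatTooSmallError(ValueError):
    pass


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def extract_roi_features(
    img: ImageVolume,
    mask: np.ndarray,
    subject_id: str,
    roi_role: str,
    ng: int = 256,
) -> FeatureVector:
    """All 47 features for one ROI (mask as boolean array on img's grid)."""
    n_vox = int(np.count_nonzero(mask))
    if n_vox < MIN_HABITAT_VOXELS:
        raise HabitatTooSmallError(
            f"subject {subject_id!r} {roi_role}: {n_vox} voxels < {MIN_HABITAT_VOXELS}"
        )
    bbox = _bounding_box(mask)
    sub_mask = mask[bbox]
    intensities = img.data[bbox][sub_mask]

    fo = first_order_features(intensities)
    q = lloyd_max_quantize(intensities, ng)
    mats = build_all(q.levels, sub_mask, ng)

    values: dict[str, float] = {}
    values.update(fo.as_dict())
    values.update(glcm_features(mats.glcm))
    values.update(glrlm_features(mats.glrlm, mats.n_voxels, mats.n_directions))
    values.update(glszm_features(mats.glszm, mats.n_voxels))
    values.update(ngtdm_features(mats.ngtdm))
    values = {name: values[name] for name in FEATURE_NAMES}

    undefined = dict(fo.undefined)
    if not np.isfinite(values["GLCM_Correlation"]):
        undefined["GLCM_Correlation"] = "single occupied gray level: zero marginal variance"
    return FeatureVector(values=values, subject_id=subject_id, roi_role=roi_role, undefined=undefined)


def extract_all(
    img: ImageVolume, pair: HabitatPair, ng: int = 256
) -> tuple[FeatureVector, FeatureVector]:
    """Feature vectors for the recurrent and non-recurrent habitats."""
    sid = pair.subject_id or img.id
    rec = extract_roi_features(img, pair.recurrent.data, sid, "GTVr", ng)
    nonrec = extract_roi_features(img, pair.nonrecurrent.data, sid, "GTVnr", ng)
    return rec, nonrec


__all__ = [
    "DIRECTIONS",
    "FAMILY_COUNTS",
    "FEATURE_NAMES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "INTENSITY_FEATURES",
    "NGTDM_FEATURES",
    "NGTDM",
    "TextureMatrices",
    "FirstOrderStats",
    "HabitatTooSmallError",
    "MIN_HABITAT_VOXELS",
    "build_all",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_ngtdm",
    "extract_all",
    "extract_roi_features",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]
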