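"""Synthetic paired-habitat phantoms standing in for patient MRI.

Each phantom emulates a contrast-enhanced T1-like head volume: an
ellipsoidal tumor (GTV) on a smooth background, containing a connected
recurrent subregion (GTVr) whose texture statistics differ controllably
from the non-recurrent remainder, plus a 95%-isodose surrogate mask.

The texture model is a Gaussian random field — white noise smoothed with
a per-habitat correlation length — plus a habitat intensity offset.  A
longer correlation length makes a habitat smoother at the voxel scale
(lower marginal variance, lower NGTDM busyness, higher coarseness and
strength), which is the kind of contrast the paired analysis is built to
detect.  Smoothing is applied to unit-variance noise of standard
deviation ``noise_sd`` without re-normalization, so the correlation
length also controls the habitat's marginal variance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageVolume, ROIMask, write_mask, write_volume

#: Scanner-style dynamic range for the synthetic intensities.
INTENSITY_RANGE = (0.0, 4095.0)


@dataclass
class TextureContrast:
    """Controllable difference between the two habitats' textures."""

    intensity_shift: float = 50.0          # added to recurrent-habitat voxels
    correlation_length_rec: float = 2.0    # Gaussian smoothing sigma, voxels
    correlation_length_nonrec: float = 0.8
    noise_sd: float = 120.0                # white-noise SD before smoothing

    def __post_init__(self) -> None:
        if self.correlation_length_rec <= 0 or self.correlation_length_nonrec <= 0:
            raise ValueError("correlation lengths must be > 0")


@dataclass
class PhantomConfig:
    """Cohort-level phantom parameters.

    Defaults are desk-scale: the in-plane spacing and slice thickness
    match a 0.7 x 0.7 x 5 mm reconstruction, while the grid is reduced
    from 512 x 512 x Z to 64 x 64 x 12 to keep a 14-subject cohort fast.
    """

    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (0.7, 0.7, 5.0)
    n_subjects: int = 14
    seed: int = 0
    tumor_radius_vox: float = 12.0         # in-plane ellipsoid semi-axis
    recurrent_fraction: float = 0.3
    texture_contrast: TextureContrast = field(default_factory=TextureContrast)
    infield_overlap: float = 1.0
    tumor_base: float = 1200.0             # tumor intensity plateau
    background: float = 600.0

    def __post_init__(self) -> None:
        if not (0.0 < self.recurrent_fraction < 1.0):
            raise ValueError("recurrent_fraction must be in (0,1)")
        if not (0.0 <= self.infield_overlap <= 1.0):
            raise ValueError("infield_overlap must be in [0,1]")
        if any(s < m for s, m in zip(self.shape, (16, 16, 4))):
            raise ValueError(f"shape {self.shape} below minimum (16,16,4)")

    @property
    def z_radius_vox(self) -> float:
        # keep the tumor roughly isotropic in mm despite thick slices
        return max(3.0, self.tumor_radius_vox * self.spacing[0] / self.spacing[2])


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def _grow_blob(gtv: np.ndarray, seed_vox: np.ndarray, k: int, z_weight: float) -> np.ndarray:
    """The k GTV voxels nearest the seed (anisotropy-weighted distance).

    Nearest-by-distance from an interior point of a convex tumor gives a
    compact, connected blob of exactly k voxels.
    """
    coords = np.argwhere(gtv)
    delta = (coords - seed_vox).astype(float)
    delta[:, 2] *= z_weight
    order = np.argsort(np.einsum("ij,ij->i", delta, delta), kind="stable")
    blob = np.zeros_like(gtv)
    sel = coords[order[:k]]
    blob[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return blob


def generate_phantom(
    config: PhantomConfig, subject_index: int
) -> tuple[ImageVolume, ROIMask, ROIMask, ROIMask]:
    """One subject's volume plus GTV, GTVr and isodose masks.

    Deterministic given (config.seed, subject_index).
    """
    if subject_index >= config.n_subjects:
        raise ValueError("subject_index out of range")
    rng = np.random.default_rng([config.seed % (2**31), subject_index])
    shape = config.shape
    tc = config.texture_contrast

    radii = (config.tumor_radius_vox, config.tumor_radius_vox, config.z_radius_vox)
    lo_ok = all(r + 1 < s / 2 for r, s in zip(radii, shape))
    if not lo_ok:
        raise ValueError(f"tumor radii {radii} do not fit in shape {shape}")
    jitter = rng.uniform(-1.5, 1.5, size=3)
    center = np.array([s / 2 for s in shape]) + jitter
    gtv = _ellipsoid_mask(shape, center, radii)
    n_gtv = int(gtv.sum())

    k = int(round(config.recurrent_fraction * n_gtv))
    if k < 1 or k >= n_gtv:
        raise ValueError(
            f"recurrent_fraction {config.recurrent_fraction} incompatible with "
            f"tumor of {n_gtv} voxels"
        )
    # seed the recurrent blob at ~half-radius from the tumor center
    theta = rng.uniform(0, 2 * np.pi)
    seed_vox = np.round(
        center + 0.5 * np.array([radii[0] * np.cos(theta), radii[1] * np.sin(theta), 0.0])
    ).astype(int)
    seed_vox = np.clip(seed_vox, 0, np.array(shape) - 1)
    if not gtv[tuple(seed_vox)]:  # jitter pushed the seed outside; fall back to center
        seed_vox = np.round(center).astype(int)
    z_weight = config.spacing[2] / config.spacing[0]
    gtvr = _grow_blob(gtv, seed_vox, k, z_weight)

    # Gaussian-random-field textures, one per habitat
    field_rec = ndimage.gaussian_filter(
        rng.normal(0.0, tc.noise_sd, size=shape), tc.correlation_length_rec
    )
    field_nonrec = ndimage.gaussian_filter(
        rng.normal(0.0, tc.noise_sd, size=shape), tc.correlation_length_nonrec
    )
    background = config.background + ndimage.gaussian_filter(
        rng.normal(0.0, 40.0, size=shape), 1.5
    )
    subject_offset = rng.uniform(-50.0, 50.0)  # scanner/session-level shift

    img = background
    nonrec = gtv & ~gtvr
    img[nonrec] = config.tumor_base + subject_offset + field_nonrec[nonrec]
    img[gtvr] = config.tumor_base + subject_offset + tc.intensity_shift + field_rec[gtvr]
    img = np.clip(img, *INTENSITY_RANGE)

    # isodose surrogate: dilated GTV, minus an out-of-field cap of GTVr if requested
    iso = ndimage.binary_dilation(gtv, iterations=2)
    n_out = int(round((1.0 - config.infield_overlap) * k))
    if n_out > 0:
        coords = np.argwhere(gtvr)
        cap = coords[np.argsort(coords[:, 0], kind="stable")[-n_out:]]
        iso[cap[:, 0], cap[:, 1], cap[:, 2]] = False

    sid = f"SUBJ{subject_index + 1:03d}"
    vol = ImageVolume(data=img, spacing=config.spacing, id=sid)
    return (
        vol,
        ROIMask(data=gtv, role="GTV"),
        ROIMask(data=gtvr, role="GTVr"),
        ROIMask(data=iso, role="isodose95"),
    )


def generate_cohort(config: PhantomConfig, outdir: str | os.PathLike) -> pd.DataFrame:
    """Write the cohort as NIfTI quadruples plus a manifest CSV.

    Returns the manifest (subject ids, file names, voxel counts and the
    generating parameters).  Files are uncompressed .nii so repeated runs
    are byte-identical.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    rows = []
    tc = config.texture_contrast
    for idx in range(config.n_subjects):
        vol, gtv, gtvr, iso = generate_phantom(config, idx)
        sid = vol.id
        names = {
            "image": f"{sid}_img.nii",
            "gtv": f"{sid}_gtv.nii",
            "gtvr": f"{sid}_gtvr.nii",
            "isodose95": f"{sid}_iso95.nii",
        }
        write_volume(vol, os.path.join(outdir, names["image"]))
        write_mask(gtv, config.spacing, os.path.join(outdir, names["gtv"]))
        write_mask(gtvr, config.spacing, os.path.join(outdir, names["gtvr"]))
        write_mask(iso, config.spacing, os.path.join(outdir, names["isodose95"]))
        rows.append(
            {
                "subject_id": sid,
                **names,
                "n_gtv": gtv.voxel_count,
                "n_gtvr": gtvr.voxel_count,
                "n_gtvnr": gtv.voxel_count - gtvr.voxel_count,
                "recurrent_fraction": config.recurrent_fraction,
                "intensity_shift": tc.intensity_shift,
                "correlation_length_rec": tc.correlation_length_rec,
                "correlation_length_nonrec": tc.correlation_length_nonrec,
                "noise_sd": tc.noise_sd,
                "infield_overlap": config.infield_overlap,
                "seed": config.seed,
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "image", "gtv", "gtvr", "isodose95",
            "n_gtv", "n_gtvr", "n_gtvnr", "recurrent_fraction",
            "intensity_shift", "correlation_length_rec",
            "correlation_length_nonrec", "noise_sd", "infield_overlap", "seed",
        ],
    )
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest
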