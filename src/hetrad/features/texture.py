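"""Scalar texture features from the GLCM, GLRLM, GLSZM and NGTDM matrices.

GLCM features follow the Haralick-style definitions; GLRLM features the
Galloway/Chu/Dasarathy run-length set; GLSZM features the Thibault
size-zone set (run length replaced by zone size); NGTDM features the
Amadasun–King set with an epsilon guard on the vanishing denominators.
"""

from __future__ import annotations

import numpy as np

from .matrices import NGTDM

#: Guard added to NGTDM denominators that can be exactly zero.
NGTDM_EPS = 1e-6


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Nine co-occurrence features of a normalized symmetric GLCM.

    Correlation is undefined (NaN) when a marginal standard deviation is
    zero (single occupied gray level).
    """
    if P.sum() <= 0:
        raise ValueError("zero GLCM")
    ii, jj = np.nonzero(P)
    p = P[ii, jj]
    i = ii + 1.0
    j = jj + 1.0
    # marginals (P is symmetric so both marginals coincide)
    px = P.sum(axis=1)
    lev = np.arange(1, P.shape[0] + 1, dtype=float)
    mu_x = float(px @ lev)
    var_x = float(px @ (lev - mu_x) ** 2)
    sd_x = np.sqrt(var_x)
    if sd_x > 0:
        correlation = float(np.sum((i - mu_x) * (j - mu_x) * p) / (sd_x * sd_x))
    else:
        correlation = float("nan")
    return {
        "GLCM_Energy": float(np.sum(p**2)),
        "GLCM_Contrast": float(np.sum((i - j) ** 2 * p)),
        "GLCM_Entropy": float(-np.sum(p * np.log2(p))),
        "GLCM_Homogeneity": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "GLCM_Correlation": correlation,
        "GLCM_SumAverage": float(np.sum((i + j) * p)),
        "GLCM_Variation": float(np.sum((i - mu_x) ** 2 * p)),
        "GLCM_Dissimilarity": float(np.sum(np.abs(i - j) * p)),
        "GLCM_AutoCorrelation": float(np.sum(i * j * p)),
    }


def _run_zone_features(M: np.ndarray, n_slots: int, prefix: str, names: tuple[str, ...]) -> dict[str, float]:
    # shared Galloway/Thibault arithmetic: rows = gray level, cols = run length / zone size
    total = M.sum()
    if total <= 0:
        raise ValueError(f"zero {prefix} matrix")
    ii, jj = np.nonzero(M)
    r = M[ii, jj].astype(float)
    i = ii + 1.0
    j = jj + 1.0
    n = float(total)
    p = r / n
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    row_sums = M.sum(axis=1).astype(float)
    col_sums = M.sum(axis=0).astype(float)
    vals = (
        float(np.sum(r / j**2) / n),            # short emphasis
        float(np.sum(r * j**2) / n),            # long emphasis
        float(np.sum(row_sums**2) / n),         # gray-level non-uniformity
        float(np.sum(col_sums**2) / n),         # length/size non-uniformity
        float(n / n_slots),                     # percentage
        float(np.sum(r / i**2) / n),            # low gray-level emphasis
        float(np.sum(r * i**2) / n),            # high gray-level emphasis
        float(np.sum(r / (i**2 * j**2)) / n),   # short+low
        float(np.sum(r * i**2 / j**2) / n),     # short+high
        float(np.sum(r * j**2 / i**2) / n),     # long+low
        float(np.sum(r * i**2 * j**2) / n),     # long+high
        float(np.sum(p * (i - mu_i) ** 2)),     # gray-level variance
        float(np.sum(p * (j - mu_j) ** 2)),     # length/size variance
    )
    return {f"{prefix}_{nm}": v for nm, v in zip(names, vals)}


_GLRLM_ORDER = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV")
_GLSZM_ORDER = ("SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
                "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV")


def glrlm_features(R: np.ndarray, n_voxels: int, n_directions: int = 13) -> dict[str, float]:
    """Thirteen run-length features.  Run percentage is the run count per
    voxel-direction slot (so an ROI of all length-1 runs scores exactly 1)."""
    return _run_zone_features(R, n_voxels * n_directions, "GLRLM", _GLRLM_ORDER)


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Thirteen size-zone features; zone percentage is zones per voxel."""
    return _run_zone_features(Z, n_voxels, "GLSZM", _GLSZM_ORDER)


def ngtdm_features(t: NGTDM) -> dict[str, float]:
    """Amadasun–King coarseness, contrast, busyness, complexity, strength."""
    occ = np.flatnonzero(t.n > 0)
    if occ.size == 0:
        raise ValueError("empty NGTDM")
    p = t.p[occ]
    s = t.s[occ]
    lev = occ + 1.0
    n_vox = t.n_voxels
    ngp = occ.size
    ps = float(np.sum(p * s))
    coarseness = 1.0 / (NGTDM_EPS + ps)
    s_total = float(np.sum(s))
    if ngp > 1:
        di = lev[:, None] - lev[None, :]
        pi = p[:, None]
        pj = p[None, :]
        contrast = (
            float(np.sum(pi * pj * di**2)) / (ngp * (ngp - 1.0))
        ) * (s_total / n_vox)
        busy_den = float(np.sum(np.abs(lev[:, None] * pi - lev[None, :] * pj)))
        busyness = ps / busy_den if busy_den > 0 else 0.0
        si = s[:, None]
        sj = s[None, :]
        complexity = float(
            np.sum(np.abs(di) * (pi * si + pj * sj) / (n_vox * (pi + pj)))
        )
        strength = float(np.sum((pi + pj) * di**2)) / (NGTDM_EPS + s_total)
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "NGTDM_Coarseness": coarseness,
        "NGTDM_Contrast": contrast,
        "NGTDM_Busyness": busyness,
        "NGTDM_Complexity": complexity,
        "NGTDM_Strength": strength,
    }
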