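"""Construction of the four 3D texture matrices (GLCM, GLRLM, GLSZM, NGTDM).

All matrices follow the 3D toolbox convention: 13 unique voxel directions
at Chebyshev distance 1 aggregated into a single matrix per family,
26-connectivity for zones and neighbourhoods, and no correction for
physical voxel anisotropy (texture lives on the voxel grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: The 13 unique 3D offsets at Chebyshev distance 1 (first nonzero step +1).
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NGTDM:
    """Neighbourhood gray-tone difference matrix.

    For every in-mask voxel with at least one in-mask 26-neighbour, the
    absolute difference between its level and the mean level of those
    neighbours is accumulated per gray level.
    """

    s: np.ndarray       # summed absolute neighbourhood difference per level (1..Ng)
    n: np.ndarray       # contributing-voxel count per level
    n_voxels: int       # total contributing voxels

    @property
    def p(self) -> np.ndarray:
        return self.n / self.n_voxels if self.n_voxels else self.n.astype(float)


@dataclass
class TextureMatrices:
    """The four texture matrices of one quantized ROI."""

    glcm: np.ndarray      # Ng x Ng joint probability, symmetric, sums to 1
    glrlm: np.ndarray     # Ng x Rmax run-length counts
    glszm: np.ndarray     # Ng x Zmax zone-size counts
    ngtdm: NGTDM
    n_voxels: int
    n_directions: int


def _levels_volume(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter 1..Ng levels back onto the (cropped) grid; 0 marks outside-ROI."""
    lv = np.zeros(mask.shape, dtype=np.int32)
    lv[mask] = levels
    return lv


def _shifted_views(lv: np.ndarray, d: tuple[int, int, int]):
    src = tuple(
        slice(max(0, -di), s - max(0, di)) for di, s in zip(d, lv.shape)
    )
    dst = tuple(
        slice(max(0, di), s - max(0, -di)) for di, s in zip(d, lv.shape)
    )
    return lv[src], lv[dst]


def build_glcm(
    levels: np.ndarray,
    mask: np.ndarray,
    ng: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS,
) -> np.ndarray:
    """Symmetric gray-level co-occurrence matrix over the given directions.

    Only voxel pairs with both endpoints inside the mask contribute; both
    orderings of each pair are counted (symmetric matrix) and the result
    is normalized to a joint probability.
    """
    lv = _levels_volume(levels, mask)
    counts = np.zeros(ng * ng, dtype=np.int64)
    for d in directions:
        a, b = _shifted_views(lv, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ai = a[valid].astype(np.int64) - 1
        bi = b[valid].astype(np.int64) - 1
        counts += np.bincount(ai * ng + bi, minlength=ng * ng)
        counts += np.bincount(bi * ng + ai, minlength=ng * ng)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid co-occurrence pairs in ROI")
    return (counts / total).reshape(ng, ng)


def build_glrlm(
    levels: np.ndarray,
    mask: np.ndarray,
    ng: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS,
) -> np.ndarray:
    """Gray-level run-length matrix aggregated over the given directions.

    A run is a maximal sequence of collinear in-mask voxels sharing one
    gray level; out-of-mask voxels break runs.  Entry (i, j) counts runs
    of level i+1 and length j+1.
    """
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("empty ROI")
    lv_flat = np.asarray(levels, dtype=np.int64)
    run_levels: list[np.ndarray] = []
    run_lengths: list[np.ndarray] = []
    for d in directions:
        dv = np.array(d)
        ax = int(np.flatnonzero(dv)[0])          # first nonzero component is +1
        t = coords[:, ax]
        base = coords - t[:, None] * dv[None, :]  # line origin (constant per line)
        order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
        ts = t[order]
        bs = base[order]
        gs = lv_flat[order]
        same_line = np.all(bs[1:] == bs[:-1], axis=1)
        contiguous = ts[1:] == ts[:-1] + 1
        same_level = gs[1:] == gs[:-1]
        joined = same_line & contiguous & same_level
        # run starts where the chain to the previous voxel is broken
        starts = np.flatnonzero(np.concatenate(([True], ~joined)))
        ends = np.concatenate((starts[1:], [ts.size]))
        run_levels.append(gs[starts])
        run_lengths.append(ends - starts)
    lev = np.concatenate(run_levels)
    ln = np.concatenate(run_lengths)
    rmax = int(ln.max())
    glrlm = np.zeros((ng, rmax), dtype=np.int64)
    np.add.at(glrlm, (lev - 1, ln - 1), 1)
    return glrlm


def build_glszm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Gray-level size-zone matrix: 26-connected equal-level zones.

    Entry (i, s) counts the zones of level i+1 containing s+1 voxels.
    """
    lv = _levels_volume(levels, mask)
    if not mask.any():
        raise ValueError("empty ROI")
    zone_levels: list[int] = []
    zone_sizes: list[int] = []
    for g in np.unique(levels):
        lab, nlab = ndimage.label(lv == g, structure=_STRUCT26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_levels.extend([int(g)] * nlab)
        zone_sizes.extend(int(s) for s in sizes)
    zmax = max(zone_sizes)
    glszm = np.zeros((ng, zmax), dtype=np.int64)
    np.add.at(glszm, (np.array(zone_levels) - 1, np.array(zone_sizes) - 1), 1)
    return glszm


def build_ngtdm(levels: np.ndarray, mask: np.ndarray, ng: int) -> NGTDM:
    """Neighbourhood gray-tone difference matrix (26-neighbourhood)."""
    lv = _levels_volume(levels, mask).astype(np.float64)
    m = mask.astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    contributing = mask & (nbr_cnt > 0.5)
    if not contributing.any():
        raise ValueError("no voxel has an in-mask neighbour")
    g = lv[contributing].astype(np.int64)
    dev = np.abs(lv[contributing] - nbr_sum[contributing] / nbr_cnt[contributing])
    s = np.zeros(ng)
    np.add.at(s, g - 1, dev)
    n = np.bincount(g - 1, minlength=ng).astype(np.int64)
    return NGTDM(s=s, n=n, n_voxels=int(n.sum()))


def build_all(
    levels: np.ndarray,
    mask: np.ndarray,
    ng: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS,
) -> TextureMatrices:
    return TextureMatrices(
        glcm=build_glcm(levels, mask, ng, directions),
        glrlm=build_glrlm(levels, mask, ng, directions),
        glszm=build_glszm(levels, mask, ng),
        ngtdm=build_ngtdm(levels, mask, ng),
        n_voxels=int(np.count_nonzero(mask)),
        n_directions=len(directions),
    )
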