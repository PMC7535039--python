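"""Shared-scale intensity histograms and Lloyd-Max gray-level quantization.

Texture matrices are computed on gray levels 1..Ng obtained with the
Lloyd-Max scalar quantizer (the MSE-optimal quantizer that alternates
centroid and decision-boundary updates), with Ng = 256 by default to match
the 256-level dynamic range of the source images.  Each habitat is
quantized independently with its own codebook.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageVolume
from .partition import HabitatPair

#: Convergence tolerance on the maximum centroid move per iteration.
DEFAULT_TOL = 1e-8
MAX_ITER = 500


@dataclass
class HistogramPair:
    """Relative-frequency histograms of both habitats on one shared scale."""

    bin_edges: np.ndarray
    density_rec: np.ndarray
    density_nonrec: np.ndarray
    degenerate: bool = False  # constant joint intensity -> single bin


@dataclass
class QuantizedROI:
    """ROI voxel intensities mapped to integer gray levels 1..Ng.

    ``levels`` follows the fixed C scan order of the in-mask voxels.
    ``mse_history`` records the quantizer's mean squared error after each
    Lloyd iteration (non-increasing for well-behaved inputs).
    """

    levels: np.ndarray
    ng: int
    centroids: np.ndarray
    boundaries: np.ndarray
    mse: float
    mse_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.boundaries.size and np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("quantizer boundaries must be strictly increasing")
        if self.levels.size and (self.levels.min() < 1 or self.levels.max() > self.ng):
            raise ValueError("levels out of [1, Ng]")


def paired_histograms(img: ImageVolume, pair: HabitatPair, n_bins: int = 64) -> HistogramPair:
    """Histogram both habitats on one shared intensity scale.

    The shared bin edges span the union of both habitats' intensity ranges
    so the two distributions are directly comparable; each histogram is
    normalized to relative frequencies (sums to 1).
    """
    rec = img.data[pair.recurrent.data]
    nonrec = img.data[pair.nonrecurrent.data]
    if rec.size == 0 or nonrec.size == 0:
        raise ValueError("both habitats must be nonempty")
    lo = min(rec.min(), nonrec.min())
    hi = max(rec.max(), nonrec.max())
    if lo == hi:
        edges = np.array([lo - 0.5, lo + 0.5])
        return HistogramPair(edges, np.array([1.0]), np.array([1.0]), degenerate=True)
    edges = np.linspace(lo, hi, n_bins + 1)
    h_rec, _ = np.histogram(rec, bins=edges)
    h_non, _ = np.histogram(nonrec, bins=edges)
    return HistogramPair(edges, h_rec / rec.size, h_non / nonrec.size)


def _exact_codebook(x: np.ndarray, distinct: np.ndarray, ng: int) -> QuantizedROI:
    # d <= Ng: every distinct value gets its own level, zero error.
    d = distinct.size
    centroids = np.empty(ng)
    centroids[:d] = distinct
    if d < ng:
        span = distinct[-1] - distinct[0]
        step = span / ng if span > 0 else 1.0
        centroids[d:] = distinct[-1] + step * np.arange(1, ng - d + 1)
    boundaries = 0.5 * (centroids[:-1] + centroids[1:])
    levels = np.searchsorted(distinct, x) + 1
    return QuantizedROI(
        levels=levels.astype(np.int32),
        ng=ng,
        centroids=centroids,
        boundaries=boundaries,
        mse=0.0,
        mse_history=np.array([0.0]),
    )


def lloyd_max_quantize(intensities: np.ndarray, ng: int, tol: float = DEFAULT_TOL) -> QuantizedROI:
    """Quantize a real-valued multiset to gray levels 1..Ng by Lloyd-Max.

    Alternate the two optimality conditions — each centroid is the
    conditional mean of its cell, each boundary the midpoint of adjacent
    centroids — until the largest centroid move falls below ``tol`` or 500
    iterations.  Two deterministic initializations are run (Ng equally
    spaced sample quantiles, and the equal-width grid) and the fixed point
    with the lower MSE is kept: the quantile start is robust to skewed
    intensity histograms, while the equal-width start guarantees the
    result is never worse than the equal-width baseline quantizer.  If the
    input has at most Ng distinct values the exact zero-error codebook is
    returned directly.  Cells that empty out during iteration are re-seeded
    by interpolating between their occupied neighbours' centroids, keeping
    the codebook size at Ng.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot quantize an empty ROI")
    if ng < 2:
        raise ValueError("Ng must be >= 2")
    distinct = np.unique(x)
    if distinct.size <= ng:
        return _exact_codebook(x, distinct, ng)

    xs = np.sort(x)
    csum = np.concatenate(([0.0], np.cumsum(xs)))
    eps = max(1e-12, 1e-12 * (xs[-1] - xs[0]))

    def run(init: np.ndarray):
        centroids = np.maximum.accumulate(init + eps * np.arange(ng))
        history: list[float] = []
        best = (np.inf, centroids)
        n = xs.size
        for _ in range(MAX_ITER):
            boundaries = 0.5 * (centroids[:-1] + centroids[1:])
            # cell k holds xs[start[k]:start[k+1]]
            start = np.concatenate(([0], np.searchsorted(xs, boundaries), [n]))
            counts = np.diff(start)
            sums = csum[start[1:]] - csum[start[:-1]]
            new_centroids = centroids.copy()
            occ = counts > 0
            new_centroids[occ] = sums[occ] / counts[occ]
            if not occ.all():
                # re-seed empty cells between their occupied neighbours
                occ_idx = np.flatnonzero(occ)
                new_centroids[~occ] = np.interp(
                    np.flatnonzero(~occ), occ_idx, new_centroids[occ_idx]
                )
                new_centroids = np.maximum.accumulate(new_centroids + eps * np.arange(ng))
            move = np.max(np.abs(new_centroids - centroids))
            centroids = new_centroids
            # MSE under the current codebook (nearest-centroid partition)
            lvl = np.searchsorted(0.5 * (centroids[:-1] + centroids[1:]), xs)
            mse = float(np.mean((xs - centroids[lvl]) ** 2))
            history.append(mse)
            if mse < best[0]:
                best = (mse, centroids)
            if move < tol:
                break
        return best, np.asarray(history)

    # quantile init is robust to skewed data; the equal-width init guarantees
    # the fixed point is no worse than the uniform baseline — keep the better.
    quant_init = np.quantile(xs, (np.arange(ng) + 0.5) / ng)
    width_init = xs[0] + (xs[-1] - xs[0]) * (np.arange(ng) + 0.5) / ng
    (mse_q, cen_q), hist_q = run(quant_init)
    (mse_u, cen_u), hist_u = run(width_init)
    if mse_q <= mse_u:
        mse, centroids, history = mse_q, cen_q, hist_q
    else:
        mse, centroids, history = mse_u, cen_u, hist_u

    boundaries = 0.5 * (centroids[:-1] + centroids[1:])
    levels = (np.searchsorted(boundaries, x) + 1).astype(np.int32)
    return QuantizedROI(
        levels=levels,
        ng=ng,
        centroids=centroids,
        boundaries=boundaries,
        mse=mse,
        mse_history=history,
    )


def quantize_habitats(
    img: ImageVolume, pair: HabitatPair, ng: int = 256, tol: float = DEFAULT_TOL
) -> tuple[QuantizedROI, QuantizedROI]:
    """Quantize each habitat independently with its own Lloyd-Max codebook."""
    rec = img.data[pair.recurrent.data]
    nonrec = img.data[pair.nonrecurrent.data]
    return lloyd_max_quantize(rec, ng, tol), lloyd_max_quantize(nonrec, ng, tol)


def uniform_quantize(intensities: np.ndarray, ng: int) -> np.ndarray:
    """Equal-width baseline quantizer (levels 1..Ng); used for comparison only."""
    x = np.asarray(intensities, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    if lo == hi:
        return np.ones(x.size, dtype=np.int32)
    lvl = np.floor((x - lo) / (hi - lo) * ng).astype(np.int32) + 1
    return np.clip(lvl, 1, ng)


def uniform_quantizer_mse(intensities: np.ndarray, ng: int) -> float:
    """MSE of the equal-width quantizer with mid-bin reconstruction levels."""
    x = np.asarray(intensities, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    width = (hi - lo) / ng
    lvl = uniform_quantize(x, ng)
    recon = lo + (lvl - 0.5) * width
    return float(np.mean((x - recon) ** 2))
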