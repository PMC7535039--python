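"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written naively (explicit Python loops, BFS flood
fill, full sign enumeration) and never shares code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def brute_glcm(lv: np.ndarray, mask: np.ndarray, ng: int, directions) -> np.ndarray:
    """Co-occurrence counts by looping over every voxel and direction."""
    counts = np.zeros((ng, ng), dtype=np.int64)
    nx, ny, nz = mask.shape
    for d in directions:
        for off in (d, tuple(-c for c in d)):
            for x in range(nx):
                for y in range(ny):
                    for z in range(nz):
                        if not mask[x, y, z]:
                            continue
                        u, v, w = x + off[0], y + off[1], z + off[2]
                        if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                            counts[lv[x, y, z] - 1, lv[u, v, w] - 1] += 1
    return counts


def brute_glrlm(lv: np.ndarray, mask: np.ndarray, ng: int, directions) -> np.ndarray:
    """Run counts by walking every line voxel by voxel."""
    nx, ny, nz = mask.shape

    def inside(p):
        return 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz

    runs: list[tuple[int, int]] = []
    for d in directions:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    p = (x, y, z)
                    if not mask[p]:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    # run starts here unless the previous voxel continues it
                    if inside(prev) and mask[prev] and lv[prev] == lv[p]:
                        continue
                    length = 1
                    nxt = (x + d[0], y + d[1], z + d[2])
                    while inside(nxt) and mask[nxt] and lv[nxt] == lv[p]:
                        length += 1
                        nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
                    runs.append((int(lv[p]), length))
    rmax = max(l for _, l in runs)
    R = np.zeros((ng, rmax), dtype=np.int64)
    for g, l in runs:
        R[g - 1, l - 1] += 1
    return R


def brute_glszm(lv: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Zone counts by BFS flood fill with 26-connectivity."""
    nx, ny, nz = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                g = lv[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in ALL_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                            and mask[u, v, w] and not seen[u, v, w] and lv[u, v, w] == g
                        ):
                            seen[u, v, w] = True
                            stack.append((u, v, w))
                zones.append((int(g), size))
    zmax = max(s for _, s in zones)
    Z = np.zeros((ng, zmax), dtype=np.int64)
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def brute_ngtdm(lv: np.ndarray, mask: np.ndarray, ng: int):
    """Per-voxel neighbourhood deviations with explicit neighbour loops."""
    nx, ny, nz = mask.shape
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=np.int64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nbrs = []
                for dx, dy, dz in ALL_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        nbrs.append(lv[u, v, w])
                if not nbrs:
                    continue
                g = lv[x, y, z]
                s[g - 1] += abs(g - sum(nbrs) / len(nbrs))
                n[g - 1] += 1
    return s, n


def wilcoxon_two_sided_exact(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1  # no ties assumed
    w_plus = ranks[d > 0].sum()
    total = n * (n + 1) / 2
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs or w >= total - w_obs:
            count += 1
    return count / 2**n


def random_roi(rng: np.random.Generator, max_shape=(6, 6, 4), ng: int = 5):
    """A random small quantized ROI: (levels_volume, mask, ng)."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(int(rng.integers(0, s)) for s in shape)] = True
    lv = np.zeros(shape, dtype=np.int32)
    lv[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return lv, mask, ng
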