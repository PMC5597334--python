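"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (BFS flood fill, exhaustive voxel
scans, direct Σ-formulas) and shares no code with the package paths it
checks.
"""

from collections import deque

import numpy as np


def _neighbors(connectivity: int):
    """Offsets for 6/18/26-connectivity in 3D."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a boolean 3D grid by BFS flood fill.

    Returns the partition as a list of frozensets of flat indices, sorted
    by smallest member, so it can be compared against any labeling.
    """
    mask = np.asarray(mask, dtype=bool)
    nz, ny, nx = mask.shape
    offs = _neighbors(connectivity)
    seen = np.zeros_like(mask)
    comps = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                comp = set()
                queue = deque([(z, y, x)])
                seen[z, y, x] = True
                while queue:
                    cz, cy, cx = queue.popleft()
                    comp.add((cz * ny + cy) * nx + cx)
                    for dz, dy, dx in offs:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if (0 <= pz < nz and 0 <= py < ny and 0 <= px < nx
                                and mask[pz, py, px] and not seen[pz, py, px]):
                            seen[pz, py, px] = True
                            queue.append((pz, py, px))
                comps.append(frozenset(comp))
    return sorted(comps, key=min)


def labels_to_partition(labels: np.ndarray) -> list[frozenset]:
    """Partition-of-flat-indices view of a labeled grid (0 = background)."""
    flat = labels.ravel()
    comps = {}
    for idx in np.flatnonzero(flat):
        comps.setdefault(flat[idx], set()).add(int(idx))
    return sorted((frozenset(c) for c in comps.values()), key=min)


def sphere_mean_exhaustive(channel: np.ndarray, spacing, center_um, radius_um):
    """Mean intensity over all voxels within the physical radius, by a full
    scan of every voxel in the grid."""
    total, count = 0.0, 0
    nz, ny, nx = channel.shape
    sz, sy, sx = spacing
    cz, cy, cx = center_um
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                d2 = (z * sz - cz) ** 2 + (y * sy - cy) ** 2 + (x * sx - cx) ** 2
                if d2 <= radius_um ** 2:
                    total += float(channel[z, y, x])
                    count += 1
    return (total / count if count else float("nan")), count


def pearson_direct(a, b) -> float:
    """Two-pass covariance Pearson from the Σ-formulas."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n = a.size
    ma, mb = a.sum() / n, b.sum() / n
    cov = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    va = sum((ai - ma) ** 2 for ai in a)
    vb = sum((bi - mb) ** 2 for bi in b)
    return cov / (va * vb) ** 0.5


def welch_direct(a, b):
    """Welch t, df and two-sided p straight from the closed forms."""
    from scipy.stats import t as tdist
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def otsu_sweep(values) -> set:
    """Indices of the 'high' class under an exhaustive threshold sweep
    maximizing between-class variance over all candidate cut points."""
    values = np.asarray(values, dtype=float)
    candidates = np.unique(values)
    best, best_thr = -np.inf, None
    for thr in candidates[:-1]:
        lo = values[values <= thr]
        hi = values[values > thr]
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        between = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if between > best:
            best, best_thr = between, thr
    return {i for i, v in enumerate(values) if v > best_thr}
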