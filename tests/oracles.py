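"""Independent brute-force reference implementations used only by the tests.

Everything here is written against the mathematical definitions, avoiding the
code paths (scipy.ndimage morphology, KD-trees, vectorised kernel sums,
generating-function convolutions) used by the package itself.
"""

from itertools import product

import numpy as np


def erode_once_cross(mask: np.ndarray) -> np.ndarray:
    """One 4-connected binary erosion; outside the array counts as background."""
    p = np.pad(mask.astype(bool), 1, constant_values=False)
    return (
        p[1:-1, 1:-1]
        & p[:-2, 1:-1]
        & p[2:, 1:-1]
        & p[1:-1, :-2]
        & p[1:-1, 2:]
    )


def erode_to_fraction_stepthrough(mask: np.ndarray, fraction: float):
    """Step-through fractional erosion: returns (final mask, iteration count)."""
    area0 = mask.sum()
    target = fraction * area0
    current = mask.astype(bool).copy()
    iters = 0
    while current.sum() > target:
        nxt = erode_once_cross(current)
        if not nxt.any():
            break
        current = nxt
        iters += 1
    return current, iters


def kde_double_loop(points, sample, h):
    """p(x) by the literal double sum with standard-normal kernels."""
    out = []
    n = len(sample)
    for x in points:
        s = 0.0
        for xi in sample:
            z = (x - xi) / h
            s += np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
        out.append(s / (n * h))
    return np.array(out)


def boundary_faces_loop(mask: np.ndarray, spacing):
    """Triple-loop voxel-face extraction (exterior = background)."""
    mask = np.asarray(mask, dtype=bool)
    sp = np.asarray(spacing, float)
    nd = mask.ndim
    faces = []
    for idx in product(*(range(s) for s in mask.shape)):
        if not mask[idx]:
            continue
        for ax in range(nd):
            for step in (-1, 1):
                nb = list(idx)
                nb[ax] += step
                inside = 0 <= nb[ax] < mask.shape[ax]
                if not inside or not mask[tuple(nb)]:
                    c = np.array(idx, float)
                    c[ax] += 0.5 * step
                    faces.append(c * sp)
    return np.array(faces) if faces else np.empty((0, nd))


def nsd_bruteforce(a: np.ndarray, b: np.ndarray, spacing, tau: float) -> float:
    """All-pairs surface-distance NSD."""
    fa = boundary_faces_loop(a, spacing)
    fb = boundary_faces_loop(b, spacing)
    if len(fa) == 0 and len(fb) == 0:
        return 1.0
    if len(fa) == 0 or len(fb) == 0:
        return 0.0
    d2 = ((fa[:, None, :] - fb[None, :, :]) ** 2).sum(-1)
    da = np.sqrt(d2.min(axis=1))
    db = np.sqrt(d2.min(axis=0))
    return ((da <= tau).sum() + (db <= tau).sum()) / (len(fa) + len(fb))


def wilcoxon_enumeration(a, b):
    """Exact one-sided signed-rank p (H1: a > b) by enumerating all 2^n signs.

    Zero differences dropped, midranks for tied |d|.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan")
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        mid = (pos + (pos + (j - i) - 1)) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        pos += j - i
        i = j
    t_obs = ranks[d > 0].sum()
    count = 0
    for signs in product([0, 1], repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if t >= t_obs - 1e-12:
            count += 1
    return count / 2.0**n


def trilinear_probe(data: np.ndarray, coord) -> float:
    """Dense trilinear interpolation at one (possibly fractional) voxel coord,
    clamped to the grid (edge replication)."""
    out = 0.0
    base = [int(np.floor(c)) for c in coord]
    frac = [c - b for c, b in zip(coord, base)]
    for corner in product((0, 1), repeat=3):
        w = 1.0
        idx = []
        for ax in range(3):
            w *= frac[ax] if corner[ax] else 1 - frac[ax]
            idx.append(int(np.clip(base[ax] + corner[ax], 0, data.shape[ax] - 1)))
        out += w * data[tuple(idx)]
    return out
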