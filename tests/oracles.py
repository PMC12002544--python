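"""Independent brute-force oracles used by the test suite.

All oracles enumerate explicitly (voxel offsets, flood fill, rank
assignments, sign patterns) and share no code with the implementation
they check.
"""

from collections import deque
from itertools import combinations, product

import numpy as np


def ball_offsets(radius: int) -> list[tuple[int, int, int]]:
    """All integer offsets with Euclidean norm <= radius, by enumeration."""
    out = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    out.append((dx, dy, dz))
    return out


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    offs = ball_offsets(radius)
    for x, y, z in np.argwhere(mask):
        for dx, dy, dz in offs:
            i, j, k = x + dx, y + dy, z + dz
            if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
                out[i, j, k] = True
    return out


def brute_erode(mask: np.ndarray) -> np.ndarray:
    """Erosion by the 6-neighborhood cross (voxels outside count as empty)."""
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for x, y, z in np.argwhere(mask):
        keep = True
        for dx, dy, dz in ball_offsets(1):
            i, j, k = x + dx, y + dy, z + dz
            if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
                keep = False
                break
            if not mask[i, j, k]:
                keep = False
                break
        if keep:
            out[x, y, z] = True
    return out


def brute_label(mask: np.ndarray, connectivity: int = 26):
    """Flood-fill connected components; returns (labels, count)."""
    if connectivity == 6:
        neigh = [o for o in ball_offsets(1) if o != (0, 0, 0)]
    else:
        neigh = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    labels = np.zeros(mask.shape, dtype=int)
    count = 0
    shape = mask.shape
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        count += 1
        queue = deque([start])
        labels[start] = count
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in neigh:
                i, j, k = x + dx, y + dy, z + dz
                if (
                    0 <= i < shape[0]
                    and 0 <= j < shape[1]
                    and 0 <= k < shape[2]
                    and mask[i, j, k]
                    and not labels[i, j, k]
                ):
                    labels[i, j, k] = count
                    queue.append((i, j, k))
    return labels, count


def brute_ring_family(lesion_k, all_lesions, wm):
    """PL and shells 1-3 of one lesion by explicit offset enumeration."""
    pl = brute_dilate(lesion_k, 2) & ~all_lesions & wm
    inner = all_lesions | pl
    shells = []
    for n in (1, 2, 3):
        s = brute_dilate(pl, n) & ~inner & wm
        shells.append(s)
        inner = inner | s
    return pl, shells


def mwu_exact_p(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    allr = np.arange(1, n1 + n2 + 1)
    us = np.array(
        [allr[list(c)].sum() - n1 * (n1 + 1) / 2 for c in combinations(range(n1 + n2), n1)]
    )
    p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return float(u_obs), float(p)


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in product([0, 1], repeat=len(d))
        ]
    )
    return float(min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())))


def random_lesion_wm_config(rng, size=24, n_lesions=2):
    """A random small WM/lesion configuration for geometry oracle tests."""
    shape = (size, size, size)
    wm = rng.random(shape) > 0.15
    lesions = np.zeros(shape, dtype=bool)
    for _ in range(n_lesions):
        r = int(rng.integers(1, 4))
        c = rng.integers(r, size - r, size=3)
        for off in ball_offsets(r):
            lesions[tuple(c + np.array(off))] = True
    return lesions, wm
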