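"""Shared fixtures and brute-force oracles.

The oracles deliberately take the slow, literal route (explicit lattice
loops, pairwise distances, exhaustive assignment enumeration with direct
pair counting) so they share no code path with the implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pytest

from ribbonfd.volumes import BinaryMask


def oracle_box_count(grid: np.ndarray, r: int) -> int:
    """Triple loop over lattice cells anchored at the foreground bbox corner."""
    idx = np.argwhere(grid)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    sub = grid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    count = 0
    for i in range(0, sub.shape[0], r):
        for j in range(0, sub.shape[1], r):
            for k in range(0, sub.shape[2], r):
                if sub[i:i + r, j:j + r, k:k + r].any():
                    count += 1
    return count


def oracle_dilate_count(grid: np.ndarray, r: float) -> int:
    """Count voxel centers within Euclidean distance r of some foreground center.

    Pads the grid so nothing is clipped, then evaluates the minimum
    pairwise distance for every candidate voxel explicitly.
    """
    pad = int(np.ceil(r)) + 1
    fg = np.argwhere(grid) + pad
    shape = tuple(s + 2 * pad for s in grid.shape)
    centers = np.argwhere(np.ones(shape, dtype=bool))
    d2 = ((centers[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    return int((d2 <= r * r + 1e-9).sum())


def oracle_mann_whitney(a, b) -> tuple[float, float]:
    """Exhaustive two-sample permutation test with direct pair-counting U.

    U is computed as the number of (a_i, b_j) pairs with a_i < b_j (and its
    mirror), never via rank sums; the two-tailed p counts assignments whose
    min-U is at least as extreme as observed.  Tie-free inputs only.
    """
    a, b = list(map(float, a)), list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle assumes tie-free data"
    n1, n2 = len(a), len(b)

    def min_u(x, y):
        wins = sum(1 for xi in x for yj in y if xi > yj)
        return min(wins, n1 * n2 - wins)

    u_obs = min_u(a, b)
    hits = sum(
        1
        for chosen in combinations(range(n1 + n2), n1)
        if min_u([pooled[i] for i in chosen],
                 [pooled[i] for i in range(n1 + n2) if i not in set(chosen)]) <= u_obs
    )
    return float(u_obs), hits / comb(n1 + n2, n1)


def random_mask(rng: np.random.Generator, max_edge: int, density: float = 0.15) -> BinaryMask:
    """A random non-empty mask with edges in [4, max_edge]."""
    shape = tuple(int(rng.integers(4, max_edge + 1)) for _ in range(3))
    grid = rng.random(shape) < density
    if not grid.any():
        grid[tuple(int(rng.integers(0, s)) for s in shape)] = True
    return BinaryMask(grid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture
def atlas_map() -> dict[int, tuple[str, str]]:
    """A complete 8-label atlas: one label per lobe/hemisphere cell."""
    labels = {}
    label = 1
    for hemi in ("left", "right"):
        for lobe in ("frontal", "parietal", "temporal", "occipital"):
            labels[label] = (lobe, hemi)
            label += 1
    return labels


@pytest.fixture
def labeled_grid(atlas_map) -> np.ndarray:
    """A 16³ volume of eight 8×8×8 octants, one per atlas label."""
    grid = np.zeros((16, 16, 16), dtype=np.int32)
    for label, (lobe, hemi) in atlas_map.items():
        i = 0 if hemi == "left" else 1
        lobes = ("frontal", "parietal", "temporal", "occipital")
        j, k = divmod(lobes.index(lobe), 2)
        grid[i * 8:(i + 1) * 8, j * 8:(j + 1) * 8, k * 8:(k + 1) * 8] = label
    return grid
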