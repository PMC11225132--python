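"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — flood fills, double loops over surface
point sets, exhaustive sign enumeration — and shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

NEIGHBOURS_2D = {
    4: [(-1, 0), (1, 0), (0, -1), (0, 1)],
    8: [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)],
}
NEIGHBOURS_3D = {
    6: [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
    26: [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
}


def flood_fill_label(grid: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Label components with an explicit BFS flood fill, raster discovery order."""
    grid = np.asarray(grid) != 0
    offsets = NEIGHBOURS_2D[connectivity] if grid.ndim == 2 else NEIGHBOURS_3D[connectivity]
    labels = np.zeros(grid.shape, dtype=np.int64)
    n = 0
    for idx in np.ndindex(grid.shape):
        if grid[idx] and labels[idx] == 0:
            n += 1
            q = deque([idx])
            labels[idx] = n
            while q:
                cur = q.popleft()
                for off in offsets:
                    nb = tuple(c + o for c, o in zip(cur, off))
                    if all(0 <= c < s for c, s in zip(nb, grid.shape)):
                        if grid[nb] and labels[nb] == 0:
                            labels[nb] = n
                            q.append(nb)
    return labels, n


def bridged_component_count(grid: np.ndarray, theta: int, connectivity: int = 8) -> int:
    """Components remaining after transitive closure of the pairwise bridging
    criterion: min Manhattan distance between two regions <= theta - 1."""
    labels, n = flood_fill_label(grid, connectivity)
    pts = [np.argwhere(labels == k) for k in range(1, n + 1)]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            dmin = min(
                abs(int(a[0]) - int(b[0])) + abs(int(a[1]) - int(b[1]))
                for a in pts[i]
                for b in pts[j]
            )
            if dmin <= theta - 1:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    return len({find(i) for i in range(n)})


def border_flood_fill_holes(grid: np.ndarray) -> np.ndarray:
    """Fill enclosed 2D background by flood-filling background from the border."""
    grid = np.asarray(grid) != 0
    outside = np.zeros(grid.shape, dtype=bool)
    q: deque = deque()
    h, w = grid.shape
    for y in range(h):
        for x in (0, w - 1):
            if not grid[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    for x in range(w):
        for y in (0, h - 1):
            if not grid[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    while q:
        y, x = q.popleft()
        for dy, dx in NEIGHBOURS_2D[4]:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not grid[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                q.append((ny, nx))
    return (grid | ~outside).astype(np.uint8)


def surface_points(grid: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with a face-adjacent background neighbour (border = bg)."""
    grid = np.asarray(grid) != 0
    pts = []
    for idx in np.argwhere(grid):
        idx = tuple(int(i) for i in idx)
        on_surface = False
        for off in NEIGHBOURS_3D[6]:
            nb = tuple(c + o for c, o in zip(idx, off))
            if not all(0 <= c < s for c, s in zip(nb, grid.shape)) or not grid[nb]:
                on_surface = True
                break
        if on_surface:
            pts.append(idx)
    return pts


def _pairwise_distances(sa, sb, spacing) -> np.ndarray:
    sa = np.asarray(sa, dtype=float) * spacing
    sb = np.asarray(sb, dtype=float) * spacing
    return np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))


def brute_asd(grid_a, grid_b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance by an O(|Sa|*|Sb|) double loop."""
    sa, sb = surface_points(grid_a), surface_points(grid_b)
    d = _pairwise_distances(sa, sb, np.asarray(spacing))
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sa) + len(sb))


def brute_hausdorff(grid_a, grid_b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Max-min surface distance in both directions, by double loop."""
    sa, sb = surface_points(grid_a), surface_points(grid_b)
    d = _pairwise_distances(sa, sb, np.asarray(spacing))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if min(t, total - t) <= w_obs + 1e-12:
            count += 1
    return count / 2 ** len(d)


def random_blob_mask(rng: np.random.Generator, shape, n_blobs=3, r_max=3) -> np.ndarray:
    """A few random balls on a grid — generic test geometry."""
    grid = np.zeros(shape, dtype=np.uint8)
    coords = np.indices(shape)
    for _ in range(n_blobs):
        c = rng.integers(0, shape)
        r = rng.integers(1, r_max + 1)
        dist2 = sum((coords[i] - c[i]) ** 2 for i in range(len(shape)))
        grid[dist2 <= r**2] = 1
    return grid
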