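"""Independent brute-force oracles used to anchor the fast implementations.

Everything here is deliberately naive: exhaustive enumeration and all-pairs
distances, computed without reusing the package's own code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def otsu_brute_force(values: np.ndarray) -> float:
    """Exhaustive search over all 256 candidate thresholds.

    Bins the observed range into 256 equal bins and, for every candidate
    split, computes the between-class variance directly from class weights
    and class mean bin centers; returns the lowest maximizing threshold.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    width = (vmax - vmin) / 256.0
    idx = np.minimum(((values - vmin) / width).astype(int), 255)
    centers = vmin + (np.arange(256) + 0.5) * width
    counts = np.bincount(idx, minlength=256).astype(float)
    n = counts.sum()
    best_var, best_t = -1.0, None
    for k in range(255):
        n0 = counts[: k + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            var = 0.0
        else:
            m0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
            m1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / n1
            var = (n0 / n) * (n1 / n) * (m0 - m1) ** 2
        if var > best_var + 1e-12 * max(best_var, 1.0):
            best_var, best_t = var, vmin + (k + 1) * width
    return best_t


def flood_fill_cavities(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed cavities by BFS flood fill from the border (6-conn)."""
    bg = ~mask
    reach = np.zeros(mask.shape, dtype=bool)
    stack = []
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if (z in (0, nz - 1) or y in (0, ny - 1) or x in (0, nx - 1)) and bg[
                    z, y, x
                ]:
                    stack.append((z, y, x))
                    reach[z, y, x] = True
    while stack:
        z, y, x = stack.pop()
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                if bg[zz, yy, xx] and not reach[zz, yy, xx]:
                    reach[zz, yy, xx] = True
                    stack.append((zz, yy, xx))
    return mask | (bg & ~reach)


def edt_brute_force(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """All-pairs minimum distance from foreground to background centers.

    Background outside the array bounds is included (one-voxel shell), so the
    result matches a transform computed on a background-padded volume.
    """
    padded = np.pad(mask, 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape, dtype=float)
    if fg.size:
        d = cdist(fg.astype(float), bg.astype(float)).min(axis=1)
        out[tuple(fg.T)] = d
    return out[1:-1, 1:-1, 1:-1] * voxel_size


def edt_interior_brute_force(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Like :func:`edt_brute_force` but without the implicit background shell
    (matches a transform limited to the given array)."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    if fg.size and bg.size:
        d = cdist(fg.astype(float), bg.astype(float)).min(axis=1)
        out[tuple(fg.T)] = d
    return out * voxel_size


def local_thickness_brute_force(
    mask: np.ndarray, voxel_size: float = 1.0
) -> np.ndarray:
    """Exhaustive largest-inscribed-sphere thickness.

    For every foreground voxel ``v``, the thickness is the maximum over all
    candidate centers ``c`` of ``2 r(c)`` such that ``|v - c| < r(c)``, where
    ``r(c)`` is the all-pairs distance to the nearest background voxel center
    (background beyond the array bounds included).
    """
    r = edt_brute_force(mask)  # voxel units
    fg = np.argwhere(mask).astype(float)
    radii = r[mask]
    dist = cdist(fg, fg)
    # strict coverage |v - c| < r(c); distances are square roots of small
    # integers, so an epsilon excludes exact ties without false negatives
    covered = dist < radii[None, :] - 1e-9
    thick = np.where(covered, 2.0 * radii[None, :], 0.0).max(axis=1)
    out = np.zeros(mask.shape, dtype=float)
    out[mask] = thick * voxel_size
    return out


def random_connected_blob(
    shape: tuple[int, int, int], rng: np.random.Generator, fill: float = 0.35
) -> np.ndarray:
    """A random connected foreground blob grown from the volume center."""
    target = int(fill * np.prod(shape))
    mask = np.zeros(shape, dtype=bool)
    center = tuple(s // 2 for s in shape)
    mask[center] = True
    frontier = [center]
    while mask.sum() < target and frontier:
        i = int(rng.integers(len(frontier)))
        z, y, x = frontier[i]
        nbrs = [
            (z + dz, y + dy, x + dx)
            for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1))
            if 0 <= z + dz < shape[0]
            and 0 <= y + dy < shape[1]
            and 0 <= x + dx < shape[2]
        ]
        new = [n for n in nbrs if not mask[n]]
        if not new:
            frontier.pop(i)
            continue
        pick = new[int(rng.integers(len(new)))]
        mask[pick] = True
        frontier.append(pick)
    return mask
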