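"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately takes the naive route (dense convolution, BFS flood
fill, per-threshold cluster rebuild, per-voxel loops) and shares no code with
the library paths it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy import ndimage


def dense_gaussian_convolve(values: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct convolution with a sampled, normalized 3D Gaussian kernel,
    symmetric (reflect) padding."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k1 /= k1.sum()
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    padded = np.pad(values.astype(float), radius, mode="symmetric")
    out = np.zeros_like(values, dtype=float)
    n0, n1, n2 = values.shape
    for i, di in enumerate(range(2 * radius + 1)):
        for j, dj in enumerate(range(2 * radius + 1)):
            for k, dk in enumerate(range(2 * radius + 1)):
                out += kernel[i, j, k] * padded[di:di + n0, dj:dj + n1, dk:dk + n2]
    return out


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or (
                    connectivity == 18 and order <= 2
                ) or connectivity == 26:
                    offs.append((dx, dy, dz))
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """BFS flood fill; returns the set of components as voxel-index sets."""
    offs = _neighbor_offsets(connectivity)
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    components = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            x, y, z = queue.popleft()
            comp.add((x, y, z))
            for dx, dy, dz in offs:
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                    if mask[nx, ny, nz] and not seen[nx, ny, nz]:
                        seen[nx, ny, nz] = True
                        queue.append((nx, ny, nz))
        components.append(frozenset(comp))
    return components


def sphere_offsets(diameter: int) -> np.ndarray:
    """All integer offsets with Euclidean norm <= diameter/2 (inclusive)."""
    radius = diameter / 2.0
    half = diameter // 2
    offs = []
    for dx in range(-half, half + 1):
        for dy in range(-half, half + 1):
            for dz in range(-half, half + 1):
                if math.sqrt(dx * dx + dy * dy + dz * dz) <= radius:
                    offs.append((dx, dy, dz))
    return np.array(offs, dtype=int)


def roi_sum_bruteforce(grid: np.ndarray, diameter: int) -> np.ndarray:
    """Per-voxel spherical-ROI summation by explicit shift-and-add (zero pad)."""
    out = np.zeros_like(grid, dtype=float)
    shape = grid.shape
    for dx, dy, dz in sphere_offsets(diameter):
        src = [slice(max(0, d), min(s, s + d)) for d, s in zip((dx, dy, dz), shape)]
        dst = [slice(max(0, -d), min(s, s - d)) for d, s in zip((dx, dy, dz), shape)]
        out[tuple(dst)] += grid[tuple(src)]
    return out


def tfce_bruteforce(stat: np.ndarray, E: float, H: float, dh: float, connectivity: int) -> np.ndarray:
    """TFCE by rebuilding clusters at every threshold independently."""
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    out = np.zeros_like(stat, dtype=float)
    vmax = float(stat.max())
    if vmax <= 0:
        return out
    n_steps = int(math.floor(1.0 / dh + 1e-9))
    step = dh * vmax
    for k in range(1, n_steps + 1):
        h = k * step
        mask = stat >= h
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        out[mask] += (sizes[labels[mask]].astype(float) ** E) * (h**H) * step
    return out


def ttest_closed_form(a, b):
    """Pooled-variance Student t and two-sided p from the textbook formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        return 0.0, 1.0
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy import stats as sps

    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def bin_and_transform_oracle(centers_vox, spacing_um, atlas_spacing, matrix, offset, atlas_shape):
    """Per-object loop: µm -> floor bin -> affine -> round, with bounds check."""
    counts = np.zeros(atlas_shape, dtype=int)
    dropped = 0
    placed = []
    for c in np.atleast_2d(centers_vox):
        um = [c[d] * spacing_um[d] for d in range(3)]
        b = [math.floor(u / atlas_spacing) for u in um]
        a = [
            matrix[r][0] * b[0] + matrix[r][1] * b[1] + matrix[r][2] * b[2] + offset[r]
            for r in range(3)
        ]
        idx = [int(np.rint(x)) for x in a]
        if all(0 <= idx[d] < atlas_shape[d] for d in range(3)):
            counts[tuple(idx)] += 1
            placed.append(tuple(idx))
        else:
            dropped += 1
    return counts, dropped, placed


def coloc_bruteforce(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Exhaustive double scan over all voxels; rows/cols = (increase, decrease)."""
    counts = np.zeros((2, 2), dtype=int)
    signs = (1, -1)
    for a, b in zip(v1.ravel(), v2.ravel()):
        for i, s1 in enumerate(signs):
            for j, s2 in enumerate(signs):
                if a == s1 and b == s2:
                    counts[i, j] += 1
    return counts
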