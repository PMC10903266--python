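"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (explicit loops,
breadth-first search, exhaustive minimization) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Dict, Tuple

import numpy as np


def neighbor_offsets(connectivity: int):
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offsets.append((dz, dy, dx))
    return offsets


def bfs_connected_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected foreground components by BFS in scan order."""
    mask = np.asarray(mask) > 0
    nz, ny, nx = mask.shape
    labels = np.zeros(mask.shape, dtype=np.int64)
    offsets = neighbor_offsets(connectivity)
    current = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or labels[z, y, x]:
                    continue
                current += 1
                queue = deque([(z, y, x)])
                labels[z, y, x] = current
                while queue:
                    cz, cy, cx = queue.popleft()
                    for dz, dy, dx in offsets:
                        tz, ty, tx = cz + dz, cy + dy, cx + dx
                        if 0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx:
                            if mask[tz, ty, tx] and not labels[tz, ty, tx]:
                                labels[tz, ty, tx] = current
                                queue.append((tz, ty, tx))
    return labels


def label_tally(labels: np.ndarray) -> Dict[int, int]:
    """Per-label voxel counts by direct iteration."""
    tally: Dict[int, int] = {}
    for value in labels.ravel():
        value = int(value)
        if value:
            tally[value] = tally.get(value, 0) + 1
    return tally


def huang_exhaustive(histogram) -> int:
    """Exhaustive minimization of the Huang fuzzy-entropy criterion."""
    hist = [float(h) for h in histogram]
    nonzero = [g for g, h in enumerate(hist) if h > 0]
    first, last = nonzero[0], nonzero[-1]
    if first == last:
        return first
    span = float(last - first)
    best_t, best_s = first, float("inf")
    for t in range(first, last):
        w0 = sum(hist[g] for g in range(t + 1))
        w1 = sum(hist[g] for g in range(t + 1, len(hist)))
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(g * hist[g] for g in range(t + 1)) / w0
        mu1 = sum(g * hist[g] for g in range(t + 1, len(hist))) / w1
        s = 0.0
        for g, h in enumerate(hist):
            if h == 0:
                continue
            mu = 1.0 / (1.0 + abs(g - (mu0 if g <= t else mu1)) / span)
            if 0.0 < mu < 1.0:
                s += h * (-mu * math.log(mu) - (1 - mu) * math.log(1 - mu))
        if s < best_s - 1e-12:
            best_s, best_t = s, t
    return best_t


def brute_force_expand(labels: np.ndarray, distance: int) -> np.ndarray:
    """Chebyshev nearest-label assignment restricted to the given distance.

    For every background voxel, scan all offsets within the Chebyshev ball;
    assign the label at minimal Chebyshev distance, ties to the lower id.
    """
    labels = np.asarray(labels)
    nz, ny, nx = labels.shape
    out = labels.astype(np.int64).copy()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if labels[z, y, x]:
                    continue
                best_d, best_l = distance + 1, 0
                for dz in range(-distance, distance + 1):
                    tz = z + dz
                    if not 0 <= tz < nz:
                        continue
                    for dy in range(-distance, distance + 1):
                        ty = y + dy
                        if not 0 <= ty < ny:
                            continue
                        for dx in range(-distance, distance + 1):
                            tx = x + dx
                            if not 0 <= tx < nx:
                                continue
                            lab = labels[tz, ty, tx]
                            if lab:
                                d = max(abs(dz), abs(dy), abs(dx))
                                if d < best_d or (d == best_d and lab < best_l):
                                    best_d, best_l = d, int(lab)
                if best_d <= distance:
                    out[z, y, x] = best_l
    return out


def brute_force_regional_minima(data: np.ndarray, mask: np.ndarray, connectivity: int) -> int:
    """Count regional minima (connected equal-value plateaus with no lower
    neighbor) of ``data`` restricted to ``mask``."""
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask) > 0
    nz, ny, nx = data.shape
    offsets = neighbor_offsets(connectivity)
    visited = np.zeros(data.shape, dtype=bool)
    n_minima = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or visited[z, y, x]:
                    continue
                value = data[z, y, x]
                plateau = [(z, y, x)]
                visited[z, y, x] = True
                queue = deque(plateau)
                is_minimum = True
                while queue:
                    cz, cy, cx = queue.popleft()
                    for dz, dy, dx in offsets:
                        tz, ty, tx = cz + dz, cy + dy, cx + dx
                        if not (0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx):
                            continue
                        if not mask[tz, ty, tx]:
                            continue
                        other = data[tz, ty, tx]
                        if other < value:
                            is_minimum = False
                        elif other == value and not visited[tz, ty, tx]:
                            visited[tz, ty, tx] = True
                            queue.append((tz, ty, tx))
                if is_minimum:
                    n_minima += 1
    return n_minima


def pairwise_min_separation(
    centers: np.ndarray, radii: np.ndarray, base_radii: Tuple[float, float, float]
) -> float:
    """Smallest pairwise surface separation (normalized metric) by O(n^2) loops."""
    n = len(centers)
    if n < 2:
        return float("inf")
    base = [float(b) for b in base_radii]
    best = float("inf")
    for i in range(n):
        for j in range(i + 1, n):
            d = math.sqrt(
                sum(((centers[i][k] - centers[j][k]) / base[k]) ** 2 for k in range(3))
            )
            si = radii[i][1] / base[1]
            sj = radii[j][1] / base[1]
            best = min(best, (d - si - sj) * base[1])
    return best
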