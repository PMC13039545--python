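"""Independent brute-force reference implementations.

Deliberately written with plain Python loops and elementary formulas,
sharing no code with the package, so agreement with the fast
implementations is an informative check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def moments_threshold(hist) -> int:
    """Moment-preserving threshold by scanning every candidate level.

    Solves the two-level moment system with numpy.roots and walks the
    cumulative distribution over all levels, picking the middle of the run
    of levels closest to the below-fraction p0.
    """
    hist = list(hist)
    total = float(sum(hist))
    p = [h / total for h in hist]
    m1 = sum(i * pi for i, pi in enumerate(p))
    m2 = sum(i * i * pi for i, pi in enumerate(p))
    m3 = sum(i * i * i * pi for i, pi in enumerate(p))
    cd = m2 - m1 * m1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    roots = np.roots([1.0, c1, c0])
    z0, z1 = sorted(float(r.real) for r in roots)
    p0 = (z1 - m1) / (z1 - z0)
    errs = []
    cdf = 0.0
    for pi in p:
        cdf += pi
        errs.append(abs(cdf - p0))
    best = min(errs)
    ties = [i for i, e in enumerate(errs) if abs(e - best) <= 1e-12]
    return ties[len(ties) // 2]


_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if 0 < abs(dz) + abs(dy) + abs(dx) <= 2
    ],
    26: [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
}


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components by breadth-first flood fill; set of voxel sets."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim == 2:
        mask = mask[None]
    offsets = _OFFSETS[connectivity]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                stack = [(z, y, x)]
                seen[z, y, x] = True
                comp = []
                while stack:
                    cz, cy, cx = stack.pop()
                    comp.append((cz, cy, cx))
                    for dz, dy, dx in offsets:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= nz < mask.shape[0]
                            and 0 <= ny < mask.shape[1]
                            and 0 <= nx < mask.shape[2]
                            and mask[nz, ny, nx]
                            and not seen[nz, ny, nx]
                        ):
                            seen[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                comps.append(frozenset(comp))
    return comps


def major_diameter(voxels, spacing) -> float:
    """All-pairs max distance between voxel centers, quarter-pitch corrected."""
    pts = [
        ((v[0] + 0.5) * spacing[0], (v[1] + 0.5) * spacing[1], (v[2] + 0.5) * spacing[2])
        for v in voxels
    ]
    pitch = (spacing[0] + spacing[1] + spacing[2]) / 3.0
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.dist(pts[i], pts[j])
            if d > best:
                best = d
    return max(best + 0.25 * pitch, pitch)


def nearest_neighbor_distances(points) -> list[float]:
    """Per-point min distance to any other point, by explicit double loop."""
    out = []
    for i, p in enumerate(points):
        best = math.inf
        for j, q in enumerate(points):
            if i != j:
                d = math.dist(p, q)
                if d < best:
                    best = d
        out.append(best)
    return out


def _point_in_polygon(px: float, py: float, poly) -> bool:
    """Even-odd ray casting."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def integrated_density(channel: np.ndarray, polygon) -> float:
    """Per-pixel accumulation of the sum projection inside a polygon.

    The polygon is given as (x, y) vertices in pixel coordinates; pixel
    (row, col) is the point (x=col, y=row).
    """
    arr = np.asarray(channel, dtype=float)
    img = arr.sum(axis=0) if arr.ndim == 3 else arr
    total = 0.0
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if _point_in_polygon(float(c), float(r), polygon):
                total += img[r, c]
    return total


def circle_crossings(image: np.ndarray, cy: float, cx: float, radius_px: float,
                     arc_step_px: float = 0.1) -> int:
    """Count foreground runs on a densely sampled circle, plain loops."""
    img = np.asarray(image).astype(bool)
    n = max(16, int(math.ceil(2.0 * math.pi * radius_px / arc_step_px)))
    fg = []
    for k in range(n):
        theta = 2.0 * math.pi * k / n
        y = int(round(cy + radius_px * math.sin(theta)))
        x = int(round(cx + radius_px * math.cos(theta)))
        if 0 <= y < img.shape[0] and 0 <= x < img.shape[1]:
            fg.append(bool(img[y, x]))
        else:
            fg.append(False)
    if not any(fg):
        return 0
    if all(fg):
        return 1
    runs = 0
    for k in range(n):
        if fg[k] and not fg[k - 1]:
            runs += 1
    return runs


def smoothed_max_z(rate, bin_s, smooth_s, t0, baseline, response) -> float:
    """Boxcar-smoothed firing-rate Z maximum, written independently."""
    rate = list(map(float, rate))
    w = max(1, int(round(smooth_s / bin_s)))
    half_lo = (w - 1) // 2
    half_hi = w // 2
    sm = []
    for i in range(len(rate)):
        lo = max(0, i - half_lo)
        hi = min(len(rate), i + half_hi + 1)
        sm.append(sum(rate[lo:hi]) / (hi - lo))
    times = [t0 + (i + 0.5) * bin_s for i in range(len(sm))]
    base = [s for s, t in zip(sm, times) if baseline[0] <= t < baseline[1]]
    mu = sum(base) / len(base)
    sd = math.sqrt(sum((b - mu) ** 2 for b in base) / len(base))
    zs = [(s - mu) / sd for s, t in zip(sm, times) if response[0] <= t < response[1]]
    return max(zs)
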