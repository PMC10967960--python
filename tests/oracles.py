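"""Independent brute-force oracles used by the tests.

Deliberately naive: flood fill with an explicit stack and direct moment
sums, sharing no code with the package's labelling/moment path.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """All connected components of a binary patch as sets of (row, col)."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError(connectivity)
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comps.append(comp)
    return comps


def brute_force_moments(pixels: set) -> tuple[tuple[float, float], float, float]:
    """(centroid, eccentricity, orientation_deg) by direct summation."""
    n = len(pixels)
    rbar = sum(r for r, _ in pixels) / n
    cbar = sum(c for _, c in pixels) / n
    if n == 1:
        return (rbar, cbar), 0.0, 0.0
    # x = col, y = -row so the angle is CCW from the horizontal on screen
    mxx = sum((c - cbar) ** 2 for _, c in pixels) / n
    myy = sum((r - rbar) ** 2 for r, _ in pixels) / n
    mxy = sum((c - cbar) * (-(r - rbar)) for r, c in pixels) / n
    disc = math.sqrt((mxx - myy) ** 2 + 4 * mxy * mxy)
    lam1 = 0.5 * (mxx + myy + disc)
    lam2 = max(0.5 * (mxx + myy - disc), 0.0)
    ecc = math.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0
    theta = 0.5 * math.atan2(2 * mxy, mxx - myy) if disc > 0 else 0.0
    deg = math.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    return (rbar, cbar), ecc, deg


def filled_ellipse_mask(a: float, b: float, theta_deg: float, span: int) -> np.ndarray:
    """Rasterise a filled ellipse (semi-axes a >= b, CCW angle from horizontal)."""
    theta = math.radians(theta_deg)
    rr, cc = np.mgrid[-span : span + 1, -span : span + 1]
    x = cc.astype(float)
    y = -rr.astype(float)
    u = x * math.cos(theta) + y * math.sin(theta)
    v = -x * math.sin(theta) + y * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
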