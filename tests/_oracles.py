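"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written from different published formulas or
brute force than the library code it checks, and stays test-only.
"""

from __future__ import annotations

import itertools
import math
from datetime import datetime, timezone

import numpy as np


def michalsky_solar_azimuth(lat: float, lon: float, t: datetime) -> float:
    """Solar azimuth (deg from north, clockwise) per Michalsky (1988).

    The Astronomical Almanac's low-precision solar ephemeris — a different
    formulation from the NOAA/Meeus equations used by the library.
    """
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    jd = 2440587.5 + t.timestamp() / 86400.0
    n = jd - 2451545.0

    L = (280.460 + 0.9856474 * n) % 360.0
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = math.radians(L + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 0.0000004 * n)

    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    dec = math.asin(math.sin(eps) * math.sin(lam))

    ut_hours = ((jd + 0.5) % 1.0) * 24.0
    gmst = (6.697375 + 0.0657098242 * n + ut_hours) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = math.radians(lmst * 15.0) - ra
    ha = (ha + math.pi) % (2 * math.pi) - math.pi

    phi = math.radians(lat)
    az = math.atan2(
        math.sin(ha),
        math.cos(ha) * math.sin(phi) - math.tan(dec) * math.cos(phi),
    )
    return (math.degrees(az) + 180.0) % 360.0


def kruskal_wallis_h(groups: list[list[float]]) -> float:
    """Kruskal-Wallis H from the explicit rank-sum formula with tie correction."""
    pooled = [v for g in groups for v in g]
    n_tot = len(pooled)
    order = sorted(range(n_tot), key=lambda i: pooled[i])
    ranks = [0.0] * n_tot
    i = 0
    while i < n_tot:
        j = i
        while j + 1 < n_tot and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r_sum = sum(ranks[start : start + len(g)])
        h += r_sum * r_sum / len(g)
        start += len(g)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)
    # tie correction
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (n_tot**3 - n_tot)
    return h / denom if denom > 0 else 0.0


def kruskal_wallis_permutation_p(groups: list[list[float]]) -> float:
    """Exact permutation p-value of H by full enumeration (tiny n only)."""
    sizes = [len(g) for g in groups]
    pooled = [v for g in groups for v in g]
    h_obs = kruskal_wallis_h(groups)
    n = len(pooled)
    count = total = 0
    indices = list(range(n))
    for first in itertools.combinations(indices, sizes[0]):
        rest1 = [i for i in indices if i not in first]
        for second in itertools.combinations(rest1, sizes[1]):
            third = [i for i in rest1 if i not in second]
            parts = [list(first), list(second), third]
            h = kruskal_wallis_h([[pooled[i] for i in part] for part in parts])
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
    return count / total


def monte_carlo_union_area_km2(
    centers_xy: list[tuple[float, float]], radius: float, n: int = 400_000, seed: int = 0
) -> float:
    """Rejection-sampling estimate of a disc-union area (m coords -> km²)."""
    c = np.asarray(centers_xy)
    lo = c.min(axis=0) - radius
    hi = c.max(axis=0) + radius
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n, 2))
    inside = np.zeros(n, dtype=bool)
    for center in c:
        inside |= np.sum((pts - center) ** 2, axis=1) <= radius * radius
    box_area = float(np.prod(hi - lo))
    return inside.mean() * box_area / 1e6


def grid_search_ray_point(
    rays: list[tuple[tuple[float, float], float]],
    span: float = 3000.0,
    coarse: int = 121,
) -> tuple[float, float]:
    """Brute-force minimizer of summed squared perpendicular ray distances.

    ``rays`` are ((x, y), bearing_deg) in a planar frame.  Coarse grid then
    two refinement passes; accurate to well under a meter.
    """

    def cost(x, y):
        total = 0.0
        for (px, py), brg in rays:
            ux, uy = math.sin(math.radians(brg)), math.cos(math.radians(brg))
            nx, ny = -uy, ux
            total += (nx * (x - px) + ny * (y - py)) ** 2
        return total

    cx = sum(p[0][0] for p in rays) / len(rays)
    cy = sum(p[0][1] for p in rays) / len(rays)
    best = (cx, cy)
    width = span
    for _ in range(6):
        xs = np.linspace(best[0] - width, best[0] + width, coarse)
        ys = np.linspace(best[1] - width, best[1] + width, coarse)
        costs = np.array([[cost(x, y) for x in xs] for y in ys])
        iy, ix = np.unravel_index(np.argmin(costs), costs.shape)
        best = (float(xs[ix]), float(ys[iy]))
        width /= 20.0
    return best
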