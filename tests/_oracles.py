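"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
loops, direct formulas, exhaustive enumeration) so it shares no code path
with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rasterize_colony_bruteforce(spec) -> tuple[int, int]:
    """Pixel-count (a_inner, a_outer) by per-pixel point tests.

    Scalar point-in-disc / point-in-rectangle tests in a double loop, plus
    a flood fill from the border to find enclosed voids. Only usable for
    small images.
    """
    w, h = spec.image_width, spec.image_height
    cx, cy = spec.center
    r2 = spec.inner_radius**2

    rects = []
    for fl in spec.filaments:
        if fl.length <= 0:
            continue
        start = fl.start_radius
        if start is None:
            start = max(0.0, spec.inner_radius - max(fl.width, 2.0))
        rects.append((math.cos(fl.angle), math.sin(fl.angle), start,
                      spec.inner_radius + fl.length, fl.width / 2.0))

    inside = np.zeros((h, w), dtype=bool)
    a_inner = 0
    for y in range(h):
        for x in range(w):
            dx, dy = x - cx, y - cy
            if dx * dx + dy * dy <= r2:
                a_inner += 1
                inside[y, x] = True
                continue
            for c, s, u0, u1, halfw in rects:
                u = dx * c + dy * s
                v = -dx * s + dy * c
                if u0 <= u <= u1 and abs(v) <= halfw:
                    inside[y, x] = True
                    break

    # flood fill the border-connected background; anything else is enclosed
    reach = np.zeros((h, w), dtype=bool)
    stack = [(y, x) for y in range(h) for x in (0, w - 1) if not inside[y, x]]
    stack += [(y, x) for x in range(w) for y in (0, h - 1) if not inside[y, x]]
    for y, x in stack:
        reach[y, x] = True
    while stack:
        y, x = stack.pop()
        for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
            if 0 <= ny < h and 0 <= nx < w and not inside[ny, nx] and not reach[ny, nx]:
                reach[ny, nx] = True
                stack.append((ny, nx))
    a_outer = int(inside.sum() + ((~inside) & (~reach)).sum())
    return a_inner, a_outer


def otsu_exhaustive(gray: np.ndarray) -> int:
    """Best integer threshold by exhaustive between-class-variance scan.

    Foreground is defined as intensity > t; returns the t in 0..254
    maximizing w0*w1*(mu0-mu1)^2.
    """
    x = gray.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(255):
        fg = x > t
        n1 = fg.sum()
        n0 = x.size - n1
        if n0 == 0 or n1 == 0:
            continue
        v = (n0 / x.size) * (n1 / x.size) * (x[~fg].mean() - x[fg].mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def ranks_bruteforce(values) -> list[float]:
    """Mid-ranks by explicit sorting and tie-group averaging."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kw_h_bruteforce(groups) -> float:
    """Tie-adjusted Kruskal-Wallis H from first principles."""
    pooled = [float(v) for g in groups for v in g]
    n = len(pooled)
    ranks = ranks_bruteforce(pooled)
    # tie correction
    tie = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie += t**3 - t
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        rbar = sum(ranks[start : start + k]) / k
        h += k * (rbar - (n + 1) / 2.0) ** 2
        start += k
    h *= 12.0 / (n * (n + 1))
    return h / (1.0 - tie / (n**3 - n))


def kw_permutation_p(groups, h_func) -> float:
    """Exact permutation p-value: P(H >= H_obs) over all group assignments.

    Enumerates every distinct assignment of the pooled values to the group
    sizes. Feasible only for total N <= ~9.
    """
    pooled = [float(v) for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = h_func(groups)
    n_total = len(pooled)
    count = 0
    total = 0
    idx = list(range(n_total))
    for perm in itertools.permutations(idx):
        parts, start = [], 0
        for s in sizes:
            parts.append([pooled[i] for i in perm[start : start + s]])
            start += s
        total += 1
        if h_func(parts) >= h_obs - 1e-12:
            count += 1
    return count / total
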