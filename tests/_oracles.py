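"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, BFS flood fill,
full enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np

_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def flood_fill_components(mask: np.ndarray, connectivity: int = 8
                          ) -> list[set[tuple[int, int]]]:
    """Connected components of a boolean mask by BFS flood fill."""
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                y, x = queue.popleft()
                comp.add((y, x))
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                            and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            comps.append(comp)
    return comps


def otsu_exhaustive(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance by exhaustive search
    over the midpoints between consecutive distinct values."""
    values = np.asarray(values, dtype=float).ravel()
    distinct = np.unique(values)
    best_t, best_var = distinct[0], -1.0
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        t = (lo + hi) / 2.0
        below, above = values[values <= t], values[values > t]
        if below.size == 0 or above.size == 0:
            continue
        w0, w1 = below.size / values.size, above.size / values.size
        var = w0 * w1 * (below.mean() - above.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def mw_u_naive(a, b) -> float:
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mw_exact_p_naive(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1, n = len(a), len(a) + len(b)
    mu = len(a) * len(b) / 2.0
    dev_obs = abs(mw_u_naive(a, b) - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        sel = set(idx)
        ga = [pooled[i] for i in range(n) if i in sel]
        gb = [pooled[i] for i in range(n) if i not in sel]
        total += 1
        if abs(mw_u_naive(ga, gb) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and \
                values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h_textbook(groups: list[list[float]]) -> float:
    """H with tie correction from the textbook rank-sum formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r_sum = sum(ranks[start:start + len(g)])
        h += r_sum ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    correction = 1.0 - sum(t ** 3 - t for t in counts.values()) / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def min_chebyshev_gap_naive(pixels_a, pixels_b) -> float:
    """Boundary gap: min Chebyshev pixel distance minus 1, floored at 0."""
    best = float("inf")
    for (r1, c1) in pixels_a:
        for (r2, c2) in pixels_b:
            d = max(abs(r1 - r2), abs(c1 - c2))
            if d < best:
                best = d
    return max(0.0, best - 1.0)
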