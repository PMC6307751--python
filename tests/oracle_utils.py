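"""Independent brute-force oracles used to check the morphological
primitives. These deliberately share no code with the implementation:
plain nested loops and first-principles definitions."""

from __future__ import annotations

import itertools
import math

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def _min_filter(img: np.ndarray, offsets) -> np.ndarray:
    h, w = img.shape
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = []
            for dy, dx in offsets:
                rr, cc = r + dy, c + dx
                # reflect padding, matching the implementation's convention
                rr = min(max(rr, -rr - 1), 2 * h - rr - 1) if not (0 <= rr < h) else rr
                cc = min(max(cc, -cc - 1), 2 * w - cc - 1) if not (0 <= cc < w) else cc
                rr = min(max(rr, 0), h - 1)
                cc = min(max(cc, 0), w - 1)
                vals.append(img[rr, cc])
            out[r, c] = min(vals)
    return out


def _max_filter(img: np.ndarray, offsets) -> np.ndarray:
    return -_min_filter(-img, offsets)


def brute_tophat(img: np.ndarray, radius: int) -> np.ndarray:
    """Top-hat as min-then-max filtering over all disk offsets."""
    offsets = disk_offsets(radius)
    opening = _max_filter(_min_filter(img, offsets), offsets)
    return img - opening


def brute_distance_transform(mask: np.ndarray) -> np.ndarray:
    """O(N^2) Euclidean distance: per foreground pixel, the minimum over
    all background pixels of sqrt(dr^2 + dc^2)."""
    mask = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    for r, c in np.argwhere(mask):
        if bg.size == 0:
            out[r, c] = np.inf
        else:
            out[r, c] = math.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min())
    return out


def geodesic_hminima(img: np.ndarray, h: float, max_iter: int = 100000) -> np.ndarray:
    """Reconstruction by erosion of (img + h) above img, by iterating
    3x3 erosion followed by a pointwise max until convergence."""
    rec = img + h
    pad = np.pad
    for _ in range(max_iter):
        padded = pad(rec, 1, mode="edge")
        eroded = np.min(
            [padded[dy : dy + rec.shape[0], dx : dx + rec.shape[1]]
             for dy in range(3) for dx in range(3)],
            axis=0,
        )
        nxt = np.maximum(eroded, img)
        if np.array_equal(nxt, rec):
            return rec
        rec = nxt
    raise RuntimeError("geodesic erosion did not converge")


def count_regional_minima(img: np.ndarray) -> int:
    """Enumerate regional minima (8-connected plateaus with no lower
    neighbor) by explicit flood fill."""
    h, w = img.shape
    seen = np.zeros((h, w), dtype=bool)
    count = 0
    for r in range(h):
        for c in range(w):
            if seen[r, c]:
                continue
            level = img[r, c]
            stack = [(r, c)]
            plateau = []
            is_min = True
            visited = {(r, c)}
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if not (0 <= yy < h and 0 <= xx < w) or (dy == dx == 0):
                            continue
                        if img[yy, xx] < level:
                            is_min = False
                        elif img[yy, xx] == level and (yy, xx) not in visited:
                            visited.add((yy, xx))
                            stack.append((yy, xx))
            for y, x in plateau:
                seen[y, x] = True
            if is_min:
                count += 1
    return count


def exact_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p by exhausting all rank assignments
    (no ties assumed): the fraction of splits whose U statistic deviates
    from its null mean at least as much as the observed one."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(a), len(b)
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total
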