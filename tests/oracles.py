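"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by the most literal method available
(double loops, exhaustive search, union-find, all-pairs counting) and is
kept free of any code path it checks.
"""

from __future__ import annotations

import numpy as np


def conv_magnitude_oracle(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct spatial complex convolution with symmetric padding, |.| taken.

    Mirrors the contract of FFT filtering: pad by the kernel radius, convolve,
    crop back — computed as an explicit shift-and-sum over kernel taps.
    """
    r = kernel.shape[0] // 2
    h, w = plane.shape
    padded = np.pad(plane, r, mode="symmetric")
    out = np.zeros((h, w), dtype=complex)
    for a in range(kernel.shape[0]):
        for b in range(kernel.shape[1]):
            out += kernel[a, b] * padded[2 * r - a:2 * r - a + h,
                                         2 * r - b:2 * r - b + w]
    return np.abs(out)


def mean3x3_oracle(plane: np.ndarray) -> np.ndarray:
    """3x3 averaging with edge replication, via an explicit double loop."""
    h, w = plane.shape
    out = np.empty_like(plane, dtype=float)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    acc += plane[ii, jj]
            out[i, j] = acc / 9.0
    return out


def two_means_split_oracle(values: np.ndarray) -> float:
    """Optimal 1-D 2-means threshold by exhaustive split-point search.

    Returns the midpoint between the two cluster means of the split that
    minimizes total within-cluster variance.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    csum = np.cumsum(v)
    csq = np.cumsum(v ** 2)
    best_sse, best_thr = np.inf, None
    for k in range(1, n):  # k = size of lower cluster
        lo_sum, lo_sq = csum[k - 1], csq[k - 1]
        hi_sum, hi_sq = csum[-1] - lo_sum, csq[-1] - lo_sq
        sse = (lo_sq - lo_sum ** 2 / k) + (hi_sq - hi_sum ** 2 / (n - k))
        if sse < best_sse - 1e-15:
            best_sse = sse
            best_thr = (lo_sum / k + hi_sum / (n - k)) / 2.0
    return best_thr


def union_find_components(mask: np.ndarray, connectivity: int) -> int:
    """Number of connected true-components via explicit union-find."""
    h, w = mask.shape
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    offs = [(-1, 0), (0, -1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1)]
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            parent.setdefault((i, j), (i, j))
            for di, dj in offs:
                ii, jj = i + di, j + dj
                if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                    parent.setdefault((ii, jj), (ii, jj))
                    union((i, j), (ii, jj))
    return len({find(p) for p in parent})


def auroc_pairs_oracle(scores, labels) -> float:
    """All-pairs positive-vs-negative comparison with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def point_in_polygon_oracle(point, vertices) -> bool:
    """Even-odd ray casting; ``vertices`` are (row, col), point likewise."""
    r, c = point
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_int:
                inside = not inside
    return inside


def polyfit_normal_equations_oracle(x, y, degree: int) -> np.ndarray:
    """Least-squares polynomial via the explicit normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.vander(x, degree + 1)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta
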