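"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a different route than the package
(brute force, closed form, full-matrix dynamic programming, enumeration) so
that agreement is informative.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def gotoh_score(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
                gap_open: float = 6.0, gap_extend: float = 1.0) -> float:
    """Full-matrix affine-gap global alignment score.

    A gap of length L costs ``gap_open + L * gap_extend``. Row-vectorized
    Gotoh recursion; the in-row (insertion) state is resolved with a
    prefix-maximum identity instead of a column scan.
    """
    n, m = len(a), len(b)
    bs = np.frombuffer(b.encode(), dtype=np.uint8)
    jdx = np.arange(m + 1, dtype=float)

    M = np.full(m + 1, NEG)
    X = np.full(m + 1, NEG)           # gap in b (deletion from a)
    Y = np.full(m + 1, NEG)           # gap in a (insertion into b)
    M[0] = 0.0
    Y[1:] = -(gap_open + gap_extend * jdx[1:])
    for i in range(1, n + 1):
        sub = np.where(bs == ord(a[i - 1]), match, mismatch)
        best_prev = np.maximum(np.maximum(M, X), Y)
        Mn = np.full(m + 1, NEG)
        Mn[1:] = best_prev[:-1] + sub
        Xn = np.maximum(np.maximum(M, Y) - gap_open - gap_extend,
                        X - gap_extend)
        Xn[0] = -(gap_open + gap_extend * i)
        # Y[j] = max_{k<j} (max(Mn,Xn)[k] - gap_open) - gap_extend*(j-k)
        B = np.maximum(Mn, Xn) - gap_open + gap_extend * jdx
        Yn = np.full(m + 1, NEG)
        Yn[1:] = np.maximum.accumulate(B[:-1]) - gap_extend * jdx[1:]
        Mn[0] = NEG
        M, X, Y = Mn, Xn, Yn
    return float(max(M[m], X[m], Y[m]))


def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """26-connected component labels by breadth-first flood fill.

    Labels are 1..K in raster order of each component's first voxel.
    """
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    next_label = 0
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        next_label += 1
        stack = [idx]
        labels[idx] = next_label
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1]
                        and 0 <= nx < mask.shape[2]
                        and mask[nz, ny, nx] and not labels[nz, ny, nx]):
                    labels[nz, ny, nx] = next_label
                    stack.append((nz, ny, nx))
    return labels


def partitions_equal(l1: np.ndarray, l2: np.ndarray) -> bool:
    """Whether two labelings define the same partition (up to relabeling)."""
    if (l1 > 0).sum() != (l2 > 0).sum() or l1.max() != l2.max():
        return False
    pairs = set(zip(l1[l1 > 0].ravel(), l2[l1 > 0].ravel()))
    return (len(pairs) == l1.max()
            and len({p[0] for p in pairs}) == len({p[1] for p in pairs}) == l1.max())


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a Markov chain via the unit eigenvector."""
    w, v = np.linalg.eig(np.asarray(P, float).T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def pearson_textbook(x: np.ndarray, y: np.ndarray):
    """Pearson r, two-sided t-test p, and 95% Fisher-z CI from the textbook
    formulas, written without reuse of the package code."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r_num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    r_den = np.sqrt((n * np.sum(x ** 2) - np.sum(x) ** 2)
                    * (n * np.sum(y ** 2) - np.sum(y) ** 2))
    r = r_num / r_den
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * tdist.sf(abs(t), n - 2)
    z = 0.5 * np.log((1 + r) / (1 - r))
    half = 1.96 / np.sqrt(n - 3)
    ci = (np.tanh(z - half), np.tanh(z + half))
    return r, p, ci
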