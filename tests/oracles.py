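"""Independent brute-force reference implementations used by the tests.

Everything here is written as plainly as possible — nested loops, explicit
enumeration — and deliberately shares no code with the package internals it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]
OFFSETS_26 = [o for d in OFFSETS_13 for o in (d, tuple(-x for x in d))]


def discretize(values, n_levels):
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=int)
    width = (hi - lo) / n_levels
    lev = np.floor((values - lo) / width).astype(int) + 1
    return np.clip(lev, 1, n_levels)


def inb(idx, shape):
    return all(0 <= i < s for i, s in zip(idx, shape))


def glcm_matrix(level_vol, n_levels, distance=1):
    """Symmetric co-occurrence counts, 13 directions pooled, by full loops."""
    mat = np.zeros((n_levels, n_levels))
    shape = level_vol.shape
    for x, y, z in itertools.product(*map(range, shape)):
        if level_vol[x, y, z] <= 0:
            continue
        for dx, dy, dz in OFFSETS_13:
            q = (x + dx * distance, y + dy * distance, z + dz * distance)
            if not inb(q, shape) or level_vol[q] <= 0:
                continue
            a, b = level_vol[x, y, z], level_vol[q]
            mat[a - 1, b - 1] += 1
            mat[b - 1, a - 1] += 1
    return mat


def runs_one_direction(level_vol, direction):
    """All (level, length) runs along one direction, exhaustively."""
    shape = level_vol.shape
    d = np.asarray(direction)
    runs = []
    for start in itertools.product(*map(range, shape)):
        g = level_vol[start]
        if g <= 0:
            continue
        prev = tuple(np.asarray(start) - d)
        if inb(prev, shape) and level_vol[prev] == g:
            continue
        length = 1
        cur = tuple(np.asarray(start) + d)
        while inb(cur, shape) and level_vol[cur] == g:
            length += 1
            cur = tuple(np.asarray(cur) + d)
        runs.append((g, length))
    return runs


def glrlm_matrix(level_vol, n_levels):
    max_len = max(level_vol.shape)
    mat = np.zeros((n_levels, max_len))
    for d in OFFSETS_13:
        for g, length in runs_one_direction(level_vol, d):
            mat[g - 1, length - 1] += 1
    return mat


def zones(level_vol):
    """26-connected equal-level zones by explicit flood fill."""
    shape = level_vol.shape
    seen = np.zeros(shape, dtype=bool)
    out = []
    for start in itertools.product(*map(range, shape)):
        g = level_vol[start]
        if g <= 0 or seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for dd in itertools.product((-1, 0, 1), repeat=3):
                if dd == (0, 0, 0):
                    continue
                q = tuple(np.asarray(cur) + dd)
                if inb(q, shape) and not seen[q] and level_vol[q] == g:
                    seen[q] = True
                    stack.append(q)
        out.append((g, size))
    return out


def glszm_matrix(level_vol, n_levels):
    n_vox = int((level_vol > 0).sum())
    mat = np.zeros((n_levels, max(n_vox, 1)))
    for g, size in zones(level_vol):
        mat[g - 1, size - 1] += 1
    return mat


def gldm_matrix(level_vol, n_levels, alpha=0):
    shape = level_vol.shape
    mat = np.zeros((n_levels, 27))
    for p in itertools.product(*map(range, shape)):
        g = level_vol[p]
        if g <= 0:
            continue
        dep = 0
        for dd in OFFSETS_26:
            q = tuple(np.asarray(p) + dd)
            if inb(q, shape) and level_vol[q] > 0 and abs(level_vol[q] - g) <= alpha:
                dep += 1
        mat[g - 1, dep] += 1
    return mat


def ngtdm_table(level_vol, n_levels):
    shape = level_vol.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for p in itertools.product(*map(range, shape)):
        g = level_vol[p]
        if g <= 0:
            continue
        nb = []
        for dd in itertools.product((-1, 0, 1), repeat=3):
            if dd == (0, 0, 0):
                continue
            q = tuple(np.asarray(p) + dd)
            if inb(q, shape) and level_vol[q] > 0:
                nb.append(level_vol[q])
        if nb:
            n_i[g - 1] += 1
            s_i[g - 1] += abs(g - sum(nb) / len(nb))
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def auc_pair_count(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def delong_components(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                             for q in neg]) for p in pos])
    v01 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                             for p in pos]) for q in neg])
    return v10, v01


def silhouette(X, labels):
    """Mean silhouette by explicit pairwise distances; singletons score 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = math.dist(X[i], X[j])
    scores = []
    for i in range(n):
        same = (labels == labels[i])
        if same.sum() == 1:
            scores.append(0.0)
            continue
        a = d[i, same & (np.arange(n) != i)].mean()
        b = min(d[i, labels == c].mean()
                for c in np.unique(labels) if c != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def icc21(X):
    """ICC(2,1) from explicit two-way ANOVA sums of squares."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = X.mean()
    msr = k * sum((X[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((X[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((X[i, j] - X[i].mean() - X[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def net_benefit(probs, labels, pt):
    n = len(labels)
    tp = sum(1 for p, y in zip(probs, labels) if p >= pt and y == 1)
    fp = sum(1 for p, y in zip(probs, labels) if p >= pt and y == 0)
    return tp / n - (fp / n) * pt / (1 - pt)


def exact_shapley(predict, x, background_rows):
    """Exact Shapley values by enumerating all coalitions.

    Absent features are averaged over the background rows.
    """
    p = len(x)
    phi = np.zeros(p)
    B = np.asarray(background_rows, dtype=float)

    def value(subset):
        out = []
        for b in B:
            z = b.copy()
            for j in subset:
                z[j] = x[j]
            out.append(z)
        return float(np.mean(predict(np.asarray(out))))

    for j in range(p):
        others = [i for i in range(p) if i != j]
        for r in range(p):
            for subset in itertools.combinations(others, r):
                w = (math.factorial(len(subset))
                     * math.factorial(p - len(subset) - 1) / math.factorial(p))
                phi[j] += w * (value(subset + (j,)) - value(subset))
    return phi
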