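"""Independent brute-force oracles used only by the test suite.

Every oracle here is a direct, loop-based transcription of the defining
enumeration (pair counting, maximal-run scanning, flood fill, neighborhood
averaging, exhaustive support search) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def glcm_oracle(levels: np.ndarray, mask: np.ndarray, offsets, distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence probabilities by exhaustive pair enumeration."""
    ng = int(levels[mask].max())
    P = np.zeros((ng, ng))
    shape = levels.shape
    for v in product(*[range(s) for s in shape]):
        if not mask[v]:
            continue
        for off in offsets:
            w = tuple(v[k] + distance * off[k] for k in range(3))
            if all(0 <= w[k] < shape[k] for k in range(3)) and mask[w]:
                P[levels[v] - 1, levels[w] - 1] += 1
                P[levels[w] - 1, levels[v] - 1] += 1
    total = P.sum()
    return P / total if total else P


def glrlm_oracle(levels: np.ndarray, mask: np.ndarray, directions) -> np.ndarray:
    """Maximal-run counts per direction by explicit run walking."""
    shape = levels.shape
    ng = int(levels[mask].max())
    lmax = max(shape)
    R = np.zeros((ng, lmax), dtype=int)

    def inside(v):
        return all(0 <= v[k] < shape[k] for k in range(3)) and mask[v]

    for d in directions:
        for v in product(*[range(s) for s in shape]):
            if not inside(v):
                continue
            prev = tuple(v[k] - d[k] for k in range(3))
            # only count a run at its first voxel
            if inside(prev) and levels[prev] == levels[v]:
                continue
            length = 1
            w = tuple(v[k] + d[k] for k in range(3))
            while inside(w) and levels[w] == levels[v]:
                length += 1
                w = tuple(w[k] + d[k] for k in range(3))
            R[levels[v] - 1, length - 1] += 1
    return R


def glszm_oracle(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """26-connected equal-level zone counts by flood fill."""
    shape = levels.shape
    ng = int(levels[mask].max())
    seen = np.zeros(shape, dtype=bool)
    neigh = [n for n in product((-1, 0, 1), repeat=3) if n != (0, 0, 0)]
    zones = []
    for v in product(*[range(s) for s in shape]):
        if not mask[v] or seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for n in neigh:
                w = tuple(u[k] + n[k] for k in range(3))
                if (
                    all(0 <= w[k] < shape[k] for k in range(3))
                    and mask[w]
                    and not seen[w]
                    and levels[w] == g
                ):
                    seen[w] = True
                    stack.append(w)
        zones.append((g, size))
    smax = max(s for _, s in zones)
    Z = np.zeros((ng, smax), dtype=int)
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def ngtdm_oracle(levels: np.ndarray, mask: np.ndarray):
    """Per-level neighborhood difference sums/probabilities by direct loops."""
    shape = levels.shape
    ng = int(levels[mask].max())
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=int)
    neigh = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for v in product(*[range(sz) for sz in shape]):
        if not mask[v]:
            continue
        vals = [
            levels[tuple(v[k] + d[k] for k in range(3))]
            for d in neigh
            if all(0 <= v[k] + d[k] < shape[k] for k in range(3))
            and mask[tuple(v[k] + d[k] for k in range(3))]
        ]
        if not vals:
            continue
        s[levels[v] - 1] += abs(levels[v] - float(np.mean(vals)))
        n[levels[v] - 1] += 1
    nv = int(n.sum())
    p = n / nv if nv else n.astype(float)
    return s, p, n, nv


def exhaustive_l0_rss(F: np.ndarray, l: np.ndarray, k: int):
    """Best support of size <= k by exhaustive least-squares enumeration.

    Returns (best_rss, best_support)."""
    p = F.shape[1]
    best = (float(l @ l), ())
    for size in range(1, k + 1):
        for supp in combinations(range(p), size):
            Fs = F[:, supp]
            coef, *_ = np.linalg.lstsq(Fs, l, rcond=None)
            r = l - Fs @ coef
            rss = float(r @ r)
            if rss < best[0] - 1e-12:
                best = (rss, supp)
    return best


def mann_whitney_enumeration(x, y):
    """Two-tailed exact Mann-Whitney p by enumerating all label assignments."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    n = pooled.size

    def u_of(idx):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        ranks = rankdata(pooled)
        return ranks[sel].sum() - n1 * (n1 + 1) / 2

    mu = n1 * (n - n1) / 2.0
    ranks = rankdata(pooled)

    def u_from(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_from(range(n1))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_from(idx) - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def auc_pair_counting(scores, labels):
    """AUC as the fraction of concordant positive-negative pairs (ties 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (pos.size * neg.size)
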