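"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (flood fill, O(n^2) scans, explicit
loops) so it cannot share a defect with the vectorized package code.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def flood_fill_components(voxels: np.ndarray, connectivity: int) -> list[set]:
    """Exhaustive flood fill over an explicit voxel set."""
    offsets = []
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        dist = sum(abs(d) for d in off)
        if connectivity == 6 and dist > 1:
            continue
        if connectivity == 18 and dist > 2:
            continue
        offsets.append(off)
    remaining = {tuple(v) for v in np.asarray(voxels).reshape(-1, 3)}
    comps = []
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        remaining.discard(seed)
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def brute_max_diameter(voxels: np.ndarray, spacing, plane: str) -> float:
    axes = {"xz": (0, 2), "yz": (1, 2)}[plane]
    pts = np.asarray(voxels, dtype=float).reshape(-1, 3)[:, axes]
    pts = pts * np.asarray(spacing, dtype=float)[list(axes)]
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.hypot(*(pts[i] - pts[j])))
            best = max(best, d)
    return best


def _neighbors(idx, shape):
    out = []
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        nb = tuple(i + d for i, d in zip(idx, off))
        if all(0 <= n < s for n, s in zip(nb, shape)):
            out.append(nb)
    return out


def gldm_bruteforce(levels: np.ndarray, mask: np.ndarray, alpha: float) -> np.ndarray:
    """P[i-1, j-1] by per-voxel neighbor scanning."""
    n_levels = int(levels[mask].max())
    P = np.zeros((n_levels, 27), dtype=np.int64)
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        dep = 1
        for nb in _neighbors(idx, mask.shape):
            if mask[nb] and abs(int(levels[nb]) - int(levels[idx])) <= alpha:
                dep += 1
        P[int(levels[idx]) - 1, dep - 1] += 1
    return P


def ngtdm_bruteforce(levels: np.ndarray, mask: np.ndarray):
    """Per-level (n_i, s_i) plus the valid-voxel count, by explicit scans."""
    n_levels = int(levels[mask].max())
    n = np.zeros(n_levels, dtype=np.int64)
    s = np.zeros(n_levels, dtype=float)
    n_valid = 0
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        nb_levels = [int(levels[nb]) for nb in _neighbors(idx, mask.shape) if mask[nb]]
        if not nb_levels:
            continue
        n_valid += 1
        lv = int(levels[idx])
        n[lv - 1] += 1
        s[lv - 1] += abs(lv - sum(nb_levels) / len(nb_levels))
    return n, s, n_valid


def ngtdm_complexity_bruteforce(levels: np.ndarray, mask: np.ndarray) -> float:
    n, s, n_valid = ngtdm_bruteforce(levels, mask)
    if n_valid == 0:
        return 0.0
    p = n / n_valid
    total = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            if p[i] > 0 and p[j] > 0:
                total += abs((i + 1) - (j + 1)) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
    return total / n_valid


def subband_bruteforce(patch: np.ndarray, letters: str, lo, hi) -> np.ndarray:
    """Triple-loop separable circular correlation: y[i] = sum_k h[k] x[i+k]."""
    taps = {"L": np.asarray(lo, float), "H": np.asarray(hi, float)}
    out = np.asarray(patch, dtype=float)
    for axis, letter in enumerate(letters):
        h = taps[letter]
        src = out.copy()
        out = np.zeros_like(src)
        n = src.shape[axis]
        for pos in range(n):
            sl = [slice(None)] * 3
            sl[axis] = pos
            acc = np.zeros_like(np.take(src, 0, axis=axis))
            for k, t in enumerate(h):
                acc = acc + t * np.take(src, (pos + k) % n, axis=axis)
            out[tuple(sl)] = acc
    return out


def newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-12) -> np.ndarray:
    """Plain Newton-Raphson on the logistic log-likelihood (with intercept)."""
    X = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-X @ beta))
        grad = X.T @ (y - mu)
        hess = X.T @ (X * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def roc_auc_mannwhitney(scores, labels) -> float:
    """ROC AUC as the normalized Mann-Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
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


def expected_kappa_from_confusion(confusion: np.ndarray,
                                  true_dist: np.ndarray) -> float:
    """Population kappa of (truth, simulated reader) by enumerating the
    joint distribution P(true=i, reported=j) = pi_i C[i, j]."""
    C = np.asarray(confusion, float)
    pi = np.asarray(true_dist, float)
    joint = pi[:, None] * C
    po = np.trace(joint)
    q = joint.sum(axis=0)
    pe = float((pi * q).sum())
    return (po - pe) / (1 - pe)
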