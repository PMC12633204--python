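"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by a route independent of the
implementation it checks: enumeration, closed forms, or a from-scratch
reference algorithm.
"""

from __future__ import annotations

import itertools

import numpy as np


def nipals_pls1(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """One-component PLS1 by the classical NIPALS recursion.

    Returns (w, t, q) with unit-norm w. Independent of the package's O-PLS
    code path.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = X.T @ y
    w = w / np.sqrt(w @ w)
    t = X @ w
    q = float(y @ t / (t @ t))
    return w, t, q


def exhaustive_pair_score(
    mz_a: np.ndarray,
    int_a: np.ndarray,
    mz_b: np.ndarray,
    int_b: np.ndarray,
    fragment_tol: float,
    shift: float | None = None,
) -> float:
    """Maximum cosine over all one-to-one peak pairings, by enumeration.

    Candidate pairs are those within ``fragment_tol`` directly or (when
    ``shift`` is given) after subtracting the precursor mass difference.
    Every subset of candidate pairs forming a one-to-one matching is tried.
    """
    sqrt_a, sqrt_b = np.sqrt(int_a), np.sqrt(int_b)
    candidates = []
    for i in range(len(mz_a)):
        for j in range(len(mz_b)):
            d = mz_a[i] - mz_b[j]
            if abs(d) <= fragment_tol or (shift is not None and abs(d - shift) <= fragment_tol):
                candidates.append((i, j, sqrt_a[i] * sqrt_b[j]))
    best = 0.0

    def extend(k: int, used_a: set, used_b: set, total: float) -> None:
        nonlocal best
        best = max(best, total)
        for idx in range(k, len(candidates)):
            i, j, w = candidates[idx]
            if i in used_a or j in used_b:
                continue
            extend(idx + 1, used_a | {i}, used_b | {j}, total + w)

    extend(0, set(), set(), 0.0)
    norm = np.sqrt(int_a.sum()) * np.sqrt(int_b.sum())
    return best / norm if norm > 0 else 0.0


def permanova_f(D2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from a squared distance matrix, written from the definition."""
    n = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += D2[i, j]
    ss_total /= n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += D2[idx[a], idx[b]]
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    g = np.unique(labels).size
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def exact_two_group_p(D2: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p over all distinct two-group assignments."""
    n = len(labels)
    groups = np.unique(labels)
    assert groups.size == 2
    n1 = int((labels == groups[0]).sum())
    f_obs = permanova_f(D2, labels)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        perm = np.full(n, groups[1], dtype=labels.dtype)
        perm[list(combo)] = groups[0]
        if permanova_f(D2, perm) >= f_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, from the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson coefficient from the definitional formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
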