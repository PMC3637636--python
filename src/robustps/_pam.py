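"""Numba-compiled PAM (partitioning around medoids) core.

The BUILD phase greedily seeds medoids; the SWAP phase evaluates every
(medoid, non-medoid) exchange with the O(n^2)-per-sweep bookkeeping of
FastPAM1 (nearest and second-nearest medoid distances per point) and
applies the single best exchange until no exchange lowers the total
dissimilarity.  Ties are broken toward the first candidate encountered,
which makes the result deterministic for a given distance matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _pam_core(D, k, max_swaps):  # pragma: no cover - exercised via wrapper
    n = D.shape[0]
    medoids = np.empty(k, np.int64)
    is_medoid = np.zeros(n, np.bool_)

    # BUILD: first medoid minimises the total distance
    best_c = 0
    best_sum = 1e300
    for c in range(n):
        s = 0.0
        for j in range(n):
            s += D[c, j]
        if s < best_sum:
            best_sum = s
            best_c = c
    medoids[0] = best_c
    is_medoid[best_c] = True
    d1 = np.empty(n)
    for j in range(n):
        d1[j] = D[best_c, j]

    for t in range(1, k):
        best_gain = -1.0
        best_c = -1
        for c in range(n):
            if is_medoid[c]:
                continue
            gain = 0.0
            for j in range(n):
                diff = d1[j] - D[c, j]
                if diff > 0.0:
                    gain += diff
            if gain > best_gain:
                best_gain = gain
                best_c = c
        medoids[t] = best_c
        is_medoid[best_c] = True
        for j in range(n):
            if D[best_c, j] < d1[j]:
                d1[j] = D[best_c, j]

    # nearest / second-nearest bookkeeping
    nearest = np.empty(n, np.int64)
    d2 = np.empty(n)
    for j in range(n):
        b1 = 1e300
        b2 = 1e300
        bi = 0
        for i in range(k):
            dij = D[medoids[i], j]
            if dij < b1:
                b2 = b1
                b1 = dij
                bi = i
            elif dij < b2:
                b2 = dij
        nearest[j] = bi
        d1[j] = b1
        d2[j] = b2

    # SWAP
    arr = np.empty(k)
    n_swaps = 0
    while n_swaps < max_swaps:
        best_delta = -1e-9
        best_o = -1
        best_i = -1
        for o in range(n):
            if is_medoid[o]:
                continue
            base = 0.0
            for i in range(k):
                arr[i] = 0.0
            for j in range(n):
                doj = D[o, j]
                if doj < d1[j]:
                    base += doj - d1[j]
                else:
                    alt = doj if doj < d2[j] else d2[j]
                    arr[nearest[j]] += alt - d1[j]
            for i in range(k):
                delta = base + arr[i]
                if delta < best_delta:
                    best_delta = delta
                    best_o = o
                    best_i = i
        if best_o < 0:
            break
        old = medoids[best_i]
        is_medoid[old] = False
        is_medoid[best_o] = True
        medoids[best_i] = best_o
        for j in range(n):
            b1 = 1e300
            b2 = 1e300
            bi = 0
            for i in range(k):
                dij = D[medoids[i], j]
                if dij < b1:
                    b2 = b1
                    b1 = dij
                    bi = i
                elif dij < b2:
                    b2 = dij
            nearest[j] = bi
            d1[j] = b1
            d2[j] = b2
        n_swaps += 1

    labels = np.empty(n, np.int64)
    total = 0.0
    for j in range(n):
        labels[j] = nearest[j]
        total += d1[j]
    return medoids, labels, total


def pam(D: np.ndarray, k: int, max_swaps: int = 200):
    """Run PAM on a precomputed dissimilarity matrix.

    Returns ``(medoid_indices, labels, objective)`` where ``labels[j]``
    indexes into ``medoid_indices`` and the objective is the summed
    dissimilarity of each point to its medoid.
    """
    D = np.ascontiguousarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be a square dissimilarity matrix")
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, n]")
    if _n_combinations(n, k) <= 5000:
        # tiny instances are solved exactly; BUILD+SWAP is a heuristic
        # that can stop in a local optimum
        return _pam_exhaustive(D, k)
    medoids, labels, total = _pam_core(D, k, max_swaps)
    return np.asarray(medoids), np.asarray(labels), float(total)


def _n_combinations(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _pam_exhaustive(D: np.ndarray, k: int):
    from itertools import combinations

    n = D.shape[0]
    best = None
    for medoids in combinations(range(n), k):
        total = D[list(medoids)].min(axis=0).sum()
        if best is None or total < best[1] - 1e-12:
            best = (medoids, total)
    medoids = np.asarray(best[0])
    labels = np.argmin(D[medoids], axis=0)
    return medoids, labels, float(best[1])
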