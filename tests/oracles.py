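"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most direct method available —
exhaustive enumeration, naive O(n^3) agglomeration, numerical quadrature —
deliberately sharing no code with the library path it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.integrate import quad


def hypergeom_tail_pvalue(n_ab: int, n_a: int, n_b: int, n_tot: int) -> float:
    """One-sided Fisher p-value by direct hypergeometric enumeration."""
    lo = max(0, n_a + n_b - n_tot)
    hi = min(n_a, n_b)
    denom = comb(n_tot, n_b)
    return sum(
        comb(n_a, x) * comb(n_tot - n_a, n_b - x) for x in range(max(n_ab, lo), hi + 1)
    ) / denom


def bh_reject_set(pvalues: np.ndarray, alpha: float, n_tests: int | None = None) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p) if n_tests is None else n_tests
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k = rank
    reject = np.zeros(len(p), dtype=bool)
    reject[order[:k]] = True
    return reject


def disparity_alpha_quadrature(p_ij: float, k: int) -> float:
    """alpha_ij = 1 - (k-1) * integral_0^p (1-x)^(k-2) dx by quadrature."""
    if k < 2:
        return 1.0
    integral, _ = quad(lambda x: (1.0 - x) ** (k - 2), 0.0, p_ij)
    return 1.0 - (k - 1) * integral


def naive_upgma_partition(dist: np.ndarray, cutoff: float) -> set[frozenset[int]]:
    """O(n^3) unweighted average-linkage agglomeration, cut below ``cutoff``.

    Repeatedly merges the pair of clusters with the smallest mean
    inter-cluster distance (ties broken by the smallest member index) while
    that distance is < cutoff. Returns the partition as index sets.
    """
    clusters: list[list[int]] = [[i] for i in range(len(dist))]
    while len(clusters) > 1:
        best_key, best_pair = None, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = float(
                    np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                )
                key = (avg, min(clusters[a] + clusters[b]))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (a, b)
        if best_key[0] >= cutoff:
            break
        a, b = best_pair
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return {frozenset(c) for c in clusters}
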