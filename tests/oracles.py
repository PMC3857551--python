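"""Brute-force reference implementations used to cross-check the library.

These are deliberately naive (O(n^3) agglomeration, explicit LCA traversal,
textbook Pearson formula) and share no code with the package.
"""

from __future__ import annotations

import math


def condensed_index(n, i, j):
    if i > j:
        i, j = j, i
    return n * i - i * (i + 1) // 2 + (j - i - 1)


def brute_single_linkage(dist, n):
    """Naive agglomeration by minimum inter-cluster distance.

    Returns merge records (left_members, right_members, height) where the
    member sets identify clusters unambiguously regardless of id scheme.
    """
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(
                    dist[condensed_index(n, i, j)]
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
    return merges


def brute_cophenetic(merges, n):
    """Cophenetic distances by explicit lowest-common-merge lookup."""
    coph = [0.0] * (n * (n - 1) // 2)
    seen = [frozenset([i]) for i in range(n)]
    for left, right, h in merges:
        for i in left:
            for j in right:
                coph[condensed_index(n, i, j)] = h
    return coph


def brute_pearson(x, y):
    """Textbook Pearson correlation coefficient."""
    nx = len(x)
    mx = sum(x) / nx
    my = sum(y) / nx
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_ccc(dist, n):
    """Cophenetic correlation via the three brute-force pieces above."""
    merges = brute_single_linkage(dist, n)
    coph = brute_cophenetic(merges, n)
    return brute_pearson(list(dist), coph)


def brute_matmul(A, B):
    """Triple-loop matrix product."""
    n, k = len(A), len(A[0])
    m = len(B[0])
    C = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            s = 0.0
            for t in range(k):
                s += A[i][t] * B[t][j]
            C[i][j] = s
    return C


def random_ultrametric(rng, n):
    """Condensed ultrametric distances from a random agglomeration order."""
    clusters = [[i] for i in range(n)]
    dist = [0.0] * (n * (n - 1) // 2)
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.05, 0.5))
        a, b = sorted(rng.choice(len(clusters), size=2, replace=False))
        for i in clusters[a]:
            for j in clusters[b]:
                dist[condensed_index(n, i, j)] = h
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return dist
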