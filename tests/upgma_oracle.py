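"""Brute-force average-linkage (UPGMA) reference, independent of scipy.

Clusters are plain index sets; the distance between two clusters is the
arithmetic mean of all pairwise original distances; at every step the
closest pair merges.  The dendrogram is summarized by its cophenetic
distance matrix (the merge height joining each leaf pair), which
characterizes the tree completely.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))

    def cluster_dist(a: frozenset[int], b: frozenset[int]) -> float:
        return float(np.mean([d[i, j] for i in a for j in b]))

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            dist = cluster_dist(a, b)
            if best is None or dist < best[0]:
                best = (dist, a, b)
        h, a, b = best
        for i in a:
            for j in b:
                coph[i, j] = coph[j, i] = h
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return coph
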