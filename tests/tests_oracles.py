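"""Independent brute-force oracles shared by the test suite."""

import itertools

import numpy as np


def brute_force_single_linkage(dist_matrix: np.ndarray) -> np.ndarray:
    """O(n^3) nearest-neighbour agglomeration; returns cophenetic distances."""
    n = dist_matrix.shape[0]
    clusters = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = min(dist_matrix[i, j] for i in clusters[a] for j in clusters[b])
            if d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] |= clusters[b]
        del clusters[b]
    return coph
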