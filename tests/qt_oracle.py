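"""Exhaustive-search oracle for QT clustering on small instances.

Enumerates every subset via bitmask dynamic programming over pairwise
distances, then repeatedly extracts the largest diameter-feasible subset
(ties resolved toward the subset containing the lowest index, matching the
lowest-seed tie-break), until the largest falls below the size floor.
Feasible only for n <= ~14.
"""

import numpy as np

from factorde.qtclust import distance_matrix


def exhaustive_qt(profiles, min_correlation, min_cluster_size):
    ids = list(profiles.index)
    n = len(ids)
    d = distance_matrix(profiles)
    thr = 1.0 - min_correlation

    diam = np.zeros(1 << n)
    for mask in range(1, 1 << n):
        j = (mask & -mask).bit_length() - 1
        rest = mask & ~(1 << j)
        if rest == 0:
            continue
        mx = 0.0
        m = rest
        while m:
            k = (m & -m).bit_length() - 1
            if d[j, k] > mx:
                mx = d[j, k]
            m &= m - 1
        diam[mask] = max(diam[rest], mx)

    alive = (1 << n) - 1
    clusters = []
    while True:
        best_size, best_mask = 0, None
        for mask in range(1, 1 << n):
            if mask & ~alive or diam[mask] > thr:
                continue
            size = bin(mask).count("1")
            if size > best_size:
                best_size, best_mask = size, mask
            elif size == best_size and best_mask is not None:
                if (mask & -mask) < (best_mask & -best_mask):
                    best_mask = mask
        if best_mask is None or best_size < min_cluster_size:
            break
        clusters.append([ids[i] for i in range(n) if best_mask >> i & 1])
        alive &= ~best_mask
    return clusters
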