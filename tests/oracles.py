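"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the vectorized code paths of the package: plain
Python loops and explicit run enumeration, so they can disagree with the
implementation if either has a logic error.
"""

from __future__ import annotations

import numpy as np


def brute_moving_average(series, halfwidth):
    """Mean of samples in [i - halfwidth, i + halfwidth], loop per index."""
    x = list(map(float, series))
    n = len(x)
    out = []
    for i in range(n):
        lo = max(0, i - halfwidth)
        hi = min(n - 1, i + halfwidth)
        window = x[lo : hi + 1]
        out.append(sum(window) / len(window))
    return np.asarray(out)


def brute_detect_peaks(values, percentile=99.0, min_run=4, min_separation=75):
    """Explicit run-enumeration peak detection.

    Returns a list of (t_peak, run_start, run_end, max_value) tuples with
    the same semantics as the production detector: strict threshold
    exceedance, runs of length >= min_run, earliest run maximum as the peak
    time, and greedy left-to-right merging of peaks closer than
    min_separation keeping the larger maximum (earlier run on ties).
    """
    x = list(map(float, values))
    thr = float(np.percentile(x, percentile))

    runs = []
    i = 0
    n = len(x)
    while i < n:
        if x[i] > thr:
            j = i
            while j + 1 < n and x[j + 1] > thr:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    candidates = []
    for start, end in runs:
        if end - start + 1 < min_run:
            continue
        best_idx, best_val = start, x[start]
        for k in range(start, end + 1):
            if x[k] > best_val:
                best_idx, best_val = k, x[k]
        candidates.append((best_idx, start, end, best_val))

    merged = []
    for cand in candidates:
        if merged and cand[0] - merged[-1][0] < min_separation:
            if cand[3] > merged[-1][3]:
                merged[-1] = cand
        else:
            merged.append(cand)
    return merged


def brute_average_linkage(points):
    """Naive agglomerative average-linkage clustering with Euclidean
    distance, returning a linkage matrix in the standard (left, right,
    height, size) encoding with clusters numbered n, n+1, ... in merge
    order. Inter-cluster distance is the unweighted mean of all pairwise
    point distances (UPGMA).
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    n = len(pts)
    clusters = {i: [i] for i in range(n)}
    linkage = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [
                        np.linalg.norm(pts[i] - pts[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        linkage.append([a, b, d, len(clusters[a]) + len(clusters[b])])
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.asarray(linkage)


def brute_leaf_order(linkage, n):
    """Left-to-right leaf order of a linkage matrix by recursive descent."""

    def leaves(node):
        if node < n:
            return [int(node)]
        left, right = linkage[int(node) - n][:2]
        return leaves(int(left)) + leaves(int(right))

    return leaves(2 * n - 2) if n > 1 else [0]
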