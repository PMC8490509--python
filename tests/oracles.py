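"""Independent brute-force references used across the test suite."""

from __future__ import annotations

import numpy as np


def disk_offsets(size_px: int) -> list[tuple[int, int]]:
    r = size_px // 2
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def sliding_extremum(image: np.ndarray, size_px: int, maximum: bool) -> np.ndarray:
    """Per-pixel min/max over the disk window intersected with the image.

    Direct definition: for every disk offset, shift the (inf-padded) image
    and reduce — no morphological decomposition shared with the code under
    test.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = size_px // 2
    fill = -np.inf if maximum else np.inf
    padded = np.full((h + 2 * r, w + 2 * r), fill)
    padded[r : r + h, r : r + w] = img
    out = np.full((h, w), fill)
    reduce_ = np.maximum if maximum else np.minimum
    for dy, dx in disk_offsets(size_px):
        np.copyto(out, reduce_(out, padded[r + dy : r + dy + h, r + dx : r + dx + w]))
    return out


def brute_top_hat(image: np.ndarray, size_px: int) -> np.ndarray:
    ero = sliding_extremum(image, size_px, maximum=False)
    opened = sliding_extremum(ero, size_px, maximum=True)
    return np.maximum(np.asarray(image, float) - opened, 0.0)


def brute_opening(image: np.ndarray, size_px: int) -> np.ndarray:
    ero = sliding_extremum(image, size_px, maximum=False)
    return sliding_extremum(ero, size_px, maximum=True)


def brute_centroid_linkage(X: np.ndarray) -> list[tuple[set, float, int]]:
    """O(n^3) agglomerative centroid linkage: greedy closest-centroid merges.

    Returns one (pair-of-cluster-ids, Euclidean height, merged size) per
    merge, with new clusters numbered n, n+1, ... (lowest-index tie-break).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    centroids: dict[int, tuple[np.ndarray, int]] = {i: (X[i].copy(), 1) for i in range(n)}
    merges: list[tuple[set, float, int]] = []
    nxt = n
    while len(centroids) > 1:
        keys = sorted(centroids)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = keys[i], keys[j]
                d = float(np.sqrt(((centroids[a][0] - centroids[b][0]) ** 2).sum()))
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        ca, na = centroids.pop(a)
        cb, nb = centroids.pop(b)
        centroids[nxt] = ((ca * na + cb * nb) / (na + nb), na + nb)
        merges.append(({a, b}, d, na + nb))
        nxt += 1
    return merges
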