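"""Independent exhaustive-search oracle for Otsu thresholding: loops over
every histogram split and computes the between-class variance directly."""

import numpy as np

N_BINS = 256


def brute_force_max(values, n_bins: int = N_BINS) -> float:
    hist, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = -np.inf
    for k in range(1, n_bins):
        w1, w2 = hist[:k].sum(), hist[k:].sum()
        if w1 == 0 or w2 == 0:
            continue
        m1 = (hist[:k] * centers[:k]).sum() / w1
        m2 = (hist[k:] * centers[k:]).sum() / w2
        best = max(best, w1 * w2 * (m1 - m2) ** 2)
    return best


def variance_at(values, threshold, n_bins: int = N_BINS) -> float:
    hist, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.searchsorted(edges, threshold, side="left"))
    k = min(max(k, 1), n_bins - 1)
    w1, w2 = hist[:k].sum(), hist[k:].sum()
    if w1 == 0 or w2 == 0:
        return -np.inf
    m1 = (hist[:k] * centers[:k]).sum() / w1
    m2 = (hist[k:] * centers[k:]).sum() / w2
    return float(w1 * w2 * (m1 - m2) ** 2)
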