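"""Shared independent oracles used by multiple test modules."""

import numpy as np


def brute_force_otsu_scan(volume, nbins=256):
    """Between-class variance of every candidate threshold over a
    256-bin histogram. Returns (thresholds, variances); a maximizer of
    the scan is an Otsu threshold (the maximum can be a plateau when
    empty bins separate the classes, so thresholds are compared by
    achieved variance, not position)."""
    counts, edges = np.histogram(np.asarray(volume).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    thresholds, variances = [], []
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        thresholds.append(centers[k - 1])
        variances.append(w0 * w1 * (m0 - m1) ** 2)
    return np.asarray(thresholds), np.asarray(variances)
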