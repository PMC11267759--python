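"""Histogram thresholding primitives shared by the imaging modules.

Both operate on a 256-bin histogram spanning [min, max] of the input and
return an intensity (a bin center), so results are invariant under affine
intensity rescaling up to bin quantization.
"""

from __future__ import annotations

import numpy as np

N_BINS = 256


def _histogram(values: np.ndarray):
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("degenerate histogram: input has a single value")
    counts, edges = np.histogram(values, bins=N_BINS, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def otsu(values: np.ndarray) -> float:
    """Otsu threshold: bin center maximizing between-class variance.

    Ties resolve to the lowest maximizing bin. The returned intensity
    separates classes as ``value > threshold``.
    """
    counts, centers = _histogram(values)
    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    mu_cum = np.cumsum(counts * centers)
    mu_tot = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu_cum / w0
        m1 = (mu_tot - mu_cum) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)
    # argmax returns the first (lowest) maximizing bin
    return float(centers[int(np.argmax(var_between))])


def triangle(values: np.ndarray) -> float:
    """Triangle threshold: bin center maximizing the perpendicular distance
    between the histogram and the line from its peak to the far end of the
    nonzero range (the longer-tail side). Ties resolve to the bin nearer
    the peak.
    """
    counts, centers = _histogram(values)
    nz = np.flatnonzero(counts)
    first, last = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(counts))
    # far end = the nonzero extreme on the longer side of the peak
    if peak - first >= last - peak:
        end = first
    else:
        end = last
    if end == peak:
        raise ValueError("degenerate histogram: peak coincides with range end")
    lo, hi = (end, peak) if end < peak else (peak, end)
    idx = np.arange(lo, hi + 1, dtype=float)
    h = counts[lo:hi + 1]
    # perpendicular distance from (idx, h) to the peak→end chord; the
    # common normalization constant is dropped (argmax-invariant)
    x1, y1 = float(peak), float(counts[peak])
    x2, y2 = float(end), float(counts[end])
    dist = np.abs((y2 - y1) * idx - (x2 - x1) * h + x2 * y1 - y2 * x1)
    # tie-break: bin nearer the peak
    best = dist.max()
    cand = np.flatnonzero(dist >= best - 1e-12)
    bins = idx[cand].astype(int)
    winner = bins[np.argmin(np.abs(bins - peak))]
    return float(centers[winner])
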