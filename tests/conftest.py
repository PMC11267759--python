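import numpy as np
import pytest
from hypothesis import settings

from stellaquant import synth
from stellaquant.types import CellMask

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ht_fixture():
    """One default holotomography volume with ground truth."""
    vol, gt = synth.gen_ht_volume(seed=0)
    return vol, gt


@pytest.fixture(scope="session")
def ht_mask(ht_fixture):
    vol, gt = ht_fixture
    return CellMask(gt.objects["cell_mask"], vol.voxel_size)


@pytest.fixture(scope="session")
def raman_fixture():
    scan, gt = synth.gen_raman_scan(seed=1)
    return scan, gt


@pytest.fixture(scope="session")
def trained_segmenter():
    """Segmentation model trained on 4 synthetic volumes (shared: training
    is the slowest step in the suite)."""
    from stellaquant import htseg

    vols, gts = zip(*[synth.gen_ht_volume(seed=s) for s in range(4)])
    feats = [htseg.compute_sharpness(v) for v in vols]
    masks = [CellMask(g.objects["cell_mask"], v.voxel_size)
             for g, v in zip(gts, vols)]
    return htseg.train_segmenter(list(feats), masks, split_seed=0)


def bfs_flood_fill_26(binary: np.ndarray):
    """Brute-force 26-connectivity component labeling (independent oracle)."""
    binary = np.asarray(binary).astype(bool)
    visited = np.zeros_like(binary)
    sizes = []
    offs = [(a, b, c)
            for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(binary & ~visited)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        n = 0
        while stack:
            z, y, x = stack.pop()
            n += 1
            for a, b, c in offs:
                p = (z + a, y + b, x + c)
                if (0 <= p[0] < binary.shape[0] and 0 <= p[1] < binary.shape[1]
                        and 0 <= p[2] < binary.shape[2]
                        and binary[p] and not visited[p]):
                    visited[p] = True
                    stack.append(p)
        sizes.append(n)
    return len(sizes), sizes


def otsu_oracle(values, n_bins=256):
    """Exhaustive between-class-variance scan (independent Otsu oracle)."""
    values = np.asarray(values, float).ravel()
    counts, edges = np.histogram(values, bins=n_bins,
                                 range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_t = -1.0, None
    total = counts.sum()
    for t in range(n_bins):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        m1 = (counts[t + 1:] * centers[t + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        # strictly better by a relative margin: plateau ties (empty bins
        # between modes) keep the lowest maximizing bin
        if v > best * (1 + 1e-12):
            best, best_t = v, t
    return centers[best_t]


def triangle_oracle(values, n_bins=256):
    """Exhaustive perpendicular-distance scan (independent Triangle oracle)."""
    values = np.asarray(values, float).ravel()
    counts, edges = np.histogram(values, bins=n_bins,
                                 range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    nz = np.flatnonzero(counts)
    peak = int(np.argmax(counts))
    end = int(nz[0]) if peak - nz[0] >= nz[-1] - peak else int(nz[-1])
    x1, y1 = peak, counts[peak]
    x2, y2 = end, counts[end]
    norm = np.hypot(x2 - x1, y2 - y1)
    best_d, best_bin = -1.0, None
    rng_bins = range(min(peak, end), max(peak, end) + 1)
    for b in rng_bins:
        d = abs((y2 - y1) * b - (x2 - x1) * counts[b] + x2 * y1 - y2 * x1) / norm
        better = d > best_d + 1e-12
        tie = abs(d - best_d) <= 1e-12
        if better or (tie and abs(b - peak) < abs(best_bin - peak)):
            best_d, best_bin = max(d, best_d), b
    return centers[best_bin]
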