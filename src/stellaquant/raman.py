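"""Confocal Raman large-area-scan preprocessing and band quantification.

The pipeline order is enforced: cosmic-ray removal → baseline subtraction
(arPLS fitted once per scan on the mean spectrum) → per-pixel unit-integral
normalization → band integration. Vitamin A is quantified in the
[1554, 1615] cm⁻¹ window (conjugated C=C stretch of retinoids), lipids in
the CH-stretch window [2800, 3000] cm⁻¹; their co-localization is the
Pearson correlation of the two per-pixel integral maps over the whole scan.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .types import BandMaps, BandWindow, LIPID_WINDOW, RamanScan, VA_WINDOW


def remove_cosmic_rays(scan: RamanScan, window: int = 5, k: float = 10.0) -> RamanScan:
    """Replace cosmic-ray spikes by the running median.

    Per pixel spectrum, a running median of length ``window`` is computed;
    channels whose residual exceeds ``k`` times the local robust scale are
    replaced by the running median. All other channels are bit-identical to
    the input.

    Two robustness details. First, residuals of a running median are
    systematically biased right at band extrema (the filter clips smooth
    peaks slightly) and that bias scales with band amplitude, not noise;
    the detector therefore compares each pixel's residual to the
    *per-channel* residual distribution across the whole scan, where the
    bias is common to every pixel and cancels (scans with fewer than 8
    pixels fall back to a per-spectrum scale). Second, the test is
    one-sided: cosmic-ray events only ever add counts, whereas a spike
    pulls the running median of its neighbouring channels upward, giving
    those victims spuriously *negative* residuals — a positive-only test
    leaves them untouched. A channel is flagged when its residual exceeds
    the channel's across-pixel median by more than ``k`` × 1.4826 × the
    channel's MAD (floored at the scan's typical channel MAD, since the
    MAD collapses to zero on steep, locally monotone flanks).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    n_ch = scan.cube.shape[2]
    if window >= n_ch:
        raise ValueError("window must be smaller than the channel count")
    cube = scan.cube
    med = ndimage.median_filter(cube, size=(1, 1, window), mode="reflect")
    resid = cube - med
    if scan.n_pixels >= 8:
        center = np.median(resid, axis=(0, 1), keepdims=True)
        mad = 1.4826 * np.median(np.abs(resid - center), axis=(0, 1),
                                 keepdims=True)
        scale = np.maximum(mad, np.median(mad))
        bad = resid - center > k * scale
    else:
        mad = 1.4826 * np.median(np.abs(resid), axis=2, keepdims=True)
        bad = resid > k * mad
    out = np.where(bad, med, cube)
    new = RamanScan(out, scan.wavenumbers, state=set(scan.state) | {"despiked"},
                    valid=scan.valid.copy())
    return new


def mean_spectrum(scan: RamanScan) -> np.ndarray:
    """Channel-wise arithmetic mean over all pixels of the scan."""
    if scan.n_pixels == 0:
        raise ValueError("empty scan")
    return scan.cube.mean(axis=(0, 1))


def arpls_baseline(
    spectrum: np.ndarray,
    lam: float = 1e5,
    ratio: float = 1e-3,
    max_iter: int = 100,
) -> np.ndarray:
    """Asymmetrically reweighted penalized least squares (arPLS) baseline.

    Iterates ``(W + λ DᵀD) z = W y`` with the second-difference matrix D and
    weights ``w_i = 1 / (1 + exp(2 (d_i − (2 s_d − m_d)) / s_d))`` where
    ``d = y − z`` and ``m_d, s_d`` are the mean and standard deviation of
    the negative residuals, until the relative change of the weight vector
    drops below ``ratio`` or ``max_iter`` is reached (then a warning is
    issued and the last iterate returned).

    ``lam`` controls smoothness (larger → stiffer baseline); in the large-λ
    limit the baseline tends to a straight line.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    y = np.asarray(spectrum, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("spectrum too short for a second-difference penalty")
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    H = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        W = sparse.diags(w, 0, format="csc")
        z = spsolve(W + H, w * y)
        d = y - z
        dn = d[d < 0]
        if dn.size == 0:
            return z
        m, s = dn.mean(), dn.std()
        if s == 0:
            return z
        arg = np.clip(2.0 * (d - (2.0 * s - m)) / s, -500, 500)
        w_new = 1.0 / (1.0 + np.exp(arg))
        if np.linalg.norm(w - w_new) / max(np.linalg.norm(w), 1e-300) < ratio:
            return z
        w = w_new
    warnings.warn("arPLS did not converge within max_iter; returning last iterate")
    return z


def subtract_baseline(
    scan: RamanScan,
    lam: float = 1e5,
    ratio: float = 1e-3,
    max_iter: int = 100,
    per_pixel: bool = False,
    allow_undespiked: bool = False,
) -> RamanScan:
    """Subtract the arPLS baseline fitted on the scan's mean spectrum.

    One baseline per scan (from the mean spectrum) is subtracted from every
    pixel spectrum; ``per_pixel=True`` instead fits each pixel separately
    (slower, not the default convention). Requires a despiked scan unless
    ``allow_undespiked``.
    """
    if "despiked" not in scan.state and not allow_undespiked:
        raise ValueError(
            "scan must be despiked before baseline subtraction "
            "(pass allow_undespiked=True to override)"
        )
    if per_pixel:
        out = np.empty_like(scan.cube)
        for i in range(scan.cube.shape[0]):
            for j in range(scan.cube.shape[1]):
                out[i, j] = scan.cube[i, j] - arpls_baseline(
                    scan.cube[i, j], lam, ratio, max_iter
                )
    else:
        base = arpls_baseline(mean_spectrum(scan), lam, ratio, max_iter)
        out = scan.cube - base[None, None, :]
    return RamanScan(out, scan.wavenumbers,
                     state=set(scan.state) | {"baselined"}, valid=scan.valid.copy())


def normalize_unit_integral(scan: RamanScan, allow_unbaselined: bool = False) -> RamanScan:
    """Rescale every pixel spectrum to unit trapezoidal integral over the
    full wavenumber axis.

    Pixels whose integral is non-positive are flagged invalid and left
    unscaled (they are excluded from downstream maps, never silently
    normalized).
    """
    if "baselined" not in scan.state and not allow_unbaselined:
        raise ValueError("scan must be baselined before normalization")
    integ = np.trapezoid(scan.cube, scan.wavenumbers, axis=2)
    valid = scan.valid & (integ > 0)
    if (~valid & scan.valid).any():
        warnings.warn(
            f"{int((~valid & scan.valid).sum())} pixel(s) with non-positive "
            "integral excluded from normalization"
        )
    scale = np.where(valid, integ, 1.0)
    out = scan.cube / scale[:, :, None]
    return RamanScan(out, scan.wavenumbers,
                     state=set(scan.state) | {"normalized"}, valid=valid)


def band_integral(scan: RamanScan, window: BandWindow, require_normalized: bool = True) -> np.ndarray:
    """Per-pixel trapezoidal integral over a wavenumber window.

    Window edges falling between samples are handled by linear
    interpolation, so the integral is exact for piecewise-linear spectra.
    """
    w = scan.wavenumbers
    if window.lo < w[0] or window.hi > w[-1]:
        raise ValueError(
            f"window [{window.lo}, {window.hi}] outside axis [{w[0]}, {w[-1]}]"
        )
    if require_normalized and "normalized" not in scan.state:
        raise ValueError("scan must be normalized before band integration")
    inside = (w >= window.lo) & (w <= window.hi)
    idx = np.flatnonzero(inside)
    cube = scan.cube
    # interpolated values at the exact window edges
    v_lo = _interp_channel(cube, w, window.lo)
    v_hi = _interp_channel(cube, w, window.hi)
    if idx.size == 0:
        # window falls entirely between two samples
        return 0.5 * (v_lo + v_hi) * (window.hi - window.lo)
    w_aug = np.concatenate(([window.lo], w[idx], [window.hi]))
    cube_aug = np.concatenate(
        [v_lo[:, :, None], cube[:, :, idx], v_hi[:, :, None]], axis=2
    )
    return np.trapezoid(cube_aug, w_aug, axis=2)


def _interp_channel(cube: np.ndarray, w: np.ndarray, x: float) -> np.ndarray:
    """Linear interpolation of every pixel spectrum at wavenumber x."""
    j = int(np.searchsorted(w, x))
    if j == 0:
        return cube[:, :, 0]
    if j >= w.size:
        return cube[:, :, -1]
    t = (x - w[j - 1]) / (w[j] - w[j - 1])
    return (1.0 - t) * cube[:, :, j - 1] + t * cube[:, :, j]


def va_lipid_correlation(
    scan: RamanScan,
    va_window: BandWindow = VA_WINDOW,
    lipid_window: BandWindow = LIPID_WINDOW,
) -> BandMaps:
    """Vitamin-A and lipid band maps and their spatial Pearson correlation.

    Both maps are per-pixel band integrals of the normalized scan; the
    product-moment correlation is computed over all valid pixels. Fewer
    than 3 valid pixels raises; a zero-variance map yields ``pearson_r =
    None`` with a warning.
    """
    va_map = band_integral(scan, va_window)
    lipid_map = band_integral(scan, lipid_window)
    valid = scan.valid
    n = int(valid.sum())
    if n < 3:
        raise ValueError(f"need at least 3 valid pixels, have {n}")
    x = va_map[valid]
    y = lipid_map[valid]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance band map; Pearson r undefined")
        r = None
    else:
        from scipy.stats import pearsonr

        r = float(pearsonr(x, y).statistic)
    return BandMaps(va_map, lipid_map, r, n, (va_window, lipid_window))


def preprocess(scan: RamanScan, despike_window: int = 5, despike_k: float = 10.0,
               lam: float = 1e5, ratio: float = 1e-3, max_iter: int = 100) -> RamanScan:
    """Full preprocessing chain: despike → baseline → normalize."""
    scan = remove_cosmic_rays(scan, despike_window, despike_k)
    scan = subtract_baseline(scan, lam, ratio, max_iter)
    return normalize_unit_integral(scan)
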