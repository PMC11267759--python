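"""2D fluorescence quantification.

Two readouts: vitamin-A storage proxied by UV-autofluorescence positive
area (Triangle threshold per image), and myofibroblast activation proxied
by the average integral α-SMA intensity restricted to PDGFR-β-positive
area (Otsu mask on the PDGFR-β channel).
"""

from __future__ import annotations

import warnings

import numpy as np

from . import _thresholds
from .types import ActinScore, UVQuant


def triangle_threshold(image: np.ndarray) -> float:
    """Triangle-method threshold of an image (256-bin histogram).

    The threshold is the bin maximizing the perpendicular distance between
    the histogram and the line from the histogram peak to the far end of
    the nonzero range; ties resolve to the bin nearer the peak. Raises on a
    constant image.
    """
    return _thresholds.triangle(np.asarray(image))


def uv_quant(image: np.ndarray, threshold_offset: float = 0.0) -> UVQuant:
    """Quantify UV-autofluorescence positivity of one image.

    Positive pixels are those strictly above the Triangle threshold (plus
    an optional additive offset); reports the positive area fraction and
    the integrated signal over positive pixels.
    """
    image = np.asarray(image, dtype=float)
    thr = triangle_threshold(image) + threshold_offset
    positive = image > thr
    return UVQuant(
        threshold=float(thr),
        positive_area_fraction=float(positive.mean()),
        integrated_positive_signal=float(image[positive].sum()),
    )


def uv_quant_batch(images: list[np.ndarray], shared_threshold: bool = False):
    """Quantify a batch of UV images.

    Default is one Triangle threshold per image (the per-image macro
    convention); ``shared_threshold=True`` pools all pixels to compute a
    single threshold applied to every image, for acquisitions made under
    identical settings.
    """
    if shared_threshold:
        pooled = np.concatenate([np.asarray(im, dtype=float).ravel() for im in images])
        thr = _thresholds.triangle(pooled)
        out = []
        for im in images:
            im = np.asarray(im, dtype=float)
            pos = im > thr
            out.append(UVQuant(float(thr), float(pos.mean()), float(im[pos].sum())))
        return out
    return [uv_quant(im) for im in images]


def asma_in_pdgfrb(
    asma_channel: np.ndarray,
    pdgfrb_channel: np.ndarray,
    pdgfrb_threshold: float | None = None,
) -> ActinScore:
    """α-SMA intensity within the PDGFR-β-positive area of one field.

    The PDGFR-β mask is ``channel > Otsu threshold`` (or a fixed threshold
    when given). Reports the mask area, the integral of α-SMA over the
    mask, and their ratio (the mean in-mask intensity). An empty mask
    yields a null score with a warning.
    """
    asma = np.asarray(asma_channel, dtype=float)
    pdg = np.asarray(pdgfrb_channel, dtype=float)
    if asma.shape != pdg.shape:
        raise ValueError("channel shapes differ")
    thr = _thresholds.otsu(pdg) if pdgfrb_threshold is None else float(pdgfrb_threshold)
    mask = pdg > thr
    area = int(mask.sum())
    if area == 0:
        warnings.warn("empty PDGFR-β mask; α-SMA score undefined for this field")
        return ActinScore(0, None, None)
    integral = float(asma[mask].sum())
    return ActinScore(area, integral, integral / area)


def aggregate_fields(scores: list[ActinScore]) -> dict:
    """Average per-field α-SMA scores over the imaged fields.

    Both conventions are reported: the mean of per-field mean-in-mask
    intensities, and the raw summed integral/area, so either can be
    recomputed downstream. Null fields (empty masks) are skipped.
    """
    ok = [s for s in scores if s.mean_intensity_in_mask is not None]
    if not ok:
        return {"n_fields": 0, "mean_of_field_means": None,
                "total_integral": 0.0, "total_area": 0}
    return {
        "n_fields": len(ok),
        "mean_of_field_means": float(np.mean([s.mean_intensity_in_mask for s in ok])),
        "total_integral": float(sum(s.asma_integral for s in ok)),
        "total_area": int(sum(s.mask_area for s in ok)),
    }
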