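"""Cell-vs-background segmentation of holotomographic volumes.

The pipeline mirrors a supervised sharpness-feature approach: per-slice 2D
Laplacian magnitude (plus multi-scale smoothed companions) feeds a
probability-scoring classifier; the decision threshold is selected by
maximizing F1 on a validation split and generalization is reported as AUROC
on a held-out test split (60/20/20).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import CellMask, VoxelVolume

_LAPLACE_2D = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class SharpnessMap:
    """Per-voxel feature stack derived from a volume.

    ``data`` has shape ``(n_features, nz, ny, nx)``. Feature 0 is the
    absolute response of the 5-point 2D Laplacian applied slice-wise
    (edge-replicated boundaries). For each smoothing scale (µm) two further
    features follow: the locally averaged sharpness and the Gaussian-smoothed
    intensity at that scale.
    """

    data: np.ndarray
    scales: tuple[float, ...]
    voxel_size: tuple[float, float, float]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Flatten to (n_voxels, n_features)."""
        return self.data.reshape(self.n_features, -1).T


@dataclass
class SegModel:
    """Trained voxel classifier with an F1-selected decision threshold."""

    classifier: object | None = None
    backend: str = "gbdt"
    scales: tuple[float, ...] = (0.5, 1.0)
    decision_threshold: float | None = None
    split_fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    metrics: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.classifier is not None and self.decision_threshold is not None


def compute_sharpness(vol: VoxelVolume, scales=(0.5, 1.0)) -> SharpnessMap:
    """Compute the sharpness feature stack of a volume.

    Per z-slice the discrete 5-point Laplacian
    ``f[y+1,x] + f[y-1,x] + f[y,x+1] + f[y,x-1] - 4 f[y,x]`` is evaluated
    with edge replication; sharpness is its absolute value. Each scale s (µm)
    adds a local average of the sharpness and a Gaussian-smoothed copy of the
    intensity, both with per-axis sigmas ``s / voxel_size``.
    """
    if vol.data.size == 0:
        raise ValueError("empty volume")
    if vol.data.shape[1] < 3 or vol.data.shape[2] < 3:
        raise ValueError("volume needs at least 3 voxels per in-plane axis")
    lap = np.empty_like(vol.data)
    for z in range(vol.data.shape[0]):
        lap[z] = ndimage.convolve(vol.data[z], _LAPLACE_2D, mode="nearest")
    sharp = np.abs(lap)

    feats = [sharp]
    for s in scales:
        sig = tuple(s / d for d in vol.voxel_size)
        feats.append(ndimage.gaussian_filter(sharp, sig))
        feats.append(ndimage.gaussian_filter(vol.data, sig))
    return SharpnessMap(np.stack(feats), tuple(scales), vol.voxel_size)


def _stratified_split(y: np.ndarray, fractions, rng: np.random.Generator):
    """Class-stratified train/val/test index split."""
    idx_out = [[], [], []]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = idx.size
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        idx_out[0].append(idx[:n_tr])
        idx_out[1].append(idx[n_tr:n_tr + n_va])
        idx_out[2].append(idx[n_tr + n_va:])
    return [np.concatenate(p) for p in idx_out]


def f1_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """F1-maximizing decision threshold over a score set.

    Scans every distinct score value as a candidate cut (positive when
    ``score >= t``). When a run of adjacent candidates ties at the maximal
    F1, the returned threshold is the midpoint between the smallest
    maximizing candidate and the next distinct score below it, i.e. the
    midpoint of the maximizing score interval.

    Returns ``(threshold, best_f1)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present to select a threshold")
    order = np.argsort(scores, kind="mergesort")[::-1]
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp_cum = np.cumsum(y_sorted)
    k = np.arange(1, scores.size + 1)
    # Candidate cuts: one per distinct score value (cut at the last — i.e.
    # lowest-ranked — occurrence of that value). F1 = 2TP/(k + P).
    last_of_value = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    f1_all = 2.0 * tp_cum / (k + n_pos)
    cand = s_sorted[last_of_value]            # distinct scores, descending
    f1c = f1_all[last_of_value]
    best = float(np.max(f1c))
    is_max = f1c >= best - 1e-12
    # First contiguous maximizing run (largest candidate scores win ties
    # between disjoint plateaus). Real thresholds in
    # (cand[run_end + 1], cand[run_start]] all achieve the best F1; return
    # that interval's midpoint.
    i0 = int(np.argmax(is_max))
    i1 = i0
    while i1 + 1 < cand.size and is_max[i1 + 1]:
        i1 += 1
    upper = cand[i0]
    lower = cand[i1 + 1] if i1 + 1 < cand.size else None
    thr = upper if lower is None else 0.5 * (upper + lower)
    return float(thr), best


def evaluate_auroc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann–Whitney) formulation.

    Ties are handled by midranks, matching trapezoidal integration of the
    empirical ROC curve exactly.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _make_classifier(backend: str, seed: int):
    if backend == "gbdt":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(
            max_iter=100, max_depth=4, random_state=seed
        )
    if backend == "logistic":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
    raise ValueError(f"unknown backend {backend!r}; use 'gbdt' or 'logistic'")


def train_segmenter(
    features: list[SharpnessMap],
    labels: list[CellMask],
    split_seed: int = 0,
    backend: str = "gbdt",
    max_train_voxels: int = 200_000,
) -> SegModel:
    """Train the cell/background voxel classifier.

    Voxels from all volumes are pooled and split 60/20/20
    (train/validation/test), stratified by class. The classifier is fit on
    the training split; the decision threshold maximizes F1 on the
    validation split (plateau ties broken at the interval midpoint); test
    AUROC is recorded in ``metrics``.

    ``max_train_voxels`` caps the voxels actually passed to ``fit`` (a
    seeded subsample of the training split) to keep fitting fast; threshold
    selection and AUROC always use the full validation/test splits.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 labeled volumes")
    if len(features) != len(labels):
        raise ValueError("features and labels length mismatch")
    X = np.concatenate([f.as_matrix() for f in features], axis=0)
    y = np.concatenate([m.data.ravel() for m in labels]).astype(int)

    rng = np.random.default_rng(split_seed)
    fractions = (0.60, 0.20, 0.20)
    tr, va, te = _stratified_split(y, fractions, rng)
    for name, idx in (("train", tr), ("validation", va), ("test", te)):
        if np.unique(y[idx]).size < 2:
            raise ValueError(f"{name} split contains a single class")

    fit_idx = tr
    if tr.size > max_train_voxels:
        fit_idx = rng.choice(tr, size=max_train_voxels, replace=False)
        if np.unique(y[fit_idx]).size < 2:  # pragma: no cover - stratified pools
            fit_idx = tr
    clf = _make_classifier(backend, int(rng.integers(0, 2**31 - 1)))
    clf.fit(X[fit_idx], y[fit_idx])

    val_scores = clf.predict_proba(X[va])[:, 1]
    thr, f1 = f1_threshold(val_scores, y[va])
    test_scores = clf.predict_proba(X[te])[:, 1]
    auroc = evaluate_auroc(test_scores, y[te])

    model = SegModel(
        classifier=clf,
        backend=backend,
        scales=features[0].scales,
        decision_threshold=thr,
        metrics={"auroc_test": auroc, "f_score_val": f1},
    )
    return model


def segment_volume(
    vol: VoxelVolume,
    model: SegModel,
    cleanup: bool = True,
) -> CellMask:
    """Apply a trained segmenter to a volume.

    The mask is ``score >= decision_threshold``; with ``cleanup`` (default)
    only the largest connected component is kept and its holes are filled.
    An all-background result produces a zero-volume mask with a warning.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    fmap = compute_sharpness(vol, model.scales)
    scores = model.classifier.predict_proba(fmap.as_matrix())[:, 1]
    mask = (scores >= model.decision_threshold).reshape(vol.data.shape)
    if cleanup and mask.any():
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        warnings.warn("segmentation produced an empty mask (cell volume 0)")
    return CellMask(mask, vol.voxel_size)
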