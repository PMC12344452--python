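"""Landmark-detection evaluation metrics: RMSE and PCK@k.

RMSE is the root of the mean squared Euclidean distance between predicted
and true landmark positions, pooled over every (image, landmark) pair.
PCK@k is the percentage of predicted landmarks within k·D of their true
position, where D is a per-image anatomical normalisation distance — here
the shoulders–tail-base distance, which is stable across poses in an
overhead view.  A distance exactly equal to k·D counts as correct.

Missing landmark pairs (NaN in either prediction or truth) are excluded
and counted, not treated as errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LandmarkPairSet:
    """Aligned predicted/true landmark positions for a set of images.

    predicted, true: (n_images, n_landmarks, 2) arrays, NaN = missing.
    norm_dist: (n_images,) per-image normalisation distance D (> 0),
    conventionally the true shoulders–tail-base distance.
    """

    predicted: np.ndarray
    true: np.ndarray
    norm_dist: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.true = np.asarray(self.true, dtype=float)
        self.norm_dist = np.asarray(self.norm_dist, dtype=float)
        if self.predicted.shape != self.true.shape or self.predicted.ndim != 3:
            raise ValueError("predicted and true must both be (n_images, n_landmarks, 2)")
        if self.predicted.shape[2] != 2:
            raise ValueError("positions must be 2-D")
        if self.norm_dist.shape != (self.predicted.shape[0],):
            raise ValueError("norm_dist must have one entry per image")
        if np.any(~np.isfinite(self.norm_dist)) or np.any(self.norm_dist <= 0):
            raise ValueError("normalisation distances must be finite and positive")

    def distances(self) -> np.ndarray:
        """(n_images, n_landmarks) Euclidean distances; NaN where missing."""
        d = self.predicted - self.true
        return np.sqrt(np.sum(d * d, axis=2))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.distances()).sum())


def rmse(pairs: LandmarkPairSet, per_coordinate: bool = False) -> float:
    """Pooled landmark RMSE in pixels.

    Default: sqrt of the mean squared Euclidean distance over landmarks.
    ``per_coordinate=True`` instead pools squared errors of individual x/y
    coordinates (a reading of the scalar formula some toolkits use; it is
    the default divided by sqrt(2) for isotropic errors).
    """
    d = pairs.distances()
    present = np.isfinite(d)
    if not present.any():
        raise ValueError("no non-missing landmark pairs")
    sq = d[present] ** 2
    if per_coordinate:
        return float(np.sqrt(sq.sum() / (2 * sq.size)))
    return float(np.sqrt(sq.mean()))


def pck(pairs: LandmarkPairSet, threshold: float = 0.1, per_image: bool = False) -> float:
    """Percentage of correct landmarks at ``threshold``·D.

    Pooled over all (image, landmark) pairs by default; ``per_image=True``
    averages the per-image percentages instead.  Boundary distances
    (== threshold·D) count as correct.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = pairs.distances()
    present = np.isfinite(d)
    if not present.any():
        raise ValueError("no non-missing landmark pairs")
    ok = d <= threshold * pairs.norm_dist[:, None]
    if per_image:
        with np.errstate(invalid="ignore"):
            per_img = np.array([
                ok[i, present[i]].mean() for i in range(d.shape[0]) if present[i].any()
            ])
        return float(100.0 * per_img.mean())
    return float(100.0 * ok[present].mean())


def pck_curve(pairs: LandmarkPairSet, thresholds) -> dict[float, float]:
    """PCK at each threshold in ``thresholds`` (monotone non-decreasing)."""
    return {float(k): pck(pairs, float(k)) for k in thresholds}


def evaluation_report(pairs: LandmarkPairSet, thresholds=(0.05, 0.1, 0.2)) -> dict:
    """Per-landmark and pooled RMSE plus a PCK grid, JSON-serialisable."""
    d = pairs.distances()
    n_lm = d.shape[1]
    per_landmark = []
    for j in range(n_lm):
        col = d[:, j]
        ok = np.isfinite(col)
        per_landmark.append(float(np.sqrt((col[ok] ** 2).mean())) if ok.any() else None)
    return {
        "rmse": rmse(pairs),
        "rmse_per_landmark": per_landmark,
        "pck": pck_curve(pairs, thresholds),
        "n_missing_pairs": pairs.n_missing,
    }
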