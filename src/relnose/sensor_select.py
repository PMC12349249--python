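"""Mutual-information ranking of gas sensors.

Each sensor contributes two scalar features per recording: the temporal
average response ``x_mean`` (static behaviour) and the maximum absolute
first difference ``x_slope`` (dynamic sensitivity).  Both are discretized
by equal-width histogram binning and scored against the class label with
the plug-in mutual information estimator

    MI(X; Y) = sum_x sum_y p(x, y) * log( p(x, y) / (p(x) p(y)) )

in nats.  A sensor's combined contribution is the arithmetic mean of its
two feature MIs; sensors are ranked by that combined score and the top-k
retained for the array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import DatasetBundle

DEFAULT_BINS = 20


@dataclass
class FeatureTable:
    """Static and dynamic per-(sample, sensor) features with class labels."""

    x_mean: np.ndarray    # [n_samples, n_sensors]
    x_slope: np.ndarray   # [n_samples, n_sensors], >= 0
    labels: np.ndarray    # [n_samples]

    def __post_init__(self) -> None:
        if self.x_mean.shape != self.x_slope.shape:
            raise ValueError("x_mean and x_slope must share shape")
        if len(self.labels) != self.x_mean.shape[0]:
            raise ValueError("one label per sample required")
        if not (np.isfinite(self.x_mean).all() and np.isfinite(self.x_slope).all()):
            raise ValueError("features must be finite")


@dataclass(frozen=True)
class SensorScore:
    """MI statistics for one sensor (all in nats)."""

    sensor_id: int
    mi_mean: float
    mi_slope: float
    combined: float


def extract_features(bundle: DatasetBundle) -> FeatureTable:
    """Per-sample, per-sensor mean response and max |first difference|."""
    stack = np.stack([s.matrix for s in bundle.samples])  # [n, T, C]
    if stack.shape[1] < 2:
        raise ValueError("need at least two timesteps for the slope feature")
    x_mean = stack.mean(axis=1)
    x_slope = np.abs(np.diff(stack, axis=1)).max(axis=1)
    labels = np.array([s.label for s in bundle.samples])
    return FeatureTable(x_mean=x_mean, x_slope=x_slope, labels=labels)


def histogram_discretize(values: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-width binning over [min, max]; the maximum falls in the last
    bin; a constant input occupies bin 0 only."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=int)
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def mutual_information(x_bins: np.ndarray, y_labels: np.ndarray) -> float:
    """Plug-in MI (nats) between two discrete vectors, with 0 log 0 := 0."""
    x_bins = np.asarray(x_bins)
    y_labels = np.asarray(y_labels)
    if x_bins.shape != y_labels.shape:
        raise ValueError("x and y must have equal length")
    n = x_bins.size
    if n == 0:
        raise ValueError("need at least one observation")
    _, xi = np.unique(x_bins, return_inverse=True)
    _, yi = np.unique(y_labels, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))
    return max(mi, 0.0)  # clip tiny negative round-off


def combined_score(mi_mean: float, mi_slope: float) -> float:
    """Combined contribution of a sensor: (mi_mean + mi_slope) / 2."""
    if mi_mean < 0 or mi_slope < 0:
        raise ValueError("mutual information cannot be negative")
    return 0.5 * (mi_mean + mi_slope)


def score_sensors(bundle: DatasetBundle, n_bins: int = DEFAULT_BINS) -> list[SensorScore]:
    """Score every sensor of a bundle; bin edges are computed per feature
    over the whole feature vector (global equal-width estimator)."""
    table = extract_features(bundle)
    scores = []
    for s in range(table.x_mean.shape[1]):
        mi_m = mutual_information(histogram_discretize(table.x_mean[:, s], n_bins),
                                  table.labels)
        mi_s = mutual_information(histogram_discretize(table.x_slope[:, s], n_bins),
                                  table.labels)
        scores.append(SensorScore(s, mi_m, mi_s, combined_score(mi_m, mi_s)))
    return scores


def rank_sensors(scores: list[SensorScore], k: int | None = None) -> list[int]:
    """Sensor ids by descending combined score; ties break toward the
    lower sensor id."""
    if k is None:
        k = len(scores)
    if not (0 < k <= len(scores)):
        raise ValueError(f"k must be in 1..{len(scores)}")
    ordered = sorted(scores, key=lambda s: (-s.combined, s.sensor_id))
    return [s.sensor_id for s in ordered[:k]]


def report_table(scores: list[SensorScore]) -> "pd.DataFrame":
    """Tabular report: one row per sensor with its MI statistics and rank."""
    import pandas as pd
    order = rank_sensors(scores)
    rank = {sid: i + 1 for i, sid in enumerate(order)}
    return pd.DataFrame(
        [{"sensor_id": s.sensor_id, "mi_mean": s.mi_mean, "mi_slope": s.mi_slope,
          "combined": s.combined, "rank": rank[s.sensor_id]} for s in scores]
    ).sort_values("rank").reset_index(drop=True)
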