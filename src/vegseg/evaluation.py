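"""Assessment machinery: cluster validity, accuracy metrics, channel importance.

Four families of assessment are provided.

* **Davies-Bouldin index** -- an internal (label-free) validity score:
  the average, over clusters, of the worst ratio of summed within-cluster
  spreads to centroid separation. Lower is better (tighter, better
  separated clusters).
* **Confusion matrices and derived metrics** -- overall accuracy,
  per-class recall (user's accuracy), precision (producer's accuracy) and
  F1, computed against a co-registered reference label plane. The
  convention throughout: rows are the predicted class, columns the true
  class.
* **Gini channel importance** -- the normalized impurity-decrease
  attribution of each of the 10 channels toward reproducing the final
  segment labels, from a seeded random-forest surrogate.
* **Class assignment** -- unsupervised cluster labels are arbitrary, so
  before any accuracy computation they are matched one-to-one to
  reference classes by maximizing diagonal agreement (Hungarian
  assignment), unless an explicit mapping is supplied.

``BENCHMARK_CONFUSION`` holds the published 5x5 confusion matrices of the
three engines evaluated against 1,920,000 hand-labeled pixels on three
800x800 urban NAIP tiles; they serve as reference inputs for metric
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import MASKED, SegmentMap
from .indices import ChannelStack, STACK_CHANNELS
from .raster_core import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ImportanceReport",
    "davies_bouldin",
    "confusion",
    "metrics",
    "gini_importance",
    "assign_classes",
    "match_labels",
    "BENCHMARK_CONFUSION",
]

#: Class order used by the benchmark matrices below.
BENCHMARK_CLASS_ORDER = ("ground/soil", "water/shadow", "grass", "trees/shrubs", "other")

#: Published engine-vs-hand-labeled confusion matrices on three 800x800
#: urban NAIP tiles (1,920,000 pixels before masking). Rows = predicted,
#: columns = true, class order as in BENCHMARK_CLASS_ORDER.
BENCHMARK_CONFUSION = {
    "kmeans": np.array([
        [73497,   6467,   4214,   9152,   7082],
        [6467,  279844,  13834,  13072,  16968],
        [4855,   13843, 173213,  14877,   6814],
        [8481,   13263,  16214, 159341,   6698],
        [7215,   17258,   7030,   6603, 137799],
    ], dtype=np.int64),
    "gmm": np.array([
        [29978,  48461,   4315,   5879,  76880],
        [42,    221292,      0,      1,  36662],
        [28477,   3418,  56075,  78574,  14456],
        [20728,  20960, 148971, 112072,  14650],
        [21290,  36544,   5144,   6519,  32713],
    ], dtype=np.int64),
    "cnn": np.array([
        [9749,   36573,     63,   1232,  28254],
        [17001, 151324,    815,   3318,  47644],
        [9829,     234,  93762,  17723,   4846],
        [49828,    298, 115913, 178877,  14075],
        [13508, 142414,   3934,   2072,  80815],
    ], dtype=np.int64),
}


@dataclass
class ConfusionMatrix:
    """K x K contingency table; rows = predicted class, columns = true class."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Overall and per-class accuracy metrics derived from a confusion matrix.

    All values are fractions in [0, 1] at full precision; ``display``
    applies the configured rounding only at presentation time.
    """

    overall_accuracy: float
    recall: dict[str, float]
    precision: dict[str, float]
    f1: dict[str, float]
    zero_denominator_classes: list[str] = field(default_factory=list)
    rounding: str = "round"
    decimals: int = 2

    def display(self, value: float) -> float:
        if self.rounding == "round":
            return round(value, self.decimals)
        factor = 10 ** self.decimals
        return np.floor(value * factor) / factor


@dataclass
class ImportanceReport:
    """Per-channel Gini importance, normalized to sum to 1."""

    coefficients: dict[str, float]
    ranking: list[str]
    surrogate: str
    seed: int


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index of a hard clustering.

    DBI = (1/K) sum_i max_{j != i} (s_i + s_j) / d_ij, with s_i the mean
    Euclidean distance of cluster i's members to their centroid and d_ij
    the distance between centroids i and j. Lower indicates lower
    in-class variance and greater between-class separation.
    """
    X = np.atleast_2d(np.asarray(points, dtype=np.float64))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([X[labels == u].mean(axis=0) for u in uniq])
    spreads = np.array([
        np.linalg.norm(X[labels == u] - centroids[i], axis=1).mean()
        for i, u in enumerate(uniq)
    ])
    k = uniq.size
    ratios = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = np.linalg.norm(centroids[i] - centroids[j])
            if d == 0:
                raise ValueError(f"coincident centroids for clusters {uniq[i]} and {uniq[j]}")
            ratios[i, j] = ratios[j, i] = (spreads[i] + spreads[j]) / d
    return float(ratios.max(axis=1).mean())


def confusion(pred: SegmentMap | np.ndarray, truth: np.ndarray,
              n_classes: int | None = None,
              class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Count pixels by (predicted, true) class.

    Sentinel (-1) pixels on either side are excluded. ``counts[p][t]`` is
    the number of pixels predicted ``p`` whose true class is ``t``.
    """
    p = pred.labels if isinstance(pred, SegmentMap) else np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    sel = (p != MASKED) & (t != MASKED)
    if not sel.any():
        raise ValueError("no overlapping valid pixels")
    p, t = p[sel], t[sel]
    if n_classes is None:
        n_classes = int(max(p.max(), t.max())) + 1
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (p, t), 1)
    if class_names is None:
        class_names = (CLASS_NAMES if n_classes == len(CLASS_NAMES)
                       else tuple(f"class_{i}" for i in range(n_classes)))
    return ConfusionMatrix(counts=counts, class_names=class_names)


def metrics(cm: ConfusionMatrix, rounding: str = "round",
            decimals: int = 2) -> MetricsReport:
    """Overall accuracy and per-class recall / precision / F1.

    Overall accuracy = trace / total. Per class: recall = diagonal /
    column sum (true positives over true pixels of the class), precision
    = diagonal / row sum (true positives over pixels predicted as the
    class), F1 = harmonic mean. A zero denominator yields 0 and the class
    is flagged.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    flagged: list[str] = []
    recall, precision, f1 = {}, {}, {}
    for i, name in enumerate(cm.class_names):
        r = diag[i] / col[i] if col[i] > 0 else 0.0
        p = diag[i] / row[i] if row[i] > 0 else 0.0
        if col[i] == 0 or row[i] == 0:
            flagged.append(name)
        recall[name] = float(r)
        precision[name] = float(p)
        f1[name] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
        if (p + r) == 0 and name not in flagged:
            flagged.append(name)
    return MetricsReport(
        overall_accuracy=float(diag.sum() / total),
        recall=recall, precision=precision, f1=f1,
        zero_denominator_classes=flagged,
        rounding=rounding, decimals=decimals,
    )


def gini_importance(stack: ChannelStack, labels: SegmentMap | np.ndarray,
                    seed: int = 0, n_estimators: int = 50,
                    max_pixels: int = 50_000) -> ImportanceReport:
    """Gini channel importance of the 10 channels for the final segments.

    Fits a seeded random-forest surrogate predicting segment labels from
    the channel values and reports each channel's normalized total
    Gini-impurity decrease. Coefficients sum to 1; a channel that alone
    determines the segments approaches 1, equally uninformative channels
    approach 0.
    """
    from sklearn.ensemble import RandomForestClassifier

    lab = labels.labels if isinstance(labels, SegmentMap) else np.asarray(labels)
    valid = (lab != MASKED) & ~stack.nodata_mask
    X = stack.values[valid]
    y = lab[valid]
    if np.unique(y).size < 2:
        raise ValueError("channel importance requires at least 2 classes")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_pixels:
        idx = rng.choice(X.shape[0], size=max_pixels, replace=False)
        X, y = X[idx], y[idx]
    surrogate = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                       n_jobs=1)
    surrogate.fit(X, y)
    imp = surrogate.feature_importances_
    imp = imp / imp.sum()
    coeff = {name: float(v) for name, v in zip(STACK_CHANNELS, imp)}
    ranking = [name for name, _ in sorted(coeff.items(), key=lambda kv: -kv[1])]
    return ImportanceReport(
        coefficients=coeff, ranking=ranking,
        surrogate=f"RandomForestClassifier(n_estimators={n_estimators})", seed=seed,
    )


def match_labels(pred: np.ndarray, truth: np.ndarray,
                 n_classes: int | None = None) -> dict[int, int]:
    """Optimal one-to-one map from predicted labels to reference classes.

    Maximizes diagonal agreement of the matched contingency table via the
    Hungarian algorithm on the (predicted x true) rectangular matrix.
    When there are more predicted labels than reference classes the
    surplus labels stay unmatched (and vice versa).
    """
    p = pred.labels if isinstance(pred, SegmentMap) else np.asarray(pred)
    t = np.asarray(truth)
    sel = (p != MASKED) & (t != MASKED)
    if not sel.any():
        raise ValueError("no overlapping valid pixels")
    p, t = p[sel], t[sel]
    n_pred = int(p.max()) + 1
    n_true = int(t.max()) + 1 if n_classes is None else n_classes
    counts = np.zeros((n_pred, n_true), dtype=np.int64)
    np.add.at(counts, (p, t), 1)
    rows, cols = linear_sum_assignment(-counts)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def majority_mapping(pred: np.ndarray | SegmentMap, truth: np.ndarray) -> dict[int, int]:
    """Map each predicted segment to its modal reference class.

    Unlike the one-to-one Hungarian matching this may merge several
    segments into one class -- the situation that arises when an engine
    splits a heterogeneous cover (e.g. shadowed and sunlit canopy) into
    multiple segments that a human would name identically.
    """
    cm = confusion(pred, truth)
    return {int(p): int(cm.counts[p].argmax())
            for p in range(cm.counts.shape[0]) if cm.counts[p].sum() > 0}


def assign_classes(segmap: SegmentMap, reference: np.ndarray | dict,
                   class_names: tuple[str, ...] = CLASS_NAMES) -> SegmentMap:
    """Map arbitrary segment labels to land-cover classes.

    With a reference label plane, labels are matched one-to-one to
    maximize agreement. With an explicit ``{label: class}`` dict, the
    mapping is applied verbatim (a non-injective mapping merges segments;
    an uncovered label raises).
    """
    labels = segmap.labels
    if isinstance(reference, dict):
        mapping = {int(k): int(v) for k, v in reference.items()}
        present = set(np.unique(labels[labels != MASKED]).tolist())
        uncovered = present - set(mapping)
        if uncovered:
            raise ValueError(f"mapping does not cover labels {sorted(uncovered)}")
    else:
        mapping = match_labels(labels, np.asarray(reference))
    out = np.full(labels.shape, MASKED, dtype=np.int64)
    for src, dst in mapping.items():
        out[labels == src] = dst
    names = {v: class_names[v] for v in mapping.values() if v < len(class_names)}
    return SegmentMap(labels=out, class_names=names)
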