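"""Impervious-surface masking: stage 1 of the pipeline.

Built surfaces (asphalt, roofs) and highly reflective pure water are
removed before any vegetation analysis by 2-cluster k-means on per-pixel
NDVI. Vegetated and soil surfaces sit at distinctly higher NDVI than
pavement and open water, so the cluster with the lower mean NDVI is
dropped and the higher-NDVI cluster kept as the pervious domain.

Masking runs on the full scene rather than per tile: the 2-cluster split
adapts to the full distribution of NDVI in the analyzed extent, so the
mask is sensitive to the boundary conditions of the study area -- a
property reproducible here by changing the input extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterConfig, compare_seeding, inertia, kmeans_fit
from .indices import ChannelStack

__all__ = ["PerviousMask", "mask_impervious", "inertia", "compare_seeding"]


class DegenerateClusteringError(ValueError):
    """Raised when the NDVI field cannot support two clusters."""


@dataclass
class PerviousMask:
    """Boolean pervious/impervious partition of the scene.

    keep : True = pervious pixel, analyzed downstream.
    cluster_means : NDVI centroid of the (kept, dropped) clusters.
    inertia : final k-means objective on NDVI.
    seed : RNG seed used, recorded for reproducibility.
    """

    keep: np.ndarray
    cluster_means: tuple[float, float]
    inertia: float
    seed: int


def mask_impervious(stack: ChannelStack, seed: int = 0) -> PerviousMask:
    """Partition pixels into pervious/impervious by 2-means on NDVI.

    k-means (k=2, k-means++ seeding, Euclidean, at most 20 iterations) on
    the per-pixel NDVI channel; the lower-mean cluster (impervious and
    pure water) is dropped. Nodata pixels are never kept.
    """
    ndvi = stack.channel("ndvi")
    valid = ~stack.nodata_mask
    x = ndvi[valid].reshape(-1, 1)
    if x.size == 0:
        raise ValueError("no valid pixels to mask")
    if np.unique(x).size < 2:
        raise DegenerateClusteringError(
            "NDVI is constant over the scene; cannot split pervious/impervious")
    cfg = ClusterConfig(k=2, max_iter=20, seed=seed, standardize=False)
    model, labels = kmeans_fit(x, cfg)
    centroids = model.centroids.ravel()
    keep_label = int(np.argmax(centroids))
    keep = np.zeros(stack.nodata_mask.shape, dtype=bool)
    keep[valid] = labels == keep_label
    return PerviousMask(
        keep=keep,
        cluster_means=(float(centroids[keep_label]), float(centroids[1 - keep_label])),
        inertia=model.inertia,
        seed=seed,
    )
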