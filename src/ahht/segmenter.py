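"""Quantization of an image by thresholds or top-level histograms, and the
shared region-merging post-process.

A segmentation here is a *color quantization*: clusters are global color
classes (distinct quantized RGB triples), not connected components.  The
merging stage first absorbs clusters holding fewer than a fraction ``T_n``
of the pixels into their nearest cluster in RGB space, then repeatedly
fuses the globally closest pair of clusters while their distance is below
``T_d``.  Cluster means stay real-valued internally; display colors are the
means rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .baselines import color_distance, compute_histon_profile, select_thresholds
from .histograms import (
    CHANNELS,
    CHANNEL_INDEX,
    DEFAULT_L,
    ChannelId,
    HierarchicalHistogram,
    build_hierarchical_histogram,
    compute_level1_histogram,
)


@dataclass
class SegmentationResult:
    """A quantized image: per-pixel cluster labels plus a cluster table.

    ``labels`` maps every pixel to a row of ``means``/``counts``.  The
    quantized image is derived from the labels and the rounded means, so the
    invariant that every pixel shows its cluster's display color holds by
    construction.
    """

    labels: np.ndarray  # (M, N) int32, values in [0, n_clusters)
    means: np.ndarray  # (n_clusters, 3) float64
    counts: np.ndarray  # (n_clusters,) int64
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.labels.size:
            raise ValueError("cluster counts must sum to the pixel count")

    @property
    def n_clusters(self) -> int:
        return len(self.counts)

    @property
    def display_colors(self) -> np.ndarray:
        """Cluster means rounded half-up, clipped to 8-bit range."""
        return np.clip(np.floor(self.means + 0.5), 0, 255).astype(np.uint8)

    @property
    def quantized(self) -> np.ndarray:
        """The (M, N, 3) quantized image."""
        return self.display_colors[self.labels]

    def cluster_table(self) -> list[dict]:
        rows = []
        for cid, (mean, count) in enumerate(zip(self.means, self.counts)):
            rows.append(
                {
                    "id": cid,
                    "count": int(count),
                    "mean_R": float(mean[0]),
                    "mean_G": float(mean[1]),
                    "mean_B": float(mean[2]),
                }
            )
        return rows


def _cluster_from_quantized(
    quantized: np.ndarray, provenance: dict[str, Any]
) -> SegmentationResult:
    """Build a result whose clusters are the distinct colors of ``quantized``."""
    M, N = quantized.shape[:2]
    flat = quantized.reshape(-1, 3)
    colors, inverse, counts = np.unique(
        flat, axis=0, return_inverse=True, return_counts=True
    )
    return SegmentationResult(
        labels=inverse.reshape(M, N).astype(np.int32),
        means=colors.astype(np.float64),
        counts=counts.astype(np.int64),
        provenance=provenance,
    )


def quantize_by_top_histograms(
    image: np.ndarray, hierarchy: HierarchicalHistogram, L: int = DEFAULT_L
) -> SegmentationResult:
    """Initial segmentation from the top-level histograms.

    Per channel, a pixel of intensity v is assigned the representative
    intensity of the first top-level bin whose right endpoint is >= v, i.e.
    the half-open interval (previous right endpoint, right endpoint].  The
    per-channel histogram of the result reproduces the top-level histogram
    exactly (the quantization is a fixed point of the hierarchy).
    """
    arr = np.asarray(image)
    quantized = np.empty_like(arr)
    top_bins: dict[str, list[list[int]]] = {}
    for channel in CHANNELS:
        top = hierarchy.top(channel)
        rights = top.right_endpoints
        reps = top.rep_intensities
        plane = arr[:, :, CHANNEL_INDEX[channel]]
        idx = np.searchsorted(rights, plane.ravel(), side="left")
        if idx.max(initial=0) >= len(rights):
            raise RuntimeError(
                "pixel intensity beyond the last bin's right endpoint; the "
                "hierarchy was not built from this image"
            )
        quantized[:, :, CHANNEL_INDEX[channel]] = reps[idx].reshape(plane.shape)
        top_bins[channel] = [
            [int(b.count), int(b.rep_intensity), int(b.right_endpoint)]
            for b in top.bins
        ]
    provenance = {
        "method": "ahht",
        "w": hierarchy.w,
        "w_i": {c: float(hierarchy.w_i[c]) for c in CHANNELS},
        "top_level_bins": top_bins,
    }
    return _cluster_from_quantized(quantized, provenance)


def quantize_by_thresholds(
    image: np.ndarray,
    thresholds: Mapping[ChannelId, Sequence[int]],
    L: int = DEFAULT_L,
    method: str = "thresholds",
) -> SegmentationResult:
    """Initial segmentation from per-channel threshold sets.

    Thresholds cut [0, L-1] into half-open intervals (a threshold belongs to
    its left interval); a pixel's cluster is the triple of its per-channel
    interval indices, and each cluster is represented by the mean RGB of its
    member pixels.
    """
    arr = np.asarray(image)
    M, N = arr.shape[:2]
    interval_idx = np.empty((M * N, 3), dtype=np.int64)
    for channel in CHANNELS:
        ts = np.asarray(list(thresholds.get(channel, [])), dtype=np.int64)
        if np.any(ts[1:] <= ts[:-1]):
            raise ValueError(f"thresholds for channel {channel} must be ascending")
        if len(ts) and (ts.min() < 0 or ts.max() > L - 1):
            raise ValueError(f"thresholds must lie in [0, {L - 1}]")
        plane = arr[:, :, CHANNEL_INDEX[channel]].ravel()
        interval_idx[:, CHANNEL_INDEX[channel]] = np.searchsorted(
            ts, plane, side="left"
        )
    _, labels_flat, counts = np.unique(
        interval_idx, axis=0, return_inverse=True, return_counts=True
    )
    labels = labels_flat.reshape(M, N).astype(np.int32)
    k = len(counts)
    means = np.zeros((k, 3), dtype=np.float64)
    for c in range(3):
        sums = np.bincount(
            labels_flat, weights=arr[:, :, c].ravel().astype(np.float64), minlength=k
        )
        means[:, c] = sums / counts
    provenance = {
        "method": method,
        "thresholds": {c: [int(t) for t in thresholds.get(c, [])] for c in CHANNELS},
    }
    return SegmentationResult(
        labels=labels, means=means, counts=counts.astype(np.int64),
        provenance=provenance,
    )


def _apply_merges(
    seg: SegmentationResult,
    assign: np.ndarray,
    means: np.ndarray,
    counts: np.ndarray,
    alive: np.ndarray,
) -> SegmentationResult:
    """Rebuild a result after merging: compress ids and relabel pixels."""
    survivors = np.flatnonzero(alive)
    new_id = np.full(len(alive), -1, dtype=np.int32)
    new_id[survivors] = np.arange(len(survivors), dtype=np.int32)
    label_map = new_id[assign]
    return SegmentationResult(
        labels=label_map[seg.labels],
        means=means[survivors],
        counts=counts[survivors],
        provenance=dict(seg.provenance),
    )


def merge_small_clusters(seg: SegmentationResult, T_n: float) -> SegmentationResult:
    """Absorb clusters holding fewer than ``T_n`` of the pixels.

    Undersized clusters are processed in ascending count order (ties to the
    lowest id); each merges into the surviving cluster with the nearest mean
    color, whose mean becomes the pixel-weighted mean.  Newly grown clusters
    are re-tested, so the loop ends only when no undersized cluster remains
    (or a single cluster is left).
    """
    if not (0 <= T_n < 1):
        raise ValueError(f"T_n must lie in [0, 1), got {T_n}")
    k = seg.n_clusters
    means = seg.means.copy()
    counts = seg.counts.copy()
    alive = np.ones(k, dtype=bool)
    assign = np.arange(k)
    min_count = T_n * seg.labels.size
    while alive.sum() > 1:
        ids = np.flatnonzero(alive)
        under = ids[counts[ids] < min_count]
        if len(under) == 0:
            break
        # smallest first, ties to the lowest id
        i = under[np.lexsort((under, counts[under]))[0]]
        others = ids[ids != i]
        d = np.sqrt(((means[others] - means[i]) ** 2).sum(axis=1))
        j = others[int(np.argmin(d))]
        total = counts[i] + counts[j]
        means[j] = (counts[i] * means[i] + counts[j] * means[j]) / total
        counts[j] = total
        counts[i] = 0
        alive[i] = False
        assign[assign == i] = j
    return _apply_merges(seg, assign, means, counts, alive)


def merge_close_clusters(seg: SegmentationResult, T_d: float) -> SegmentationResult:
    """Fuse the globally closest cluster pair while their distance < ``T_d``.

    Pairs at equal distance are broken toward the lowest id pair; the lower
    id survives with the pixel-weighted mean.  On return every pairwise
    distance is >= ``T_d``.
    """
    if T_d < 0:
        raise ValueError(f"T_d must be non-negative, got {T_d}")
    k = seg.n_clusters
    means = seg.means.copy()
    counts = seg.counts.copy()
    alive = np.ones(k, dtype=bool)
    assign = np.arange(k)
    while alive.sum() > 1:
        ids = np.flatnonzero(alive)
        sub = means[ids]
        diff = sub[:, None, :] - sub[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(len(ids), k=1)
        pair_d = dist[iu]
        best = int(np.argmin(pair_d))  # argmin takes the first, i.e. lowest id pair
        if pair_d[best] >= T_d:
            break
        i = ids[iu[0][best]]
        j = ids[iu[1][best]]
        total = counts[i] + counts[j]
        means[i] = (counts[i] * means[i] + counts[j] * means[j]) / total
        counts[i] = total
        counts[j] = 0
        alive[j] = False
        assign[assign == j] = i
    return _apply_merges(seg, assign, means, counts, alive)


def region_merging(
    seg: SegmentationResult, T_n: float = 0.001, T_d: float = 20.0
) -> SegmentationResult:
    """Small-cluster absorption followed by close-cluster fusion."""
    return merge_close_clusters(merge_small_clusters(seg, T_n), T_d)


def count_colors(seg: SegmentationResult | np.ndarray) -> int:
    """Number of distinct RGB triples in a quantized image."""
    img = seg.quantized if isinstance(seg, SegmentationResult) else np.asarray(seg)
    return len(np.unique(img.reshape(-1, 3), axis=0))


def segment_ahht(
    image: np.ndarray,
    w: float = 15.0,
    T_n: float = 0.001,
    T_d: float = 20.0,
    trim_fraction: float = 0.01,
    criterion: str = "span",
    L: int = DEFAULT_L,
) -> SegmentationResult:
    """Full adaptive hierarchical-histogram segmentation pipeline.

    Builds the per-channel hierarchical histograms, quantizes the image with
    the top levels, then runs the region-merging post-process.  Provenance
    records the parameters, the top-level bins and the pre-merge color count.
    """
    hierarchy = build_hierarchical_histogram(image, w, trim_fraction, L, criterion)
    initial = quantize_by_top_histograms(image, hierarchy, L)
    merged = region_merging(initial, T_n, T_d)
    merged.provenance.update(
        {
            "T_n": T_n,
            "T_d": T_d,
            "trim_fraction": trim_fraction,
            "merge_criterion": criterion,
            "initial_colors": initial.n_clusters,
            "levels_per_channel": {
                c: hierarchy.num_levels(c) for c in CHANNELS
            },
        }
    )
    return merged


def segment_by_profile(
    image: np.ndarray,
    kind: str,
    P: int = 3,
    Q: int = 3,
    T0: float = 100.0,
    height_frac: float = 0.2,
    min_distance: int = 10,
    T_n: float = 0.001,
    T_d: float = 20.0,
    L: int = DEFAULT_L,
) -> SegmentationResult:
    """Histon- or roughness-index-based segmentation pipeline.

    ``kind`` selects the profile thresholded per channel ("histon" or
    "roughness"); thresholds sit at the minima between significant peaks,
    and the same region-merging post-process as the hierarchical method is
    applied.
    """
    if kind not in ("histon", "roughness"):
        raise ValueError(f"unknown profile kind {kind!r}")
    profile = compute_histon_profile(image, P, Q, T0, L)
    thresholds = {
        c: select_thresholds(profile.profile(c, kind), height_frac, min_distance)
        for c in CHANNELS
    }
    initial = quantize_by_thresholds(image, thresholds, L, method=kind)
    merged = region_merging(initial, T_n, T_d)
    merged.provenance.update(
        {
            "P": P,
            "Q": Q,
            "T0": T0,
            "height_frac": height_frac,
            "min_distance": min_distance,
            "T_n": T_n,
            "T_d": T_d,
            "initial_colors": initial.n_clusters,
        }
    )
    return merged
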