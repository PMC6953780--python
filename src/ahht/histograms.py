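"""Per-channel histograms and the hierarchical histogram at the core of AHHT.

A *hierarchical histogram* is a per-channel stack of histograms.  Level 1 is
the classic dense intensity histogram of one color plane.  Each further level
is obtained by (a) locating the valleys of the previous level's count
sequence, (b) cutting the bin sequence into "bell-shaped regions" at those
valleys, and (c) greedily merging the bins of each region into wider bins,
subject to a per-channel intensity-span budget ``w_i``.  The iteration stops
at a fixed point; the top level is what the segmenter thresholds the image
with.

Every bin is the triple (pixel count, representative intensity, right
endpoint).  The representative intensity is the count-weighted mean of the
merged members, rounded half-up so it remains a displayable integer; the
right endpoint delimits the half-open intensity interval the bin covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

ChannelId = Literal["R", "G", "B"]

#: Column index of each color plane in an (M, N, 3) array.
CHANNEL_INDEX: Mapping[str, int] = {"R": 0, "G": 1, "B": 2}

CHANNELS: tuple[ChannelId, ...] = ("R", "G", "B")

#: Default intensity scale (8-bit planes).
DEFAULT_L = 256

MergeCriterion = Literal["span", "gap"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, with .5 ties resolved upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Bin:
    """One merged intensity class: (count, representative intensity, right endpoint)."""

    count: int
    rep_intensity: int
    right_endpoint: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"bin count must be non-negative, got {self.count}")
        if self.rep_intensity > self.right_endpoint:
            raise ValueError(
                f"rep_intensity {self.rep_intensity} exceeds right_endpoint "
                f"{self.right_endpoint}"
            )


@dataclass(frozen=True)
class ChannelHistogram:
    """Ordered bin sequence for one color plane at one hierarchy level."""

    bins: tuple[Bin, ...]
    level: int
    channel: ChannelId
    total_pixels: int

    def __post_init__(self) -> None:
        reps = [b.rep_intensity for b in self.bins]
        if any(b >= a for a, b in zip(reps[1:], reps[:-1])):
            raise ValueError("rep_intensity must be strictly increasing")
        for prev, cur in zip(self.bins[:-1], self.bins[1:]):
            if not (prev.right_endpoint < cur.rep_intensity):
                raise ValueError(
                    "bins overlap: right_endpoint of one bin must lie strictly "
                    "left of the next bin's rep_intensity"
                )
        total = sum(b.count for b in self.bins)
        if total != self.total_pixels:
            raise ValueError(
                f"bin counts sum to {total}, expected total_pixels={self.total_pixels}"
            )

    @property
    def counts(self) -> np.ndarray:
        return np.array([b.count for b in self.bins], dtype=np.int64)

    @property
    def rep_intensities(self) -> np.ndarray:
        return np.array([b.rep_intensity for b in self.bins], dtype=np.int64)

    @property
    def right_endpoints(self) -> np.ndarray:
        return np.array([b.right_endpoint for b in self.bins], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class HierarchicalHistogram:
    """Per-channel stack of histograms, level 1 (dense) up to the fixed point."""

    levels: Mapping[ChannelId, tuple[ChannelHistogram, ...]]
    w: float
    w_i: Mapping[ChannelId, float]

    def top(self, channel: ChannelId) -> ChannelHistogram:
        return self.levels[channel][-1]

    def num_levels(self, channel: ChannelId) -> int:
        return len(self.levels[channel])

    def to_records(self) -> list[dict]:
        """Flatten every bin of every level into one row per bin."""
        rows = []
        for channel in CHANNELS:
            for hist in self.levels[channel]:
                for b in hist.bins:
                    rows.append(
                        {
                            "channel": channel,
                            "level": hist.level,
                            "count": b.count,
                            "rep_intensity": b.rep_intensity,
                            "right_endpoint": b.right_endpoint,
                        }
                    )
        return rows


def _validate_image(image: np.ndarray, L: int) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (M, N, 3) RGB array, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"intensities must be integer, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > L - 1:
        raise ValueError(f"intensities must lie in [0, {L - 1}]")
    return arr


def compute_level1_histogram(
    image: np.ndarray, channel: ChannelId, L: int = DEFAULT_L
) -> ChannelHistogram:
    """Dense classic histogram of one color plane: L bins, one per intensity.

    Every level-1 bin has ``rep_intensity == right_endpoint == l`` and counts
    the pixels with intensity ``l`` in the requested plane.
    """
    arr = _validate_image(image, L)
    plane = arr[:, :, CHANNEL_INDEX[channel]]
    counts = np.bincount(plane.ravel(), minlength=L)
    bins = tuple(Bin(int(c), l, l) for l, c in enumerate(counts))
    return ChannelHistogram(
        bins=bins, level=1, channel=channel, total_pixels=int(plane.size)
    )


def find_valleys(hist: ChannelHistogram) -> list[int]:
    """Valley intensities of a histogram's count sequence, ascending.

    A valley is a strict local minimum of the counts taken in bin order.  A
    plateau of k+1 equal counts strictly below both flanks contributes a
    single valley at offset floor(k/2) from the plateau's left end.  The
    first and last bins are never valleys (both neighbors are required).
    Returned values are the rep_intensities of the valley bins.
    """
    c = hist.counts
    n = len(c)
    valley_idx: list[int] = []
    i = 1
    while i < n:
        if c[i] < c[i - 1]:
            j = i
            while j + 1 < n and c[j + 1] == c[i]:
                j += 1
            # plateau is bins i..j (k = j - i); needs a strictly higher right flank
            if j + 1 < n and c[i] < c[j + 1]:
                valley_idx.append(i + (j - i) // 2)
            i = j + 1
        else:
            i += 1
    return [int(hist.bins[m].rep_intensity) for m in valley_idx]


def robust_span(hist: ChannelHistogram, trim_fraction: float = 0.01) -> int:
    """Trimmed intensity span of a level-1 histogram.

    Returns the distance between the largest intensity whose upper-tail mass
    exceeds ``trim_fraction`` and the smallest intensity whose lower-tail
    mass exceeds it.  With ``trim_fraction == 0`` this is simply the span
    between the extreme populated intensities.
    """
    if not (0 <= trim_fraction < 0.5):
        raise ValueError(f"trim_fraction must lie in [0, 0.5), got {trim_fraction}")
    c = hist.counts.astype(np.float64)
    n = c.sum()
    if n == 0:
        raise ValueError("histogram is empty: no populated intensities")
    lower_mass = np.cumsum(c) / n
    upper_mass = np.cumsum(c[::-1])[::-1] / n
    lower = int(np.argmax(lower_mass > trim_fraction))
    upper_hits = np.nonzero(upper_mass > trim_fraction)[0]
    upper = int(upper_hits[-1])
    return upper - lower


def channel_merge_threshold(w: float, span: int, L: int = DEFAULT_L) -> float:
    """Per-channel merge budget w_i = w * span / L (real-valued, not rounded)."""
    if w <= 0:
        raise ValueError(f"w must be positive, got {w}")
    if not (0 <= span <= L - 1):
        raise ValueError(f"span must lie in [0, {L - 1}], got {span}")
    return w * span / L


def merge_bell_region(
    hist: ChannelHistogram,
    left_index: int,
    right_index: int,
    w_i: float,
    criterion: MergeCriterion = "span",
) -> list[Bin]:
    """Merge the bins of one bell-shaped region into wider bins.

    Bins are grouped greedily left-to-right.  Under the default ``"span"``
    criterion a group closes when the next bin's rep_intensity minus the
    group's first rep_intensity exceeds ``w_i``; this guarantees at most
    floor(region_span / w_i) + 1 output bins.  The alternative ``"gap"``
    criterion closes a group when the gap to the previous member exceeds
    ``w_i``.  Each output bin carries the summed count, the count-weighted
    mean rep_intensity (rounded half-up) and the last member's right
    endpoint; groups with zero pixels are dropped.
    """
    nbins = len(hist.bins)
    if not (0 <= left_index <= right_index < nbins):
        raise IndexError(
            f"region [{left_index}, {right_index}] out of range for {nbins} bins"
        )
    groups: list[list[Bin]] = []
    current = [hist.bins[left_index]]
    for b in hist.bins[left_index + 1 : right_index + 1]:
        if criterion == "span":
            close = (b.rep_intensity - current[0].rep_intensity) > w_i
        elif criterion == "gap":
            close = (b.rep_intensity - current[-1].rep_intensity) > w_i
        else:
            raise ValueError(f"unknown merge criterion {criterion!r}")
        if close:
            groups.append(current)
            current = [b]
        else:
            current.append(b)
    groups.append(current)

    merged: list[Bin] = []
    for group in groups:
        count = sum(b.count for b in group)
        if count == 0:
            continue
        rep = round_half_up(
            sum(b.count * b.rep_intensity for b in group) / count
        )
        merged.append(Bin(count, rep, group[-1].right_endpoint))
    return merged


def next_level_histogram(
    hist: ChannelHistogram,
    valleys: Sequence[int],
    w_i: float,
    criterion: MergeCriterion = "span",
) -> ChannelHistogram:
    """Build the next hierarchy level by splitting at valleys and merging.

    The bin sequence is cut after every valley bin (a valley closes the
    region on its left); each region, including the trailing one past the
    last valley, is merged with :func:`merge_bell_region` and the results
    are concatenated in intensity order.  Pixel counts are conserved.
    """
    rep_to_index = {b.rep_intensity: m for m, b in enumerate(hist.bins)}
    new_bins: list[Bin] = []
    left = 0
    for v in valleys:
        if v not in rep_to_index:
            raise ValueError(f"valley intensity {v} is not a bin of this histogram")
        right = rep_to_index[v]
        new_bins.extend(merge_bell_region(hist, left, right, w_i, criterion))
        left = right + 1
    if left <= len(hist.bins) - 1:
        new_bins.extend(
            merge_bell_region(hist, left, len(hist.bins) - 1, w_i, criterion)
        )
    return ChannelHistogram(
        bins=tuple(new_bins),
        level=hist.level + 1,
        channel=hist.channel,
        total_pixels=hist.total_pixels,
    )


def build_channel_hierarchy(
    image: np.ndarray,
    channel: ChannelId,
    w: float,
    trim_fraction: float = 0.01,
    L: int = DEFAULT_L,
    criterion: MergeCriterion = "span",
) -> tuple[tuple[ChannelHistogram, ...], float]:
    """Hierarchy of one color plane plus the w_i used to build it."""
    h1 = compute_level1_histogram(image, channel, L)
    span = robust_span(h1, trim_fraction)
    w_i = channel_merge_threshold(w, span, L)
    levels = [h1]
    current = h1
    # bin count strictly decreases until the fixed point, so L iterations suffice
    for _ in range(L):
        valleys = find_valleys(current)
        nxt = next_level_histogram(current, valleys, w_i, criterion)
        if nxt.bins == current.bins:
            break
        levels.append(nxt)
        current = nxt
    return tuple(levels), w_i


def build_hierarchical_histogram(
    image: np.ndarray,
    w: float = 15.0,
    trim_fraction: float = 0.01,
    L: int = DEFAULT_L,
    criterion: MergeCriterion = "span",
) -> HierarchicalHistogram:
    """Hierarchical histogram for every color plane of an RGB image.

    Per channel: compute the trimmed span and the merge budget w_i, start
    from the dense level-1 histogram, and iterate valley detection plus bin
    merging until a level reproduces its predecessor.
    """
    levels: dict[ChannelId, tuple[ChannelHistogram, ...]] = {}
    w_is: dict[ChannelId, float] = {}
    for channel in CHANNELS:
        levels[channel], w_is[channel] = build_channel_hierarchy(
            image, channel, w, trim_fraction, L, criterion
        )
    return HierarchicalHistogram(levels=levels, w=w, w_i=w_is)
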