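"""Seeded synthetic fixtures: block images with known palettes and toy
histograms with known modes.

The block generator emulates the regime thresholding-based segmentation is
designed for: a small number of large, nearly uniform color regions whose
per-channel intensity distributions are well-separated modes, plus additive
Gaussian pixel noise.  It deliberately does not emulate natural-image
texture, gradients or illumination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .histograms import Bin, ChannelHistogram, ChannelId, DEFAULT_L


@dataclass(frozen=True)
class BlockFixture:
    """A block image, its ground-truth label map and the generating palette."""

    image: np.ndarray  # (M, N, 3) uint8
    truth: np.ndarray  # (M, N) int32 labels indexing the palette
    palette: np.ndarray  # (k, 3) uint8
    noise_sigma: float
    seed: int


def _candidate_colors(rng: np.random.Generator) -> np.ndarray:
    """Shuffled 3x3x3 grid over {10, 130, 250}: any two grid colors differ by
    at least 120 in some channel, so pairwise RGB distances are >= 120."""
    grid = np.array(
        list(itertools.product((10, 130, 250), repeat=3)), dtype=np.float64
    )
    return grid[rng.permutation(len(grid))]


def _pick_palette(
    k: int, min_color_distance: float, rng: np.random.Generator
) -> np.ndarray:
    candidates = _candidate_colors(rng)
    if min_color_distance > 120:
        # greedy filter; the grid may not support large separations for big k
        kept: list[np.ndarray] = []
        for c in candidates:
            if all(
                np.sqrt(((c - p) ** 2).sum()) >= min_color_distance for p in kept
            ):
                kept.append(c)
        candidates = np.array(kept) if kept else np.empty((0, 3))
    if len(candidates) < k:
        raise ValueError(
            f"cannot place {k} colors pairwise >= {min_color_distance} apart"
        )
    return candidates[:k].astype(np.uint8)


def make_block_image(
    k: int,
    size: tuple[int, int] = (96, 128),
    min_color_distance: float = 120.0,
    noise_sigma: float = 4.0,
    seed: int = 0,
) -> BlockFixture:
    """Deterministic k-block RGB image with additive clipped Gaussian noise.

    The image is split into ``k`` vertical stripes of near-equal width (every
    stripe holds well above 1% of the pixels for any practical ``k``); stripe
    colors are drawn pairwise at least ``min_color_distance`` apart in RGB
    space.  Noise is i.i.d. per channel, rounded half-up and clipped to the
    8-bit range.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    M, N = size
    if N < k:
        raise ValueError(f"image width {N} cannot hold {k} stripes")
    rng = np.random.default_rng(seed)
    palette = _pick_palette(k, min_color_distance, rng)

    edges = np.linspace(0, N, k + 1).round().astype(int)
    truth = np.zeros((M, N), dtype=np.int32)
    for label in range(k):
        truth[:, edges[label] : edges[label + 1]] = label

    clean = palette[truth].astype(np.float64)
    noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
    image = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)
    return BlockFixture(
        image=image,
        truth=truth,
        palette=palette,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_toy_histogram(
    modes: list[tuple[int, int, int]],
    L: int = DEFAULT_L,
    channel: ChannelId = "R",
) -> ChannelHistogram:
    """Dense level-1 histogram with triangular bumps at known centers.

    Each mode is a (center, mass, width) triple: a triangular count profile
    of the given half-width is laid over the intensity axis and integerized
    with largest-remainder rounding so the bump holds exactly ``mass``
    pixels.  Overlapping bumps sum.
    """
    counts = np.zeros(L, dtype=np.int64)
    for center, mass, width in modes:
        if not (0 <= center <= L - 1):
            raise ValueError(f"mode center {center} outside [0, {L - 1}]")
        if width < 1 or mass < 1:
            raise ValueError("mode width and mass must be positive")
        ls = np.arange(L)
        tri = np.maximum(0.0, 1.0 - np.abs(ls - center) / width)
        weights = tri / tri.sum() * mass
        base = np.floor(weights).astype(np.int64)
        remainder = mass - base.sum()
        if remainder > 0:
            frac = weights - base
            # largest fractional parts first, ties to the lower intensity
            order = np.lexsort((ls, -frac))
            base[order[:remainder]] += 1
        counts += base
    bins = tuple(Bin(int(c), l, l) for l, c in enumerate(counts))
    return ChannelHistogram(
        bins=bins, level=1, channel=channel, total_pixels=int(counts.sum())
    )
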