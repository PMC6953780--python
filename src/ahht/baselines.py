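"""Histon and roughness-index profiles and peak/valley threshold selection.

These are the two classic histogram-variant thresholders the hierarchical
method is benchmarked against.  The *histon* counts each pixel once, plus a
second time when its neighborhood is color-similar (a rough-set upper
approximation of the plain histogram); the *roughness index* is
``1 - histogram / histon`` per intensity and highlights homogeneous modes.
Thresholds are placed at the minima between significant peaks of the chosen
profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .histograms import CHANNELS, CHANNEL_INDEX, DEFAULT_L, ChannelId

ProfileKind = Literal["histon", "roughness"]


def color_distance(c1, c2) -> np.ndarray | float:
    """Euclidean distance between RGB vectors (broadcasts over leading axes)."""
    a = np.asarray(c1, dtype=np.float64)
    b = np.asarray(c2, dtype=np.float64)
    d = np.sqrt(((a - b) ** 2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


def similarity_mask(
    image: np.ndarray, P: int = 3, Q: int = 3, T0: float = 100.0
) -> np.ndarray:
    """Binary similarity flags: 1 where the neighborhood is color-similar.

    For each pixel the total color distance ``d_T`` to every pixel of its
    P x Q window is accumulated; the flag is 1 iff ``d_T < T0``.  Border
    windows are truncated to the in-image part, so ``d_T`` there sums over
    fewer neighbors.
    """
    if P % 2 == 0 or Q % 2 == 0 or P < 1 or Q < 1:
        raise ValueError(f"window dims must be odd and positive, got {P}x{Q}")
    if T0 <= 0:
        raise ValueError(f"T0 must be positive, got {T0}")
    img = np.asarray(image, dtype=np.float64)
    M, N = img.shape[:2]
    d_total = np.zeros((M, N), dtype=np.float64)
    hp, hq = P // 2, Q // 2
    for dp in range(-hp, hp + 1):
        for dq in range(-hq, hq + 1):
            if dp == 0 and dq == 0:
                continue  # self-distance is zero
            rs = slice(max(0, -dp), min(M, M - dp))
            cs = slice(max(0, -dq), min(N, N - dq))
            rs2 = slice(max(0, dp), min(M, M + dp))
            cs2 = slice(max(0, dq), min(N, N + dq))
            diff = img[rs, cs] - img[rs2, cs2]
            d_total[rs, cs] += np.sqrt((diff**2).sum(axis=-1))
    return (d_total < T0).astype(np.uint8)


def compute_histon(
    image: np.ndarray,
    mask: np.ndarray,
    channel: ChannelId,
    L: int = DEFAULT_L,
) -> np.ndarray:
    """Histon of one color plane: similar-neighborhood pixels count double."""
    arr = np.asarray(image)
    m = np.asarray(mask)
    if m.shape != arr.shape[:2]:
        raise ValueError(
            f"mask shape {m.shape} does not match image spatial shape {arr.shape[:2]}"
        )
    plane = arr[:, :, CHANNEL_INDEX[channel]]
    return np.bincount(
        plane.ravel(), weights=(1.0 + m).ravel(), minlength=L
    )


def compute_roughness(h: np.ndarray, h_prime: np.ndarray) -> np.ndarray:
    """Roughness index rho = 1 - h / h' where h' > 0, else 0."""
    h = np.asarray(h, dtype=np.float64)
    hp = np.asarray(h_prime, dtype=np.float64)
    if np.any(hp < h):
        raise ValueError("histon must dominate the histogram pointwise (h' >= h)")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(hp > 0, 1.0 - h / np.where(hp > 0, hp, 1.0), 0.0)
    return rho


@dataclass(frozen=True)
class HistonProfile:
    """Per-channel histogram / histon / roughness arrays for one image."""

    h: Mapping[ChannelId, np.ndarray]
    h_prime: Mapping[ChannelId, np.ndarray]
    rho: Mapping[ChannelId, np.ndarray]
    P: int
    Q: int
    T0: float

    def profile(self, channel: ChannelId, kind: ProfileKind) -> np.ndarray:
        return self.h_prime[channel] if kind == "histon" else self.rho[channel]

    def to_records(self) -> list[dict]:
        rows = []
        for channel in CHANNELS:
            for l in range(len(self.h[channel])):
                rows.append(
                    {
                        "channel": channel,
                        "intensity": l,
                        "h": float(self.h[channel][l]),
                        "h_prime": float(self.h_prime[channel][l]),
                        "rho": float(self.rho[channel][l]),
                    }
                )
        return rows


def compute_histon_profile(
    image: np.ndarray,
    P: int = 3,
    Q: int = 3,
    T0: float = 100.0,
    L: int = DEFAULT_L,
) -> HistonProfile:
    """Histogram, histon and roughness index for all three color planes."""
    arr = np.asarray(image)
    mask = similarity_mask(arr, P, Q, T0)
    h: dict[ChannelId, np.ndarray] = {}
    hp: dict[ChannelId, np.ndarray] = {}
    rho: dict[ChannelId, np.ndarray] = {}
    for channel in CHANNELS:
        plane = arr[:, :, CHANNEL_INDEX[channel]]
        h[channel] = np.bincount(plane.ravel(), minlength=L).astype(np.float64)
        hp[channel] = compute_histon(arr, mask, channel, L)
        rho[channel] = compute_roughness(h[channel], hp[channel])
    return HistonProfile(h=h, h_prime=hp, rho=rho, P=P, Q=Q, T0=T0)


def significant_peaks(
    profile: np.ndarray,
    height_frac: float = 0.2,
    min_distance: int = 10,
) -> list[int]:
    """Significant peaks of a 1-D profile.

    All local maxima (plateau maxima at their midpoint) are candidates.
    Candidates are visited in descending height (ties: lower intensity
    first) and accepted only if at least ``min_distance`` intensity units
    from every already-accepted peak; accepted peaks whose height does not
    exceed ``height_frac`` times the mean height of *all* local maxima are
    then discarded.  The result is sorted ascending.
    """
    prof = np.asarray(profile, dtype=np.float64)
    if np.any(prof < 0):
        raise ValueError("profile must be non-negative")
    peaks, _ = find_peaks(prof)
    if len(peaks) == 0:
        return []
    heights = prof[peaks]
    order = sorted(range(len(peaks)), key=lambda i: (-heights[i], peaks[i]))
    accepted: list[int] = []
    for i in order:
        p = int(peaks[i])
        if all(abs(p - a) >= min_distance for a in accepted):
            accepted.append(p)
    mean_height = float(heights.mean())
    kept = [p for p in accepted if prof[p] > height_frac * mean_height]
    return sorted(kept)


def valley_thresholds(profile: np.ndarray, peaks: Sequence[int]) -> list[int]:
    """Thresholds at the minimum between every adjacent pair of peaks.

    For each adjacent pair the intensity of the smallest profile value
    strictly between them is taken (leftmost on ties).  Fewer than two
    peaks yield no thresholds.
    """
    prof = np.asarray(profile, dtype=np.float64)
    ps = sorted(int(p) for p in peaks)
    thresholds: list[int] = []
    for a, b in zip(ps[:-1], ps[1:]):
        if b - a < 2:
            continue  # no strict interior
        interior = prof[a + 1 : b]
        thresholds.append(a + 1 + int(np.argmin(interior)))
    return thresholds


def select_thresholds(
    profile: np.ndarray,
    height_frac: float = 0.2,
    min_distance: int = 10,
) -> list[int]:
    """Peak detection followed by valley placement, for one profile."""
    peaks = significant_peaks(profile, height_frac, min_distance)
    return valley_thresholds(profile, peaks)
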