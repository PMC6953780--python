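"""Image and ground-truth I/O, preprocessing and result export.

Images are 8-bit RGB arrays; grayscale inputs are promoted to three equal
channels and alpha channels are dropped.  Ground truth uses the plain-text
``.seg`` run-length dialect (header lines, then ``label row col_start
col_end`` runs with inclusive, 0-based columns).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize

from .segmenter import SegmentationResult


class UnsupportedDepthError(IOError):
    """Raised for images deeper than 8 bits per channel."""


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/PPM/BMP into an (M, N, 3) uint8 array.

    Grayscale images are replicated to three channels; alpha is dropped;
    bit depths above 8 bits/channel are rejected.
    """
    with Image.open(path) as img:
        if img.mode in ("I", "I;16", "I;16B", "I;16L", "I;16N", "F"):
            raise UnsupportedDepthError(
                f"{path}: only 8 bits per channel are supported (mode {img.mode})"
            )
        if img.mode != "RGB":
            img = img.convert("RGB")
        arr = np.asarray(img, dtype=np.uint8)
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    arr = np.asarray(image, dtype=np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def normalize_longest_side(
    image: np.ndarray, target: int = 320, order: int = 1
) -> np.ndarray:
    """Resize so the longest side equals ``target``, aspect preserved.

    Interpolation is bilinear by default (``order=0`` for nearest-neighbor);
    interpolated intensities are rounded half-up back to integers.  Images
    already at the target size are returned unchanged.
    """
    if target < 1:
        raise ValueError(f"target must be >= 1, got {target}")
    arr = np.asarray(image)
    M, N = arr.shape[:2]
    longest = max(M, N)
    if longest == target:
        return arr.copy()
    scale = target / longest
    M2 = target if M == longest else int(np.floor(M * scale + 0.5))
    N2 = target if N == longest else int(np.floor(N * scale + 0.5))
    out = _sk_resize(
        arr.astype(np.float64),
        (max(M2, 1), max(N2, 1)),
        order=order,
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def read_seg_groundtruth(path: str | Path) -> np.ndarray:
    """Read a ``.seg`` ground-truth file into a dense label map.

    The format is a header (lines such as ``width W``, ``height H``,
    ``segments K`` until a ``data`` line) followed by one run per line:
    ``label row col_start col_end`` with inclusive 0-based columns.  Every
    pixel must be covered exactly once.
    """
    width = height = None
    lines = Path(path).read_text().splitlines()
    data_start = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0].lower()
        if key == "width":
            width = int(tokens[1])
        elif key == "height":
            height = int(tokens[1])
        elif key == "data":
            data_start = i + 1
            break
    if width is None or height is None or data_start is None:
        raise ValueError(f"{path}: malformed header (need width, height, data)")
    labels = np.full((height, width), -1, dtype=np.int32)
    for line in lines[data_start:]:
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 4:
            raise ValueError(f"{path}: malformed data row {line!r}")
        seg, row, c0, c1 = (int(t) for t in tokens)
        if not (0 <= row < height and 0 <= c0 <= c1 < width):
            raise ValueError(f"{path}: run {line!r} outside the image")
        if np.any(labels[row, c0 : c1 + 1] != -1):
            raise ValueError(f"{path}: doubly covered pixels in run {line!r}")
        labels[row, c0 : c1 + 1] = seg
    if np.any(labels == -1):
        raise ValueError(f"{path}: uncovered pixels remain")
    return labels


def write_seg_groundtruth(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map in the ``.seg`` run-length dialect."""
    lab = np.asarray(labels)
    height, width = lab.shape
    lines = [
        "format ascii",
        f"width {width}",
        f"height {height}",
        f"segments {len(np.unique(lab))}",
        "data",
    ]
    for row in range(height):
        r = lab[row]
        starts = np.flatnonzero(np.diff(r) != 0) + 1
        bounds = np.concatenate(([0], starts, [width]))
        for c0, c1 in zip(bounds[:-1], bounds[1:]):
            lines.append(f"{int(r[c0])} {row} {int(c0)} {int(c1 - 1)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cluster_table(seg: SegmentationResult, path: str | Path) -> None:
    rows = seg.cluster_table()
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def write_records_csv(records: Iterable[Mapping], path: str | Path) -> None:
    records = list(records)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
        writer.writeheader()
        writer.writerows(records)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}
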