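"""Reading and writing scans (16-bit grayscale PNG) and dataset manifests."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

PNG_MAX = 65535


def write_png16(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG (deterministic bytes)."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    u16 = np.round(arr * PNG_MAX).astype(np.uint16)
    iio.imwrite(Path(path), u16, extension=".png")


def read_png16(path) -> np.ndarray:
    """Read a grayscale PNG back to a float image in [0, 1]."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:  # collapse accidental RGB
        raw = raw[..., 0]
    denom = PNG_MAX if raw.dtype == np.uint16 else 255
    return raw.astype(float) / denom


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint16(PNG_MAX)), extension=".png")


def read_mask_png(path) -> np.ndarray:
    return iio.imread(Path(path)) > 0


def save_manifest(path, manifest: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
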