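"""Pseudoaveraging: tiled model inference with seam-free blending, plus
brightness/contrast matching of the output to its input scan."""

from __future__ import annotations

import numpy as np

from .model import PatchGrid, UNet, extract_patches, stitch_patches
from .nn import F32
from .types import EnfaceImage


def _cosine2_window(p: int) -> np.ndarray:
    """Separable cosine-squared (Hann) window, strictly positive so every
    pixel keeps support even where tiles do not overlap."""
    w = np.sin(np.pi * (np.arange(p) + 0.5) / p) ** 2
    return np.outer(w, w) + 1e-3


def pseudoaverage(
    image,
    model: UNet,
    tile: int = 64,
    stride: int = 32,
    batch_size: int = 64,
    match_contrast: bool = False,
) -> EnfaceImage:
    """Apply a trained denoiser to a full scan via overlapping tiles.

    Edge tiles are snapped inside the frame (no padding, so no synthetic
    content enters the network); overlapping predictions are blended with
    normalised cosine-squared weights.  Deterministic given the weights.
    """
    px = image.pixels if isinstance(image, EnfaceImage) else np.asarray(image, dtype=float)
    d = model.spec.divisor
    if tile % d:
        raise ValueError(f"tile must be divisible by 2**(levels-1) = {d}")
    grid, patches = extract_patches(px, patch_size=tile, stride=stride)
    preds = np.empty_like(patches)
    for start in range(0, len(patches), batch_size):
        preds[start : start + batch_size] = model.forward(
            patches[start : start + batch_size].astype(F32)
        )
    out = stitch_patches(preds, grid, window=_cosine2_window(tile))
    out = np.clip(out, 0.0, 1.0)
    if match_contrast:
        out = _match_moments(out, px)

    if isinstance(image, EnfaceImage):
        return EnfaceImage(
            pixels=out,
            eye_id=image.eye_id,
            frame_index=image.frame_index,
            role="pseudoaveraged",
            pixel_size_um=image.pixel_size_um,
            motion_rows=image.motion_rows,
            shadow_bbox=image.shadow_bbox,
        )
    return EnfaceImage(pixels=out, role="pseudoaveraged")


def _match_moments(output: np.ndarray, reference: np.ndarray) -> np.ndarray:
    mu_o, sd_o = float(output.mean()), float(output.std())
    mu_r, sd_r = float(reference.mean()), float(reference.std())
    if sd_o < 1e-9:
        a, b = 1.0, mu_r - mu_o  # zero-variance output: mean shift only
    else:
        a = sd_r / sd_o
        b = mu_r - a * mu_o
    return np.clip(a * output + b, 0.0, 1.0)


def match_brightness_contrast(output, reference) -> EnfaceImage:
    """Affine intensity map so the output's mean/std equal the reference's.

    This mirrors the brightness/contrast adjustment applied after denoising
    so that pre- and post-processing scans are directly comparable; matching
    is per scan (global two-parameter map), then clipped to [0, 1].
    """
    out_px = output.pixels if isinstance(output, EnfaceImage) else np.asarray(output, dtype=float)
    ref_px = (
        reference.pixels if isinstance(reference, EnfaceImage) else np.asarray(reference, dtype=float)
    )
    if out_px.shape != ref_px.shape:
        raise ValueError("output and reference must share a shape")
    matched = _match_moments(out_px, ref_px)
    if isinstance(output, EnfaceImage):
        return EnfaceImage(
            pixels=matched,
            eye_id=output.eye_id,
            frame_index=output.frame_index,
            role=output.role,
            pixel_size_um=output.pixel_size_um,
            motion_rows=output.motion_rows,
            shadow_bbox=output.shadow_bbox,
        )
    return EnfaceImage(pixels=matched, role="pseudoaveraged")
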