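"""Rigid registration and averaging of repeated enface frames.

Repeated OCTA acquisitions of one eye differ by small rigid eye movements
(translation up to ~10 px, rotation up to ~2 deg on a 6x6 mm scan), plus
independent speckle, background noise and motion lines.  Registration here is
two-stage: a phase-correlation translation initialisation followed by a Powell
refinement of (dx, dy, theta) maximising normalised cross-correlation on the
valid overlap.  The N-frame average is the per-pixel mean over frames whose
warped validity mask covers the pixel, with the best-quality frame as the
fixed reference.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter
from scipy.optimize import minimize
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .types import EnfaceImage, FrameStack, Transform2D


class RegistrationFailure(RuntimeError):
    """Raised when a frame pair cannot be registered (degenerate content or
    no credible correlation peak); callers fall back to the identity."""


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, EnfaceImage) else np.asarray(image, dtype=float)


def warp_rigid(image: np.ndarray, t: Transform2D, cval: float = 0.0, order: int = 1) -> np.ndarray:
    """Warp ``image`` so content moves by (+dx right, +dy down) and rotates
    ``theta`` counter-clockwise about the image centre (bilinear by default)."""
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    d = np.array([t.dy, t.dx])
    ct, st = math.cos(t.theta), math.sin(t.theta)
    r_inv = np.array([[ct, st], [-st, ct]])
    offset = center - r_inv @ (center + d)
    return affine_transform(image, r_inv, offset=offset, order=order, mode="constant", cval=cval)


def transform_validity_mask(shape, t: Transform2D) -> np.ndarray:
    """Boolean mask of output pixels whose bilinear source support lies fully
    inside the original frame."""
    h, w = shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    ct, st = math.cos(t.theta), math.sin(t.theta)
    r_inv = np.array([[ct, st], [-st, ct]])
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    out = np.stack([rr.ravel(), cc.ravel()])
    src = r_inv @ (out - (center + np.array([t.dy, t.dx]))[:, None]) + center[:, None]
    valid = (
        (src[0] >= 0.0) & (src[0] <= h - 1) & (src[1] >= 0.0) & (src[1] <= w - 1)
    )
    return valid.reshape(h, w)


def apply_transform(image, transform: Transform2D):
    """Apply a rigid transform with bilinear interpolation.

    Returns ``(warped, validity_mask)`` where the mask is False wherever the
    source location falls outside the original frame.  ``image`` may be an
    :class:`EnfaceImage` (returned as one) or a bare 2-D array.
    """
    px = _pixels(image)
    warped = np.clip(warp_rigid(px, transform), 0.0, 1.0)
    mask = transform_validity_mask(px.shape, transform)
    if isinstance(image, EnfaceImage):
        out = EnfaceImage(
            pixels=warped,
            eye_id=image.eye_id,
            frame_index=image.frame_index,
            role=image.role,
            pixel_size_um=image.pixel_size_um,
            motion_rows=image.motion_rows,
            shadow_bbox=image.shadow_bbox,
            true_transform=image.true_transform,
        )
        return out, mask
    return warped, mask


def quality_score(image) -> float:
    """Sharpness-to-noise proxy for frame quality: mean gradient magnitude
    divided by an estimate of the background-region standard deviation.

    Higher is better; a constant image scores 0.  Invariant to adding a
    constant intensity offset.  This is an objective stand-in for subjective
    best-frame selection.
    """
    px = _pixels(image)
    gy, gx = np.gradient(px)
    mean_grad = float(np.hypot(gy, gx).mean())
    if mean_grad == 0.0:
        return 0.0
    if float(px.std()) < 1e-12:
        return 0.0
    try:
        thr = threshold_otsu(px)
        bg = px[px < thr]
    except ValueError:  # constant-valued image histograms
        bg = px.ravel()
    sigma = float(bg.std()) if bg.size >= 16 else float(px.std())
    return mean_grad / max(sigma, 1e-6)


def _preprocess(px: np.ndarray) -> np.ndarray:
    """Band-pass (smooth + high-pass) to stabilise correlation under motion
    lines and speckle."""
    smooth = gaussian_filter(px, 1.5)
    return smooth - gaussian_filter(px, 12.0)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = math.sqrt(float(av @ av) * float(bv @ bv))
    if denom < 1e-12:
        return 0.0
    return float(av @ bv) / denom


def _refine(ref_f: np.ndarray, mov_f: np.ndarray, x0: np.ndarray):
    """Powell refinement of (dx, dy, theta_deg) maximising NCC of ``mov_f``
    warped onto ``ref_f``, sampled on interior pixels with valid support."""
    from scipy.ndimage import map_coordinates

    h, w = ref_f.shape
    margin = max(4, min(h, w) // 16)
    rr, cc = np.mgrid[margin : h - margin, margin : w - margin]
    out = np.stack([rr.ravel().astype(float), cc.ravel().astype(float)])
    ref_vals = ref_f[margin : h - margin, margin : w - margin].ravel()
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])[:, None]
    min_overlap = 0.25 * out.shape[1]

    def objective(params):
        dx, dy, theta_deg = params
        th = math.radians(theta_deg)
        ct, st = math.cos(th), math.sin(th)
        r_inv = np.array([[ct, st], [-st, ct]])
        src = r_inv @ (out - center - np.array([dy, dx])[:, None]) + center
        valid = (src[0] >= 0) & (src[0] <= h - 1) & (src[1] >= 0) & (src[1] <= w - 1)
        if valid.sum() < min_overlap:
            return 1.0
        sampled = map_coordinates(mov_f, src[:, valid], order=1)
        return -_ncc_flat(ref_vals[valid], sampled)

    res = minimize(
        objective,
        x0,
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-7, "maxfev": 300},
    )
    return res.x, -objective(res.x)


def _ncc_flat(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom < 1e-12:
        return 0.0
    return float(a @ b) / denom


def estimate_transform(reference, moving, max_rot_deg: float = 5.0) -> Transform2D:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Plain (unwhitened) cross-correlation initialises the translation; Powell
    then refines (dx, dy, theta) by maximising normalised cross-correlation
    over the valid overlap, in both directions (moving->reference and
    reference->moving); the two estimates are averaged to cancel the
    interpolation bias of warping only one side.  Raises
    :class:`RegistrationFailure` on feature-free input or when no credible
    alignment is found.
    """
    ref = _pixels(reference)
    mov = _pixels(moving)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving frames must share a shape")
    if float(ref.std()) < 1e-8 or float(mov.std()) < 1e-8:
        raise RegistrationFailure("feature-free (constant) image")

    ref_f = _preprocess(ref)
    mov_f = _preprocess(mov)
    # phase whitening is markedly less robust on speckle-dominated frames
    # with motion lines, hence normalization=None
    shift, _, _ = phase_cross_correlation(
        ref_f, mov_f, upsample_factor=16, normalization=None
    )
    x0 = np.array([shift[1], shift[0], 0.0])  # (dx, dy, theta_deg)

    x_fwd, score_fwd = _refine(ref_f, mov_f, x0)
    if abs(x_fwd[2]) > max_rot_deg:
        raise RegistrationFailure("rotation estimate outside plausible range")
    if score_fwd < 0.15:
        raise RegistrationFailure(f"no credible alignment (ncc={score_fwd:.3f})")

    t_fwd = Transform2D(
        dx=float(x_fwd[0]), dy=float(x_fwd[1]), theta=math.radians(float(x_fwd[2]))
    )
    # backward fit warm-started at the inverse of the forward estimate
    t_inv = t_fwd.inverse()
    x_bwd, score_bwd = _refine(
        mov_f, ref_f, np.array([t_inv.dx, t_inv.dy, math.degrees(t_inv.theta)])
    )
    if score_bwd >= 0.15 and abs(x_bwd[2]) <= max_rot_deg:
        t_bwd = Transform2D(
            dx=float(x_bwd[0]), dy=float(x_bwd[1]), theta=math.radians(float(x_bwd[2]))
        ).inverse()
        return Transform2D(
            dx=0.5 * (t_fwd.dx + t_bwd.dx),
            dy=0.5 * (t_fwd.dy + t_bwd.dy),
            theta=0.5 * (t_fwd.theta + t_bwd.theta),
        )
    return t_fwd


def average_frames(stack: FrameStack, return_info: bool = False):
    """Register every frame to the best-quality reference and average.

    The reference is the frame with the highest :func:`quality_score` (ties
    broken by lowest frame index).  Each other frame is warped onto it and the
    output is the per-pixel mean over frames valid at that pixel (the
    reference is valid everywhere, so the divisor is always >= 1).  Frames
    whose registration fails are excluded; if all fail the reference frame is
    returned with ``info["all_failed"]`` set.
    """
    scores = [quality_score(f) for f in stack.frames]
    ref_idx = int(np.argmax(scores))
    ref = stack.frames[ref_idx]

    acc = ref.pixels.astype(float).copy()
    count = np.ones(ref.shape, dtype=float)
    info = {
        "reference_index": ref_idx,
        "quality_scores": scores,
        "transforms": {ref_idx: Transform2D()},
        "failed": [],
        "all_failed": False,
    }
    motion_rows = set(ref.motion_rows)
    for i, frame in enumerate(stack.frames):
        if i == ref_idx:
            continue
        try:
            t = estimate_transform(ref.pixels, frame.pixels)
        except RegistrationFailure:
            info["failed"].append(i)
            continue
        warped, valid = apply_transform(frame.pixels, t)
        acc[valid] += warped[valid]
        count += valid
        info["transforms"][i] = t
        row_shift = int(round(t.dy))
        h = ref.shape[0]
        motion_rows.update(
            r + row_shift for r in frame.motion_rows if 0 <= r + row_shift < h
        )

    if len(info["failed"]) == len(stack.frames) - 1 and len(stack.frames) > 1:
        info["all_failed"] = True
        out = EnfaceImage(
            pixels=ref.pixels.copy(),
            eye_id=ref.eye_id,
            role="averaged",
            pixel_size_um=ref.pixel_size_um,
            motion_rows=tuple(sorted(motion_rows)),
            shadow_bbox=ref.shadow_bbox,
        )
        return (out, info) if return_info else out

    avg = acc / count
    out = EnfaceImage(
        pixels=np.clip(avg, 0.0, 1.0),
        eye_id=ref.eye_id,
        role="averaged",
        pixel_size_um=ref.pixel_size_um,
        motion_rows=tuple(sorted(motion_rows)),
        shadow_bbox=ref.shadow_bbox,
    )
    return (out, info) if return_info else out
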