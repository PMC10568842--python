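"""Seeded synthetic OCTA-like phantoms and noisy enface renderings.

The simulator emulates the statistical structure of macular enface OCTA
projections: a branching arteriolar/venular tree converging on a foveal
avascular zone (FAZ), an interstitial capillary mesh, multiplicative flow
speckle, an additive decorrelation background floor, horizontal motion-line
artifacts, media-opacity shadow patches, and (for diabetic-retinopathy-like
eyes) microaneurysm dots and capillary-dropout regions.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import save_manifest, write_mask_png, write_png16
from .types import (
    VESSEL_THRESHOLD,
    EnfaceImage,
    FrameStack,
    GroundTruthPhantom,
    NoiseParams,
    Transform2D,
)

PATHOLOGY_LEVELS = ("healthy", "npdr", "pdr")

# Pathology knob -> (microaneurysm count range, dropout-region count range,
# FAZ contour attenuated-arc range in degrees).
_PATHOLOGY = {
    "healthy": ((0, 0), (0, 0), (0.0, 0.0)),
    "npdr": ((3, 8), (1, 3), (0.0, 0.0)),
    "pdr": ((8, 15), (3, 6), (20.0, 40.0)),
}


def _stamp_disk(canvas: np.ndarray, r: float, c: float, radius: float, value: float) -> None:
    """Deposit a soft-edged disk of ``value`` at (r, c), max-compositing."""
    h, w = canvas.shape
    rad = max(radius, 0.6)
    lo_r, hi_r = int(max(0, r - rad - 1)), int(min(h, r + rad + 2))
    lo_c, hi_c = int(max(0, c - rad - 1)), int(min(w, c + rad + 2))
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    profile = value * np.exp(-d2 / (2.0 * (rad / 1.6) ** 2))
    region = canvas[lo_r:hi_r, lo_c:hi_c]
    np.maximum(region, profile, out=region)


def _grow_vessel_tree(canvas: np.ndarray, faz_center, faz_radius, rng) -> None:
    """Recursive branching random walk: trunks start at the image border and
    grow toward the FAZ, branching with width decay per generation."""
    h, w = canvas.shape
    n_trunks = int(rng.integers(3, 6))
    stack = []
    for _ in range(n_trunks):
        side = rng.integers(0, 4)
        if side == 0:
            start = (0.0, float(rng.uniform(0, w)))
        elif side == 1:
            start = (float(h - 1), float(rng.uniform(0, w)))
        elif side == 2:
            start = (float(rng.uniform(0, h)), 0.0)
        else:
            start = (float(rng.uniform(0, h)), float(w - 1))
        angle = math.atan2(faz_center[0] - start[0], faz_center[1] - start[1])
        angle += rng.normal(0.0, 0.25)
        stack.append((start[0], start[1], angle, float(rng.uniform(2.2, 3.2)), 0))

    max_segments = 400
    n_segments = 0
    while stack and n_segments < max_segments:
        r, c, angle, width, gen = stack.pop()
        n_segments += 1
        intensity = float(rng.uniform(0.80, 0.95))
        for _ in range(300):
            if width < 0.55 or not (0 <= r < h and 0 <= c < w):
                break
            dist_faz = math.hypot(r - faz_center[0], c - faz_center[1])
            if dist_faz < faz_radius + 1.0:
                break
            _stamp_disk(canvas, r, c, width, intensity)
            # gentle attraction toward the FAZ keeps trunks macula-bound
            target = math.atan2(faz_center[0] - r, faz_center[1] - c)
            delta = (target - angle + math.pi) % (2 * math.pi) - math.pi
            angle += 0.02 * delta + rng.normal(0.0, 0.15)
            step = 1.5
            r += step * math.sin(angle)
            c += step * math.cos(angle)
            width *= 0.985
            if width > 0.9 and rng.random() < 0.035 and gen < 4:
                side = 1.0 if rng.random() < 0.5 else -1.0
                stack.append(
                    (r, c, angle + side * rng.uniform(0.35, 0.8), width * 0.7, gen + 1)
                )


def _capillary_mesh(shape, rng) -> np.ndarray:
    """Cellular capillary web from the zero-crossing band of smoothed noise."""
    g = gaussian_filter(rng.standard_normal(shape), sigma=1.6)
    g /= g.std() + 1e-12
    band = np.abs(g) < 0.28
    mod = gaussian_filter(rng.standard_normal(shape), sigma=6.0)
    mod /= mod.std() + 1e-12
    return np.where(band, np.clip(0.52 + 0.08 * mod, 0.0, 1.0), 0.0)


def generate_phantom(
    size_px=(256, 256), pathology_level: str = "healthy", seed: int = 0
) -> GroundTruthPhantom:
    """Generate a noiseless ground-truth perfusion phantom.

    ``pathology_level`` controls microaneurysm count, capillary-dropout region
    count, and FAZ contour completeness (``healthy`` < ``npdr`` < ``pdr``).
    Deterministic given identical arguments.
    """
    h, w = int(size_px[0]), int(size_px[1])
    if h < 64 or w < 64:
        raise ValueError("phantom size must be at least 64 px per dimension")
    if pathology_level not in PATHOLOGY_LEVELS:
        raise ValueError(f"unknown pathology_level {pathology_level!r}; "
                         f"expected one of {PATHOLOGY_LEVELS}")

    rng = np.random.default_rng(np.random.SeedSequence([0x9AE1, seed]))
    scale = min(h, w) / 256.0

    faz_center = (
        h / 2.0 + float(rng.uniform(-5, 5)) * scale,
        w / 2.0 + float(rng.uniform(-5, 5)) * scale,
    )
    faz_radius = float(rng.uniform(11, 15)) * scale

    pm = np.zeros((h, w))
    _grow_vessel_tree(pm, faz_center, faz_radius, rng)
    caps = _capillary_mesh((h, w), rng)
    pm = np.maximum(pm, caps)

    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - faz_center[0], cc - faz_center[1])
    ring_half = 1.5
    interior = dist < faz_radius - ring_half
    ring = np.abs(dist - faz_radius) <= ring_half
    pm[interior] = 0.0
    pm[ring] = np.maximum(pm[ring], 0.75)

    ma_range, drop_range, arc_range = _PATHOLOGY[pathology_level]

    dropout_regions = []
    n_drop = int(rng.integers(drop_range[0], drop_range[1] + 1)) if drop_range[1] else 0
    for _ in range(n_drop):
        for _attempt in range(50):
            cy = float(rng.uniform(0.1 * h, 0.9 * h))
            cx = float(rng.uniform(0.1 * w, 0.9 * w))
            if math.hypot(cy - faz_center[0], cx - faz_center[1]) > faz_radius + 12 * scale:
                break
        a = float(rng.uniform(8, 20)) * scale
        b = float(rng.uniform(8, 20)) * scale
        phi = float(rng.uniform(0, math.pi))
        u = (rr - cy) * math.cos(phi) + (cc - cx) * math.sin(phi)
        v = -(rr - cy) * math.sin(phi) + (cc - cx) * math.cos(phi)
        region = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        region &= dist > faz_radius + ring_half  # never erode the FAZ ring
        pm[region] *= 0.08
        dropout_regions.append(region)

    ma_centers = []
    n_ma = int(rng.integers(ma_range[0], ma_range[1] + 1)) if ma_range[1] else 0
    for _ in range(n_ma):
        ang = float(rng.uniform(0, 2 * math.pi))
        rad = float(rng.uniform(1.3, 4.0)) * faz_radius
        my = faz_center[0] + rad * math.sin(ang)
        mx = faz_center[1] + rad * math.cos(ang)
        if not (2 <= my < h - 2 and 2 <= mx < w - 2):
            continue
        _stamp_disk(pm, my, mx, float(rng.uniform(1.5, 2.5)), float(rng.uniform(0.85, 0.95)))
        ma_centers.append((my, mx))

    if arc_range[1] > 0:  # partial FAZ contour attenuation (proliferative-like)
        arc = math.radians(float(rng.uniform(*arc_range)))
        theta0 = float(rng.uniform(0, 2 * math.pi))
        ang = np.arctan2(rr - faz_center[0], cc - faz_center[1]) % (2 * math.pi)
        in_arc = ((ang - theta0) % (2 * math.pi)) < arc
        pm[ring & in_arc] *= 0.3

    # Decorrelation flow signal is quasi-binary (flow vs no-flow), so keep the
    # truth bimodal: suppress sub-threshold residue and lift near-threshold
    # vessel edges away from the vessel/background cut.
    vessel = pm >= VESSEL_THRESHOLD
    pm = np.where(vessel, np.maximum(pm, VESSEL_THRESHOLD + 0.10), 0.55 * pm)

    pm = np.clip(pm, 0.0, 1.0)
    return GroundTruthPhantom(
        perfusion_map=pm,
        vessel_mask=pm >= VESSEL_THRESHOLD,
        faz_center_xy=faz_center,
        faz_radius=faz_radius,
        microaneurysm_centers=ma_centers,
        dropout_regions=dropout_regions,
        contour_ring_mask=ring,
        pathology_level=pathology_level,
        mm_extent=(6.0, 6.0),
    )


def render_single_frame(
    phantom: GroundTruthPhantom,
    noise_params: NoiseParams,
    eye_id: str = "eye",
    frame_index: int = 0,
    transform: Transform2D | None = None,
    rng: np.random.Generator | None = None,
) -> EnfaceImage:
    """Render one noisy single-frame scan from a phantom.

    Noise model: ``clip(perfusion * (1 + speckle) + background, 0, 1)``, then a
    Poisson number of motion-corrupted rows (bright-line replacement or a
    horizontal shift of up to 6 px, equal probability), then optional shadow
    attenuation of a rectangular patch.  Corrupted rows and the shadow box are
    recorded in the returned image metadata.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([0x51F2, noise_params.seed]))
    pm = phantom.perfusion_map
    if transform is not None and (transform.dx or transform.dy or transform.theta):
        from .registration import warp_rigid

        pm = warp_rigid(pm, transform)
    h, w = pm.shape

    speckle = noise_params.speckle_sigma * rng.standard_normal((h, w))
    background = rng.normal(noise_params.background_level, noise_params.background_sigma, (h, w))
    px = np.clip(pm * (1.0 + speckle) + background, 0.0, 1.0)

    n_rows = int(rng.poisson(noise_params.motion_line_rate))
    n_rows = min(n_rows, h // 4)
    motion_rows = sorted(int(r) for r in rng.choice(h, size=n_rows, replace=False))
    for row in motion_rows:
        if rng.random() < 0.5:  # bright white-line artifact
            px[row] = np.clip(rng.normal(0.7, 0.15, w), 0.0, 1.0)
        else:  # horizontal jitter of the scan line
            shift = int(rng.integers(1, 7)) * (1 if rng.random() < 0.5 else -1)
            px[row] = np.roll(px[row], shift)

    shadow_bbox = None
    if rng.random() < noise_params.shadow_prob:
        bh = int(rng.integers(h // 6, h // 3))
        bw = int(rng.integers(w // 6, w // 3))
        r0 = int(rng.integers(0, h - bh))
        c0 = int(rng.integers(0, w - bw))
        px[r0 : r0 + bh, c0 : c0 + bw] *= noise_params.shadow_attenuation
        shadow_bbox = (r0, c0, bh, bw)

    return EnfaceImage(
        pixels=px,
        eye_id=eye_id,
        frame_index=frame_index,
        role="single",
        pixel_size_um=phantom.mm_extent[0] * 1000.0 / h,
        motion_rows=tuple(motion_rows),
        shadow_bbox=shadow_bbox,
        true_transform=transform,
    )


def render_frame_stack(
    phantom: GroundTruthPhantom,
    n_frames: int = 4,
    noise_params: NoiseParams | None = None,
    max_shift_px: float = 8.0,
    max_rot_deg: float = 2.0,
    eye_id: str = "eye",
) -> FrameStack:
    """Render repeated co-acquired frames with independent rigid eye motion,
    noise and motion lines per frame.  True transforms are stored on each
    frame for registration parameter-recovery tests."""
    if n_frames < 2:
        raise ValueError("a frame stack needs n_frames >= 2")
    noise_params = noise_params or NoiseParams()
    ss = np.random.SeedSequence([0xA5C3, noise_params.seed])
    children = ss.spawn(n_frames)
    frames = []
    for i in range(n_frames):
        rng = np.random.default_rng(children[i])
        if max_shift_px > 0 or max_rot_deg > 0:
            t = Transform2D(
                dx=float(rng.uniform(-max_shift_px, max_shift_px)),
                dy=float(rng.uniform(-max_shift_px, max_shift_px)),
                theta=math.radians(float(rng.uniform(-max_rot_deg, max_rot_deg))),
            )
        else:
            t = Transform2D()
        frames.append(
            render_single_frame(
                phantom, noise_params, eye_id=eye_id, frame_index=i, transform=t, rng=rng
            )
        )
    return FrameStack(frames=frames, reference_index=0)


def _pathology_for(index: int, mix: dict, rng: np.random.Generator) -> str:
    levels = sorted(mix)
    probs = np.array([mix[k] for k in levels], dtype=float)
    probs /= probs.sum()
    return str(rng.choice(levels, p=probs))


def make_dataset(
    n_eyes: int,
    splits: dict,
    config: dict | None = None,
    out_dir=None,
    seed: int = 0,
):
    """Write a synthetic dataset (PNG scans + truth + JSON manifest) to disk.

    ``splits`` maps split name to eye count and must partition ``n_eyes``
    (e.g. ``{"train": 5, "val": 34}``).  ``train``/``val`` eyes get full
    repeated-frame stacks; ``test`` eyes get a single frame only.  Re-running
    with identical arguments reproduces byte-identical files.
    """
    config = dict(config or {})
    if sum(splits.values()) != n_eyes:
        raise ValueError("splits must partition n_eyes exactly")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)

    size = tuple(config.get("size_px", (256, 256)))
    n_frames = int(config.get("n_frames", 4))
    max_shift = float(config.get("max_shift_px", 8.0))
    max_rot = float(config.get("max_rot_deg", 2.0))
    mix = config.get("pathology_mix", {"healthy": 0.42, "npdr": 0.38, "pdr": 0.20})
    noise_cfg = config.get("noise", {})

    mix_rng = np.random.default_rng(np.random.SeedSequence([0xD1CE, seed]))
    eyes: dict = {}
    order = [name for name in splits for _ in range(splits[name])]
    for idx, split in enumerate(order):
        eye_id = f"{split}{idx:04d}"
        pathology = _pathology_for(idx, mix, mix_rng)
        phantom = generate_phantom(size, pathology, seed=seed * 100003 + idx)
        np_params = NoiseParams(**noise_cfg).with_seed(seed * 100003 + idx)

        perf_path = out_dir / "truth" / f"{eye_id}_perfusion.png"
        mask_path = out_dir / "truth" / f"{eye_id}_vessel_mask.png"
        write_png16(perf_path, phantom.perfusion_map)
        write_mask_png(mask_path, phantom.vessel_mask)

        frame_entries = []
        if split == "test":
            frame = render_single_frame(phantom, np_params, eye_id=eye_id)
            path = out_dir / "images" / f"{eye_id}_f0.png"
            write_png16(path, frame.pixels)
            frame_entries.append(_frame_entry(frame, path, out_dir))
        else:
            stack = render_frame_stack(
                phantom, n_frames, np_params, max_shift, max_rot, eye_id=eye_id
            )
            for frame in stack.frames:
                path = out_dir / "images" / f"{eye_id}_f{frame.frame_index}.png"
                write_png16(path, frame.pixels)
                frame_entries.append(_frame_entry(frame, path, out_dir))

        eyes[eye_id] = {
            "split": split,
            "pathology": pathology,
            "faz_center": list(phantom.faz_center_xy),
            "faz_radius": phantom.faz_radius,
            "truth": {
                "perfusion": str(perf_path.relative_to(out_dir)),
                "vessel_mask": str(mask_path.relative_to(out_dir)),
            },
            "frames": frame_entries,
        }

    manifest = {
        "seed": seed,
        "size_px": list(size),
        "splits": {k: int(v) for k, v in splits.items()},
        "config": {
            "n_frames": n_frames,
            "max_shift_px": max_shift,
            "max_rot_deg": max_rot,
            "pathology_mix": mix,
            "noise": noise_cfg,
        },
        "eyes": eyes,
    }
    save_manifest(out_dir / "manifest.json", manifest)
    return manifest


def _frame_entry(frame: EnfaceImage, path: Path, out_dir: Path) -> dict:
    t = frame.true_transform or Transform2D()
    return {
        "path": str(path.relative_to(out_dir)),
        "role": frame.role,
        "frame_index": frame.frame_index,
        "true_transform": t.as_dict(),
        "motion_rows": list(frame.motion_rows),
        "shadow_bbox": list(frame.shadow_bbox) if frame.shadow_bbox else None,
    }
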