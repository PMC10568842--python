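"""Core domain containers for enface OCTA simulation, averaging and denoising.

Conventions used throughout the package:

* images are 2-D ``float64``/``float32`` arrays with intensities in ``[0, 1]``;
* coordinates are row-major, 0-based ``(row, col)`` with the origin at the
  top-left pixel;
* rigid transforms are parameterised as ``(dx, dy, theta)`` where ``dx`` moves
  content to the right (columns), ``dy`` moves content down (rows) and
  ``theta`` rotates counter-clockwise about the image centre, in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Global perfusion threshold separating vessel from background in truth maps.
VESSEL_THRESHOLD = 0.35

VALID_ROLES = ("single", "averaged", "pseudoaveraged", "truth")


@dataclass(frozen=True)
class Transform2D:
    """Rigid 2-D transform: translation ``(dx, dy)`` px plus rotation ``theta``
    (radians, counter-clockwise) about the image centre."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.dx, self.dy, self.theta)):
            raise ValueError("transform parameters must be finite")

    def compose(self, other: "Transform2D") -> "Transform2D":
        """Return the transform equivalent to applying ``other`` first, then
        ``self`` (both about the same image centre)."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        dx = self.dx + ct * other.dx - st * other.dy
        dy = self.dy + st * other.dx + ct * other.dy
        return Transform2D(dx=dx, dy=dy, theta=self.theta + other.theta)

    def inverse(self) -> "Transform2D":
        ct, st = math.cos(self.theta), math.sin(self.theta)
        return Transform2D(
            dx=-(ct * self.dx + st * self.dy),
            dy=-(-st * self.dx + ct * self.dy),
            theta=-self.theta,
        )

    def as_dict(self) -> dict:
        return {"dx": self.dx, "dy": self.dy, "theta": self.theta}


@dataclass
class NoiseParams:
    """Noise and artifact model for rendering single enface frames.

    ``speckle_sigma`` scales multiplicative flow speckle; the decorrelation
    background is additive Gaussian with mean ``background_level`` and std
    ``background_sigma``.  ``motion_line_rate`` is the Poisson mean number of
    corrupted rows per frame; ``shadow_prob``/``shadow_attenuation`` control a
    rectangular low-signal patch emulating media-opacity shadowing.
    """

    speckle_sigma: float = 0.25
    background_level: float = 0.10
    background_sigma: float = 0.05
    motion_line_rate: float = 1.0
    shadow_prob: float = 0.2
    shadow_attenuation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_sigma < 0 or self.background_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must be in [0, 1)")
        if self.motion_line_rate < 0:
            raise ValueError("motion_line_rate must be >= 0")
        if not 0.0 <= self.shadow_prob <= 1.0:
            raise ValueError("shadow_prob must be a probability")
        if not 0.0 < self.shadow_attenuation < 1.0:
            raise ValueError("shadow_attenuation must be in (0, 1)")

    def with_seed(self, seed: int) -> "NoiseParams":
        return replace(self, seed=int(seed))


@dataclass
class EnfaceImage:
    """One 2-D grayscale enface scan plus acquisition metadata.

    ``motion_rows`` and ``shadow_bbox`` carry simulator artifact annotations
    (empty/None for clean or real data); ``true_transform`` records the rigid
    motion applied when the frame was rendered as part of a repeated stack.
    """

    pixels: np.ndarray
    eye_id: str = ""
    frame_index: int = 0
    role: str = "single"
    pixel_size_um: float = 23.4375  # 6 mm / 256 px
    motion_rows: tuple = ()
    shadow_bbox: tuple | None = None
    true_transform: Transform2D | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("enface images must be at least 64x64")
        if not np.isfinite(px).all():
            raise ValueError("pixels must be finite")
        self.pixels = np.clip(px, 0.0, 1.0)
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class FrameStack:
    """Co-acquired repeated frames of one eye — the unit of averaging."""

    frames: list
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a FrameStack needs at least 2 frames")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError("all frames must share one shape")
        if not 0 <= self.reference_index < len(self.frames):
            raise ValueError("reference_index out of range")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple:
        return self.frames[0].shape


@dataclass
class GroundTruthPhantom:
    """Noiseless perfusion truth for one synthetic eye.

    ``vessel_mask`` is always exactly ``perfusion_map >= VESSEL_THRESHOLD``;
    the FAZ (foveal avascular zone) is a capillary-free disk whose bounding
    contour ring is itself vessel-positive (modelling FAZ contour continuity).
    """

    perfusion_map: np.ndarray
    vessel_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    faz_center_xy: tuple = (0.0, 0.0)  # (row, col)
    faz_radius: float = 12.0
    microaneurysm_centers: list = field(default_factory=list)
    dropout_regions: list = field(default_factory=list)
    contour_ring_mask: np.ndarray | None = None
    pathology_level: str = "healthy"
    mm_extent: tuple = (6.0, 6.0)

    def __post_init__(self) -> None:
        pm = np.asarray(self.perfusion_map, dtype=float)
        if pm.ndim != 2:
            raise ValueError("perfusion_map must be 2-D")
        if not np.isfinite(pm).all():
            raise ValueError("perfusion_map must be finite")
        if pm.min() < 0.0 or pm.max() > 1.0:
            raise ValueError("perfusion_map must lie in [0, 1]")
        self.perfusion_map = pm
        if self.vessel_mask is None:
            self.vessel_mask = pm >= VESSEL_THRESHOLD
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        if self.vessel_mask.shape != pm.shape:
            raise ValueError("vessel_mask shape mismatch")

    @property
    def size_px(self) -> tuple:
        return self.perfusion_map.shape

    @property
    def background_mask(self) -> np.ndarray:
        return ~self.vessel_mask
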