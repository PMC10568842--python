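"""The 5-level patch U-Net and the patch-extraction scheme it consumes.

"5-level" means five resolution levels (four 2x down/up-samplings), the
standard encoder-decoder reading of U-Net depth; an input patch side must
therefore be divisible by ``2**(levels-1)`` (16 for the default 64x64
patches).  Skip connections concatenate encoder features into the decoder at
each level and a [0, 1]-bounded head (hard clip with straight-through
gradient by default, sigmoid optionally) matches the target range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import F32, Conv3x3, MaxPool2, Upsample2, sigmoid
from .types import EnfaceImage


@dataclass(frozen=True)
class UNetSpec:
    levels: int = 5
    base_channels: int = 16
    convs_per_level: int = 2
    in_channels: int = 1
    out_channels: int = 1
    #: output activation keeping predictions in [0, 1]: "clip" (hard clip with
    #: straight-through gradient; default — avoids the saturation that stalls
    #: L1+SGD convergence) or "sigmoid"
    head: str = "clip"

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 1 or self.convs_per_level < 1:
            raise ValueError("base_channels and convs_per_level must be >= 1")
        if self.head not in ("clip", "sigmoid"):
            raise ValueError("head must be 'clip' or 'sigmoid'")

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


class Conv1x1:
    """1x1 projection head (linear; the output activation is the model's)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((c_in, c_out)) * np.sqrt(1.0 / c_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.c_in, self.c_out = c_in, c_out

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        b, h, w, _ = self._x.shape
        xf = self._x.reshape(-1, self.c_in)
        dyf = dy.reshape(-1, self.c_out)
        self.dw = xf.T @ dyf
        self.db = dyf.sum(axis=0)
        dx = (dyf @ self.w.T).reshape(self._x.shape)
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class UNet:
    """Encoder-decoder with skip concatenation; numpy forward/backward."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([0x0DE7, seed]))
        L, B, K = spec.levels, spec.base_channels, spec.convs_per_level

        def block(c_in, c_out):
            convs = [Conv3x3(c_in, c_out, rng)]
            convs += [Conv3x3(c_out, c_out, rng) for _ in range(K - 1)]
            return convs

        self.enc = []
        c_prev = spec.in_channels
        for i in range(L - 1):
            c = B * 2**i
            self.enc.append(block(c_prev, c))
            c_prev = c
        self.bottleneck = block(c_prev, B * 2 ** (L - 1))
        self.upconvs = []
        self.dec = []
        for i in reversed(range(L - 1)):
            c = B * 2**i
            self.upconvs.append(Conv3x3(2 * c, c, rng))
            self.dec.append(block(2 * c, c))
        self.head_conv = Conv1x1(B, spec.out_channels, rng)

    # ---- parameter plumbing -------------------------------------------------
    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.bottleneck
        for upc, blk in zip(self.upconvs, self.dec):
            yield upc
            yield from blk
        yield self.head_conv

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def grads(self):
        out = []
        for layer in self._layers():
            out.extend(layer.grads())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # ---- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[1:3]
        d = self.spec.divisor
        if h % d or w % d:
            raise ValueError(
                f"input size {h}x{w} rejected: a {self.spec.levels}-level U-Net "
                f"requires height and width divisible by 2**(levels-1) = {d}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (B, H, W) or (B, H, W, 1) float input to same-shape output in
        [0, 1]."""
        squeeze = x.ndim == 3
        if squeeze:
            x = x[..., None]
        x = x.astype(F32, copy=False)
        self._check_input(x)

        skips = []
        pools = []
        for blk in self.enc:
            for conv in blk:
                x = conv.forward(x, train)
            skips.append(x)
            pool = MaxPool2()
            x = pool.forward(x, train)
            pools.append(pool)
        for conv in self.bottleneck:
            x = conv.forward(x, train)

        ups = []
        for upc, blk, skip in zip(self.upconvs, self.dec, reversed(skips)):
            up = Upsample2()
            x = up.forward(x, train)
            ups.append(up)
            x = upc.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            for conv in blk:
                x = conv.forward(x, train)

        z = self.head_conv.forward(x, train)
        if self.spec.head == "sigmoid":
            y = sigmoid(z)
        else:
            y = np.clip(z, 0.0, 1.0)
        if train:
            self._y = y
            self._pools = pools
            self._ups = ups
        return y[..., 0] if squeeze else y

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for dLoss/dOutput ``dy``."""
        if dy.ndim == 3:
            dy = dy[..., None]
        y = self._y
        if self.spec.head == "sigmoid":
            dz = (dy * y * (1.0 - y)).astype(F32)
        else:  # straight-through gradient for the hard clip
            dz = dy.astype(F32, copy=False)
        dx = self.head_conv.backward(dz)

        skip_grads = []
        for upc, blk in zip(reversed(self.upconvs), reversed(self.dec)):
            for conv in reversed(blk):
                dx = conv.backward(dx)
            c = dx.shape[-1] // 2
            skip_grads.append(dx[..., :c])
            dx = upc.backward(np.ascontiguousarray(dx[..., c:]))
            dx = self._ups.pop().backward(dx)
        for conv in reversed(self.bottleneck):
            dx = conv.backward(dx)
        for blk, pool in zip(reversed(self.enc), reversed(self._pools)):
            dx = pool.backward(dx)
            dx = dx + skip_grads.pop()
            for conv in reversed(blk):
                dx = conv.backward(dx)
        self._y = self._pools = self._ups = None


def build_model(spec: UNetSpec, seed: int = 0) -> UNet:
    """Construct a randomly initialised U-Net; deterministic given seed."""
    return UNet(spec, seed=seed)


def build_identity_model(spec: UNetSpec | None = None) -> UNet:
    """A U-Net whose weights exactly compute the identity map.

    Channel 0 carries the input through the first encoder block and its skip
    connection into the last decoder block and the head; every other kernel
    is zero.  Because inputs are nonnegative (ReLU is exact on them) and the
    head is a hard clip, the output equals the input bit-for-bit up to float
    rounding — a diagnostic reference for tiled-inference stitching, which
    must then reproduce any scan exactly.
    """
    spec = spec or UNetSpec(head="clip")
    if spec.head != "clip":
        raise ValueError("the exact identity construction needs the clip head")
    model = UNet(spec, seed=0)
    for layer in model._layers():
        for p in layer.params():
            p[...] = 0.0
    # first encoder block: centre-tap delta from input channel 0
    for conv in model.enc[0]:
        w4 = conv.w.reshape(3, 3, conv.c_in, conv.c_out)
        w4[1, 1, 0, 0] = 1.0
    # last decoder block: delta from the skip half (channel 0)
    for conv in model.dec[-1]:
        w4 = conv.w.reshape(3, 3, conv.c_in, conv.c_out)
        w4[1, 1, 0, 0] = 1.0
    model.head_conv.w[0, 0] = 1.0
    return model


def save_model(model: UNet, path) -> None:
    """Serialise weights plus the architecture spec into one ``.npz`` file."""
    meta = dict(
        levels=model.spec.levels,
        base_channels=model.spec.base_channels,
        convs_per_level=model.spec.convs_per_level,
        in_channels=model.spec.in_channels,
        out_channels=model.spec.out_channels,
        head=model.spec.head,
    )
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(path, spec=np.array(list(meta.items()), dtype=object), **arrays)


def load_model(path) -> UNet:
    data = np.load(path, allow_pickle=True)
    meta = {k: (str(v) if k == "head" else int(v)) for k, v in data["spec"]}
    model = UNet(UNetSpec(**meta))
    params = model.params()
    for i, p in enumerate(params):
        saved = data[f"p{i}"]
        if saved.shape != p.shape:
            raise ValueError("weight file is incompatible with its stored spec")
        p[...] = saved
    return model


# ---- patch extraction -------------------------------------------------------

@dataclass
class PatchGrid:
    patch_size: int
    stride: int
    positions: list = field(default_factory=list)
    image_shape: tuple = (0, 0)

    def __len__(self) -> int:
        return len(self.positions)


def _axis_positions(extent: int, patch: int, stride: int) -> list:
    """Stride lattice with the final position snapped to the image edge so
    the union of patches covers every pixel.

    The last lattice point is moved to the edge when the previous patch
    still covers the vacated span (keeping the lattice count); otherwise an
    extra edge position is appended."""
    n = (extent - patch) // stride + 1
    pos = [i * stride for i in range(n)]
    edge = extent - patch
    if pos[-1] != edge:
        if len(pos) >= 2 and pos[-2] + patch >= edge:
            pos[-1] = edge
        else:
            pos.append(edge)
    return pos


def extract_patches(image, patch_size: int = 64, stride: int | None = None):
    """Extract fully-inside patches on a stride lattice.

    Returns ``(grid, patches)`` with ``patches`` of shape (N, p, p), positions
    row-major.  Default stride is 14 for 500x500 scans (giving the ~1000
    training patches per scan) and ``patch_size // 4`` otherwise.
    """
    px = image.pixels if isinstance(image, EnfaceImage) else np.asarray(image, dtype=float)
    h, w = px.shape
    if h < patch_size or w < patch_size:
        raise ValueError("image smaller than patch_size")
    if stride is None:
        stride = 14 if (h, w) == (500, 500) else max(1, patch_size // 4)
    if stride <= 0:
        raise ValueError("stride must be positive")

    rows = _axis_positions(h, patch_size, stride)
    cols = _axis_positions(w, patch_size, stride)
    positions = [(r, c) for r in rows for c in cols]
    patches = np.stack(
        [px[r : r + patch_size, c : c + patch_size] for r, c in positions]
    ).astype(F32)
    grid = PatchGrid(patch_size=patch_size, stride=stride, positions=positions, image_shape=(h, w))
    return grid, patches


def stitch_patches(patches, grid: PatchGrid, window: np.ndarray | None = None) -> np.ndarray:
    """Blend patches back onto the image canvas (weighted overlap average).

    With ``window=None`` overlapping patches are averaged uniformly, which
    reconstructs the image exactly when patches are exact crops.
    """
    h, w = grid.image_shape
    p = grid.patch_size
    if window is None:
        window = np.ones((p, p))
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    for patch, (r, c) in zip(patches, grid.positions):
        num[r : r + p, c : c + p] += window * patch
        den[r : r + p, c : c + p] += window
    return num / den
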