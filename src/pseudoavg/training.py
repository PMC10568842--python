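"""Training-pair construction and the masked-L1 SGD loop.

Two pair kinds feed the denoiser, mirroring how averaged-scan supervision is
assembled in practice:

* ``single_to_average`` — the best single frame of an eye paired with its
  registered N-frame average; artifact regions of the *target* (residual
  motion rows, shadow patches) are masked out of the loss, not the input.
* ``peer_to_peer`` — a low-quality single frame paired with a high-quality
  single frame of the same eye.  These pairs teach the network that
  low-signal regions still contain perfusion, countering the tendency of a
  pure single-to-average model to erase dim vasculature (false-negative
  perfusion).

The loss is the mean absolute difference over valid pixels only.  Training
is plain SGD with momentum, seeded shuffling and dihedral (flip/rot90)
augmentation, and is bit-deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import UNet, UNetSpec, build_model, extract_patches
from .nn import F32
from .registration import quality_score
from .types import EnfaceImage

PAIR_KINDS = ("single_to_average", "peer_to_peer")


@dataclass
class TrainingPair:
    input_patch: np.ndarray
    target_patch: np.ndarray
    valid_mask: np.ndarray
    pair_kind: str
    source_eye: str = ""

    def __post_init__(self):
        if not (
            self.input_patch.shape == self.target_patch.shape == self.valid_mask.shape
        ):
            raise ValueError("patch and mask shapes must match")
        if self.pair_kind not in PAIR_KINDS:
            raise ValueError(f"pair_kind must be one of {PAIR_KINDS}")
        if not self.valid_mask.any():
            raise ValueError("pairs with an all-false valid_mask must be dropped")


@dataclass
class TrainConfig:
    learning_rate: float = 0.05
    momentum: float = 0.9
    lr_decay: float = 1.0  # per-epoch multiplicative decay (1.0 = constant)
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    augmentations: frozenset = frozenset({"hflip", "vflip", "rot90"})
    augment_mode: str = "random"  # one random dihedral variant per pair per epoch
    p2p_fraction: float = 0.25  # peer-to-peer : single-to-average mix per epoch

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.augment_mode not in ("random", "full", "none"):
            raise ValueError("augment_mode must be random, full or none")


def _pixels(image):
    return image.pixels if isinstance(image, EnfaceImage) else np.asarray(image, dtype=float)


def _make_pairs(inp, tgt, artifact_mask, grid_kw, kind, source_eye):
    inp = _pixels(inp)
    tgt = _pixels(tgt)
    if inp.shape != tgt.shape:
        raise ValueError("input and target must share a shape")
    if artifact_mask is None:
        artifact_mask = np.ones(inp.shape, dtype=bool)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != inp.shape:
        raise ValueError("artifact_mask must match the image shape")

    grid, in_patches = extract_patches(inp, **grid_kw)
    _, tgt_patches = extract_patches(tgt, **grid_kw)
    _, mask_patches = extract_patches(artifact_mask.astype(float), **grid_kw)
    pairs = []
    for ip, tp, mp in zip(in_patches, tgt_patches, mask_patches):
        valid = mp > 0.5
        if not valid.any():
            continue  # fully-masked tiles carry no supervision
        pairs.append(
            TrainingPair(
                input_patch=ip.astype(F32),
                target_patch=tp.astype(F32),
                valid_mask=valid,
                pair_kind=kind,
                source_eye=source_eye,
            )
        )
    return pairs


def make_single_to_average_pairs(
    single, averaged, artifact_mask=None, patch_size: int = 64, stride: int | None = None,
    source_eye: str = "",
):
    """Patch pairs (single input, averaged target) on the stride lattice.

    ``artifact_mask`` is True where the target is trustworthy; masked-out
    regions are excluded from the loss only.  Tiles with zero valid pixels
    are dropped.
    """
    return _make_pairs(
        single, averaged, artifact_mask,
        {"patch_size": patch_size, "stride": stride},
        "single_to_average", source_eye,
    )


def make_peer_to_peer_pairs(
    low_quality, high_quality, patch_size: int = 64, stride: int | None = None,
    source_eye: str = "",
):
    """Patch pairs using a high-quality frame of the same eye as the target.

    Requires ``quality_score(low) < quality_score(high)``; frames must be
    pre-registered to a common reference.
    """
    q_low = quality_score(_pixels(low_quality))
    q_high = quality_score(_pixels(high_quality))
    if not q_low < q_high:
        raise ValueError(
            f"peer-to-peer pairs need quality(low) < quality(high); "
            f"got {q_low:.3f} >= {q_high:.3f}"
        )
    return _make_pairs(
        low_quality, high_quality, None,
        {"patch_size": patch_size, "stride": stride},
        "peer_to_peer", source_eye,
    )


def masked_l1_loss(pred, target, valid_mask) -> float:
    """Mean absolute difference over valid pixels only."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    valid = np.asarray(valid_mask, dtype=bool)
    if pred.shape != target.shape or pred.shape != valid.shape:
        raise ValueError("pred, target and valid_mask must share a shape")
    n = valid.sum()
    if n == 0:
        raise ValueError("masked_l1_loss needs at least one valid pixel")
    return float(np.abs(pred - target)[valid].sum() / n)


_DIHEDRAL = [
    lambda a: a,
    lambda a: a[::-1],          # vflip
    lambda a: a[:, ::-1],       # hflip
    lambda a: a[::-1, ::-1],
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 1)[::-1],
    lambda a: np.rot90(a, 1)[:, ::-1],
    lambda a: np.rot90(a, 3),
]


def _allowed_ops(augmentations) -> list:
    ops = [0]
    if "vflip" in augmentations:
        ops.append(1)
    if "hflip" in augmentations:
        ops.append(2)
    if "hflip" in augmentations and "vflip" in augmentations:
        ops.append(3)
    if "rot90" in augmentations:
        ops += [4, 7]
        if "hflip" in augmentations and "vflip" in augmentations:
            ops += [5, 6]
    return ops


def _augment(pair: TrainingPair, op: int):
    f = _DIHEDRAL[op]
    return f(pair.input_patch), f(pair.target_patch), f(pair.valid_mask)


def train(pairs, spec: UNetSpec | None = None, config: TrainConfig | None = None,
          model: UNet | None = None):
    """Run the masked-L1 SGD loop; returns ``(model, loss_history)``.

    ``loss_history`` is the mean training loss per epoch.  Identical pairs,
    spec and config (and a fixed seed) reproduce bit-identical weights in
    single-threaded execution.  Raises on NaN loss with a diagnostic.
    """
    if not pairs:
        raise ValueError("train() needs at least one TrainingPair")
    spec = spec or UNetSpec()
    config = config or TrainConfig()
    if model is None:
        model = build_model(spec, seed=config.seed)

    s2a = [p for p in pairs if p.pair_kind == "single_to_average"]
    p2p = [p for p in pairs if p.pair_kind == "peer_to_peer"]
    rng = np.random.default_rng(np.random.SeedSequence([0x7EA1, config.seed]))

    params = model.params()
    velocity = [np.zeros_like(p) for p in params]
    mom = np.float32(config.momentum)

    loss_history = []
    for epoch in range(config.epochs):
        lr = np.float32(config.learning_rate * config.lr_decay**epoch)
        epoch_pairs = list(s2a) if s2a else []
        if p2p and s2a:
            n_p2p = max(1, int(round(config.p2p_fraction * len(s2a))))
            idx = rng.choice(len(p2p), size=min(n_p2p, len(p2p)), replace=False)
            epoch_pairs += [p2p[i] for i in idx]
        elif p2p:
            epoch_pairs += list(p2p)

        if config.augment_mode == "full":
            allowed = _allowed_ops(config.augmentations)
            expanded = [(p, op) for p in epoch_pairs for op in allowed]
        elif config.augment_mode == "random":
            allowed = _allowed_ops(config.augmentations)
            ops = rng.choice(allowed, size=len(epoch_pairs))
            expanded = list(zip(epoch_pairs, (int(o) for o in ops)))
        else:
            expanded = [(p, 0) for p in epoch_pairs]

        order = rng.permutation(len(expanded))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [expanded[i] for i in order[start : start + config.batch_size]]
            xb = np.stack([_augment(p, op)[0] for p, op in batch])
            tb = np.stack([_augment(p, op)[1] for p, op in batch])
            mb = np.stack([_augment(p, op)[2] for p, op in batch])

            pred = model.forward(xb, train=True)
            diff = pred - tb
            n_valid = np.float32(mb.sum())
            loss = float(np.abs(diff)[mb].sum() / n_valid)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // config.batch_size}; "
                    "lower the learning rate"
                )
            losses.append(loss)
            dpred = (np.sign(diff) * mb).astype(F32) / n_valid
            model.backward(dpred)
            for p, v, g in zip(params, velocity, model.grads()):
                v *= mom
                v -= lr * g
                p += v
        loss_history.append(float(np.mean(losses)))
    return model, loss_history
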