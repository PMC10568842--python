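"""Training-pair construction, the masked L1 loss and the SGD loop."""

import numpy as np
import pytest

from pseudoavg.model import UNetSpec, extract_patches
from pseudoavg.synthdata import generate_phantom, render_single_frame
from pseudoavg.training import (
    TrainConfig,
    TrainingPair,
    _DIHEDRAL,
    make_peer_to_peer_pairs,
    make_single_to_average_pairs,
    masked_l1_loss,
    train,
)
from pseudoavg.types import NoiseParams


class TestSingleToAveragePairs:
    def test_full_grid_no_mask(self, rng):
        single = rng.random((256, 256))
        pairs = make_single_to_average_pairs(single, single * 0.9, stride=64)
        assert len(pairs) == 16
        assert all(p.valid_mask.all() for p in pairs)
        assert all(p.pair_kind == "single_to_average" for p in pairs)

    def test_fully_masked_tile_dropped(self, rng):
        single = rng.random((256, 256))
        mask = np.ones((256, 256), dtype=bool)
        mask[0:64, 0:64] = False
        pairs = make_single_to_average_pairs(single, single, mask, stride=64)
        assert len(pairs) == 15

    def test_half_masked_tile_retains_valid_count(self, rng):
        single = rng.random((256, 256))
        mask = np.ones((256, 256), dtype=bool)
        mask[0:64, 0:32] = False  # half of the first tile
        pairs = make_single_to_average_pairs(single, single, mask, stride=64)
        assert len(pairs) == 16
        assert int(pairs[0].valid_mask.sum()) == 2048

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            make_single_to_average_pairs(rng.random((256, 256)), rng.random((128, 128)))


class TestPeerToPeerPairs:
    def test_identical_frames_rejected(self, noisy_frame):
        with pytest.raises(ValueError, match="quality"):
            make_peer_to_peer_pairs(noisy_frame, noisy_frame)

    def test_shadowed_vs_clean_accepted_and_darker(self, healthy_phantom):
        clean = render_single_frame(
            healthy_phantom,
            NoiseParams(motion_line_rate=0.0, shadow_prob=0.0, seed=3),
        )
        shadowed = render_single_frame(
            healthy_phantom,
            NoiseParams(speckle_sigma=0.45, motion_line_rate=0.0,
                        shadow_prob=1.0, shadow_attenuation=0.5, seed=4),
        )
        pairs = make_peer_to_peer_pairs(shadowed, clean, stride=64)
        assert pairs and all(p.pair_kind == "peer_to_peer" for p in pairs)
        r0, c0, bh, bw = shadowed.shadow_bbox
        shadow = np.zeros((256, 256), dtype=bool)
        shadow[r0 : r0 + bh, c0 : c0 + bw] = True
        grid, _ = extract_patches(shadowed.pixels, 64, 64)
        for pair, (r, c) in zip(pairs, grid.positions):
            tile_shadow = shadow[r : r + 64, c : c + 64]
            if tile_shadow.sum() > 100:
                assert pair.input_patch[tile_shadow].mean() <= pair.target_patch[tile_shadow].mean()


class TestMaskedL1:
    def test_zero_when_equal(self, rng):
        x = rng.random((64, 64))
        assert masked_l1_loss(x, x, np.ones_like(x, bool)) == 0.0

    def test_constant_offset(self, rng):
        x = rng.random((64, 64)) * 0.5
        assert masked_l1_loss(x + 0.1, x, np.ones_like(x, bool)) == pytest.approx(0.1)

    def test_masked_out_differences_ignored(self, rng):
        x = rng.random((64, 64))
        y = x.copy()
        y[:, :32] += 0.4
        mask = np.zeros_like(x, bool)
        mask[:, 32:] = True
        assert masked_l1_loss(y, x, mask) == 0.0

    def test_errors(self, rng):
        x = rng.random((8, 8))
        with pytest.raises(ValueError, match="valid"):
            masked_l1_loss(x, x, np.zeros_like(x, bool))
        with pytest.raises(ValueError, match="shape"):
            masked_l1_loss(x, x[:4], np.ones_like(x, bool))


def _identity_pairs(patch, stride, seeds=(11,)):
    pairs = []
    for s in seeds:
        ph = generate_phantom((256, 256), "npdr", seed=s)
        img = render_single_frame(ph, NoiseParams(seed=s)).pixels
        _, patches = extract_patches(img, patch, stride)
        for p in patches:
            pairs.append(
                TrainingPair(p, p.copy(), np.ones_like(p, dtype=bool), "single_to_average")
            )
    return pairs


class TestTrainLoop:
    def test_identity_task_converges_toward_zero(self):
        pairs = _identity_pairs(32, 8)
        _, history = train(
            pairs,
            UNetSpec(levels=3, base_channels=4, convs_per_level=1),
            TrainConfig(epochs=5, learning_rate=0.05, lr_decay=0.7, seed=0),
        )
        assert history[-1] < history[0] * 0.6
        assert history[-1] < 0.08

    def test_training_is_bit_deterministic(self):
        pairs = _identity_pairs(32, 64)
        spec = UNetSpec(levels=3, base_channels=4, convs_per_level=1)
        config = TrainConfig(epochs=2, seed=9)
        model_a, hist_a = train(pairs, spec, config)
        model_b, hist_b = train(pairs, spec, config)
        assert hist_a == hist_b
        for pa, pb in zip(model_a.params(), model_b.params()):
            assert np.array_equal(pa, pb)

    def test_nan_loss_aborts_with_diagnostic(self):
        bad = np.full((32, 32), np.nan, dtype=np.float32)
        pairs = [TrainingPair(bad, bad.copy(), np.ones((32, 32), bool), "single_to_average")]
        with pytest.raises(RuntimeError, match="NaN"):
            train(pairs, UNetSpec(levels=2, base_channels=2, convs_per_level=1),
                  TrainConfig(epochs=1, seed=0))

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="TrainingPair"):
            train([], UNetSpec(levels=2, base_channels=2), TrainConfig(epochs=1))


class TestAugmentation:
    def test_dihedral_group_has_eight_distinct_elements(self, rng):
        patch = rng.random((8, 8))
        variants = [op(patch) for op in _DIHEDRAL]
        for i in range(8):
            for j in range(i + 1, 8):
                assert not np.array_equal(variants[i], variants[j])

    def test_all_false_mask_pair_rejected(self):
        p = np.zeros((16, 16), dtype=np.float32)
        with pytest.raises(ValueError, match="all-false"):
            TrainingPair(p, p, np.zeros((16, 16), bool), "single_to_average")


class TestAntiOverDenoising:
    def test_shadowed_vessels_not_erased(self, study_bundle):
        """Low-signal (shadowed) regions keep their perfusion after
        pseudoaveraging when peer-to-peer pairs were part of training: the
        network must brighten, not erase, dim vasculature."""
        _, result = study_bundle
        checked = 0
        for rec in result.cohort:
            bbox = rec["original"].shadow_bbox
            if bbox is None:
                continue
            r0, c0, bh, bw = bbox
            region = np.zeros(rec["original"].shape, dtype=bool)
            region[r0 : r0 + bh, c0 : c0 + bw] = True
            region &= rec["phantom"].vessel_mask
            if region.sum() < 100:
                continue
            checked += 1
            inp = rec["original"].pixels[region].mean()
            out = rec["processed"].pixels[region].mean()
            assert out >= inp, "shadowed vasculature was dimmed further"
        assert checked >= 3  # the cohort must actually contain shadow scans
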