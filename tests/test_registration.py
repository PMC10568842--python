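"""Rigid transform algebra, frame registration and stack averaging."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pseudoavg.registration import (
    RegistrationFailure,
    apply_transform,
    average_frames,
    estimate_transform,
    quality_score,
    warp_rigid,
)
from pseudoavg.synthdata import generate_phantom, render_single_frame
from pseudoavg.types import EnfaceImage, FrameStack, NoiseParams, Transform2D


class TestTransformAlgebra:
    @pytest.mark.parametrize("seed", range(5))
    def test_compose_with_inverse_is_identity(self, seed):
        r = np.random.default_rng(seed)
        t = Transform2D(dx=r.uniform(-10, 10), dy=r.uniform(-10, 10), theta=r.uniform(-0.1, 0.1))
        ident = t.compose(t.inverse())
        assert abs(ident.dx) < 1e-12 and abs(ident.dy) < 1e-12 and abs(ident.theta) < 1e-12

    def test_compose_matches_sequential_warp(self, noisy_frame):
        a = Transform2D(dx=3.0, dy=-2.0, theta=0.02)
        b = Transform2D(dx=-1.5, dy=4.0, theta=-0.01)
        img = gaussian_filter(noisy_frame.pixels, 2.0)
        seq = warp_rigid(warp_rigid(img, b), a)
        combined = warp_rigid(img, a.compose(b))
        interior = np.s_[24:-24, 24:-24]
        assert np.abs(seq[interior] - combined[interior]).max() < 0.03


class TestQualityScore:
    def test_constant_image_scores_zero(self):
        assert quality_score(np.full((64, 64), 0.5)) == 0.0

    def test_noise_lowers_score(self, healthy_phantom):
        clean = render_single_frame(
            healthy_phantom,
            NoiseParams(speckle_sigma=0.0, background_sigma=0.0,
                        motion_line_rate=0.0, shadow_prob=0.0, seed=1),
        )
        noisy = render_single_frame(
            healthy_phantom,
            NoiseParams(speckle_sigma=0.5, background_sigma=0.05,
                        motion_line_rate=0.0, shadow_prob=0.0, seed=1),
        )
        assert quality_score(clean) > quality_score(noisy)

    @pytest.mark.parametrize("offset", [0.02, 0.05, 0.09])
    def test_offset_invariance(self, noisy_frame, offset):
        base = quality_score(noisy_frame.pixels * 0.8)  # headroom for the offset
        shifted = quality_score(noisy_frame.pixels * 0.8 + offset)
        assert shifted == pytest.approx(base, rel=1e-6)


class TestApplyTransform:
    def test_identity_unchanged(self, noisy_frame):
        out, mask = apply_transform(noisy_frame.pixels, Transform2D())
        assert np.allclose(out, noisy_frame.pixels)
        assert mask.all()

    def test_full_width_shift_invalidates_everything(self, noisy_frame):
        w = noisy_frame.shape[1]
        _, mask = apply_transform(noisy_frame.pixels, Transform2D(dx=float(w)))
        assert not mask.any()

    def test_roundtrip_within_interpolation_error(self, healthy_phantom):
        img = gaussian_filter(healthy_phantom.perfusion_map, 3.0)
        t = Transform2D(dx=2.5, dy=-1.5, theta=0.01)
        fwd, _ = apply_transform(img, t)
        back, _ = apply_transform(fwd, t.inverse())
        interior = np.s_[16:-16, 16:-16]
        assert np.abs(back[interior] - img[interior]).max() <= 0.02

    def test_enface_image_in_enface_image_out(self, noisy_frame):
        out, mask = apply_transform(noisy_frame, Transform2D(dx=1.0))
        assert isinstance(out, EnfaceImage)
        assert out.eye_id == noisy_frame.eye_id


class TestEstimateTransform:
    def test_identity_pair(self, noisy_frame):
        t = estimate_transform(noisy_frame.pixels, noisy_frame.pixels)
        assert abs(t.dx) < 0.1 and abs(t.dy) < 0.1
        assert abs(math.degrees(t.theta)) < 0.05

    def test_pure_shift_recovered(self, healthy_phantom):
        ref = render_single_frame(
            healthy_phantom,
            NoiseParams(speckle_sigma=0.0, background_sigma=0.0,
                        motion_line_rate=0.0, shadow_prob=0.0, seed=1),
        ).pixels
        moved = warp_rigid(ref, Transform2D(dx=3.0, dy=-5.0))
        t = estimate_transform(ref, moved)
        # the estimate aligns the moved frame back onto the reference
        assert abs(t.dx - (-3.0)) <= 0.5
        assert abs(t.dy - 5.0) <= 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_parameter_recovery_with_noise(self, seed):
        r = np.random.default_rng(np.random.SeedSequence([55, seed]))
        ph = generate_phantom((256, 256), "healthy", seed=seed)
        t_true = Transform2D(
            dx=float(r.uniform(-10, 10)), dy=float(r.uniform(-10, 10)),
            theta=math.radians(float(r.uniform(-2, 2))),
        )
        ref = render_single_frame(ph, NoiseParams(seed=1),
                                  rng=np.random.default_rng(np.random.SeedSequence([1, seed])))
        mov = render_single_frame(ph, NoiseParams(seed=2), transform=t_true,
                                  rng=np.random.default_rng(np.random.SeedSequence([2, seed])))
        t_est = estimate_transform(ref.pixels, mov.pixels)
        t_want = t_true.inverse()
        assert abs(t_est.dx - t_want.dx) <= 0.5
        assert abs(t_est.dy - t_want.dy) <= 0.5
        assert abs(math.degrees(t_est.theta - t_want.theta)) <= 0.2

    def test_degenerate_images_flagged(self):
        flat = np.full((128, 128), 0.3)
        with pytest.raises(RegistrationFailure):
            estimate_transform(flat, flat)


def _stack_of(pixel_arrays, eye="e"):
    frames = [
        EnfaceImage(pixels=p, eye_id=eye, frame_index=i) for i, p in enumerate(pixel_arrays)
    ]
    return FrameStack(frames=frames)


class TestAverageFrames:
    def test_identical_noiseless_frames_unchanged(self, healthy_phantom):
        clean = render_single_frame(
            healthy_phantom,
            NoiseParams(speckle_sigma=0.0, background_sigma=0.0,
                        motion_line_rate=0.0, shadow_prob=0.0, seed=1),
        ).pixels
        avg = average_frames(_stack_of([clean.copy() for _ in range(4)]))
        assert np.abs(avg.pixels - clean).max() < 5e-3

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_sqrt_n_noise_law(self, healthy_phantom, n):
        sigma = 0.05
        rng = np.random.default_rng(100 + n)
        base = np.clip(healthy_phantom.perfusion_map * 0.6 + 0.3, 0, 0.9)
        frames = [np.clip(base + rng.normal(0, sigma, base.shape), 0, 1) for _ in range(n)]
        avg = average_frames(_stack_of(frames))
        background = healthy_phantom.perfusion_map < 0.05
        resid = (avg.pixels - base)[background]
        assert abs(resid.std() - sigma / np.sqrt(n)) / (sigma / np.sqrt(n)) < 0.10

    def test_motion_row_residual_is_quarter(self, healthy_phantom):
        from pseudoavg.evaluation import motion_index

        base = np.clip(gaussian_filter(healthy_phantom.perfusion_map, 2.0) + 0.1, 0, 1)
        corrupted = base.copy()
        corrupted[100] = 1.0
        single_idx = motion_index(corrupted, [100])
        avg = average_frames(_stack_of([corrupted, base.copy(), base.copy(), base.copy()]))
        avg_idx = motion_index(avg.pixels, [100])
        assert avg_idx < single_idx
        assert avg_idx == pytest.approx(single_idx / 4, rel=0.15)

    def test_never_noisier_than_best_frame(self, healthy_phantom):
        from pseudoavg.evaluation import background_sigma

        params = NoiseParams(motion_line_rate=0.0, shadow_prob=0.0)
        frames = [
            render_single_frame(healthy_phantom, params.with_seed(s)).pixels
            for s in range(4)
        ]
        avg = average_frames(_stack_of(frames))
        bg = ~healthy_phantom.vessel_mask
        best = min(background_sigma(f, bg) for f in frames)
        assert background_sigma(avg.pixels, bg) <= best

    def test_all_registrations_failed_returns_reference(self, noisy_frame):
        flat = np.full(noisy_frame.shape, 0.5)
        stack = _stack_of([noisy_frame.pixels, flat])
        avg, info = average_frames(stack, return_info=True)
        assert info["all_failed"]
        assert np.array_equal(avg.pixels, noisy_frame.pixels)
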