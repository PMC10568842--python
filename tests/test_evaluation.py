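"""Objective quality metrics, artifact detectors and paired statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from pseudoavg.evaluation import (
    cnr,
    cohort_report,
    faz_contour_continuity,
    fn_perfusion,
    fp_perfusion,
    motion_index,
    rank_scans,
    wilcoxon_signed_rank,
)
from pseudoavg.synthdata import generate_phantom
from pseudoavg.types import EnfaceImage


class TestCNR:
    def _masks(self):
        vessel = np.zeros((100, 100), dtype=bool)
        vessel[:, :40] = True
        return vessel, ~vessel

    def test_closed_form(self, rng):
        vessel, background = self._masks()
        img = np.where(vessel, 1.0, 0.0) + rng.normal(0, 0.1, (100, 100))
        assert cnr(img, vessel, background) == pytest.approx(10.0, rel=0.1)

    def test_identical_distributions_give_zero(self, rng):
        vessel, background = self._masks()
        img = rng.normal(0.5, 0.1, (100, 100))
        assert abs(cnr(img, vessel, background)) < 0.2

    def test_offset_invariance(self, rng):
        vessel, background = self._masks()
        img = np.where(vessel, 0.7, 0.1) + rng.normal(0, 0.05, (100, 100))
        assert cnr(img + 0.13, vessel, background) == pytest.approx(
            cnr(img, vessel, background), rel=1e-9
        )

    def test_validation(self, rng):
        vessel, background = self._masks()
        with pytest.raises(ValueError, match="disjoint"):
            cnr(rng.random((100, 100)), vessel, vessel)
        with pytest.raises(ValueError, match="zero"):
            cnr(np.zeros((100, 100)), vessel, background)
        tiny = np.zeros((100, 100), dtype=bool)
        tiny[0, :50] = True
        with pytest.raises(ValueError, match="100 pixels"):
            cnr(rng.random((100, 100)), tiny, background & ~tiny)


@pytest.fixture(scope="module")
def flag_phantom():
    return generate_phantom((256, 256), "healthy", seed=9)


class TestPerfusionFlags:
    def test_truth_output_is_clean(self, flag_phantom):
        assert not fn_perfusion(flag_phantom, flag_phantom.perfusion_map)
        assert not fp_perfusion(flag_phantom, flag_phantom.perfusion_map)

    def test_erased_vessel_segment_flagged(self):
        # truth with one isolated 30-px vessel segment; erasing it entirely
        # must raise the false-negative flag
        truth = np.zeros((128, 128), dtype=bool)
        truth[60, 40:70] = True
        out = np.where(truth, 0.8, 0.05)
        assert not fn_perfusion(truth, out)
        out[60, 40:70] = 0.0
        assert fn_perfusion(truth, out)

    def test_fn_flag_monotone_in_tau(self, flag_phantom, rng):
        out = np.clip(flag_phantom.perfusion_map * 0.35 + rng.normal(0, 0.02, (256, 256)), 0, 1)
        flags = [fn_perfusion(flag_phantom, out, tau=t) for t in (0.10, 0.15, 0.20)]
        assert flags == sorted(flags)  # non-decreasing as tau rises

    def test_fictional_vessel_flagged(self, flag_phantom):
        out = flag_phantom.perfusion_map.copy()
        # paint a 5x5 bright blob in deep background
        background = ~flag_phantom.vessel_mask
        from scipy.ndimage import binary_erosion

        deep = binary_erosion(background, iterations=4)
        rows, cols = np.nonzero(deep)
        r, c = rows[len(rows) // 2], cols[len(cols) // 2]
        out[r - 2 : r + 3, c - 2 : c + 3] = 0.8
        assert fp_perfusion(flag_phantom, out)

    def test_residual_motion_line_not_counted_as_fictional_vessel(self):
        truth = np.zeros((128, 128), dtype=bool)  # no real vessels at all
        out = np.full((128, 128), 0.05)
        out[40] = 0.8  # bright line artifact spanning the scan
        assert fp_perfusion(truth, out)
        assert not fp_perfusion(truth, out, motion_rows=(40,))


class TestMotionIndex:
    def test_no_annotated_rows_gives_zero(self, rng):
        assert motion_index(rng.random((64, 64)), []) == 0.0

    def test_white_line_in_constant_image(self):
        img = np.full((64, 64), 0.2)
        img[30] = 1.0
        assert motion_index(img, [30]) == pytest.approx(0.8)

    def test_neighbours_skip_other_annotated_rows(self):
        img = np.full((64, 64), 0.2)
        img[30] = 1.0
        img[31] = 1.0
        assert motion_index(img, [30, 31]) == pytest.approx(0.8)


@pytest.fixture(scope="module")
def faz_phantom():
    return generate_phantom((256, 256), "healthy", seed=4)


class TestFAZContourContinuity:
    def test_truth_is_fully_continuous(self, faz_phantom):
        assert faz_contour_continuity(faz_phantom.perfusion_map, faz_phantom) == 1.0

    def test_30_degree_gap_fails_three_bins(self, faz_phantom):
        out = faz_phantom.perfusion_map.copy()
        h, w = out.shape
        rr, cc = np.mgrid[0:h, 0:w]
        ang = np.arctan2(rr - faz_phantom.faz_center_xy[0], cc - faz_phantom.faz_center_xy[1])
        ang = ang % (2 * np.pi)
        arc = (ang >= 0) & (ang < np.pi / 6)
        out[faz_phantom.contour_ring_mask & arc] = 0.0
        assert faz_contour_continuity(out, faz_phantom) == pytest.approx(33 / 36)

    def test_fully_attenuated_ring_scores_zero(self, faz_phantom):
        out = faz_phantom.perfusion_map.copy()
        out[faz_phantom.contour_ring_mask] = 0.0
        assert faz_contour_continuity(out, faz_phantom) == 0.0


def brute_force_wilcoxon(diffs):
    """Independent oracle: full enumeration of the 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    n = d.size
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    stats = np.asarray(stats)
    upper = np.mean(stats >= t_obs - 1e-9)
    lower = np.mean(stats <= t_obs + 1e-9)
    return t_obs, min(1.0, 2 * min(upper, lower))


class TestWilcoxon:
    def test_all_zero_differences_na(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.p_value)
        assert res.n == 0

    def test_fewer_than_five_nonzero_na(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 0.5, 0.1], [0.0, 0.0, 0.0, 0.0])
        assert np.isnan(res.p_value)
        assert res.n == 4

    def test_five_positive_differences_exact(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5)
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(1 / 16)  # 2 * 1/32

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_brute_force_enumeration_n8(self, trial):
        r = np.random.default_rng(np.random.SeedSequence([3100, trial]))
        # integer-valued differences exercise ties in |d|
        d = r.integers(-5, 6, size=8).astype(float)
        if np.count_nonzero(d) < 5:
            d[d == 0] = 1.0
        stat, p = brute_force_wilcoxon(d)
        res = wilcoxon_signed_rank(d)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("n", range(5, 11))
    def test_matches_brute_force_all_small_n(self, n):
        r = np.random.default_rng(n)
        d = np.round(r.normal(0.5, 1.0, size=n), 1)
        d[d == 0] = 0.3
        stat, p = brute_force_wilcoxon(d)
        res = wilcoxon_signed_rank(d)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        r = np.random.default_rng(7)
        x = r.normal(0.3, 1.0, size=12)
        ref = scipy_wilcoxon(x, alternative="two-sided", method="exact")
        res = wilcoxon_signed_rank(x)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestRankScans:
    def test_best_variant_gets_highest_rank_with_ties(self):
        table = {
            "single": [1.0, 2.0, 3.0],
            "averaged": [2.0, 2.0, 4.0],
            "pseudoaveraged": [3.0, 5.0, 4.0],
        }
        ranks, tests = rank_scans(table)
        assert list(ranks.iloc[0]) == [1, 2, 3]
        assert list(ranks.iloc[1]) == [1, 1, 3]  # equal ranking allowed
        assert list(ranks.iloc[2]) == [1, 2, 2]
        assert set(tests) == {
            ("single", "averaged"), ("single", "pseudoaveraged"),
            ("averaged", "pseudoaveraged"),
        }

    def test_wrong_variant_count_rejected(self):
        with pytest.raises(ValueError, match="2 or 3"):
            rank_scans({"a": [1.0]})


def _clean_record(eye_id, seed):
    phantom = generate_phantom((128, 128), "healthy", seed=seed)
    img = EnfaceImage(pixels=phantom.perfusion_map, eye_id=eye_id, role="single")
    processed = EnfaceImage(pixels=phantom.perfusion_map, eye_id=eye_id, role="pseudoaveraged")
    return {"eye_id": eye_id, "phantom": phantom, "original": img, "processed": processed}


class TestCohortReport:
    def test_identity_processing_improves_nothing(self):
        records = [_clean_record(f"e{i}", i) for i in range(3)]
        report = cohort_report(records)
        s = report.summary
        assert s["cnr_improved_pct"] == 0.0
        assert s["background_sigma_reduced_pct"] == 0.0
        assert s["fn_perfusion_pct"] == 0.0
        assert s["fp_perfusion_pct"] == 0.0

    def test_motion_denominator_counts_only_affected_scans(self):
        records = [_clean_record(f"e{i}", i) for i in range(4)]
        # give two scans an annotated motion row
        for rec in records[:2]:
            px = rec["original"].pixels.copy()
            px[10] = 1.0
            rec["original"] = EnfaceImage(
                pixels=px, eye_id=rec["eye_id"], role="single", motion_rows=(10,)
            )
            rec["processed"] = EnfaceImage(
                pixels=rec["phantom"].perfusion_map, eye_id=rec["eye_id"],
                role="pseudoaveraged", motion_rows=(10,),
            )
        report = cohort_report(records)
        assert report.summary["motion_scans"] == 2
        assert report.summary["motion_index_reduced_pct"] == 100.0

    def test_summary_recomputable_from_per_scan_table(self, study_bundle):
        _, result = study_bundle
        df = result.report.per_scan
        orig = df[df.variant == "original"].set_index("eye_id").sort_index()
        proc = df[df.variant == "processed"].set_index("eye_id").sort_index()
        n = len(orig)
        assert result.report.summary["cnr_improved_pct"] == pytest.approx(
            100.0 * (proc.cnr > orig.cnr).sum() / n
        )
        motion_eyes = orig.index[orig.n_motion_rows > 0]
        assert result.report.summary["motion_index_reduced_pct"] == pytest.approx(
            100.0
            * (proc.loc[motion_eyes, "motion_index"] < orig.loc[motion_eyes, "motion_index"]).sum()
            / len(motion_eyes)
        )
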