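"""VOI quantification: frame summation, TACs, ratios, stability, SUVR."""

import numpy as np
import pytest

from taupet.images import DynamicImage
from taupet.petquant import (
    RatioCurve,
    TimeActivityCurve,
    compute_suvr,
    extract_tac,
    find_stable_window,
    ratio_tac,
    relative_uptake,
    sum_frames,
    washout_metrics,
)

from conftest import make_dynamic


class TestSumFrames:
    def test_single_frame_identity(self):
        img = make_dynamic([7.0])
        out = sum_frames(img, (0.0, 5.0))
        np.testing.assert_array_equal(out.data, img.data[..., 0])

    def test_duration_weighted_mean(self):
        img = make_dynamic([2.0, 4.0])
        out = sum_frames(img, (0.0, 10.0))
        np.testing.assert_allclose(out.data, 3.0)

    def test_partial_frame_overlap_weighting(self):
        # frames 0-5 (value 1) and 5-10 (value 3); window 2.5-10 weights
        # them 2.5 : 5 -> (2.5*1 + 5*3) / 7.5 = 7/3
        img = make_dynamic([1.0, 3.0])
        out = sum_frames(img, (2.5, 10.0))
        np.testing.assert_allclose(out.data, 7.0 / 3.0)

    def test_union_of_disjoint_windows_combines(self):
        img = make_dynamic([1.0, 5.0, 9.0])
        full = sum_frames(img, (0.0, 15.0))
        w1 = sum_frames(img, (0.0, 5.0))
        w2 = sum_frames(img, (5.0, 15.0))
        combined = (5.0 * w1.data + 10.0 * w2.data) / 15.0
        np.testing.assert_allclose(full.data, combined)

    def test_window_outside_acquisition_errors(self):
        img = make_dynamic([1.0, 2.0])
        with pytest.raises(ValueError, match="0-10"):
            sum_frames(img, (20.0, 30.0))


class TestExtractTac:
    def test_uniform_image_constant_tac(self, two_label_atlas):
        img = make_dynamic([5.0, 5.0])
        tac = extract_tac(img, two_label_atlas, "a")
        np.testing.assert_allclose(tac.values, 5.0)

    def test_two_voxel_mean(self, two_label_atlas):
        data = np.zeros((2, 2, 2, 1))
        data[1, 1, 1, 0] = 1.0
        data[0, 1, 1, 0] = 3.0
        img = DynamicImage(data, [0.0], [5.0], (1, 1, 1))
        tac = extract_tac(img, two_label_atlas, "b")
        assert tac.values[0] == pytest.approx(2.0)

    def test_unknown_voi_errors(self, two_label_atlas):
        with pytest.raises(KeyError, match="nope"):
            extract_tac(make_dynamic([1.0]), two_label_atlas, "nope")


class TestRatioTac:
    def test_identity_ratio_is_one(self, two_label_atlas):
        img = make_dynamic([2.0, 3.0])
        tac = extract_tac(img, two_label_atlas, "a")
        rc = ratio_tac(tac, tac)
        np.testing.assert_allclose(rc.values, 1.0)

    def test_scaled_target(self):
        t = TimeActivityCurve([1, 2, 3], [1.3, 2.6, 3.9], [1, 1, 1], "t")
        r = TimeActivityCurve([1, 2, 3], [1.0, 2.0, 3.0], [1, 1, 1], "r")
        np.testing.assert_allclose(ratio_tac(t, r).values, 1.3)

    def test_schedule_mismatch_errors(self):
        t = TimeActivityCurve([1, 2, 3], [1, 1, 1], [1, 1, 1], "t")
        r = TimeActivityCurve([1, 2, 4], [1, 1, 1], [1, 1, 1], "r")
        with pytest.raises(ValueError, match="schedule"):
            ratio_tac(t, r)

    def test_nonpositive_reference_errors(self):
        t = TimeActivityCurve([1, 2, 3], [1, 1, 1], [1, 1, 1], "t")
        r = TimeActivityCurve([1, 2, 3], [1, 0, 1], [1, 1, 1], "r")
        with pytest.raises(ValueError, match="non-positive"):
            ratio_tac(t, r)


def brute_force_stable_onset(times, values, tol, min_span):
    """Independent exhaustive scan used as the oracle."""
    best = None
    for i in range(len(times)):
        tt, rr = times[i:], values[i:]
        if len(tt) < 3 or tt[-1] - tt[0] < min_span:
            continue
        slope = np.polyfit(tt, rr, 1)[0]
        if abs(slope) <= tol * np.mean(rr):
            best = (float(tt[0]), float(times[-1]))
            break
    return best


class TestFindStableWindow:
    def test_constant_curve_onset_at_first_frame(self):
        rc = RatioCurve(np.arange(5, 65, 5.0), np.full(12, 1.2), np.full(12, 5.0), "t", "r")
        assert find_stable_window(rc) == (5.0, 60.0)

    def test_matches_bruteforce_on_saturating_exponential(self):
        t = np.arange(2.5, 65, 5.0)
        r = 1.2 - 0.4 * np.exp(-t / 8.0)
        rc = RatioCurve(t, r, np.full_like(t, 5.0), "t", "r")
        got = find_stable_window(rc, 0.002, 20.0)
        want = brute_force_stable_onset(t, r, 0.002, 20.0)
        assert got == want
        assert got is not None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        t = np.cumsum(rng.uniform(2, 6, n))
        r = 1.0 + rng.normal(0, 0.05, n) + rng.uniform(-0.01, 0.01) * t
        rc = RatioCurve(t, r, np.full(n, 1.0), "t", "r")
        tol, span = 0.002, 10.0
        assert find_stable_window(rc, tol, span) == brute_force_stable_onset(t, r, tol, span)

    def test_no_stable_window_returns_none(self):
        t = np.arange(2.5, 65, 5.0)
        rc = RatioCurve(t, 0.1 * t, np.full_like(t, 5.0), "t", "r")
        assert find_stable_window(rc, 1e-6, 20.0) is None


class TestSuvr:
    def test_target_equals_reference_gives_one(self, two_label_atlas):
        img = make_dynamic([2.0, 4.0, 1.0])
        rec = compute_suvr(img, two_label_atlas, "a", "a", (0, 15))
        assert rec.value == pytest.approx(1.0)

    def test_global_rescaling_invariance(self, two_label_atlas):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.5, 2.0, (2, 2, 2, 3))
        img = DynamicImage(data, [0, 5, 10], [5, 10, 15], (1, 1, 1))
        scaled = DynamicImage(7.7 * data, [0, 5, 10], [5, 10, 15], (1, 1, 1))
        a = compute_suvr(img, two_label_atlas, "a", "b", (0, 15)).value
        b = compute_suvr(scaled, two_label_atlas, "a", "b", (0, 15)).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_equals_ratio_of_summed_frames(self, two_label_atlas):
        rng = np.random.default_rng(1)
        data = rng.uniform(0.5, 2.0, (2, 2, 2, 4))
        img = DynamicImage(data, [0, 5, 10, 20], [5, 10, 20, 30], (1, 1, 1))
        window = (2.5, 25.0)
        rec = compute_suvr(img, two_label_atlas, "a", "b", window)
        static = sum_frames(img, window)
        expect = static.data[two_label_atlas.mask("a")].mean() / static.data[
            two_label_atlas.mask("b")
        ].mean()
        assert rec.value == pytest.approx(expect, rel=1e-12)


class TestWashout:
    def test_constant_tac_is_100_percent(self):
        tac = TimeActivityCurve([0, 10, 60], [5, 5, 5], [1, 1, 1], "wb")
        np.testing.assert_allclose(washout_metrics(tac, [0, 10, 60]), 100.0)

    def test_monoexponential_half_life(self):
        t = np.arange(0.0, 65.0, 5.0)
        tac = TimeActivityCurve(t, 100.0 * 0.5 ** (t / 10.0), np.full_like(t, 5.0), "wb")
        assert washout_metrics(tac, [10.0])[0] == pytest.approx(50.0)

    def test_time_outside_support_errors(self):
        tac = TimeActivityCurve([5, 10, 15], [3, 2, 1], [5, 5, 5], "wb")
        with pytest.raises(ValueError, match="support"):
            washout_metrics(tac, [60.0])


class TestRelativeUptake:
    def test_identity_ratio(self):
        tac = TimeActivityCurve([2.5, 7.5], [4, 2], [5, 5], "x")
        assert relative_uptake(tac, tac, 3.0) == pytest.approx(1.0)

    def test_double_uptake(self):
        wb = TimeActivityCurve([2.5, 7.5], [4.0, 2.0], [5, 5], "wb")
        bone = TimeActivityCurve([2.5, 7.5], [8.0, 4.0], [5, 5], "bone")
        assert relative_uptake(bone, wb, 7.0) == pytest.approx(2.0)

    def test_no_covering_frame_errors(self):
        wb = TimeActivityCurve([2.5, 7.5], [4.0, 2.0], [5, 5], "wb")
        with pytest.raises(ValueError, match="covers"):
            relative_uptake(wb, wb, 30.0)
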