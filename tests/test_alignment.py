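import numpy as np
import pytest

from neurostates import (
    BoundaryTimeline,
    DegenerateDataError,
    PressLog,
    align_subject,
    align_to_behavior,
    behavioral_density,
    loo_group_timeline,
    max_correlation,
    shuffle_null,
    smooth_boundaries,
)
from neurostates.alignment import _pearson, gaussian_kernel, smooth_indices
from neurostates.simulate import draw_boundaries

from conftest import make_segmentation


class TestSmoothing:
    def test_no_boundaries_gives_zero_timeline(self):
        seg = make_segmentation([], T=50)
        tl = smooth_boundaries(seg)
        assert np.all(tl.values == 0)

    def test_single_boundary_peak_and_symmetry(self):
        seg = make_segmentation([50], T=101)
        tl = smooth_boundaries(seg, sd_samples=2.0)
        assert np.argmax(tl.values) == 50
        assert tl.values[50] == pytest.approx(1.0)  # unit-peak kernel
        np.testing.assert_allclose(tl.values[50 - 8: 50], tl.values[51: 59][::-1])

    def test_default_sd_two_samples_is_about_400ms(self):
        # 2 samples at 5.12 Hz = 390.6 ms
        assert 2 / 5.12 == pytest.approx(0.4, abs=0.01)
        kernel = gaussian_kernel(2.0)
        assert kernel.size == 17  # +/- 4 SD

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0)


class TestLeaveOneOut:
    def test_two_identical_others(self):
        common = np.abs(np.sin(np.arange(30)))
        tls = [BoundaryTimeline(common, 5.12) for _ in range(3)]
        out = loo_group_timeline(tls, 0)
        np.testing.assert_allclose(out.values, common)
        assert out.kind == "group_mean"

    def test_mean_of_loo_equals_grand_mean(self, rng):
        tls = [BoundaryTimeline(rng.random(40), 5.12) for _ in range(6)]
        loos = np.stack(
            [loo_group_timeline(tls, i).values for i in range(len(tls))]
        )
        grand = np.stack([t.values for t in tls]).mean(axis=0)
        np.testing.assert_allclose(loos.mean(axis=0), grand, atol=1e-12)

    def test_leave_out_range_checked(self, rng):
        tls = [BoundaryTimeline(rng.random(10), 5.12) for _ in range(3)]
        with pytest.raises(IndexError):
            loo_group_timeline(tls, 5)

    def test_unequal_lengths_rejected(self, rng):
        tls = [
            BoundaryTimeline(rng.random(10), 5.12),
            BoundaryTimeline(rng.random(11), 5.12),
            BoundaryTimeline(rng.random(10), 5.12),
        ]
        with pytest.raises(ValueError, match="unequal"):
            loo_group_timeline(tls, 0)


class TestShuffleNull:
    def test_equal_durations_give_zero_variance_null(self):
        seg = make_segmentation([10, 20, 30], T=40)
        ref = BoundaryTimeline(np.abs(np.sin(np.arange(40))), 5.12)
        null = shuffle_null(seg, ref, n_shuffles=50, seed=0)
        assert np.ptp(null) == pytest.approx(0.0, abs=1e-12)

    def test_constant_reference_warns_and_returns_zero(self):
        seg = make_segmentation([10, 25], T=40)
        ref = BoundaryTimeline(np.ones(40), 5.12)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            null = shuffle_null(seg, ref, n_shuffles=20, seed=0)
        assert np.all(null == 0)

    def test_single_state_degenerate(self):
        seg = make_segmentation([], T=40)
        ref = BoundaryTimeline(np.abs(np.sin(np.arange(40))), 5.12)
        with pytest.raises(DegenerateDataError):
            shuffle_null(seg, ref, n_shuffles=10, seed=0)

    def test_seeded_reproducibility(self):
        seg = make_segmentation([7, 19, 30], T=64)
        ref = BoundaryTimeline(smooth_indices([8, 20, 31], 64), 5.12)
        a = shuffle_null(seg, ref, n_shuffles=100, seed=9)
        b = shuffle_null(seg, ref, n_shuffles=100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestMaxCorrelation:
    def test_self_reference_reaches_one(self):
        idx = [10, 25, 40, 55]
        ref = BoundaryTimeline(smooth_indices(idx, 70), 5.12)
        assert max_correlation(ref, len(idx)) == pytest.approx(1.0, abs=1e-9)

    def test_flat_reference_degenerate(self):
        ref = BoundaryTimeline(np.zeros(50), 5.12)
        with pytest.raises(DegenerateDataError):
            max_correlation(ref, 3)

    def test_raw_never_exceeds_max(self):
        gen = np.random.default_rng(33)
        segs = [
            make_segmentation(draw_boundaries(gen, 128, 8), T=128, subject_id=f"s{i}")
            for i in range(30)
        ]
        tls = [smooth_boundaries(s) for s in segs]
        for i, seg in enumerate(segs):
            res = align_subject(seg, tls, i, n_shuffles=50, seed=i)
            assert res.r_raw <= res.r_max + 1e-9


class TestAlignSubject:
    def _cohort(self, jitter, n=10, T=256, seed=5):
        from neurostates.simulate import _perturb_boundaries

        gen = np.random.default_rng(seed)
        shared = draw_boundaries(gen, T, 12)
        return [
            make_segmentation(
                _perturb_boundaries(gen, shared, T, jitter, 0.0),
                T=T, subject_id=f"s{i}",
            )
            for i in range(n)
        ]

    def test_adjusted_match_identity(self):
        segs = self._cohort(jitter=1)
        tls = [smooth_boundaries(s) for s in segs]
        res = align_subject(segs[0], tls, 0, n_shuffles=100, seed=0)
        assert res.adjusted_match == pytest.approx(
            (res.r_raw - res.null_mean) / res.r_max
        )
        assert res.null_mean == pytest.approx(res.null_samples.mean())

    def test_shared_boundaries_align_above_chance(self):
        segs = self._cohort(jitter=1)
        tls = [smooth_boundaries(s) for s in segs]
        matches = [
            align_subject(segs[i], tls, i, n_shuffles=200, seed=i).adjusted_match
            for i in range(len(segs))
        ]
        assert np.mean(matches) > 0.3

    def test_correlation_scale_invariance(self, rng):
        a, b = rng.random(50), rng.random(50)
        assert _pearson(3.7 * a, b) == pytest.approx(_pearson(a, b), abs=1e-12)
        assert _pearson(a, 0.2 * b) == pytest.approx(_pearson(a, b), abs=1e-12)


class TestBehavioralDensity:
    def test_synchronized_presses_fill_window(self):
        fs, T = 5.12, 1024  # 200 s
        logs = [
            PressLog(f"p{i}", [100.9], movie_duration_s=200.0) for i in range(5)
        ]
        density = behavioral_density(logs, T=T, sampling_rate_hz=fs)
        times = np.arange(T) / fs
        inside = np.abs(times - 100.0) <= 1.0
        assert np.all(density.values[inside] == 1.0)
        assert np.all(density.values[~inside] == 0.0)

    def test_no_presses_zero_density(self):
        logs = [PressLog("p1", [], movie_duration_s=10.0)]
        density = behavioral_density(logs, T=51, sampling_rate_hz=5.12)
        assert np.all(density.values == 0)

    def test_default_rt_correction(self):
        import inspect

        sig = inspect.signature(behavioral_density)
        assert sig.parameters["rt_correction_s"].default == 0.9
        assert sig.parameters["window_s"].default == 2.0

    def test_early_press_clipped_with_warning(self):
        logs = [PressLog("p1", [0.2], movie_duration_s=10.0)]
        with pytest.warns(RuntimeWarning, match="clipped"):
            density = behavioral_density(logs, T=51, sampling_rate_hz=5.12)
        assert density.values[0] == 1.0

    def test_group_filtering(self):
        logs = [
            PressLog("y1", [5.9], 20.0, group="younger"),
            PressLog("o1", [15.9], 20.0, group="older"),
        ]
        d_young = behavioral_density(logs, T=103, sampling_rate_hz=5.12, group="younger")
        times = np.arange(103) / 5.12
        assert d_young.values[np.argmin(np.abs(times - 5.0))] == 1.0
        assert d_young.values[np.argmin(np.abs(times - 15.0))] == 0.0


class TestAlignToBehavior:
    def test_self_alignment_near_maximum(self):
        T, fs = 512, 5.12
        gen = np.random.default_rng(8)
        bounds = draw_boundaries(gen, T, 12)
        seg = make_segmentation(bounds, T=T, fs=fs)
        # everyone presses 0.9 s after each of this subject's boundaries
        press_times = [float(b / fs + 0.9) for b in bounds]
        logs = [PressLog(f"p{i}", press_times, T / fs) for i in range(8)]
        density = behavioral_density(logs, T=T, sampling_rate_hz=fs)
        res = align_to_behavior(seg, density, n_shuffles=200, seed=0)
        assert res.adjusted_match > 0.5

    def test_unrelated_boundaries_near_zero_on_average(self):
        T, fs = 256, 5.12
        gen = np.random.default_rng(17)
        press_bounds = draw_boundaries(gen, T, 10)
        logs = [
            PressLog("p0", [float(b / fs + 0.9) for b in press_bounds], T / fs)
        ]
        density = behavioral_density(logs, T=T, sampling_rate_hz=fs)
        matches = []
        for i in range(40):
            seg = make_segmentation(draw_boundaries(gen, T, 10), T=T, fs=fs)
            matches.append(
                align_to_behavior(seg, density, n_shuffles=100, seed=i).adjusted_match
            )
        assert abs(np.mean(matches)) < 0.1
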