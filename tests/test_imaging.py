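"""Imaging pipeline: background subtraction, bleach correction, registration,
dF/F, event-triggered averages, mosaics."""

import numpy as np
import pytest

from neurorig.imaging import (ROI, AlignmentAdjustment, bleach_correct,
                              compose_mosaic, event_triggered_average,
                              ratiometric_dff_series, register_frames,
                              roi_dff_series, rolling_background_subtract)
from neurorig.rig import Transform3D
from neurorig.signals import Frame, FrameSeries, Trace

PX = 2e-6  # 2 um/px frame scale used throughout


def make_frames(stacks, dt=0.1, origin=(0.0, 0.0)):
    t = Transform3D.from_parts(offset=(origin[0], origin[1], 0),
                               scale=(PX, PX, 1))
    return FrameSeries([Frame(pixels=np.asarray(p, float), transform=t,
                              objective="5x", t_start=i * dt, exposure=dt / 2)
                        for i, p in enumerate(stacks)])


class TestBackgroundSubtraction:
    def test_matches_recursion_oracle(self):
        rng = np.random.default_rng(0)
        stacks = rng.normal(100, 5, size=(8, 4, 4))
        out = rolling_background_subtract(make_frames(stacks, dt=0.1),
                                          time_constant=0.5)
        alpha = 0.1 / 0.5
        bg = stacks[0].copy()
        expect = [np.zeros((4, 4))]
        for f in stacks[1:]:
            expect.append(f - bg)
            bg = (1 - alpha) * bg + alpha * f
        assert np.allclose(out.stack(), expect)

    def test_static_video_goes_to_zero(self):
        stacks = np.full((10, 4, 4), 50.0)
        out = rolling_background_subtract(make_frames(stacks), 0.3)
        assert np.allclose(out.stack(), 0.0)

    def test_transient_passes_through(self):
        stacks = np.full((10, 4, 4), 50.0)
        stacks[5, 1, 1] += 20.0  # one-frame flash
        out = rolling_background_subtract(make_frames(stacks), 1.0)
        assert out[5].pixels[1, 1] == pytest.approx(20.0, rel=0.05)

    def test_nonuniform_intervals_warn(self):
        frames = list(make_frames(np.zeros((4, 2, 2))))
        frames[3] = Frame(frames[3].pixels, frames[3].transform,
                          frames[3].objective, t_start=10.0,
                          exposure=frames[3].exposure)
        with pytest.warns(UserWarning, match="non-uniform"):
            rolling_background_subtract(FrameSeries(frames), 0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            rolling_background_subtract(make_frames(np.zeros((3, 2, 2))), 0.0)
        with pytest.raises(ValueError, match="2 frames"):
            rolling_background_subtract(make_frames(np.zeros((1, 2, 2))), 1.0)


class TestBleachCorrection:
    def test_flattens_pure_exponential(self):
        t = np.arange(500) / 10.0
        y = 80.0 * np.exp(-t / 20.0) + 20.0
        corrected, ok = bleach_correct(Trace(y, 10.0))
        assert ok
        assert np.ptp(corrected.samples) < 1e-6 * y[0]
        assert corrected.samples[0] == pytest.approx(y[0])

    def test_preserves_fractional_transient(self):
        t = np.arange(1000) / 10.0
        bleach = 100.0 * np.exp(-t / 30.0) + 50.0
        transient = np.zeros_like(t)
        m = (t >= 50) & (t < 52)
        transient[m] = 0.10  # 10% dF/F
        y = bleach * (1 + transient)
        corrected, ok = bleach_correct(Trace(y, 10.0))
        assert ok
        f0 = corrected.samples[0]
        dff = (corrected.samples.max() - f0) / f0
        # the transient slightly biases the bleach fit; 10% tolerance
        assert dff == pytest.approx(0.10, rel=0.1)

    def test_flat_series_unchanged(self):
        tr = Trace(np.full(100, 42.0), 10.0)
        corrected, ok = bleach_correct(tr)
        assert ok and np.allclose(corrected.samples, 42.0)

    def test_too_short(self):
        with pytest.raises(ValueError, match="10 samples"):
            bleach_correct(Trace(np.ones(5), 1.0))


class TestRegistration:
    def scene(self, shift=(0, 0)):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(32, 32))
        return np.roll(base, shift, axis=(0, 1))

    def test_known_integer_shifts_recovered(self):
        shifts_true = [(0, 0), (2, 1), (-3, 4), (5, -2)]
        frames = make_frames([self.scene((dy, dx)) for dx, dy in shifts_true])
        shifts, reg = register_frames(frames)
        assert shifts == shifts_true
        # registered frames match the reference in the unclipped interior
        ref = reg[0].pixels
        for f in reg[1:]:
            inner = (slice(6, 26), slice(6, 26))
            assert np.allclose(f.pixels[inner], ref[inner])

    def test_identical_frames_zero_shift(self):
        frames = make_frames([self.scene()] * 3)
        shifts, _ = register_frames(frames, reference="mean")
        assert shifts == [(0, 0)] * 3

    def test_flat_reference_warns(self):
        frames = make_frames(np.zeros((3, 8, 8)))
        with pytest.warns(UserWarning, match="flat"):
            shifts, _ = register_frames(frames)
        assert shifts == [(0, 0)] * 3

    def test_bad_reference(self):
        with pytest.raises(ValueError, match="first|mean"):
            register_frames(make_frames(np.zeros((2, 4, 4))), reference="last")


class TestRoiSeries:
    def test_dff_hand_case(self):
        """Baseline 100, peak 130: dF/F = 0.3 exactly."""
        stacks = np.full((6, 8, 8), 100.0)
        stacks[3] = 130.0
        frames = make_frames(stacks, dt=0.1)
        roi = ROI((2 * PX, 2 * PX, 4 * PX, 4 * PX))
        tr = roi_dff_series(frames, roi, baseline_window=(0.0, 0.3))
        assert np.allclose(tr.samples[[0, 1, 2]], 0.0)
        assert tr.samples[3] == pytest.approx(0.3)

    def test_dff_scale_invariance(self):
        rng = np.random.default_rng(1)
        stacks = 100 + rng.normal(0, 3, size=(10, 8, 8))
        roi = ROI((0, 0, 8 * PX, 8 * PX))
        a = roi_dff_series(make_frames(stacks), roi, (0.0, 0.5))
        b = roi_dff_series(make_frames(7.0 * stacks), roi, (0.0, 0.5))
        assert np.allclose(a.samples, b.samples)

    def test_ellipse_mask_subset_of_rectangle(self):
        f = make_frames(np.ones((1, 16, 16)))[0]
        rect = ROI((2 * PX, 2 * PX, 10 * PX, 10 * PX)).mask(f)
        ell = ROI((2 * PX, 2 * PX, 10 * PX, 10 * PX), shape="ellipse").mask(f)
        assert np.all(rect[ell]) and ell.sum() < rect.sum()

    def test_roi_outside_frame(self):
        frames = make_frames(np.ones((2, 4, 4)))
        roi = ROI((1.0, 1.0, 1e-6, 1e-6), label="far")
        with pytest.raises(ValueError, match="far"):
            roi_dff_series(frames, roi, (0.0, 0.1))

    def test_ratiometric_cancels_common_mode(self):
        rng = np.random.default_rng(2)
        common = 1 + 0.2 * rng.normal(size=10)  # shared illumination flicker
        num = np.array([np.full((8, 8), 100.0 * c) for c in common])
        den = np.array([np.full((8, 8), 50.0 * c) for c in common])
        num[6] *= 1.25  # genuine 25% signal in the numerator channel only
        roi = ROI((0, 0, 8 * PX, 8 * PX))
        tr = ratiometric_dff_series(make_frames(num), make_frames(den), roi,
                                    (0.0, 0.5))
        assert np.allclose(np.delete(tr.samples, 6), 0.0, atol=1e-12)
        assert tr.samples[6] == pytest.approx(0.25)


class TestEventTriggeredAverage:
    def test_exact_for_identical_events(self):
        rate = 1e3
        y = np.zeros(int(5 * rate))
        events = [1.0, 2.0, 3.5]
        for et in events:
            i = int(et * rate)
            y[i:i + 100] = np.exp(-np.arange(100) / 30)
        avg, n = event_triggered_average(Trace(y, rate), events, (0.05, 0.2))
        assert n == 3
        assert avg.t0 == -0.05
        assert np.allclose(avg.samples[:50], 0.0)
        assert avg.samples[50] == pytest.approx(1.0)

    def test_partial_windows_skipped(self):
        rate = 1e3
        tr = Trace(np.zeros(1000), rate)
        avg, n = event_triggered_average(tr, [0.01, 0.5, 0.99], (0.05, 0.05))
        assert n == 1
        with pytest.raises(ValueError, match="no events"):
            event_triggered_average(tr, [0.01], (0.05, 0.05))

    def test_noise_averages_down_as_sqrt_n(self):
        rate = 1e3
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1.0, int(200 * rate))
        events = list(np.arange(1.0, 199.0, 2.0))  # 99 events
        avg, n = event_triggered_average(Trace(y, rate), events, (0.1, 0.1))
        assert n == 99
        assert avg.samples.std() == pytest.approx(1.0 / np.sqrt(99), rel=0.25)


class TestMosaic:
    def tile(self, value, origin):
        t = Transform3D.from_parts(offset=(origin[0], origin[1], 0),
                                   scale=(PX, PX, 1))
        return Frame(pixels=np.full((10, 10), float(value)), transform=t,
                     objective="5x", t_start=0.0, exposure=0.01)

    def test_two_tile_placement(self):
        # tiles abutting in x: 10 px at 2 um/px each -> 20x10 px mosaic
        f0 = self.tile(1.0, (0.0, 0.0))
        f1 = self.tile(2.0, (10 * PX, 0.0))
        img, t = compose_mosaic([f0, f1], resolution=PX)
        assert img.shape == (10, 20)
        assert np.all(img[:, :10] == 1.0) and np.all(img[:, 10:] == 2.0)
        # mosaic transform maps pixel (0,0) near the global bounding-box corner
        assert np.allclose(t.map((0, 0, 0))[:2], (0.0, 0.0), atol=PX)

    def test_overlap_policies(self):
        f0 = self.tile(10.0, (0.0, 0.0))
        f1 = self.tile(30.0, (5 * PX, 0.0))  # half-overlapping
        last, _ = compose_mosaic([f0, f1], resolution=PX, overlap="last")
        mean, _ = compose_mosaic([f0, f1], resolution=PX, overlap="mean")
        assert np.all(last[:, 5:10] == 30.0)
        assert np.all(mean[:, 5:10] == 20.0)

    def test_adjustment_is_metadata_only(self):
        f0 = self.tile(1.0, (0.0, 0.0))
        f1 = self.tile(2.0, (9 * PX, 0.0))  # misplaced by 1 px
        before = f1.transform.matrix.copy()
        adj = AlignmentAdjustment(
            Transform3D.from_parts(offset=(PX, 0, 0)), applies_to={1})
        img_adj, _ = compose_mosaic([f0, f1], adjustments=[adj], resolution=PX)
        img_true, _ = compose_mosaic([f0, self.tile(2.0, (10 * PX, 0.0))],
                                     resolution=PX)
        assert np.array_equal(img_adj, img_true)
        assert np.array_equal(f1.transform.matrix, before)  # untouched

    def test_round_trip_feature_position(self):
        """A point feature lands within 0.5 px of its true global position."""
        px = np.zeros((10, 10))
        px[3, 7] = 1.0
        t = Transform3D.from_parts(offset=(11 * PX, -4 * PX, 0),
                                   scale=(PX, PX, 1))
        f = Frame(px, t, "5x", 0.0, 0.01)
        true_pos = t.map((7, 3, 0))[:2]
        img, mt = compose_mosaic([f], resolution=PX)
        r, c = np.unravel_index(np.argmax(img), img.shape)
        got = mt.map((c, r, 0))[:2]
        assert np.hypot(*(got - true_pos)) <= 0.5 * PX

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            compose_mosaic([], resolution=PX)
        with pytest.raises(ValueError, match="resolution"):
            compose_mosaic([self.tile(1, (0, 0))], resolution=0)
        with pytest.raises(ValueError, match="policy"):
            compose_mosaic([self.tile(1, (0, 0))], resolution=PX,
                           overlap="max")
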