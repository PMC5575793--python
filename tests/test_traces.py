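import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from wormtouch import (
    RoiSpec,
    SceneConfig,
    background_intensity,
    extract_trial,
    fluor_trace,
    normalize,
    ratio_trace,
    render_scene,
    roi_intensity,
)
from wormtouch.tracking import Trajectory
from wormtouch.traces import _disc_values


def static_traj(n, pos):
    return Trajectory(
        positions=np.tile(pos, (n, 1)), locked=np.ones(n, bool)
    )


DISC_SPEC = RoiSpec(radius=10, top_k=100, background_center=(45.0, 45.0))


class TestRoiIntensity:
    def test_constant_disc(self):
        frame = np.full((60, 60), 5.0)
        assert roi_intensity(frame, (20, 20), DISC_SPEC) == 5.0

    def test_top_100_of_mixed_disc(self):
        """100 pixels at 10 inside the disc, rest 0 -> mean of top-100 is 10;
        only 50 at 10 -> mean is 5."""
        frame = np.zeros((60, 60))
        # fill disc pixels in scan order
        vals, full = _disc_values(frame, (20, 20), 10.0)
        assert full == 317  # pixels with center within 10 px
        coords = [
            (20 + dr, 20 + dc)
            for dr in range(-10, 11)
            for dc in range(-10, 11)
            if dr * dr + dc * dc <= 100
        ]
        for r, c in coords[:100]:
            frame[r, c] = 10.0
        assert roi_intensity(frame, (20, 20), DISC_SPEC) == 10.0
        frame[:] = 0.0
        for r, c in coords[:50]:
            frame[r, c] = 10.0
        assert roi_intensity(frame, (20, 20), DISC_SPEC) == 5.0

    def test_clipped_disc_uses_available_pixels(self):
        frame = np.full((60, 60), 3.0)
        value, count = roi_intensity(frame, (0, 0), DISC_SPEC, with_count=True)
        assert value == 3.0
        assert count < 317

    def test_disc_fully_outside_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            roi_intensity(np.zeros((60, 60)), (200, 200), DISC_SPEC)

    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_any_pixel(self, seed):
        """Raising any pixel's value cannot decrease the statistic."""
        spec = RoiSpec(radius=5, top_k=20, background_center=(25.0, 25.0))
        center = (15, 15)
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 100, (30, 30))
        base = roi_intensity(frame, center, spec)
        r, c = rng.integers(0, 30, size=2)
        bumped = frame.copy()
        bumped[r, c] += rng.uniform(0, 200)
        assert roi_intensity(bumped, center, spec) >= base - 1e-12

    def test_permutation_of_disc_values_irrelevant(self):
        """The statistic depends on the multiset of in-disc values, not on
        their arrangement."""
        spec = RoiSpec(radius=5, top_k=20, background_center=(25.0, 25.0))
        rng = np.random.default_rng(10)
        frame = rng.uniform(0, 100, (30, 30))
        base = roi_intensity(frame, (15, 15), spec)
        coords = [
            (15 + dr, 15 + dc)
            for dr in range(-5, 6)
            for dc in range(-5, 6)
            if dr * dr + dc * dc <= 25
        ]
        vals = [frame[rc] for rc in coords]
        shuffled = frame.copy()
        for rc, v in zip(coords, rng.permutation(vals)):
            shuffled[rc] = v
        assert roi_intensity(shuffled, (15, 15), spec) == pytest.approx(base)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        frame = rng.uniform(0, 50, (80, 80))
        spec = RoiSpec(radius=7, top_k=30, background_center=(70.0, 70.0))
        a = roi_intensity(frame, (30, 30), spec)
        shifted = np.roll(np.roll(frame, 5, axis=0), -3, axis=1)
        b = roi_intensity(shifted, (35, 27), spec)
        assert a == b


class TestBackgroundIntensity:
    def test_uniform(self):
        frame = np.full((60, 60), 50.0)
        assert background_intensity(frame, DISC_SPEC) == 50.0

    def test_mean_of_two_halves(self):
        frame = np.full((60, 60), 40.0)
        frame[:, 45:] = 60.0
        # background disc centered on the boundary: equal pixel counts on
        # both sides of column 45 within the disc
        spec = RoiSpec(radius=10, top_k=100, background_center=(30.0, 44.5))
        vals, _ = _disc_values(frame, spec.background_center, spec.background_radius)
        assert background_intensity(frame, spec) == pytest.approx(vals.mean())
        assert background_intensity(frame, spec) == pytest.approx(50.0, abs=1.0)

    def test_overlap_with_signal_roi_rejected(self):
        frame = np.zeros((60, 60))
        with pytest.raises(ValueError, match="overlap"):
            background_intensity(frame, DISC_SPEC, signal_center=(40, 40))

    def test_recovers_scaled_background_on_rendered_scene(
        self, model, pulse_protocol
    ):
        """Zero-noise scene: the background ROI reads background_level times
        the per-frame motion gain."""
        n = pulse_protocol.n_frames(0.1)
        rng = np.random.default_rng(2)
        gains = np.exp(rng.normal(0, 0.2, n))
        cfg = SceneConfig(
            n_frames=n,
            neuron_path=np.tile([48.0, 48.0], (n, 1)),
            motion_gain_series=gains,
            noise_sd=0.0,
            rng_seed=2,
        )
        green, _, _ = render_scene(cfg, pulse_protocol, model)
        spec = RoiSpec(background_center=(12.0, 12.0))
        got = np.array(
            [background_intensity(green.frames[t], spec) for t in range(n)]
        )
        np.testing.assert_allclose(got, cfg.background_level * gains, rtol=1e-9)


def _two_level_stack(n, roi_value, back_value, roi_center=(20, 20), bg_center=(45, 45)):
    frame = np.full((60, 60), roi_value)
    rr = np.arange(60)[:, None] - bg_center[0]
    cc = np.arange(60)[None, :] - bg_center[1]
    frame[rr * rr + cc * cc <= 100] = back_value
    return np.stack([frame] * n)


class TestRatioAndFluor:
    def test_stated_ratio_arithmetic(self):
        """I_G_roi=200, I_G_back=50, I_R_roi=100, I_R_back=50 -> R = 3."""
        n = 6
        green = _two_level_stack(n, 200.0, 50.0)
        red = _two_level_stack(n, 100.0, 50.0)
        trace = ratio_trace(static_traj(n, (20, 20)), green, red, DISC_SPEC)
        np.testing.assert_allclose(trace.R_or_F, 3.0)
        assert trace.valid.all()

    def test_identical_channels_give_unit_ratio(self):
        n = 5
        stack = _two_level_stack(n, 200.0, 50.0)
        trace = ratio_trace(static_traj(n, (20, 20)), stack, stack, DISC_SPEC)
        np.testing.assert_allclose(trace.R_or_F, 1.0)

    def test_nonpositive_denominator_flagged_invalid(self):
        n = 4
        green = _two_level_stack(n, 200.0, 50.0)
        red = _two_level_stack(n, 40.0, 50.0)  # ROI below background
        trace = ratio_trace(static_traj(n, (20, 20)), green, red, DISC_SPEC)
        assert not trace.valid.any()

    def test_mismatched_lengths_rejected(self):
        green = _two_level_stack(4, 200.0, 50.0)
        red = _two_level_stack(5, 100.0, 50.0)
        with pytest.raises(ValueError, match="equal length"):
            ratio_trace(static_traj(4, (20, 20)), green, red, DISC_SPEC)

    def test_quiet_scene_ratio_constant_under_motion_gain(
        self, model, pulse_protocol
    ):
        """No calcium transient + shared gain artifact -> flat ratio."""
        n = pulse_protocol.n_frames(0.1)
        rng = np.random.default_rng(3)
        cfg = SceneConfig(
            n_frames=n,
            neuron_path=np.tile([48.0, 48.0], (n, 1)),
            motion_gain_series=np.exp(rng.normal(0, 0.3, n)),
            noise_sd=0.0,
            bleach_rate=0.0,
            rng_seed=3,
        )
        green, red, _ = render_scene(
            cfg, pulse_protocol, model, true_trace=np.zeros(n)
        )
        spec = RoiSpec(background_center=(12.0, 12.0))
        trace = ratio_trace(static_traj(n, (48, 48)), green, red, spec)
        np.testing.assert_allclose(trace.R_or_F, trace.R_or_F[0], rtol=1e-10)

    def test_fluor_arithmetic(self):
        n = 3
        green = _two_level_stack(n, 120.0, 20.0)
        trace = fluor_trace(static_traj(n, (20, 20)), green, DISC_SPEC)
        np.testing.assert_allclose(trace.R_or_F, 100.0)

    def test_fluor_zero_on_uniform_frame(self):
        n = 3
        green = np.full((n, 60, 60), 37.0)
        trace = fluor_trace(static_traj(n, (20, 20)), green, DISC_SPEC)
        np.testing.assert_allclose(trace.R_or_F, 0.0)


class TestNormalize:
    def test_constant_trace(self, make_trace, pulse_protocol):
        tr = make_trace(np.full(300, 2.0), pulse_protocol)
        tr.dRR = None
        tr.R_or_F = np.full(300, 2.0)
        out = normalize(tr)
        assert out.baseline == 2.0
        np.testing.assert_allclose(out.dRR, 0.0)

    def test_peak_normalization(self, make_trace, pulse_protocol):
        R = np.ones(300)
        R[150] = 2.5
        tr = make_trace(R, pulse_protocol)
        tr.dRR = None
        out = normalize(tr)
        assert out.baseline == 1.0
        assert out.dRR[150] == pytest.approx(1.5)

    def test_prestimulus_mean_is_zero(self, make_trace, pulse_protocol):
        rng = np.random.default_rng(8)
        tr = make_trace(1.0 + rng.normal(0, 0.1, 300), pulse_protocol)
        tr.dRR = None
        out = normalize(tr)
        pre = out.time < pulse_protocol.onsets[0]
        assert abs(out.dRR[pre].mean()) < 1e-12

    def test_requires_prestimulus_frames(self, make_trace):
        from wormtouch import StimulusProtocol

        proto = StimulusProtocol(
            onsets=[0.2], durations=[1], pressures=[40],
            baseline_window=0.2, record_duration=30,
        )
        tr = make_trace(np.ones(300), proto)
        tr.dRR = None
        with pytest.raises(ValueError, match="pre-stimulus"):
            normalize(tr)

    def test_negative_ratiometric_baseline_rejected(
        self, make_trace, pulse_protocol
    ):
        tr = make_trace(np.full(300, -1.0), pulse_protocol)
        tr.dRR = None
        tr.mode = "ratiometric"
        with pytest.raises(ValueError, match="positive"):
            normalize(tr)


class TestGainInvariance:
    def test_ratiometric_dRR_invariant_under_per_frame_gain(
        self, model, pulse_protocol
    ):
        """Multiplying both channels by an arbitrary positive per-frame gain
        leaves the normalized ratio trace unchanged to machine precision."""
        n = pulse_protocol.n_frames(0.1)
        rng = np.random.default_rng(6)
        base = dict(
            n_frames=n,
            neuron_path=np.tile([48.0, 48.0], (n, 1)),
            noise_sd=0.0,
            rng_seed=6,
        )
        gains = np.exp(rng.normal(0, 0.5, n))
        g1, r1, _ = render_scene(
            SceneConfig(motion_gain_series=gains, **base),
            pulse_protocol, model, force_respond=True,
        )
        g2, r2, _ = render_scene(
            SceneConfig(motion_gain_series=np.ones(n), **base),
            pulse_protocol, model, force_respond=True,
        )
        t1, _ = extract_trial(g1, r1, pulse_protocol)
        t2, _ = extract_trial(g2, r2, pulse_protocol)
        np.testing.assert_allclose(t1.dRR, t2.dRR, atol=1e-10)

    def test_end_to_end_recovery_of_true_trace(self, model, pulse_protocol):
        """Rendered noisy scene -> tracked, extracted, normalized dR/R0
        reproduces the ground-truth trace (RMSE well under 0.05)."""
        from wormtouch import simulate_trial

        green, red, truth, _ = simulate_trial(pulse_protocol, model, seed=17,
                                              force_respond=True)
        trace, _ = extract_trial(green, red, pulse_protocol)
        ok = trace.valid
        rmse = np.sqrt(np.mean((trace.dRR[ok] - truth.true_trace[ok]) ** 2))
        assert rmse < 0.05
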