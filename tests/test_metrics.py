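import numpy as np
import pytest

from wormtouch import (
    ResponseModel,
    StimulusProtocol,
    classify_responder,
    delay_time,
    ensemble_mean_sem,
    habituation_series,
    half_life,
    peak_response,
    response_fraction,
    summarize_grid,
    trial_metrics,
)
from wormtouch.evaluation import model_for_probability
from wormtouch.synthetic import build_true_trace, simulate_trace


class TestPeakResponse:
    def test_flat_trace(self, make_trace, pulse_protocol):
        peak, t_peak = peak_response(make_trace(np.zeros(300), pulse_protocol))
        assert peak == 0.0
        assert t_peak == pulse_protocol.onsets[0]

    def test_triangular_pulse(self, make_trace, pulse_protocol):
        t = np.arange(300) * 0.1
        dRR = np.interp(t, [11, 13, 20], [0, 1.2, 0])
        peak, t_peak = peak_response(make_trace(dRR, pulse_protocol))
        assert peak == pytest.approx(1.2)
        assert t_peak == pytest.approx(13.0)

    def test_tie_broken_by_earliest_time(self, make_trace, pulse_protocol):
        dRR = np.zeros(300)
        dRR[150] = dRR[200] = 1.0
        _, t_peak = peak_response(make_trace(dRR, pulse_protocol))
        assert t_peak == pytest.approx(15.0)

    def test_windows_are_local(self, model):
        """Adding a later stimulus does not change an earlier window's peak."""
        t = np.arange(0, 60, 0.1)
        rng = np.random.default_rng(0)
        p2 = StimulusProtocol(onsets=[10, 25], durations=[1, 1],
                              pressures=[40, 40], record_duration=60)
        p3 = StimulusProtocol(onsets=[10, 25, 40], durations=[1, 1, 1],
                              pressures=[40, 40, 40], record_duration=60)
        tr2, _, _ = build_true_trace(t, p2, model, rng, force_respond=True,
                                     amplitude_multipliers=[1, 1])
        tr3, _, _ = build_true_trace(t, p3, model, rng, force_respond=True,
                                     amplitude_multipliers=[1, 1, 1])
        from wormtouch import CalciumTrace

        def as_trace(arr, proto):
            return CalciumTrace(
                time=t, I_G_roi=arr, I_G_back=np.zeros_like(arr), R_or_F=arr,
                valid=np.ones_like(arr, bool), mode="single_channel",
                protocol=proto, dRR=arr,
            )

        assert peak_response(as_trace(tr2, p2), 0) == peak_response(
            as_trace(tr3, p3), 0
        )

    def test_mean_peak_increases_with_pressure(self, model):
        """Ensembles at a higher pressure have a higher mean peak."""
        peaks = {}
        for p in (35.0, 45.0):
            proto = StimulusProtocol.single_pulse(pressure=p, record_duration=30)
            vals = []
            for s in range(30):
                _, noisy, _ = simulate_trace(proto, model, seed=1000 + s)
                from wormtouch import CalciumTrace

                tr = CalciumTrace(
                    time=np.arange(len(noisy)) * 0.1, I_G_roi=noisy,
                    I_G_back=np.zeros_like(noisy), R_or_F=noisy,
                    valid=np.ones_like(noisy, bool), mode="single_channel",
                    protocol=proto, dRR=noisy,
                )
                vals.append(peak_response(tr)[0])
            peaks[p] = np.mean(vals)
        assert peaks[45.0] >= peaks[35.0]


class TestDelayTime:
    def test_subtraction(self, pulse_protocol):
        d, flagged = delay_time(12.5, pulse_protocol, 0)  # stimulus 10-11 s
        assert d == pytest.approx(1.5)
        assert not flagged

    def test_zero_at_stimulus_end(self, pulse_protocol):
        d, flagged = delay_time(11.0, pulse_protocol, 0)
        assert d == 0.0 and not flagged

    def test_negative_delay_reported_and_flagged(self, pulse_protocol):
        d, flagged = delay_time(10.6, pulse_protocol, 0)
        assert d == pytest.approx(-0.4)
        assert flagged


class TestHalfLife:
    def test_sampled_exponential_matches_closed_form(self, make_trace):
        """tau = 2 s at 10 Hz: interpolated half-life within 0.01 s of
        2 ln 2."""
        t = np.arange(0, 40, 0.1)
        dRR = np.where(t >= 10, np.exp(-(t - 10) / 2.0), 0.0)
        hl = half_life(make_trace(dRR), t_peak=10.0, max_dRR=1.0)
        assert hl == pytest.approx(2 * np.log(2), abs=0.01)

    @pytest.mark.parametrize("dt", [0.2, 0.1, 0.01])
    def test_converges_with_sampling_rate(self, make_trace, dt):
        t = np.arange(0, 40, dt)
        dRR = np.where(t >= 10, np.exp(-(t - 10) / 2.0), 0.0)
        hl = half_life(make_trace(dRR, frame_interval=dt), 10.0, 1.0)
        assert hl == pytest.approx(2 * np.log(2), abs=2 * dt)

    def test_clamped_trace_has_no_half_life(self, make_trace):
        dRR = np.ones(200)
        assert half_life(make_trace(dRR), t_peak=5.0, max_dRR=1.0) is None

    def test_nonpositive_peak_undefined(self, make_trace):
        assert half_life(make_trace(np.zeros(100)), 5.0, 0.0) is None


class TestResponderClassification:
    @pytest.mark.parametrize(
        "peak,expected", [(0.5, False), (0.51, True), (0.0, False)]
    )
    def test_threshold_is_strict(self, peak, expected):
        assert classify_responder(peak) is expected

    def test_fraction_counts_strict_exceedances(self):
        assert response_fraction([0.4, 0.6, 1.2, 0.2]) == 0.5
        assert response_fraction([0.0, 0.0, 0.0]) == 0.0

    def test_fraction_of_empty_list_rejected(self):
        with pytest.raises(ValueError):
            response_fraction([])

    def test_fraction_order_and_duplication(self):
        peaks = [0.1, 0.7, 0.9, 0.3, 0.55]
        f = response_fraction(peaks)
        assert response_fraction(peaks[::-1]) == f
        assert response_fraction(peaks * 3) == pytest.approx(f)

    def test_consistent_with_classifier(self):
        rng = np.random.default_rng(0)
        peaks = rng.uniform(0, 1.5, 50)
        frac = response_fraction(peaks)
        assert frac == sum(classify_responder(p) for p in peaks) / 50

    def test_bernoulli_ensemble_fraction_near_probability(self):
        """200 trials with responder probability 0.9: measured fraction lands
        in the binomial 95% interval."""
        model = model_for_probability(0.9, 40.0, ResponseModel())
        proto = StimulusProtocol.single_pulse(record_duration=30)
        peaks = []
        from wormtouch import CalciumTrace

        for s in range(200):
            _, noisy, _ = simulate_trace(proto, model, seed=5000 + s)
            tr = CalciumTrace(
                time=np.arange(len(noisy)) * 0.1, I_G_roi=noisy,
                I_G_back=np.zeros_like(noisy), R_or_F=noisy,
                valid=np.ones_like(noisy, bool), mode="single_channel",
                protocol=proto, dRR=noisy,
            )
            peaks.append(peak_response(tr)[0])
        half_width = 1.96 * np.sqrt(0.9 * 0.1 / 200)
        assert abs(response_fraction(peaks) - 0.9) <= half_width


class TestGridSummary:
    def test_single_trial_cell(self):
        s = summarize_grid([(45.0, 1.0, 1.0)])
        row = s.table.iloc[0]
        assert (row["mean_peak"], row["response_fraction"], row["n"]) == (1.0, 1.0, 1)

    def test_two_trials_same_cell(self):
        s = summarize_grid([(45.0, 1.0, 0.4), (45.0, 1.0, 0.8)])
        row = s.table.iloc[0]
        assert row["mean_peak"] == pytest.approx(0.6)
        assert row["response_fraction"] == 0.5
        assert row["n"] == 2

    def test_untested_cells_absent(self):
        s = summarize_grid([(45.0, 1.0, 1.0), (25.0, 2.0, 0.2)])
        assert len(s.table) == 2
        mat = s.matrix("mean_peak")
        assert np.isnan(mat.loc[1.0, 25.0])  # never tested


class TestHabituation:
    def _trace(self, multipliers, model, isi=10.0, seed=0):
        proto = StimulusProtocol.pulse_train(
            n_stimuli=len(multipliers), isi=isi, pressure=40, duration=1
        )
        from wormtouch import CalciumTrace

        # force all stimuli to respond for a deterministic sequence
        t = np.arange(proto.n_frames(0.1)) * 0.1
        rng = np.random.default_rng(seed)
        trace, _, _ = build_true_trace(
            t, proto, model, rng, amplitude_multipliers=multipliers,
            force_respond=True,
        )
        return CalciumTrace(
            time=t, I_G_roi=trace, I_G_back=np.zeros_like(trace), R_or_F=trace,
            valid=np.ones_like(trace, bool), mode="single_channel",
            protocol=proto, dRR=trace,
        )

    def test_facilitation_then_depression_ordering(self, model):
        """Planted short-ISI multipliers (1.0, 1.3, 0.8, 0.5): recovered
        peaks keep the 2nd > 1st > 3rd > 4th ordering."""
        tr = self._trace([1.0, 1.3, 0.8, 0.5], model)
        p = habituation_series(tr).per_stimulus_peaks
        assert p[1] > p[0] > p[2] > p[3]

    def test_long_isi_strictly_decreasing(self, model):
        tr = self._trace([1.0, 0.7, 0.5, 0.35], model, isi=40.0)
        p = habituation_series(tr).per_stimulus_peaks
        assert np.all(np.diff(p) < 0)

    def test_identical_responses_give_constant_series(self, model):
        slow = model.with_(tau_decay=1.0)  # negligible carry-over at ISI 10
        tr = self._trace([1.0, 1.0, 1.0], slow)
        p = habituation_series(tr).per_stimulus_peaks
        np.testing.assert_allclose(p, p[0], rtol=1e-3)

    def test_requires_two_stimuli(self, make_trace, pulse_protocol):
        with pytest.raises(ValueError, match="at least 2"):
            habituation_series(make_trace(np.zeros(300), pulse_protocol))


class TestTrialMetricsAndEnsemble:
    def test_full_metric_set_on_kernel_trace(self, model, make_trace):
        proto = StimulusProtocol.single_pulse(record_duration=40)
        t = np.arange(0, 40, 0.1)
        rng = np.random.default_rng(1)
        trace, _, amps = build_true_trace(t, proto, model, rng, force_respond=True)
        m = trial_metrics(make_trace(trace, proto))
        assert m.max_dRR == pytest.approx(amps[0], rel=1e-3)
        # kernel peaks tau_rise after stimulus end
        assert m.delay_time == pytest.approx(model.tau_rise, abs=0.1)
        assert m.half_life == pytest.approx(model.tau_decay * np.log(2), abs=0.1)
        assert m.responder

    def test_ensemble_mean_sem_shapes(self, make_trace, pulse_protocol):
        traces = [
            make_trace(np.full(300, float(i)), pulse_protocol) for i in range(3)
        ]
        df = ensemble_mean_sem(traces)
        np.testing.assert_allclose(df["mean_dRR"], 1.0)
        np.testing.assert_allclose(df["n"], 3)
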