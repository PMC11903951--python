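"""Timing validation: edges, period statistics, drift fitting, throughput."""

import numpy as np
import pytest

from corestream import (
    BASE_CLOCK_HZ,
    ChannelConfig,
    DeviceEmulator,
    EmulatorConfig,
    Mode,
    compensate_timestamps,
    detect_rising_edges,
    drift_series,
    effective_sampling_period,
    fit_drift,
    fit_drift_least_squares,
    period_stats,
    quantization_drift_slope,
    square,
    throughput_feasible,
)
from corestream.errors import AlignmentError, ConfigError, InsufficientDataError
from corestream.timing import DriftModel

from conftest import config_for

AI1 = ChannelConfig(internal=("AI1",))


def square_trace(freq_hz, fs_hz, duration_s, low=0.0, high=1.0):
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    return np.where(np.mod(t * freq_hz, 1.0) < 0.5, low, high)


class TestDetectRisingEdges:
    def test_ideal_square_ten_edges_per_second(self):
        edges = detect_rising_edges(square_trace(10, 1000, 1.0), 1000)
        assert len(edges) == 10
        assert np.allclose(np.diff(edges), 0.1)

    def test_flat_signal_yields_no_edges(self):
        assert detect_rising_edges(np.full(100, 7.0), 1000).size == 0

    def test_interpolation_is_subsample(self):
        # ramp crossing: threshold crossing position is interpolated
        s = np.array([0.0, 0.0, 0.25, 0.75, 1.0, 1.0])
        (edge,) = detect_rising_edges(s, 1.0)
        assert 2.0 < edge < 3.0

    def test_hysteresis_rejects_chatter_at_threshold(self):
        # noise riding on the high level never re-arms the detector
        s = np.array([0.0, 1.0, 0.45, 1.0, 0.45, 1.0, 0.0, 1.0])
        edges = detect_rising_edges(s, 1.0, threshold=0.5, hysteresis=0.1)
        assert len(edges) == 2  # only the two true low-to-high transitions

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_rising_edges([1.0], 100)


class TestPeriodStats:
    def test_perfectly_regular_edges(self):
        stats = period_stats([0.0, 0.1, 0.2, 0.3], 100.0)
        assert stats.mean_ms == pytest.approx(100.0)
        assert stats.median_ms == pytest.approx(100.0)
        assert stats.std_ms == pytest.approx(0.0, abs=1e-9)
        assert stats.max_deviation_ms == pytest.approx(0.0, abs=1e-9)
        assert stats.n_cycles == 4

    def test_hand_computed_statistics(self):
        # periods 99, 100, 101 ms against a 100 ms nominal
        edges = [0.0, 0.099, 0.199, 0.300]
        stats = period_stats(edges, 100.0)
        assert stats.mean_ms == pytest.approx(100.0)
        assert stats.median_ms == pytest.approx(100.0)
        assert stats.std_ms == pytest.approx(np.std([99.0, 100.0, 101.0]))
        assert stats.max_deviation_ms == pytest.approx(1.0)
        assert stats.min_deviation_ms == pytest.approx(-1.0)

    def test_single_edge_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            period_stats([0.5], 100.0)

    def test_divisor_rate_emulated_stream_centred_on_nominal(self):
        """At an exact-divisor rate the emulated square has zero period spread."""
        emu = DeviceEmulator(
            EmulatorConfig(channels=AI1, waveforms={"AI1": square(10, 0, 4095)})
        )
        emu.mode = Mode.SIMULATED
        _t, traces = emu.waveform_trace(duration_s=60.0)
        edges = detect_rising_edges(traces["AI1"], 1000)
        stats = period_stats(edges, 100.0)
        assert stats.n_cycles == 600
        assert stats.mean_ms == pytest.approx(100.0, abs=1e-9)
        assert stats.median_ms == pytest.approx(100.0, abs=1e-9)
        assert stats.std_ms == pytest.approx(0.0, abs=1e-9)


class TestDriftSeries:
    def test_identical_sequences_give_zero(self):
        edges = np.arange(10) * 0.1
        assert np.allclose(drift_series(edges, edges), 0.0)

    def test_uniform_shift_gives_constant(self):
        ref = np.arange(10) * 0.1
        assert np.allclose(drift_series(ref + 1e-3, ref), 1.0)

    def test_sign_convention_device_behind_is_negative(self):
        ref = np.arange(10) * 0.1
        drift = drift_series(ref - 5e-4, ref)
        assert np.all(drift < 0)

    def test_empty_sequences_rejected(self):
        with pytest.raises(AlignmentError):
            drift_series([], [0.1])


class TestDriftModelFit:
    def test_linear_formula(self):
        model = DriftModel(min_drift_ms=-2.4, duration_s=240.0)
        assert model.slope_ms_per_s == pytest.approx(-0.01)
        assert model.f(100.0) == pytest.approx(-1.0)
        assert model.compensation_per_second_ms == pytest.approx(0.01)

    def test_all_zero_drift_gives_zero_model(self):
        model = fit_drift(np.zeros(100), 240.0)
        assert model.slope_ms_per_s == 0.0
        assert np.all(model.f(np.linspace(0, 240, 5)) == 0.0)

    def test_min_based_fit_recovers_seeded_noisy_slope(self):
        rng = np.random.default_rng(3)
        slope = -0.01  # ms/s
        t = np.arange(2400) * 0.1
        drift = slope * t + rng.normal(0.0, 0.05, t.size)
        model = fit_drift(drift, 240.0)
        assert model.slope_ms_per_s == pytest.approx(slope, rel=0.10)

    def test_least_squares_fit_recovers_seeded_noisy_slope(self):
        rng = np.random.default_rng(4)
        slope = -0.0125
        t = np.arange(2400) * 0.1
        drift = slope * t + rng.normal(0.0, 0.05, t.size)
        model = fit_drift_least_squares(drift, t, 240.0)
        assert model.slope_ms_per_s == pytest.approx(slope, rel=0.02)


class TestCompensation:
    def test_zero_slope_is_identity(self):
        t = np.linspace(0, 240, 100)
        model = DriftModel(min_drift_ms=0.0, duration_s=240.0)
        assert np.array_equal(compensate_timestamps(t, model), t)

    def test_arithmetic(self):
        model = DriftModel(min_drift_ms=-2.4, duration_s=240.0)
        assert compensate_timestamps(np.array([100.0]), model)[0] == pytest.approx(
            100.001
        )

    def test_recompensation_after_refit_is_near_identity(self):
        """Compensate, re-fit the residual: the second model is ~null."""
        sr = 3000
        eps = effective_sampling_period(sr) - 1 / sr
        n = 240 * sr
        true = np.arange(n) * (1 / sr + eps)
        reconstructed = np.arange(n) / sr
        model = fit_drift(drift_series(reconstructed, true), 240.0)
        corrected = compensate_timestamps(reconstructed, model)
        residual_model = fit_drift_least_squares(
            drift_series(corrected, true), corrected, 240.0
        )
        assert abs(residual_model.slope_ms_per_s) < 0.1 * abs(model.slope_ms_per_s)
        recompensated = compensate_timestamps(corrected, residual_model)
        assert np.max(np.abs(recompensated - corrected)) < (1 / sr)


class TestQuantizedStreamDrift:
    """Simulation and closed-form analysis must agree on the drift slope."""

    def test_divisor_rate_has_zero_drift(self):
        assert quantization_drift_slope(1000) == 0.0
        assert quantization_drift_slope(8000) == 0.0

    def test_closed_form_slope_value(self):
        # SR=3000: 26667 ticks -> slope -(3000*26667/80e6 - 1) * 1000 ms/s
        expected = -(3000 * 26667 / BASE_CLOCK_HZ - 1) * 1000
        assert quantization_drift_slope(3000) == pytest.approx(expected)

    def test_emulated_stream_recovers_closed_form_slope(self):
        sr = 3000
        emu = DeviceEmulator(
            EmulatorConfig(
                sampling_rate_hz=sr,
                channels=AI1,
                waveforms={"AI1": square(10, 0, 4095)},
            )
        )
        emu.mode = Mode.SIMULATED
        _t, traces = emu.waveform_trace(duration_s=240.0)
        device_edges = detect_rising_edges(traces["AI1"], sr)  # n/SR axis
        reference_edges = (np.arange(device_edges.size) + 0.5) / 10.0
        drift = drift_series(device_edges, reference_edges)
        model = fit_drift_least_squares(drift, device_edges, 240.0)
        assert model.slope_ms_per_s == pytest.approx(
            quantization_drift_slope(sr), rel=0.05
        )

    def test_sawtooth_residual_bounded_by_one_period(self):
        sr = 3000
        emu = DeviceEmulator(
            EmulatorConfig(
                sampling_rate_hz=sr,
                channels=AI1,
                waveforms={"AI1": square(10, 0, 4095)},
            )
        )
        emu.mode = Mode.SIMULATED
        _t, traces = emu.waveform_trace(duration_s=120.0)
        device_edges = detect_rising_edges(traces["AI1"], sr)
        reference_edges = (np.arange(device_edges.size) + 0.5) / 10.0
        drift = drift_series(device_edges, reference_edges)
        # remove the known closed-form trend; the remainder is the
        # timestamp-reconstruction sawtooth
        residual = drift - quantization_drift_slope(sr) * device_edges
        assert np.ptp(residual) <= 1000.0 / sr + 1e-9


class TestThroughput:
    def test_single_internal_channel_budget(self):
        result = throughput_feasible(config_for(1, 0), 10000, 40000)
        assert result.feasible and result.max_sr_hz == 10000

    def test_all_channels_lower_ceiling(self):
        result = throughput_feasible(config_for(6, 2), 10000, 40000)
        assert not result.feasible
        assert result.max_sr_hz == 40000 // 18

    def test_more_channels_never_raise_max_rate(self):
        capacity = 50000
        prev = None
        for ni in range(1, 7):
            result = throughput_feasible(config_for(ni, 0), 1000, capacity)
            if prev is not None:
                assert result.max_sr_hz <= prev
            prev = result.max_sr_hz

    def test_divisor_friendly_restriction(self):
        result = throughput_feasible(
            config_for(1, 0), 1000, 4 * 2223, divisor_friendly=True
        )
        # floor gives 2223; largest divisor of 80 MHz at or below it is 2000
        assert result.max_sr_hz == 2000

    def test_empty_config_propagates_configuration_error(self):
        with pytest.raises(ConfigError):
            throughput_feasible(ChannelConfig(), 1000, 1000)

    def test_capacity_must_be_positive(self):
        with pytest.raises(ValueError):
            throughput_feasible(config_for(1, 0), 1000, 0)
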