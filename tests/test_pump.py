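import math

import numpy as np
import pytest

from linebp import (
    FrequencyBand,
    InvalidParameterError,
    NoPumpSignalError,
    PumpFlowEstimator,
    PumpGeometry,
    SimulationConfig,
    flow_from_frequency,
    flow_series,
    frequency_from_flow,
    fundamental_frequency,
    simulate_session,
)


def dense_dft_peak_hz(segment, fs, f_lo=0.4, f_hi=3.0, step=0.005):
    """Independent oracle: Hann-windowed DFT evaluated on a dense frequency
    grid, argmax of power."""
    x = np.asarray(segment, float)
    x = (x - x.mean()) * np.hanning(x.size)
    t = np.arange(x.size) / fs
    grid = np.arange(f_lo, f_hi + step / 2, step)
    power = np.abs(np.exp(-2j * np.pi * grid[:, None] * t[None, :]) @ x) ** 2
    return float(grid[np.argmax(power)])


class TestFundamentalFrequency:
    def test_pure_tone_within_half_percent(self):
        t = np.arange(5000) / 1000.0
        fr = fundamental_frequency(np.sin(2 * np.pi * 1.0 * t), 1000.0)
        assert fr == pytest.approx(2 * math.pi, rel=5e-3)

    def test_tone_with_harmonic_and_noise_matches_oracle(self, rng):
        t = np.arange(5000) / 1000.0
        seg = (
            np.sin(2 * np.pi * 1.2 * t)
            + 0.4 * np.sin(2 * np.pi * 2.4 * t + 0.7)
            + rng.normal(0, 0.05, 5000)
        )
        fr = fundamental_frequency(seg, 1000.0)
        f_oracle = dense_dft_peak_hz(seg, 1000.0)
        assert abs(fr / (2 * math.pi) - f_oracle) < 0.05  # one interpolation step
        assert fr / (2 * math.pi) == pytest.approx(1.2, rel=5e-3)

    def test_white_noise_raises_no_pump_signal(self, rng):
        with pytest.raises(NoPumpSignalError):
            fundamental_frequency(rng.normal(0, 1, 5000), 1000.0)

    def test_band_must_be_resolvable(self):
        # 1 s of data cannot resolve two periods of anything below 2 Hz
        with pytest.raises(InvalidParameterError):
            fundamental_frequency(
                np.sin(np.arange(1000) / 1000.0), 1000.0, FrequencyBand(0.2, 1.5)
            )

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            fundamental_frequency(np.zeros(5000), 5.0, FrequencyBand(0.2, 3.0))


class TestFlowFromFrequency:
    pump = PumpGeometry(line_radius_mm=4.0, effective_length_mm=107.8, lobe_count=2)

    def test_zero_frequency_zero_flow(self):
        assert flow_from_frequency(0.0, self.pump) == 0.0

    def test_one_rev_per_second_hand_computed(self):
        # 1 rev/s sweeps pi*r^2*Ln per rev: 60 rev/min * pi*16*107.8 mm^3 -> ml/min
        expected = 60.0 * math.pi * 16.0 * 107.8 / 1000.0
        assert flow_from_frequency(2 * math.pi, self.pump) == pytest.approx(expected)
        assert expected == pytest.approx(325.12, abs=0.01)

    def test_linear_in_frequency(self):
        f1 = flow_from_frequency(2.0, self.pump)
        assert flow_from_frequency(4.0, self.pump) == pytest.approx(2 * f1)

    def test_lobe_frequency_flag_divides_by_lobe_count(self):
        direct = flow_from_frequency(2 * math.pi, self.pump)
        lobe = flow_from_frequency(2 * math.pi, self.pump, detected_is_lobe_frequency=True)
        assert lobe == pytest.approx(direct / 2)

    def test_negative_frequency_rejected(self):
        with pytest.raises(InvalidParameterError):
            flow_from_frequency(-1.0, self.pump)

    def test_frequency_from_flow_inverts(self):
        fr = frequency_from_flow(325.0, self.pump)
        assert flow_from_frequency(fr, self.pump) == pytest.approx(325.0)
        fr_lobe = frequency_from_flow(325.0, self.pump, at_lobe_frequency=True)
        assert fr_lobe == pytest.approx(2 * fr)


class TestFlowSeries:
    def test_constant_flow_recovered_within_one_percent(self, short_session):
        session, truth = short_session
        ests = flow_series(session.venous, session.pump)
        assert len(ests) > 100
        flows = np.array([e.flow_ml_min for e in ests])
        assert np.abs(flows / session.set_flow_ml_min - 1).max() < 0.01

    def test_pump_off_prefix_yields_gaps(self):
        cfg = SimulationConfig(duration_s=120.0, pump_start_s=60.0, seed=3)
        session, _ = simulate_session(cfg)
        times = np.array([e.time_s for e in flow_series(session.venous, session.pump)])
        assert times.size > 0
        assert (times < 60.0).sum() == 0

    def test_all_pump_off_yields_no_estimates(self):
        cfg = SimulationConfig(duration_s=120.0, pump_start_s=120.0, seed=0)
        session, _ = simulate_session(cfg)
        assert flow_series(session.venous, session.pump) == []

    def test_step_change_tracked_after_window_majority(self):
        cfg = SimulationConfig(
            duration_s=120.0,
            set_flow_ml_min=300.0,
            flow_steps=[(60.0, 350.0)],
            cuff_interval_s=200.0,
            seed=4,
        )
        session, _ = simulate_session(cfg)
        ests = flow_series(session.venous, session.pump)
        for e in ests:
            if e.time_s <= 60.0:  # window fully in the old regime
                assert e.flow_ml_min == pytest.approx(300.0, rel=0.01)
            # majority of the 5 s window covers the new rate from t = 62.5 s;
            # tracking settles within 2 further 1 s hops
            elif e.time_s >= 64.5:
                assert e.flow_ml_min == pytest.approx(350.0, rel=0.01)

    def test_invariant_to_moderate_cardiac_component(self, short_session):
        session, _ = short_session
        base = flow_series(session.venous, session.pump)
        t = session.venous.times()
        contaminated = session.venous
        # non-harmonic contaminant, separated beyond the 5 s window's
        # spectral resolution, at under a third of the pump amplitude
        contaminated = type(contaminated)(
            contaminated.values + 8.0 * np.sin(2 * np.pi * 1.9 * t),
            contaminated.sample_rate_hz,
            contaminated.start_time,
            "venous",
        )
        with_cardiac = flow_series(contaminated, session.pump)
        assert len(with_cardiac) == len(base)
        for a, b in zip(base, with_cardiac):
            assert b.flow_ml_min == pytest.approx(a.flow_ml_min, rel=1e-3)

    def test_frequency_within_band_and_metadata(self, short_session):
        session, _ = short_session
        band = FrequencyBand()
        for e in flow_series(session.venous, session.pump, band=band):
            assert 2 * math.pi * band.low_hz <= e.frequency_rad_s <= 2 * math.pi * band.high_hz
            assert e.window_width_samples == 5000
            assert e.spectral_peak_power > 0


class TestPumpFlowEstimatorAPI:
    def test_transform_matches_flow_series(self, short_session):
        session, _ = short_session
        est = PumpFlowEstimator().fit(session)
        out = est.transform(session)
        ref = flow_series(session.venous, session.pump)
        assert [e.flow_ml_min for e in out] == [e.flow_ml_min for e in ref]

    def test_bare_trace_requires_pump_parameter(self, short_session):
        session, _ = short_session
        with pytest.raises(InvalidParameterError):
            PumpFlowEstimator().transform(session.venous)
        out = PumpFlowEstimator(pump=session.pump).transform(session.venous)
        assert len(out) > 0

    def test_get_set_params_roundtrip(self):
        est = PumpFlowEstimator(low_hz=0.3)
        params = est.get_params()
        assert params["low_hz"] == 0.3
        est.set_params(high_hz=2.5)
        assert est.high_hz == 2.5
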