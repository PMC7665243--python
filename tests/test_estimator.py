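import numpy as np
import pytest
from sklearn.base import clone

from linebp import (
    BrachialMAPEstimator,
    DegenerateFitError,
    NoEstimateError,
    SimulationConfig,
    compensated_fit,
    continuous_bp,
    estimate_map,
    fit_map_vs_arterial,
    noiseless,
    simulate_cohort,
    simulate_session,
)
from linebp.calibration import session_calibration


def _calibrations(cohort):
    cals = []
    for session, _ in cohort:
        est = BrachialMAPEstimator().fit(session)
        cals.append(est.calibration_)
    return cals


class TestEstimateMap:
    def test_zero_c_degenerates_to_line_pressure(self):
        assert estimate_map(0.0, -150.0, 300.0, 2.0) == -150.0

    def test_roundtrip_random_inputs(self, rng):
        from linebp import c_from_point

        for _ in range(200):
            pb = rng.uniform(50, 150)
            p2 = rng.uniform(-500, -20)
            flow = rng.uniform(100, 500)
            a2 = rng.uniform(0.5, 3.0)
            c = c_from_point(pb, p2, flow, a2)
            assert estimate_map(c, p2, flow, a2) == pytest.approx(pb, rel=1e-12)


class TestContinuousBP:
    def test_noiseless_tracks_truth_within_one_mmhg(self, noiseless_session):
        session, truth = noiseless_session
        est = BrachialMAPEstimator().fit(session)
        trace = est.predict()
        values, times = trace.values, trace.times()
        mask = ~np.isnan(values)
        assert mask.sum() > 250
        err = values[mask] - truth.map_at(times[mask])
        assert np.abs(err).max() < 1.0

    def test_hypotensive_dip_visible_with_correct_timing(self):
        cfg = SimulationConfig(
            duration_s=600.0, cuff_interval_s=120.0, seed=5,
            dips=[(250.0, 120.0, 25.0)],
        )
        session, truth = simulate_session(cfg)
        est = BrachialMAPEstimator().fit(session)
        trace = est.predict()
        values, times = trace.values, trace.times()
        mask = ~np.isnan(values)
        t_min = times[mask][np.argmin(values[mask])]
        assert t_min == pytest.approx(310.0, abs=10.0)  # dip centre, +/- a few hops
        depth = np.nanmax(values) - np.nanmin(values)
        assert depth > 15.0

    def test_pump_off_prefix_has_no_estimates(self):
        cfg = SimulationConfig(duration_s=240.0, pump_start_s=120.0, seed=3,
                               cuff_interval_s=40.0)
        session, _ = simulate_session(cfg)
        est = BrachialMAPEstimator().fit(session)
        trace = est.predict()
        assert trace.start_time >= 120.0

    def test_empty_flow_series_raises(self, noiseless_session):
        session, _ = noiseless_session
        est = BrachialMAPEstimator().fit(session)
        with pytest.raises(NoEstimateError):
            continuous_bp(session, est.c_, [], est.filtered_arterial_)

    def test_causal_variant_starts_after_first_cuff(self, noiseless_session):
        session, _ = noiseless_session
        est = BrachialMAPEstimator(causal_c=True).fit(session)
        trace = est.predict()
        first_cuff = session.cuffs[0].time_s
        values, times = trace.values, trace.times()
        assert np.all(np.isnan(values[times < first_cuff]))
        assert np.isfinite(values[times >= first_cuff + 1]).any()

    def test_insensitive_to_added_arterial_noise(self, noiseless_session):
        session, _ = noiseless_session
        est = BrachialMAPEstimator().fit(session)
        base = est.predict()

        rng = np.random.default_rng(11)
        noisy_arterial = type(session.arterial)(
            session.arterial.values + rng.normal(0, 2.0, len(session.arterial)),
            session.arterial.sample_rate_hz,
            session.arterial.start_time,
            "arterial",
        )
        from linebp import moving_average

        filtered = moving_average(noisy_arterial, 5000)
        perturbed = continuous_bp(session, est.c_, est.flow_, filtered)
        delta = perturbed.values - base.values
        assert np.nanmax(np.abs(delta)) < 0.5

    def test_annotated_with_c_value(self, noiseless_session):
        session, _ = noiseless_session
        est = BrachialMAPEstimator().fit(session)
        trace = est.predict()
        assert trace.channel == "map_estimate"
        assert trace.meta["c_value"] == est.c_


class TestFitMapVsArterial:
    def test_exact_line_recovered(self):
        x = np.linspace(-350.0, -250.0, 20)
        pts = np.column_stack([x, 0.8 * x - 150.0])
        res = fit_map_vs_arterial(pts)
        assert res.slope == pytest.approx(0.8)
        assert res.intercept == pytest.approx(-150.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_points == 20

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=50)
        y = 2.0 * x + rng.normal(size=50)
        res = fit_map_vs_arterial(np.column_stack([x, y]))
        X = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_response(self):
        pts = [(-1.0, 5.0), (0.0, 5.0), (1.0, 5.0)]
        res = fit_map_vs_arterial(pts)
        assert res.slope == 0.0
        assert res.r_squared == 0.0

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            fit_map_vs_arterial([(0.0, 1.0), (1.0, 2.0)])
        with pytest.raises(DegenerateFitError):
            fit_map_vs_arterial([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])


class TestCompensatedFit:
    def test_constant_c_everywhere_gives_identical_fits(self):
        # flow fixed at 325 ml/min puts the pump at an integer number of
        # cycles per averaging window, so the boxcar leaves no ripple and
        # the identity holds to numerical precision
        cohort = simulate_cohort(
            n_sessions=4,
            gauge_mix={14: 2, 15: 2},
            between_session_c_sd=0.0,
            within_session_c_sd=0.0,
            seed=8,
            flow_ranges_ml_min={14: (325.0, 325.0), 15: (325.0, 325.0)},
            noise_sd_mmhg=0.0,
            cuff_noise_sd_mmhg=0.0,
        )
        pooled, comp = compensated_fit(_calibrations(cohort))
        # residual tolerance covers the ~1e-4 wobble of the windowed flow
        # estimates entering the per-point C values
        assert comp.slope == pytest.approx(pooled.slope, rel=1e-3)
        assert comp.r_squared == pytest.approx(pooled.r_squared, abs=1e-3)

    def test_within_session_drift_compensation_improves_r2(self):
        cohort = simulate_cohort(seed=2)
        pooled, comp = compensated_fit(_calibrations(cohort))
        assert comp.r_squared > pooled.r_squared
        assert abs(comp.slope / pooled.slope - 1) <= 0.05

    def test_compensation_gap_grows_with_within_session_variation(self):
        gaps = []
        for wsd in (0.25, 0.5, 1.0):
            cohort = simulate_cohort(seed=2, within_session_c_sd=wsd)
            pooled, comp = compensated_fit(_calibrations(cohort))
            gaps.append(comp.r_squared - pooled.r_squared)
        assert gaps[0] < gaps[1] < gaps[2]

    def test_requires_two_sessions_with_two_points(self, noiseless_session):
        session, _ = noiseless_session
        cal = BrachialMAPEstimator().fit(session).calibration_
        with pytest.raises(DegenerateFitError):
            compensated_fit([cal])


class TestSklearnAPI:
    def test_get_params_set_params_clone(self):
        est = BrachialMAPEstimator(window_samples=4000, robust_c=True)
        params = est.get_params()
        assert params["window_samples"] == 4000
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(hop_samples=500)
        assert est.hop_samples == 500

    def test_fitted_attributes(self, noiseless_session):
        session, truth = noiseless_session
        est = BrachialMAPEstimator().fit(session)
        assert est.c_ == pytest.approx(truth.c_mean, rel=0.01)
        assert est.n_points_ == len(est.calibration_.points)
        assert len(est.flow_) > 0

    def test_predict_before_fit_raises(self):
        with pytest.raises(NoEstimateError):
            BrachialMAPEstimator().predict()

    def test_calibration_transfers_to_new_session(self, noiseless_session):
        session, truth = noiseless_session
        est = BrachialMAPEstimator().fit(session)
        cfg = noiseless(
            SimulationConfig(duration_s=120.0, cuff_interval_s=30.0, seed=9)
        )
        other, other_truth = simulate_session(cfg)
        trace = est.predict(other)
        values, times = trace.values, trace.times()
        mask = ~np.isnan(values)
        err = values[mask] - other_truth.map_at(times[mask])
        # same true C (6.0) in both sessions: transferred calibration works
        assert np.abs(err).max() < 1.0
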