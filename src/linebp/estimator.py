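"""Continuous brachial MAP estimation and its validation regressions.

Inverting the calibration relation gives the estimator::

    Pb = P2 + 0.5 · (f/A2)² · C

evaluated at the flow-window cadence (1 Hz by default) on the 5 s
moving-averaged arterial pressure — the exact algebraic inverse of
:func:`linebp.calibration.c_from_point`, so a session generated with a known
constant C reproduces its cuff MAPs identically in the noiseless limit.

Two regression analyses quantify how far a *single* linear relation carries
across a cohort: a pooled ordinary-least-squares fit of cuff MAP against
filtered arterial line pressure over all sessions, and a compensated fit in
which each point is re-predicted with its session-mean C before regressing,
removing within-session C variation.  The R² gain of the compensated fit
measures how much of the pooled scatter is attributable to time-varying
session effects rather than between-patient physiology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .calibration import (
    SessionCalibration,
    c_from_point,  # noqa: F401  (re-exported pairing for the identity)
    session_calibration,
)
from .core import C_SCALE, FlowEstimate, PressureTrace, SessionRecord
from .errors import (
    DegenerateFitError,
    InvalidParameterError,
    NoEstimateError,
)
from .pump import FrequencyBand, flow_series
from .signal import WindowSpec, moving_average, value_at_time


def estimate_map(
    c_value: float, p2_mmhg: float, flow_ml_min: float, a2_mm2: float
) -> float:
    """Brachial MAP (mmHg) from filtered line pressure, flow and C.

    Exact inverse of :func:`~linebp.calibration.c_from_point`; with
    ``c_value = 0`` the estimate degenerates to the line pressure itself.
    """
    if a2_mm2 <= 0:
        raise InvalidParameterError("needle area must be positive")
    if flow_ml_min < 0:
        raise InvalidParameterError("flow must be >= 0")
    velocity_sq = (flow_ml_min / a2_mm2) ** 2
    return p2_mmhg + 0.5 * velocity_sq * c_value / C_SCALE


def continuous_bp(
    session: SessionRecord,
    c_value: float,
    flow: Sequence[FlowEstimate],
    filtered_arterial: PressureTrace,
    calibration: Optional[SessionCalibration] = None,
    causal: bool = False,
) -> PressureTrace:
    """Continuous brachial-MAP trace at the flow-estimate cadence.

    One estimate per flow window; times with no flow estimate (pump off,
    no coherent peak) are NaN gaps.  By default a single session-level
    ``c_value`` is used; with ``causal=True`` and a ``calibration``, each
    estimate instead uses the running mean of the calibration points
    available at that time (real-time emulation), with gaps before the first
    cuff.  The output trace is annotated with the C value used.

    Raises
    ------
    NoEstimateError
        if the flow series is empty.
    """
    if not flow:
        raise NoEstimateError("no flow estimates: cannot produce a MAP trace")
    if causal and calibration is None:
        raise InvalidParameterError("causal estimation requires a calibration")

    times = np.array([est.time_s for est in flow])
    diffs = np.diff(times)
    cadence = float(np.min(diffs)) if diffs.size else 1.0
    grid = np.arange(times[0], times[-1] + cadence / 2, cadence)
    values = np.full(grid.size, np.nan)

    if causal:
        pt_times = np.array([p.time_s for p in calibration.points])
        pt_c = np.array([p.c_value for p in calibration.points])

    a2 = session.arterial_needle.area_mm2
    for est in flow:
        i = int(round((est.time_s - grid[0]) / cadence))
        if not (0 <= i < grid.size):
            continue
        if causal:
            k = int(np.searchsorted(pt_times, est.time_s, side="right"))
            if k == 0:
                continue  # no cuff seen yet: not estimable in real time
            c_here = float(pt_c[:k].mean())
        else:
            c_here = c_value
        p2 = value_at_time(filtered_arterial, est.time_s)
        values[i] = estimate_map(c_here, p2, est.flow_ml_min, a2)

    return PressureTrace(
        values=values,
        sample_rate_hz=1.0 / cadence,
        start_time=float(grid[0]),
        channel="map_estimate",
        meta={"c_value": c_value, "causal": causal},
    )


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares summary for MAP-vs-line-pressure fits."""

    slope: float
    intercept: float
    rmse: float
    r_squared: float
    p_value: float
    n_points: int


def fit_map_vs_arterial(
    points: Union[Sequence[tuple[float, float]], np.ndarray],
) -> RegressionResult:
    """OLS fit of brachial cuff MAP (y) on filtered arterial pressure (x).

    ``points`` is a sequence of (p2, pb) pairs.  RMSE is the root mean
    squared residual; the p-value tests slope ≠ 0.  A constant response
    yields slope 0 and R² 0; a constant predictor is degenerate.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateFitError("need at least 3 (p2, pb) points")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in arterial pressure")
    if np.ptp(y) == 0:
        # linregress is well defined here but returns nan p-value pieces on
        # some platforms; the limit is unambiguous.
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 1.0, len(y))
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=float(np.sqrt(np.mean(resid**2))),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(y),
    )


def compensated_fit(
    calibrations: Sequence[SessionCalibration],
) -> tuple[RegressionResult, RegressionResult]:
    """Pooled and session-mean-C-compensated cohort regressions.

    The pooled fit regresses every raw (P2, cuff MAP) point across sessions.
    The compensated fit recomputes each point's arterial coordinate from its
    cuff MAP and flow using the *session-mean* C —
    ``p2' = pb − 0.5·(f/A2)²·c̄``, the line pressure that would have been
    recorded had C sat at its session mean — and refits.  Within-session
    wander of C is thereby removed from the scatter while between-session
    differences remain.  Returns (pooled, compensated) so the R² improvement
    and slope stability can be asserted; with C constant within every
    session the two fits coincide.
    """
    if len(calibrations) < 2:
        raise DegenerateFitError("need at least 2 calibrated sessions")
    if any(len(cal.points) < 2 for cal in calibrations):
        raise DegenerateFitError("every session needs at least 2 points")

    raw, comp = [], []
    for cal in calibrations:
        for p in cal.points:
            raw.append((p.p2_mmhg, p.pb_mmhg))
            gap = 0.5 * (p.flow_ml_min / p.a2_mm2) ** 2 * cal.c_session / C_SCALE
            comp.append((p.pb_mmhg - gap, p.pb_mmhg))
    return fit_map_vs_arterial(raw), fit_map_vs_arterial(comp)


class BrachialMAPEstimator(BaseEstimator):
    """Scikit-learn style estimator for continuous brachial MAP.

    ``fit`` takes a :class:`SessionRecord`: it smooths the arterial trace
    with the trailing boxcar, estimates the windowed pump-flow series from
    the venous trace, and calibrates the lumped coefficient C against the
    session's cuff readings.  ``predict`` returns the continuous MAP trace
    for the fitted session (or for another session, reusing the learned C —
    e.g. applying a patient's previous calibration to a new treatment).

    Parameters mirror the pipeline stages: analysis-window geometry, the
    pump-frequency search band, the lobe-frequency convention, and whether
    the session C is the robust median and/or applied causally (running mean
    of cuffs seen so far) instead of the session mean.

    Attributes (after ``fit``)
    --------------------------
    c_ : float
        Session lumped coefficient (mean or median of point values).
    calibration_ : SessionCalibration
        Per-cuff calibration points and dispersion.
    flow_ : list of FlowEstimate
        Windowed pump-flow estimates for the fitted session.
    filtered_arterial_ : PressureTrace
        Moving-averaged arterial trace used for calibration.
    """

    def __init__(
        self,
        window_samples: int = 5000,
        hop_samples: int = 1000,
        low_hz: float = 0.2,
        high_hz: float = 3.0,
        min_peak_snr: float = 5.0,
        detected_is_lobe_frequency: bool = False,
        robust_c: bool = False,
        causal_c: bool = False,
        max_flow_age_s: float = 30.0,
    ):
        self.window_samples = window_samples
        self.hop_samples = hop_samples
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.min_peak_snr = min_peak_snr
        self.detected_is_lobe_frequency = detected_is_lobe_frequency
        self.robust_c = robust_c
        self.causal_c = causal_c
        self.max_flow_age_s = max_flow_age_s

    def _stages(self, session: SessionRecord):
        spec = WindowSpec(self.window_samples, self.hop_samples)
        band = FrequencyBand(self.low_hz, self.high_hz, self.min_peak_snr)
        filtered = moving_average(
            session.arterial, min(self.window_samples, len(session.arterial))
        )
        flow = flow_series(
            session.venous, session.pump, spec, band, self.detected_is_lobe_frequency
        )
        return filtered, flow

    def fit(self, X: SessionRecord, y=None) -> "BrachialMAPEstimator":
        filtered, flow = self._stages(X)
        self.filtered_arterial_ = filtered
        self.flow_ = flow
        self.calibration_ = session_calibration(
            X, flow, filtered, robust=self.robust_c, max_flow_age_s=self.max_flow_age_s
        )
        self.c_ = self.calibration_.c_session
        self.n_points_ = len(self.calibration_.points)
        self.session_ = X
        return self

    def predict(self, X: Optional[SessionRecord] = None) -> PressureTrace:
        if not hasattr(self, "c_"):
            raise NoEstimateError("estimator is not fitted")
        if X is None or X is self.session_:
            session, filtered, flow = self.session_, self.filtered_arterial_, self.flow_
        else:
            session = X
            filtered, flow = self._stages(X)
        return continuous_bp(
            session,
            self.c_,
            flow,
            filtered,
            calibration=self.calibration_,
            causal=self.causal_c,
        )
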