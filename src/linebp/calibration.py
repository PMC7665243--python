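"""Lumped-parameter calibration against intermittent cuff readings.

Bernoulli/continuity analysis of the arterial needle relates brachial
pressure Pb, filtered arterial line pressure P2, blood flow f and the needle
lumen area A2 through a single experimentally determined coefficient::

    C = 2·(Pb − P2) / (f/A2)²

C absorbs every unmodelled and unmeasurable feature of the access — discharge
losses, blood density and viscosity, fistula geometry, the unmeasurable
needle-tip state — and is recomputed from each cuff reading.  The ratio is
evaluated in SI units (Pa, m³/s, m²) and reported on the 10³ kg·m⁻³ scale
(numerically g/ml), on which dialysis-needle values fall in the range ≈5–11,
rising as needle lumen shrinks.

A session's calibration is the set of per-cuff C values plus their mean,
which then drives continuous estimation (see :mod:`linebp.estimator`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import C_SCALE, CalibrationPoint, FlowEstimate, PressureTrace, SessionRecord
from .errors import InvalidParameterError, NoCalibrationError, OutOfRangeError
from .signal import value_at_time

logger = logging.getLogger(__name__)

#: a cuff reading is only paired with a flow estimate at most this old
DEFAULT_MAX_FLOW_AGE_S = 30.0


def c_from_point(
    pb_mmhg: float, p2_mmhg: float, flow_ml_min: float, a2_mm2: float
) -> float:
    """Lumped coefficient C from one measured (Pb, P2, flow, A2) quartet.

    Returns ``2·(pb − p2)/(flow/a2)²`` with the pressure gap in Pa and the
    flow/area ratio in m/s, reported in 10³ kg·m⁻³.  Positive whenever
    pb > p2 — the physiological case, the arterial line being under pump
    suction.  Unit-consistent: scaling flow and a2 by a common factor leaves
    C unchanged.
    """
    if flow_ml_min <= 0:
        raise InvalidParameterError("C is undefined at zero or negative flow")
    if a2_mm2 <= 0:
        raise InvalidParameterError("needle area must be positive")
    velocity_sq = (flow_ml_min / a2_mm2) ** 2  # (ml·min⁻¹·mm⁻²)², → SI via C_SCALE
    return C_SCALE * 2.0 * (pb_mmhg - p2_mmhg) / velocity_sq


@dataclass
class SessionCalibration:
    """Per-cuff C values and their session aggregate."""

    session_id: str
    gauge_label: int
    points: list[CalibrationPoint]
    c_session: float
    c_sd: float
    c_min: float
    c_max: float
    skipped: list[tuple[float, str]] = field(default_factory=list)

    @property
    def c_values(self) -> np.ndarray:
        return np.array([p.c_value for p in self.points])


def session_calibration(
    session: SessionRecord,
    flow: Sequence[FlowEstimate],
    filtered_arterial: PressureTrace,
    robust: bool = False,
    max_flow_age_s: float = DEFAULT_MAX_FLOW_AGE_S,
) -> SessionCalibration:
    """Calibrate one session from its cuff readings.

    Each cuff reading that falls within the pumped, flow-estimable span
    yields one :class:`CalibrationPoint`: Pb is the cuff MAP, P2 the filtered
    arterial pressure at the cuff time, flow the nearest preceding windowed
    estimate (at most ``max_flow_age_s`` old), A2 the arterial needle area.
    Cuffs outside that span are skipped with a logged reason.  The session
    aggregate is the unweighted mean of point C values (median if
    ``robust``), with sd and range reported as dispersion diagnostics.

    Raises
    ------
    NoCalibrationError
        if no cuff reading is usable.
    """
    flow_times = np.array([est.time_s for est in flow])
    a2 = session.arterial_needle.area_mm2
    points: list[CalibrationPoint] = []
    skipped: list[tuple[float, str]] = []

    for cuff in session.cuffs:
        if flow_times.size == 0:
            skipped.append((cuff.time_s, "no flow estimates in session"))
            continue
        i = int(np.searchsorted(flow_times, cuff.time_s, side="right")) - 1
        if i < 0:
            skipped.append((cuff.time_s, "before first flow estimate"))
            continue
        est = flow[i]
        if cuff.time_s - est.time_s > max_flow_age_s:
            skipped.append(
                (cuff.time_s, "nearest preceding flow estimate is stale (pump off?)")
            )
            continue
        try:
            p2 = value_at_time(filtered_arterial, cuff.time_s)
        except OutOfRangeError:
            skipped.append((cuff.time_s, "outside arterial trace span"))
            continue
        points.append(
            CalibrationPoint(
                time_s=cuff.time_s,
                pb_mmhg=cuff.map_mmhg,
                p2_mmhg=p2,
                flow_ml_min=est.flow_ml_min,
                a2_mm2=a2,
                c_value=c_from_point(cuff.map_mmhg, p2, est.flow_ml_min, a2),
            )
        )

    for t, reason in skipped:
        logger.info("session %s: cuff at %.1f s skipped: %s", session.session_id, t, reason)
    if not points:
        raise NoCalibrationError(
            f"session {session.session_id}: no cuff reading falls within the "
            "flow-estimable span"
        )
    c = np.array([p.c_value for p in points])
    return SessionCalibration(
        session_id=session.session_id,
        gauge_label=session.gauge_label,
        points=points,
        c_session=float(np.median(c) if robust else np.mean(c)),
        c_sd=float(np.std(c, ddof=1)) if c.size > 1 else 0.0,
        c_min=float(c.min()),
        c_max=float(c.max()),
        skipped=skipped,
    )


@dataclass
class GaugeSummary:
    """All C values observed for one needle-gauge set.

    ``core_mean`` averages the points surviving the median ± k·MAD outlier
    screen; ``mean_all`` includes every point.  ``outliers`` lists the
    flagged (session_id, time_s, c_value) triples.
    """

    gauge: int
    c_values: np.ndarray
    mean_all: float
    core_mean: float
    median: float
    mad: float
    outliers: list[tuple[str, float, float]]

    @property
    def outlier_sessions(self) -> set[str]:
        return {sid for sid, _, _ in self.outliers}


def group_c_by_gauge(
    calibrations: Sequence[SessionCalibration],
    mad_k: float = 3.0,
) -> dict[int, GaugeSummary]:
    """Summarise point C values per needle-gauge set, flagging outliers.

    Points further than ``mad_k`` median absolute deviations from the group
    median are flagged (groups of fewer than 3 points are never flagged);
    the core mean excludes them, mirroring the tight core grouping such
    cohorts exhibit once immature-fistula sessions are screened out.
    Summaries are keyed and ordered by gauge.
    """
    by_gauge: dict[int, list[tuple[str, float, float]]] = {}
    for cal in calibrations:
        rows = by_gauge.setdefault(cal.gauge_label, [])
        rows.extend((cal.session_id, p.time_s, p.c_value) for p in cal.points)

    out: dict[int, GaugeSummary] = {}
    for gauge in sorted(by_gauge):
        rows = by_gauge[gauge]
        c = np.array([r[2] for r in rows])
        med = float(np.median(c))
        mad = float(np.median(np.abs(c - med)))
        if c.size >= 3 and mad > 0:
            is_out = np.abs(c - med) > mad_k * mad
        else:
            is_out = np.zeros(c.size, dtype=bool)
        core = c[~is_out]
        out[gauge] = GaugeSummary(
            gauge=gauge,
            c_values=c,
            mean_all=float(c.mean()),
            core_mean=float(core.mean()) if core.size else float("nan"),
            median=med,
            mad=mad,
            outliers=[rows[i] for i in np.flatnonzero(is_out)],
        )
    return out
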