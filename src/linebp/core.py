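"""Domain types for extracorporeal blood-pressure estimation.

The package works in one canonical unit system throughout: pressure in mmHg,
flow in ml/min, area in mm², time in seconds from session start, angular
frequency in rad/s.  The lumped hydraulic coefficient C is the single
exception: it is computed from the Bernoulli relation in SI units and reported
in 10³ kg·m⁻³ (numerically equal to g/ml), the scale on which values for
dialysis needles fall in the observed 5–11 range.  See
:data:`C_SCALE` and :func:`linebp.calibration.c_from_point`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .errors import InvalidParameterError

#: pascal per mmHg
MMHG_PA = 133.322387415

#: Multiplier taking ``2·ΔP/(flow/area)²`` evaluated in canonical units
#: (mmHg, ml/min, mm²) to the reported C unit of 10³ kg·m⁻³:
#: ΔP·133.322… Pa/mmHg, (flow/area)² · (1/60)² (m/s)² per (ml·min⁻¹·mm⁻²)²,
#: then ÷1000 for the 10³ kg·m⁻³ scale.
C_SCALE = MMHG_PA * 3600.0 / 1000.0

#: Default needle gauge → inner diameter (mm).  Conventional dialysis-needle
#: sizes; overridable wherever a NeedleSpec is constructed.
GAUGE_INNER_DIAMETER_MM: dict[int, float] = {14: 1.60, 15: 1.37, 16: 1.19}

Channel = Literal["arterial", "venous", "map_estimate"]


@dataclass
class PressureTrace:
    """A uniformly sampled pressure signal.

    Parameters
    ----------
    values : array of pressure samples, mmHg.
    sample_rate_hz : sampling rate, default 1000.
    start_time : time of the first sample, seconds from session start.
    channel : which line the sensor sits on ("arterial", "venous"), or
        "map_estimate" for derived brachial-MAP traces.
    meta : free-form annotations (e.g. the C value used to derive an
        estimate trace).  Not interpreted by the signal path.
    """

    values: np.ndarray
    sample_rate_hz: float = 1000.0
    start_time: float = 0.0
    channel: Channel = "arterial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidParameterError("trace values must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        """Span covered by the samples (first to last), seconds."""
        return max(len(self.values) - 1, 0) / self.sample_rate_hz

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s

    def times(self) -> np.ndarray:
        """Sample times in seconds from session start."""
        return self.start_time + np.arange(len(self.values)) / self.sample_rate_hz


@dataclass(frozen=True)
class CuffMeasurement:
    """One brachial arm-cuff reading (the intermittent reference, Pb)."""

    time_s: float
    systolic_mmhg: float
    diastolic_mmhg: float
    map_mmhg: float

    def __post_init__(self) -> None:
        if min(self.systolic_mmhg, self.diastolic_mmhg, self.map_mmhg) <= 0:
            raise InvalidParameterError("cuff pressures must be positive")
        if not (self.diastolic_mmhg <= self.map_mmhg <= self.systolic_mmhg):
            raise InvalidParameterError(
                "cuff reading must satisfy diastolic <= MAP <= systolic"
            )


@dataclass(frozen=True)
class PumpGeometry:
    """Peristaltic pump geometry entering the frequency→flow conversion.

    ``line_radius_mm`` is the radius r of the dialysis line within the pump
    (lines are typically 8 mm diameter at the pump, so r ≈ 4);
    ``effective_length_mm`` is the length Ln of line swept per rotation.
    One rotation displaces π·r²·Ln mm³.
    """

    line_radius_mm: float = 4.0
    effective_length_mm: float = 107.8
    lobe_count: int = 2

    def __post_init__(self) -> None:
        if self.line_radius_mm <= 0 or self.effective_length_mm <= 0:
            raise InvalidParameterError("pump radius and length must be positive")
        if self.lobe_count < 1:
            raise InvalidParameterError("lobe_count must be >= 1")

    @property
    def displacement_mm3(self) -> float:
        """Volume displaced per pump rotation, mm³."""
        return math.pi * self.line_radius_mm**2 * self.effective_length_mm


@dataclass(frozen=True)
class NeedleSpec:
    """A fistula needle; its lumen area A2 enters the Bernoulli relation."""

    gauge: int
    inner_diameter_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.inner_diameter_mm is None:
            try:
                object.__setattr__(
                    self, "inner_diameter_mm", GAUGE_INNER_DIAMETER_MM[self.gauge]
                )
            except KeyError:
                raise InvalidParameterError(
                    f"no default inner diameter for gauge {self.gauge}; "
                    "pass inner_diameter_mm explicitly"
                ) from None
        if self.inner_diameter_mm <= 0:
            raise InvalidParameterError("inner_diameter_mm must be positive")

    @property
    def area_mm2(self) -> float:
        """Lumen cross-section A2 = π·(ID/2)², mm²."""
        return math.pi * (self.inner_diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class FlowEstimate:
    """One windowed pump-flow estimate.

    ``time_s`` is the time of the window's last sample — the moment at which
    a real-time system could have produced the estimate.
    """

    time_s: float
    frequency_rad_s: float
    flow_ml_min: float
    window_width_samples: int
    spectral_peak_power: float

    def __post_init__(self) -> None:
        if self.flow_ml_min < 0:
            raise InvalidParameterError("flow_ml_min must be >= 0")


@dataclass(frozen=True)
class CalibrationPoint:
    """A (Pb, P2, flow, A2) quartet and the lumped coefficient it yields."""

    time_s: float
    pb_mmhg: float
    p2_mmhg: float
    flow_ml_min: float
    a2_mm2: float
    c_value: float


@dataclass
class SessionRecord:
    """One dialysis treatment: both line traces, cuff series, hardware."""

    arterial: PressureTrace
    venous: PressureTrace
    cuffs: list[CuffMeasurement]
    arterial_needle: NeedleSpec = NeedleSpec(14)
    venous_needle: NeedleSpec = NeedleSpec(14)
    pump: PumpGeometry = PumpGeometry()
    set_flow_ml_min: Optional[float] = None
    session_id: str = "session"

    @property
    def gauge_label(self) -> int:
        """Gauge-set label; sets are named by the venous needle gauge."""
        return self.venous_needle.gauge


@dataclass(frozen=True)
class ValidationFinding:
    severity: Literal["error", "warning"]
    code: str
    message: str


def validate_session(session: SessionRecord) -> list[ValidationFinding]:
    """Check a session's structural invariants.

    Returns a (possibly empty) list of findings rather than raising: a
    well-formed session yields ``[]``; each violated invariant yields one
    finding tagged ``error`` or (for soft sign conventions) ``warning``.
    """
    findings: list[ValidationFinding] = []

    def err(code: str, msg: str) -> None:
        findings.append(ValidationFinding("error", code, msg))

    def warn(code: str, msg: str) -> None:
        findings.append(ValidationFinding("warning", code, msg))

    for name, trace in (("arterial", session.arterial), ("venous", session.venous)):
        if len(trace) == 0:
            err("empty-trace", f"{name} trace has no samples")
    if session.arterial.sample_rate_hz != session.venous.sample_rate_hz:
        err(
            "rate-mismatch",
            "arterial and venous traces have different sample rates "
            f"({session.arterial.sample_rate_hz} vs {session.venous.sample_rate_hz})",
        )
    if len(session.arterial) and len(session.venous):
        overlap_start = max(session.arterial.start_time, session.venous.start_time)
        overlap_end = min(session.arterial.end_time, session.venous.end_time)
        if overlap_start >= overlap_end:
            err("no-overlap", "arterial and venous traces do not overlap in time")
        for i, cuff in enumerate(session.cuffs):
            if not (overlap_start <= cuff.time_s <= overlap_end):
                err(
                    "cuff-outside-span",
                    f"cuff #{i} at t={cuff.time_s:.1f} s lies outside the "
                    f"trace span [{overlap_start:.1f}, {overlap_end:.1f}] s",
                )
        # Sign conventions under pump suction/return are soft checks only:
        # a pump-off or mis-labelled channel is suspicious, not fatal.
        if float(np.mean(session.arterial.values)) > 0:
            warn(
                "arterial-sign",
                "arterial line mean pressure is positive; expected predominantly "
                "negative under pump suction",
            )
        if float(np.mean(session.venous.values)) < 0:
            warn(
                "venous-sign",
                "venous line mean pressure is negative; expected predominantly "
                "positive under pump return",
            )
    return findings
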