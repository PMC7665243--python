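"""Synthetic dialysis sessions with known ground truth.

The generator produces the dual-channel 1 kHz line-pressure record a
dialysis monitoring rig would capture, built *from* the model the pipeline
inverts, so that true flow, true C and true MAP are known exactly:

* venous trace — positive baseline (~+150 mmHg) plus the peristaltic pump
  oscillation (fundamental at the rotation — or, optionally, lobe-passing —
  frequency, with a weaker 2nd harmonic) plus sensor noise;
* arterial trace — the Bernoulli relation inverted,
  ``p2(t) = map(t) − 0.5·(flow(t)/A2)²·c(t)`` (C on its 10³ kg·m⁻³ scale),
  plus pump oscillation, a cardiac component and sensor noise;
* cuff readings — true MAP at the cuff time plus reading noise, with
  systolic/diastolic synthesised around it at a plausible pulse pressure;
* before the pump starts, both lines sit near a static fistula pressure.

Realism terms (cardiac component, harmonics, noise, C drift, hypotensive
dips) are additive and individually configurable, so the noiseless limit
recovers the model exactly.  The cardiac default of 1.2 Hz is deliberately
non-harmonic with the 1 Hz pump default; configuring them to coincide
reproduces the known failure mode of line-pressure methods.

Cohorts mirror an 11-session study design: needle-gauge sets 14/15/16 (the
set label is the venous gauge; the 16g set pairs a 15g arterial needle) with
gauge-dependent mean C of 6 / 8.5 / 10.25, between- and within-session C
variation, and per-patient flow prescriptions in the 278–394 ml/min range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    C_SCALE,
    CuffMeasurement,
    NeedleSpec,
    PressureTrace,
    PumpGeometry,
    SessionRecord,
)
from .errors import InvalidParameterError
from .pump import frequency_from_flow

#: gauge-set label → (arterial gauge, venous gauge); the 16g set uses a 15g
#: arterial needle, matching clinical practice for new fistulae
GAUGE_SETS: dict[int, tuple[int, int]] = {14: (14, 14), 15: (15, 15), 16: (15, 16)}

#: nominal lumped-coefficient mean per gauge set (10³ kg·m⁻³)
GAUGE_C_MEANS: dict[int, float] = {14: 6.0, 15: 8.5, 16: 10.25}


@dataclass
class SimulationConfig:
    """Everything that defines one simulated treatment.

    Durations default to 600 s (tests); a full treatment is 14400 s.  The
    flow prescription is constant (``set_flow_ml_min``) unless
    ``flow_steps`` gives piecewise-constant (time_s, flow) breakpoints.
    ``true_c_start``/``true_c_end`` define a linear C drift across the
    session; ``true_c_noise_sd`` adds slow correlated wander on top.
    ``dips`` lists (start_s, duration_s, depth_mmhg) hypotensive events.
    """

    duration_s: float = 600.0
    sample_rate_hz: float = 1000.0
    set_flow_ml_min: float = 325.0
    flow_steps: Optional[Sequence[tuple[float, float]]] = None
    pump: PumpGeometry = field(default_factory=PumpGeometry)
    pump_start_s: float = 0.0
    pump_amplitude_venous_mmhg: float = 30.0
    pump_amplitude_arterial_mmhg: float = 40.0
    second_harmonic_ratio: float = 0.3
    pump_waveform_at_lobe_frequency: bool = False
    cardiac_freq_hz: float = 1.2
    cardiac_amplitude_mmhg: float = 5.0
    noise_sd_mmhg: float = 1.0
    venous_baseline_mmhg: float = 150.0
    static_baseline_mmhg: float = 20.0
    true_c_start: float = 6.0
    true_c_end: Optional[float] = None
    true_c_noise_sd: float = 0.0
    true_c_noise_corr_s: float = 300.0
    base_map_mmhg: float = 93.0
    map_drift_mmhg: float = 0.0
    dips: Sequence[tuple[float, float, float]] = ()
    cuff_interval_s: float = 1800.0
    cuff_offset_s: float = 60.0
    cuff_noise_sd_mmhg: float = 2.0
    arterial_gauge: int = 14
    venous_gauge: int = 14
    session_id: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise InvalidParameterError("duration and sample rate must be positive")
        if not (0 <= self.pump_start_s <= self.duration_s):
            raise InvalidParameterError("pump_start_s must lie within the session")
        flows = [self.set_flow_ml_min] + [f for _, f in (self.flow_steps or [])]
        if any(not (0 < f <= 600) for f in flows):
            raise InvalidParameterError("flow must be in (0, 600] ml/min")
        for name in (
            "pump_amplitude_venous_mmhg",
            "pump_amplitude_arterial_mmhg",
            "cardiac_amplitude_mmhg",
            "noise_sd_mmhg",
            "true_c_noise_sd",
            "cuff_noise_sd_mmhg",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.true_c_start <= 0 or (self.true_c_end or self.true_c_start) <= 0:
            raise InvalidParameterError("true C must be positive")


@dataclass
class GroundTruth:
    """True flow, C and MAP trajectories on a 1 s grid."""

    times_s: np.ndarray
    flow_ml_min: np.ndarray
    c_value: np.ndarray
    map_mmhg: np.ndarray
    pump_start_s: float

    def _at(self, arr: np.ndarray, t) -> np.ndarray:
        return np.interp(t, self.times_s, arr)

    def flow_at(self, t):
        return self._at(self.flow_ml_min, t)

    def c_at(self, t):
        return self._at(self.c_value, t)

    def map_at(self, t):
        return self._at(self.map_mmhg, t)

    @property
    def c_mean(self) -> float:
        """Mean true C over the pumped span."""
        pumped = self.times_s >= self.pump_start_s
        return float(self.c_value[pumped].mean())


def _piecewise_flow(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    flow = np.full(t.size, float(cfg.set_flow_ml_min))
    for start, value in cfg.flow_steps or []:
        flow[t >= start] = value
    flow[t < cfg.pump_start_s] = 0.0
    return flow


def _smooth_noise(
    rng: np.random.Generator, t: np.ndarray, sd: float, corr_s: float
) -> np.ndarray:
    """Slowly varying zero-mean noise: linear interpolation between knots."""
    if sd == 0:
        return np.zeros(t.size)
    n_knots = max(int(np.ceil((t[-1] - t[0]) / corr_s)) + 2, 2)
    knot_t = np.linspace(t[0], t[-1], n_knots)
    return np.interp(t, knot_t, rng.normal(0.0, sd, n_knots))


def simulate_session(config: SimulationConfig) -> tuple[SessionRecord, GroundTruth]:
    """Generate one session and its ground truth.  Same seed → same output."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    pumped = t >= cfg.pump_start_s

    arterial_needle = NeedleSpec(cfg.arterial_gauge)
    venous_needle = NeedleSpec(cfg.venous_gauge)
    a2 = arterial_needle.area_mm2

    flow = _piecewise_flow(cfg, t)
    fr = np.array(
        [
            frequency_from_flow(f, cfg.pump, cfg.pump_waveform_at_lobe_frequency)
            for f in np.unique(flow)
        ]
    )
    fr_of = dict(zip(np.unique(flow), fr))
    fr_t = np.vectorize(fr_of.get)(flow).astype(float)
    phase = np.cumsum(fr_t) / fs

    c_end = cfg.true_c_end if cfg.true_c_end is not None else cfg.true_c_start
    c_t = np.interp(t, [t[0], t[-1]], [cfg.true_c_start, c_end])
    c_t = c_t + _smooth_noise(rng, t, cfg.true_c_noise_sd, cfg.true_c_noise_corr_s)

    map_t = cfg.base_map_mmhg + cfg.map_drift_mmhg * (t - t[0]) / max(
        cfg.duration_s, 1e-9
    )
    for start, dur, depth in cfg.dips:
        in_dip = (t >= start) & (t < start + dur)
        map_t[in_dip] -= depth * np.sin(np.pi * (t[in_dip] - start) / dur) ** 2

    pump_ven = cfg.pump_amplitude_venous_mmhg * (
        np.sin(phase) + cfg.second_harmonic_ratio * np.sin(2 * phase + 0.5)
    )
    pump_art = cfg.pump_amplitude_arterial_mmhg * (
        np.sin(phase + 2.1) + cfg.second_harmonic_ratio * np.sin(2 * phase + 2.6)
    )
    cardiac = cfg.cardiac_amplitude_mmhg * np.sin(
        2 * np.pi * cfg.cardiac_freq_hz * t + 1.0
    )

    gap = np.where(pumped, 0.5 * (flow / a2) ** 2 * c_t / C_SCALE, 0.0)
    arterial = np.where(pumped, map_t - gap + pump_art, cfg.static_baseline_mmhg)
    arterial = arterial + cardiac + rng.normal(0.0, cfg.noise_sd_mmhg, n)
    venous = np.where(
        pumped, cfg.venous_baseline_mmhg + pump_ven, cfg.static_baseline_mmhg
    )
    venous = venous + rng.normal(0.0, cfg.noise_sd_mmhg, n)

    cuffs: list[CuffMeasurement] = []
    cuff_times = np.arange(
        cfg.pump_start_s + cfg.cuff_offset_s, cfg.duration_s - 1.0, cfg.cuff_interval_s
    )
    if cfg.pump_start_s >= 2 * cfg.cuff_offset_s:
        # one pre-pump reading, as in practice where monitoring starts early
        cuff_times = np.concatenate(([cfg.pump_start_s / 2.0], cuff_times))
    for tc in cuff_times:
        true_map = float(np.interp(tc, t, map_t))
        reading = true_map + rng.normal(0.0, cfg.cuff_noise_sd_mmhg)
        delta = float(np.clip(rng.normal(37.0, 3.0), 20.0, 60.0))
        cuffs.append(
            CuffMeasurement(
                time_s=float(tc),
                systolic_mmhg=reading + delta,
                diastolic_mmhg=reading - delta / 2.0,
                map_mmhg=reading,
            )
        )

    session = SessionRecord(
        arterial=PressureTrace(arterial, fs, 0.0, "arterial"),
        venous=PressureTrace(venous, fs, 0.0, "venous"),
        cuffs=cuffs,
        arterial_needle=arterial_needle,
        venous_needle=venous_needle,
        pump=cfg.pump,
        set_flow_ml_min=cfg.set_flow_ml_min,
        session_id=cfg.session_id,
    )

    grid = np.arange(0.0, cfg.duration_s + 0.5, 1.0)
    truth = GroundTruth(
        times_s=grid,
        flow_ml_min=np.interp(grid, t, flow),
        c_value=np.interp(grid, t, c_t),
        map_mmhg=np.interp(grid, t, map_t),
        pump_start_s=cfg.pump_start_s,
    )
    return session, truth


def noiseless(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with all stochastic disturbance terms zeroed."""
    return replace(
        config, noise_sd_mmhg=0.0, cuff_noise_sd_mmhg=0.0, true_c_noise_sd=0.0
    )


def full_session_config(**overrides) -> SimulationConfig:
    """A full-length treatment profile: 4 h at 1 kHz, pump enabled at 2000 s,
    cuffs every 30 min."""
    base = dict(
        duration_s=14400.0,
        pump_start_s=2000.0,
        cuff_interval_s=1800.0,
        cuff_offset_s=300.0,
        session_id="full-session",
    )
    base.update(overrides)
    return SimulationConfig(**base)


#: per-gauge-set flow prescriptions (ml/min): smaller needles (new fistulae)
#: are run at lower blood flows; the pooled range spans 278–394
GAUGE_FLOW_RANGES: dict[int, tuple[float, float]] = {
    14: (325.0, 394.0),
    15: (278.0, 330.0),
    16: (278.0, 310.0),
}


def simulate_cohort(
    n_sessions: int = 11,
    gauge_mix: Optional[dict[int, int]] = None,
    between_session_c_sd: float = 0.5,
    within_session_c_sd: float = 0.5,
    seed: int = 0,
    duration_s: float = 600.0,
    cuff_interval_s: float = 60.0,
    flow_ranges_ml_min: Optional[dict[int, tuple[float, float]]] = None,
    gauge_c_means: Optional[dict[int, float]] = None,
    base_map_mean_mmhg: float = 95.0,
    base_map_sd_mmhg: float = 8.0,
    map_gap_coupling: float = 0.12,
    n_outlier_sessions: int = 0,
    outlier_c_offset: float = 3.5,
    **session_overrides,
) -> list[tuple[SessionRecord, GroundTruth]]:
    """Generate a cohort of sessions mirroring a small feasibility study.

    Each session draws its mean C from the nominal gauge-set mean plus
    between-session variation; within a session C drifts linearly and
    wanders slowly with scale ``within_session_c_sd``.  Flow prescriptions
    are drawn per session from the gauge-dependent ranges and held constant.
    Each patient's baseline MAP couples to the session's nominal arterial
    pressure gap with slope ``map_gap_coupling`` (patients dialysed through
    smaller needles at higher C present higher MAP — the cohort-level
    correlation such feasibility data exhibits), plus independent spread and
    a drawn intradialytic MAP drift.  ``n_outlier_sessions`` sessions (taken
    from the largest-gauge end of the roster, emulating an immature-fistula
    patient) have their true C offset by ``outlier_c_offset``.
    """
    if n_sessions < 1:
        raise InvalidParameterError("n_sessions must be >= 1")
    gauge_mix = dict(gauge_mix or {14: 5, 15: 3, 16: 3})
    if sum(gauge_mix.values()) != n_sessions:
        raise InvalidParameterError("gauge_mix counts must sum to n_sessions")
    if any(g not in GAUGE_SETS for g in gauge_mix):
        raise InvalidParameterError(f"gauge sets must be among {sorted(GAUGE_SETS)}")
    c_means = dict(gauge_c_means or GAUGE_C_MEANS)
    flow_ranges = dict(flow_ranges_ml_min or GAUGE_FLOW_RANGES)
    if n_outlier_sessions > n_sessions:
        raise InvalidParameterError("more outlier sessions than sessions")

    roster = [g for g in sorted(gauge_mix) for _ in range(gauge_mix[g])]
    rng = np.random.default_rng(seed)
    out: list[tuple[SessionRecord, GroundTruth]] = []
    for i, gauge_set in enumerate(roster):
        art_g, ven_g = GAUGE_SETS[gauge_set]
        is_outlier = i >= n_sessions - n_outlier_sessions
        c_sess = c_means[gauge_set] + rng.normal(0.0, between_session_c_sd)
        if is_outlier:
            c_sess += outlier_c_offset
        # C drifts upward through a treatment (ultrafiltration concentrates
        # the blood, raising viscosity); the span scales with the
        # within-session variability setting.
        drift = 2.0 * within_session_c_sd * rng.uniform(0.5, 1.5)
        flow = float(rng.uniform(*flow_ranges[gauge_set]))
        a2 = NeedleSpec(art_g).area_mm2
        nominal_gap = 0.5 * (flow / a2) ** 2 * c_means[gauge_set] / C_SCALE
        base_map = (
            base_map_mean_mmhg
            + map_gap_coupling * (nominal_gap - 300.0)
            + rng.normal(0.0, base_map_sd_mmhg)
        )
        cfg = SimulationConfig(
            duration_s=duration_s,
            set_flow_ml_min=flow,
            true_c_start=max(c_sess - drift / 2.0, 0.5),
            true_c_end=max(c_sess + drift / 2.0, 0.5),
            true_c_noise_sd=within_session_c_sd / 2.0,
            true_c_noise_corr_s=max(cuff_interval_s, 60.0),
            base_map_mmhg=float(base_map),
            map_drift_mmhg=float(rng.normal(-8.0, 4.0)),
            cuff_interval_s=cuff_interval_s,
            arterial_gauge=art_g,
            venous_gauge=ven_g,
            session_id=f"cohort-{i:02d}-{gauge_set}g" + ("-outlier" if is_outlier else ""),
            seed=int(rng.integers(0, 2**31 - 1)),
            **session_overrides,
        )
        out.append(simulate_session(cfg))
    return out
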