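"""Windowing and smoothing primitives.

The method treats both line pressures as quasi-steady-state quantities: the
raw 1 kHz signals are reduced by a trailing 5000-sample (5 s) boxcar before
any frequency estimation or calibration pairing.  The filter is causal —
output sample i averages input samples max(0, i−w+1)..i — because every
downstream consumer is framed as a real-time estimator and must not look
ahead.  At the start of a trace the effective window is simply shorter (a
running mean over the samples seen so far) rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core import PressureTrace
from .errors import InvalidParameterError, OutOfRangeError


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for real-time estimation.

    Defaults follow the method's 5000-sample (5 s at 1 kHz) analysis window,
    advanced by 1000 samples for a 1 s update cadence.
    """

    width_samples: int = 5000
    hop_samples: int = 1000

    def __post_init__(self) -> None:
        if self.width_samples < 2:
            raise InvalidParameterError("width_samples must be >= 2")
        if self.hop_samples < 1:
            raise InvalidParameterError("hop_samples must be >= 1")
        if self.hop_samples > self.width_samples:
            raise InvalidParameterError("hop_samples must not exceed width_samples")


def moving_average(trace: PressureTrace, width_samples: int) -> PressureTrace:
    """Causal (trailing) boxcar mean of a trace.

    Output sample i is the mean of input samples max(0, i−width+1)..i, so
    length, channel and sample rate are preserved and no future samples are
    used.  The first width−1 samples average over a shorter, growing window.
    """
    n = len(trace)
    if width_samples < 1 or width_samples > n:
        raise InvalidParameterError(
            f"width_samples must be in [1, {n}], got {width_samples}"
        )
    x = trace.values
    if width_samples == 1:
        out = x.copy()
        return PressureTrace(
            values=out,
            sample_rate_hz=trace.sample_rate_hz,
            start_time=trace.start_time,
            channel=trace.channel,
            meta=dict(trace.meta),
        )
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - width_samples + 1, 0)
    out = (cs[idx + 1] - cs[lo]) / (idx + 1 - lo)
    return PressureTrace(
        values=out,
        sample_rate_hz=trace.sample_rate_hz,
        start_time=trace.start_time,
        channel=trace.channel,
        meta=dict(trace.meta),
    )


def sliding_windows(
    trace: PressureTrace, spec: WindowSpec
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield (as_of_time, segment) pairs of exactly ``spec.width_samples``.

    Segments advance by ``spec.hop_samples``; a final partial window is
    dropped.  The reported time is that of the segment's *last* sample — the
    time at which a real-time estimate over that window becomes available.
    A trace shorter than one window yields nothing.
    """
    n = len(trace)
    w, h = spec.width_samples, spec.hop_samples
    for start in range(0, n - w + 1, h):
        end = start + w
        as_of = trace.start_time + (end - 1) / trace.sample_rate_hz
        yield as_of, trace.values[start:end]


def value_at_time(trace: PressureTrace, t_s: float) -> float:
    """Sample nearest to ``t_s`` (no interpolation; midpoint ties → earlier)."""
    if len(trace) == 0:
        raise OutOfRangeError("trace is empty")
    x = (t_s - trace.start_time) * trace.sample_rate_hz
    if x < 0 or x > len(trace) - 1:
        raise OutOfRangeError(
            f"t={t_s} s outside trace span "
            f"[{trace.start_time}, {trace.end_time}] s"
        )
    idx = int(np.ceil(x - 0.5))  # round half down: tie goes to earlier sample
    return float(trace.values[idx])
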