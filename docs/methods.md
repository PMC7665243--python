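# Methods

This note records the model, the numerical choices and the design decisions
behind `linebp`, and what the synthetic-data tests do and do not demonstrate.

## Signal model and assumptions

Two pressure channels are assumed, sampled synchronously at 1 kHz in mmHg:
the arterial line near the fistula needle (negative under pump suction) and
the venous air trap (positive). Both are treated as quasi-steady-state
signals: every consumer works on the trailing 5000-sample (5 s) boxcar mean
or on 5 s analysis windows. The filter is causal — output *i* averages
inputs max(0, i−4999)..i — because the method is framed as a real-time
estimator; at the start of a trace the effective window simply grows instead
of padding with fabricated values.

### Pump flow

One pump rotation displaces the volume of line swept by the rollers,
π·r²·Ln, so flow is linear in rotation frequency. The frequency is read off
the venous spectrum per window: DC removal, Hann taper, FFT zero-padded 4×,
in-band argmax, parabolic interpolation on the log-power of the peak and its
neighbours. With 5 s windows the padded bin is ≈0.049 Hz and the interpolated
estimate lands within ~10⁻³ Hz of a dense-grid DFT oracle, comfortably inside
the ±1 % flow band across the clinical 278–394 ml/min range.

Frequencies completing fewer than two periods in the window are not
searched: the effective search band is [max(low, 2/T), high], 0.4–3 Hz for
the defaults. This resolves the tension between a 0.2 Hz nominal band edge
and a 5 s window.

**Pump-off detection.** A window is declared pump-off unless two conditions
hold: (a) the smoothed (≈9 native bins) peak power exceeds `min_peak_snr`
(default 5) times the median smoothed power over the reference band just
above the search band — an estimate of the sensor noise floor, with the
2nd-harmonic region excluded; and (b) at least `min_peak_concentration`
(default 0.9) of the in-band energy lies within the mainlobes of the peak
and its 2nd harmonic. A single peak/median ratio over the narrow in-band
spectrum cannot separate noise from tone at any modest threshold (the raw
periodogram's exponential scatter trips it on ~20 % of pure-noise windows);
the two-part gate measures ~2·10⁻⁴ false positives per white-noise window
with no missed detections on weak-tone fixtures. The floor estimate assumes
the sensor noise spectrum is locally flat between 3 and 9 Hz; strongly
coloured noise would degrade the gate.

**Lobe ambiguity.** The venous fundamental may be the rotation frequency or
the lobe-passing frequency (lobe count × rotation). Both the simulator and
the estimator expose a flag (`pump_waveform_at_lobe_frequency` /
`detected_is_lobe_frequency`, default false = rotation), which must be set
consistently; the default matches the ~1 Hz ↔ ~325 ml/min arithmetic.

### Calibration and estimation

The arterial needle is modelled as a Bernoulli orifice with every
unmodelled and unmeasurable term (discharge coefficient, blood density and
viscosity, upstream geometry, the fistula-to-cuff pressure offset) absorbed
into one lumped coefficient C:

    C = 2 (Pb − P2) / (f / A2)²,        P̂b = P2 + ½ (f/A2)² C.

The two operations are exact algebraic inverses (verified to 1e-10 relative
on 10⁴ random inputs). C is computed in SI (Pa, m³ s⁻¹, m²) and reported in
10³ kg·m⁻³ — numerically g/ml, i.e. the scale of blood density times the
effective loss factor. On this scale a 14g needle at 325 ml/min with a
≈160 mmHg line-to-cuff gap gives C ≈ 6, and typical dialysis needles span
≈5–11, rising with gauge number (smaller lumen). This unit choice is what
makes both realistic line pressures (arterial −70 to −450 mmHg, within a
±15 PSI sensor) and C values of that magnitude simultaneously possible; the
raw mmHg/(ml·min⁻¹·mm⁻²)² ratio would put C near 0.01–0.02 for the same
physics. The conversion constant (133.322 Pa/mmHg · 3600 / 1000 ≈ 479.96) is
a single documented multiplier, so every recovery result is unaffected by
the choice.

Per cuff reading: Pb is the cuff MAP (MAP is the calibrated quantity —
systolic/diastolic are carried but not modelled), P2 is the filtered
arterial pressure at the cuff time (nearest sample, ties to the earlier
one), flow is the nearest *preceding* window estimate and must be at most
`max_flow_age_s` (30 s) old — a staleness guard so cuffs taken after a pump
stop are skipped rather than paired with an obsolete flow. A2 is the
arterial needle area; the venous gauge is metadata that names the gauge set.
The session C is the unweighted mean of point values (median behind
`robust_c`). Continuous MAP is emitted at the flow cadence (1 Hz): finer
output would be spurious given the 5 s averaging. A causal variant
(`causal_c`) uses the running mean of cuffs seen so far, for real-time
emulation.

### Cohort analytics

`group_c_by_gauge` pools point C values per gauge set and flags outliers
beyond median ± 3·MAD (groups under 3 points are never flagged); the core
mean excludes them. The exact membership of a clinical "core grouping"
cannot be reproduced from a rule this simple, but an immature-fistula
session offset by ~3.5 C units is flagged reliably.

`compensated_fit` returns the pooled OLS of cuff MAP on filtered arterial
pressure together with the same fit after recomputing each point's arterial
coordinate with the session-mean C (p2′ = pb − ½(f/A2)²C̄). Recomputing the
*arterial* coordinate removes within-session C wander from the scatter;
replacing the MAP coordinate with the model prediction would instead inject
that wander into y and systematically worsen the fit, so it is not used.
With C constant within every session the two fits coincide (to the ~1e-4
wobble of the windowed flow estimates). Fits report slope, intercept, RMSE,
R² and the slope p-value; a constant response returns slope 0/R² 0, a
constant predictor is an error.

## The simulator

The arterial trace is generated *from* the inverted model —
p2(t) = map(t) − ½(flow(t)/A2)²·c(t) — plus additive disturbance terms, so
the model is exactly recoverable in the noiseless limit and every test has
ground truth. Disturbances and their defaults:

| term | default | note |
|---|---|---|
| venous baseline | +150 mmHg | pump-on; +20 mmHg static before pump start |
| pump oscillation | 30 mmHg venous / 40 mmHg arterial, 2nd harmonic 0.3× | phase-continuous across flow steps |
| cardiac component | 1.2 Hz, 5 mmHg, arterial only | non-harmonic with the 1 Hz pump by default; set equal to expose the known coincident-frequency failure mode |
| sensor noise | 1 mmHg white, both channels | |
| cuff noise | 2 mmHg on MAP | systolic/diastolic synthesised at a plausible pulse pressure around MAP |
| true C | constant 6, optional linear drift + slow wander | |
| MAP profile | 93 mmHg, optional linear drift and raised-cosine hypotensive dips | |
| cuffs | every 1800 s (60 s intervals in scaled tests), first at pump start + 60 s | one pre-pump cuff when the pump starts late, exercising the skip path |

Test sessions default to 600 s (a full 4 h profile is provided by
`full_session_config`); cohorts are 11 sessions with gauge sets 5×14g,
3×15g, 3×16g (the 16g set pairs a 15g arterial needle, as in clinical
practice for new fistulae), gauge C means 6 / 8.5 / 10.25, between-session
C sd 0.5, and flow prescriptions drawn per gauge (14g 325–394, 15g 278–330,
16g 278–310 ml/min — smaller needles run slower; pooled range 278–394).
Within a session C drifts upward (span 2·sd·U(0.5, 1.5), sd 0.5 by default)
— ultrafiltration concentrates the blood and raises viscosity through a
treatment — plus slow zero-mean wander. Each patient's baseline MAP couples
to the session's nominal pressure gap (slope 0.12, residual sd 8 mmHg):
small cohorts of this kind show a strong pooled MAP-vs-line-pressure
correlation, which is a property of the cohort, not of physiology, and is
encoded as such. Under these conditions the compensated fit raises R² and
moves the slope by only 2–4 %.

**What the simulator does not contain:** real hemodynamics (no Windkessel,
no ultrafiltration-driven MAP dynamics beyond scripted dips), patient
movement or needle-repositioning artifacts, coloured sensor noise, pump
speed servo dynamics, or any coupling between cardiac output and line
pressures. Passing tests therefore demonstrate correct inversion,
calibration statistics and detection behaviour under the stated disturbance
model — not clinical accuracy on real treatments.

## Numerical choices and edge cases

* Moving average via cumulative sums, O(n); width 1 is an exact identity;
  width beyond the trace length is an error.
* Sliding windows drop the final partial window; each window is stamped with
  the time of its last sample (the real-time "as of" moment).
* The 5000-sample boxcar nulls the pump oscillation exactly only when the
  window spans an integer number of pump periods (e.g. 325 ml/min ↔ 1 Hz);
  elsewhere up to ~2 mmHg of ripple leaks into filtered P2, which is the
  dominant error floor of the noiseless recovery tests.
* Flow-series gaps (pump off, no coherent peak) are represented as absent
  estimates, never zeros; the continuous MAP trace carries NaN there.
* Simulated sessions are bit-reproducible for a given seed; cohort session
  seeds are derived from the master seed below 2³¹.
* CSV traces round-trip bit-compatibly (`repr` floats on write,
  `float_precision="round_trip"` on read); timestamp uniformity is enforced
  to 1e-9 s jitter at the metadata sample rate.

## Known limitations

* MAP only — systolic/diastolic reconstruction is out of scope.
* A single session-level C (or its causal running mean); iterative/adaptive
  updating and nonlinear or time-variant models are not implemented.
* Pump-off detection has a measured ~2·10⁻⁴ per-window false-positive rate
  on white noise; a temporal-consistency debounce would lower it further but
  would add latency and is left out.
* When the patient's heart rate coincides with a pump harmonic, the cardiac
  component biases the frequency estimate; the estimator does not attempt
  to separate the two (the simulator can reproduce the condition).
* The gauge→inner-diameter table (14g 1.60 mm, 15g 1.37 mm, 16g 1.19 mm)
  follows common dialysis-needle conventions and is overridable everywhere;
  unknown gauges require an explicit inner diameter.
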