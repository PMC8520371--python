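# Methods

## Detection model

The detector treats the demodulated Doppler audio of the fetal heart as a
cyclostationary random signal: its waveform is noisy and variable, but its
envelope repeats once per cardiac cycle. Heart rate is therefore estimated
from envelope periodicity, not from any waveform feature.

**Demodulation.** Full-wave rectification followed by a 4th-order
zero-phase Butterworth low-pass at 10 Hz and polyphase decimation to an
envelope rate of 1000 Hz. Ten hertz comfortably passes the beat
fundamental (0.8–4 Hz over the 50–240 bpm search range) and its first
harmonics while rejecting the Doppler carrier content. The zero-phase
filter can undershoot near sharp pulses, so the envelope is clipped at
zero; the autocorrelation operates on a mean-removed copy.

**Autocorrelation.** The biased estimator
R(m) = (1/N) Σ x(n) x(n+m) over a window of N envelope samples. The 1/N
normalisation guarantees R(0) is the global maximum, so R(m)/R(0) is a
well-defined periodicity confidence in [0, 1]. It is computed by FFT
correlation; tests hold it to the time-domain double-loop sum at 1e-9
relative (measured agreement is at machine precision).

**Rate lookup.** Candidate rates on a 50–240 bpm grid with 1 bpm step are
mapped to lags S = round(60 f_s / R_f), precomputed once per envelope
rate. Consecutive rates that round to the same lag are collapsed keeping
the lowest rate, so each usable lag carries one label. The detector
samples R only at table lags and reports the rate of the maximum; ties
resolve to the lower rate (the longer period — fundamental over
harmonic).

**Envelope rate choice.** The lag grid quantises rate as
ΔR ≈ R²/(60 f_s) between adjacent lags. At 200 Hz the spacing at 240 bpm
is ≈4.7 bpm — adjacent integer lags label 240 and 235 bpm — which is too
coarse to resolve the top of the clinical range. The default envelope
rate is therefore 1000 Hz, giving ≤ ~1 bpm quantisation at 240 bpm while
the table stays small (≤ 1200 lags) and a 4-s window costs a single
4000-point correlation.

**Octave guard.** An envelope with two similar sounds per beat (valve
opening and closing) can put its strongest autocorrelation peak at the
half period, doubling the rate. The guard compares bias-corrected values
R(m)·N/(N−m) at the winning lag and at twice that lag and moves to the
doubled lag only under strict dominance (corrected ratio > 1.05). The
bias correction and strict inequality matter: for a genuinely periodic
envelope the *raw* biased estimator satisfies R(2P)/R(P) = (N−2P)/(N−P),
which exceeds 0.9 for all rates above ~165 bpm at a 4-s window — a
threshold test on raw values would systematically halve correct high
rates, while corrected values are equal at P and 2P for a pure periodic
signal and the guard stays quiet.

**AMDF estimator.** D(m) = (1/(N−m)) Σ |x(n) − x(n+m)|, minimised over
the same table. D vanishes at the period *and at every multiple of it*,
so the raw minimum can sit at 2P or 3P (with a 1200-lag table, 3P is in
range for rates ≥ 150 bpm). The subharmonic guard collects all table lags
whose dip is within 5% of the series range of the global minimum, keeps
the cluster around the shortest such lag, and reports its deepest point —
locking onto the fundamental. AMDF confidence is 1 − D(S*)/max D.

**Tracking.** A 4-s window with 1-s hop (≥ 2 beat periods at the 50 bpm
search floor), one estimate per window, then a 3-point median smoother
over the rate series with `no_signal` windows excluded; status is
re-derived from the smoothed rate. Windows whose normalised peak falls
below 0.3 report `no_signal` rather than a spurious rate.

**Classification.** Rates in the inclusive 120–160 bpm band are `normal`;
anything outside is `distress`. The bounds are inclusive so that a rate
measured exactly at a limit is not flagged.

## Simulator

The simulator generates the signal the detector assumes: a cardiac wall
velocity trace of one raised-cosine systolic pulse per beat (width 30% of
the cycle — band-limited, with an unambiguous envelope period), mapped
through f_D = 2 v f₀ cosθ / c to an instantaneous frequency, emitted as a
tone amplitude-modulated by the normalised speed profile, plus additive
white Gaussian noise scaled to the requested SNR over the clean-signal
power. Defaults — 2 MHz carrier, 1540 m/s sound speed, 0.15 m/s peak
velocity, 4 kHz audio rate — are typical fetal-Doppler values chosen as
implementation defaults. Synthesis refuses configurations whose peak
Doppler shift exceeds half the sampling rate.

What the simulator does **not** model: RF/quadrature ultrasound physics,
transducer response, maternal-heartbeat and movement interference,
beat-to-beat variability, or the double heart sound per cycle of real
fetal Doppler audio. Passing recovery tests therefore demonstrates
correctness of the periodicity estimator under the stated noise model,
not clinical performance on recorded signals.

## Umbilical waveform typing

A velocity trace is segmented into cycles of 60/HR seconds; the
end-diastolic velocity (EDV) of a cycle is the minimum over its final
20%. A cycle is *abnormal* when EDV ≤ 0.5 cm/s — a configurable dead band
around zero, since clinical machines cannot resolve a true zero velocity.
No abnormal cycle → Type I; all cycles abnormal ("continuous") → Type II;
a mixture ("intermittent") → Type III. The continuous/intermittent
boundary (`abnormal_threshold`, default 1.0) is configurable; at least 3
complete cycles are required, a floor rather than a clinically validated
strip length. The SGA screen is strict: weight must be *below* the
interpolated 10th percentile. The bundled growth table is a synthetic
demonstration reference of plausible magnitude; real assessments must
supply a population-appropriate standard as CSV.

## Cohort statistics

Group comparisons are computed from (mean, SD, n) summaries so printed
tables can be checked without raw data. The default t-test is pooled
variance (Student), with Welch available by flag. Percentages use
half-up rounding to one decimal, matching the count(percent) convention
of clinical tables. The Mann-Whitney Z uses midranks with the standard
tie-corrected variance and no continuity correction; a p printed as
"0.000" is treated as p < 0.0005. For 2×2 tables, Fisher's exact test is
used whenever any expected cell count is below 5 (small cohort tables
routinely contain cells of 0 or 1) and chi-square with Yates correction
otherwise; which rule produced any particular published p is generally
unstated, so the switch is an explicit, documented choice.

One caveat the tests encode: recomputing the control-group larger-vs-
smaller twin comparison (2362 ± 546 vs 2112 ± 553, n = 32 per group) as
an unpaired pooled t gives ≈1.82, not the 1.567 sometimes reported for
such cohorts — consistent with an unstated within-pair pairing. The
package deliberately does not use that value as a check; the sFGR-group
comparison (t ≈ 5.65) is reproduced from its summaries.

## Numerical choices and limitations

* Problem sizes in the test suite and reproduction script — 8-s signals,
  4-s windows, 10–20 noise seeds per rate, 200 noiseless fixtures —
  are chosen to give stable pass/fail behaviour at second-scale runtimes.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; fixture generation derives per-file seeds from one base
  seed and is byte-reproducible.
* CSV signal files store full `repr` precision and round-trip exactly;
  WAV round-trips to within 16-bit quantisation of the peak-normalised
  signal.
* The detector assumes a quasi-stationary rate within each window; a step
  change in rate produces a monotone transition over the windows that
  straddle it rather than an instantaneous jump.
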