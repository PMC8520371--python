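# fhrdop — ultrasound-Doppler fetal heart rate detection

`fhrdop` is a signal-processing toolkit for fetal cardiotocography built
around the classic autocorrelation heart-rate detector used in
ultrasound-Doppler fetal monitors, together with the clinical companions a
monochorionic-twin growth-restriction workup needs: umbilical-artery
waveform typing and cohort-level comparison statistics. It is aimed at
biomedical-signal engineers validating detector behaviour against known
ground truth, and at anyone reproducing the summary statistics of twin
selective-fetal-growth-restriction (sFGR) cohorts.

## The method

A Doppler probe transmitting at carrier frequency *f₀* returns an echo
from the moving fetal heart wall offset by the Doppler shift

```
f_D = 2 v f₀ cos(θ) / c
```

(*v* wall velocity, *θ* beam angle, *c* speed of sound in tissue). The
audible Doppler signal pulses once per heartbeat, so after full-wave
rectification, low-pass filtering and decimation to an envelope rate
*f_s*, the heart period shows up as the peak of the biased autocorrelation
over a window of *N* envelope samples:

```
R(m) = (1/N) Σₙ x(n) x(n+m)
```

Instead of searching every lag, a candidate heart rate *R_f* (beats/min)
is mapped to its lag ("serial number")

```
Sₙ = round(60 f_s / R_f)
```

and a precomputed table over the search grid (50–240 bpm by default) lets
the detector sample R only at those lags and report the rate of the
maximum. An average-magnitude-difference (AMDF) estimator,
`D(m) = (1/(N−m)) Σ |x(n) − x(n+m)|`, minimised over the same table, is
available as a cheaper alternative. Estimated rates inside 120–160 bpm
are classed `normal`; outside, `distress`.

The package also:

* simulates Doppler audio with known ground-truth rate, SNR and beam
  geometry (`fhrdop.simulate`);
* types umbilical-artery velocity traces into sFGR Doppler classes —
  Type I (positive end-diastolic flow), Type II (continuously absent or
  reversed), Type III (intermittently absent or reversed) — and screens
  estimated fetal weight against a 10th-percentile growth reference
  (`fhrdop.umbilical`);
* reproduces cohort tables from printed summaries: two-sample t from
  mean ± SD, count(percent) cells, tie-corrected Mann-Whitney Z, and a
  Fisher/chi-square rule for small 2×2 tables (`fhrdop.cohortstats`).

## Worked example

```
$ fhrdop simulate --hr 140 --snr 10 --duration 8 --seed 1 -o sig.wav
wrote sig.wav: 8 s at 4000 Hz, truth 140 bpm
$ fhrdop detect sig.wav --window 4 --hop 1
window_start_s,bpm,confidence,status
0,140,0.8990,normal
1,140,0.8878,normal
2,140,0.8903,normal
3,140,0.8969,normal
4,140,0.8883,normal
```

Each line is one 4-s analysis window: its start time, the heart rate of
the table-sampled autocorrelation maximum after 3-point median smoothing,
the peak value normalised by R(0) (a periodicity confidence in [0, 1] —
windows below 0.3 report `no_signal`), and the 120–160 bpm band check.
The simulated truth of 140 bpm is recovered exactly in every window at
10 dB SNR.

The same from Python:

```python
from fhrdop import DopplerConfig, synthesize_doppler, track

sig = synthesize_doppler(DopplerConfig(heart_rate_bpm=140, snr_db=10, seed=1))
for est in track(sig):
    print(est.window_start_s, est.bpm, est.status)
```

And the cohort statistics — the larger vs smaller twin birth weights of a
23-pair sFGR cohort, from the printed summaries alone:

```
$ fhrdop stats t --mean1 2119 --sd1 454 --n1 23 --mean2 1444 --sd2 350 --n2 23
t=5.647 df=44 p=1.111e-06
```

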