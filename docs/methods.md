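# Methods

## Signal model and artifact estimator

The observed bipolar EGG is modelled as `y = x + e`: an additive motion
artifact `x` on top of the gastric component `e`. Over a window spanning
one average slow-wave cycle the gastric component is assumed zero-mean
with constant variance σ²ₑ. Under that assumption the linear minimum
mean-squared error estimate of the artifact at each sample is

    x̂[t] = E[y][t] + g[t] (y[t] − E[y][t]),
    g[t]  = max(0, Var(y)[t] − σ²ₑ) / max(Var(y)[t], σ²ₑ),

where E[y] and Var(y) are the local mean and population variance of the
observation and σ²ₑ is estimated as the time-average of the local
variance. The two `max` guards handle windows whose sample variance
falls below σ²ₑ (statistically possible even though Var(y) = Var(x) + σ²ₑ
in the model): there the gain is clamped to zero and x̂ reduces to the
local mean, so subtracting it is local detrending. Inside a burst
Var(y) ≫ σ²ₑ, the gain approaches (but never reaches) one, and the burst
is subtracted. The cleaned signal is `e = y − x̂`, stored as the exact
floating-point difference so the additive decomposition holds to machine
precision by construction.

Assumptions and consequences:

* The estimator is purely local; it adapts to non-stationary signal,
  artifact and noise statistics, needs no training data, and does not
  discard data segments (important when features must stay aligned to
  logged events). It cannot recover the EGG during *sustained* artifacts
  (e.g. continuous vigorous movement), where the local statistics are
  artifact-dominated for longer than a window.
* σ²ₑ is a single global constant per record. Records whose quiet-region
  variance changes drastically over hours are handled adequately because
  the gain depends on the *ratio* of local variance to σ²ₑ, but a
  per-epoch σ²ₑ would be a natural extension.
* Local moments use centered sliding windows with shrinking windows at
  the record edges (no fabricated padding). A disjoint-block mode
  (`mode="block"`) is provided for comparison with blockwise
  formulations; sliding windows avoid discontinuities at block edges and
  are the default.
* Population variance (divide by n) is used; the estimator only needs a
  consistent convention.
* The window length is `round(fs / f_peak)` forced odd for exact
  centering — 101 samples (20.2 s) at 5 Hz with the default 0.05 Hz
  mean peak frequency. `f_peak` may alternatively be estimated from the
  data (spectral peak in the gastric band) and passed explicitly.
* Degenerate inputs: a constant signal has Var(y) = σ²ₑ = 0; the gain is
  defined as 0 there (a constant carries no artifact beyond its mean)
  and a warning is emitted.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| analysis rate | 5 | Hz | 25× oversampled for a 0.20 Hz band; keeps windows small |
| peak frequency | 0.05 | Hz | normal 3 cpm gastric rhythm; sets window n = 101 |
| spectrogram window | 240 | s | 1/240 Hz resolution separates 2, 3, 4 cpm |
| overlap | 0.75 | – | 60 s feature hop, matched by the motility index |
| taper | Hamming | – | standard leakage control at this resolution |
| signal band | 0.04–0.06 | Hz | slow-wave power |
| background band | 0.06–0.10 | Hz | noise reference for normalized power |
| analysis band | 0.02–0.20 | Hz | dominant-frequency search range |
| normal band | 2–4 | cpm | conventional normal gastric rhythm |
| motility threshold | 9 | mmHg | supra-threshold pressure area |
| area floor | 1 | mmHg·s | motility index floor ln(1) = 0 for quiet windows |
| significance | 0.01 | – | two-sided, Bonferroni-adjusted by channel count |

All of these live in `PipelineConfig`; operations take them as arguments
and hard-code nothing.

## Spectral conventions

Segments are mean-removed before tapering (prevents DC leakage into the
0.02 Hz bin), transformed at native resolution (no zero padding), and
reported as 10·log₁₀ of one-sided power density with a −120 dB floor
guarding exact zeros. Only dB *differences* enter any feature, so the
reference cancels. Window counts follow floor((L − W)/hop) + 1 and times
are window centers, which event alignment interpolates against. Band
membership is by bin-center inclusion in the closed band. Two
consequences worth knowing: a sinusoid exactly on a bin center under a
periodic Hamming taper occupies only three bins (its immediate
neighbors are numerically zero and sit at the floor), and dB-domain
averaging across bins is sensitive to deep noise nulls — the per-window
normalized power of a realistic record fluctuates by a few dB
regardless of the absolute noise level, which is why event-aligned
curves are averaged across repeated events before interpretation.

SNR averages dB values (not linear power) across bins and windows; a
linear-averaging variant would differ by Jensen's inequality but every
comparison in the package is internally consistent.

## Motility index and association statistics

Per window (identical framing to the spectrogram), the supra-threshold
area is the rectangle-rule sum Σ max(p − 9, 0)/fs in mmHg·s, and the
motility index is ln(max(area, 1)). Rectangle integration makes the
closed forms exact (a constant 10 mmHg window of 240 s gives exactly
240 mmHg·s); the floor keeps contraction-free windows finite at 0 and is
flagged in the output. Pressure is assumed baseline-corrected; no
intragastric baseline estimation is attempted.

EGG power (dB) vs motility index uses ordinary least-squares regression;
the p-value tests the zero-slope null and is Bonferroni-adjusted as
min(1, m·p) for m pressure channels. Paired and unpaired (pooled
variance) two-sided t-tests cover across-subject comparisons; a paired
comparison with constant nonzero differences is reported as (±inf, 0)
rather than failing, while identical samples raise.

## The simulator: what it emulates, and what it does not

`simulate_egg` builds records as an exact sum of labelled components:

* slow wave: amplitude-modulated sinusoid at the configured rate
  (default 3 cpm, 100 µV — mid-range of the physiological 50–200 µV);
* contraction envelope: smoothed log-normal around 1 (log-SD
  `envelope_sigma`, correlation time `envelope_timescale_s`). σ = 0.5
  and 600 s in the coupled-manometry scenario, where inter-window power
  variability is the point; σ = 0 in recovery scenarios where amplitude
  modulation unrelated to the effect under test would only be a
  confounder, and σ = 0.1 in the general ambulatory scenario;
* artifacts: raised-cosine-edged (Tukey) pulses of random polarity,
  0.5–5 s and 1–5 mV by default, placed uniformly with a Poisson count
  (or an exact count when a scenario fixes one);
* drift: white noise low-passed below 0.01 Hz, scaled to a target RMS;
* noise: white Gaussian, 20 µV RMS by default.

`simulate_coupled_manometry` drives antral pressure bumps (half-wave
squared, locked to the slow-wave rate) with the same envelope on a
5 mmHg baseline, so windows with a strong EGG envelope exceed the 9 mmHg
threshold and the motility index is coupled to EGG power by
construction. `simulate_ambulatory_day` adds meal gains (+6 dB at meal
completion, decaying linearly in dB to baseline over 3.5 h; overlapping
meals add with a warning) and a circadian frequency profile (2.74 cpm
during the sleep interval, 2.91 cpm awake, smooth two-minute
transitions), and emits the matching event log.

What the simulator does **not** model: biophysical dipole propagation
across the electrode array (multichannel records are a shared source
plus independent noise), spatially correlated noise, electrode pops or
baseline steps, catheter migration, and artifact statistics of any
specific activity pattern. Passing the simulation-based checks therefore
demonstrates that the pipeline recovers the structures it claims to
recover under realistic amplitude/noise/artifact scales — not that any
clinical threshold (e.g. the 70 % percent-normal cutoff) transfers to
patient data.

## Numerical choices

* The vectorized local-moment computation (strided sliding windows) is
  bitwise-identical to a per-sample loop, which the tests exploit for
  exact oracle comparisons.
* `e = y − x̂` is the stored exact difference; re-addition is checked at
  ≤ 4 eps · max|y|.
* Downsampling uses a zero-phase FIR low-pass (cutoff 0.4 × target rate)
  before decimation, preserving the analysis band without phase
  distortion; CSV round-trips print 17 significant digits and parse with
  round-trip float precision, so file I/O is value-exact.
* Ties in best-pair selection break toward the earlier pair in label
  order; all-identical channels return the first pair with a warning.
* Simulation checks aggregate where single realizations are dominated by
  sampling flutter: the burst-suppression battery averages ten seeded
  replicates, and meal-response recovery pools the isolated meals of
  three simulated days (nine meals), mirroring the multi-recording
  pooling such analyses use in practice.

## Scope limits

File I/O is plain CSV/TSV with JSON sidecars and JSON-lines event logs;
no EDF or vendor formats. No ICA or supervised artifact classification,
no real-time processing, no propagation/phase mapping across the array,
and no clinical interpretation beyond the computed metrics.
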