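# Methods

This document records the model behind the synthetic generator, the exact
conventions used by each pipeline stage, and the package's own parameter
choices (with the reasoning), so that every number in the code is either a
documented interface constant or derivable from this file.

## Signal model

A recognition-tunnelling trace is a pair of synchronously sampled channels
(20 µs interval → 25 kHz Nyquist): the tunnel current in pA and the z-piezo
servo position in arbitrary units. The current fluctuates around a 4 pA
servo setpoint; analyte binding events appear as bursts of upward spikes.

The generator composes a trace as:

- **Baseline + noise.** White Gaussian noise (σ = 1 pA default) around the
  4 pA baseline. The z channel carries white readout noise plus three slow
  (0.2–1 Hz) drift sinusoids.
- **Cluster arrivals.** Poisson with rate λ(c) = λ_max·(c/K_d)/(1+c/K_d);
  λ_max = 0.5 s⁻¹ and K_d = 0.74 µM by default. Without a concentration
  the saturated rate is used. λ_max = 0.5 was chosen because at 2 s⁻¹
  neighbouring clusters merge often enough that clean peaks are dragged
  into contaminated clusters, biasing the planted-filter recovery.
- **Class draw per cluster.** Analyte weights from the run's mixture; the
  water/common class is mixed in at `water_fraction` (default 0.5 —
  half of all spikes in an analyte run are chemistry-independent). An
  explicit `{"water": 1.0}` mixture is a buffer-only control run.
- **Telegraph waveform.** Each cluster holds 1+Poisson(4) spikes:
  exponential on/off dwells (class-specific means), lognormal amplitudes
  (class-specific log-mean/log-sd), within-spike noise of 0.08·amplitude,
  the whole cluster low-passed by a one-pole filter at the class's
  spectral corner. Amplitude and arrival rate are multiplied by one
  lognormal junction effect (σ = 0.2) per junction — the dominant source
  of junction-to-junction heterogeneity and the reason leave-one-junction-
  out accuracy is below the optimistic protocol.
- **Servo artifact.** A fraction of clusters (default 10%) are
  "contaminated": the z channel tracks the 800 Hz low-passed cluster
  current (scaled to 3× its s.d.), making the two channels strongly
  correlated over the cluster span while the current is untouched. An
  earlier design that injected a shared sinusoid into *both* channels was
  rejected: the injected component was itself harvested as spurious
  sub-threshold peaks, so the rejected fraction no longer matched the
  planted fraction. Any injection that correlates the channels suffices
  for the filter's purpose; this one keeps the current channel clean so
  planted-vs-recovered comparisons are exact.

Default class profiles (median amplitude, mean on-dwell, spectral corner):
alphaMGlu 48 pA / 1.0 ms / 3 kHz (capture weight 1.8), betaMGlu 40 pA /
1.6 ms / 2 kHz, water 34 pA / 0.4 ms / 8 kHz. The analytes overlap in any
single property; the water class is deliberately well separated (amplitude
log-sd 0.22 vs 0.35) because the common-class filter's planted-recovery
check presumes a control class the SVM can reject with high confidence —
with milder separation the filter's true-positive rate at posterior 0.7
fluctuated between 0.84 and 0.97 across junction draws and the rejected
fraction centred points below the planted 50%.

## Detection conventions

- Baseline subtraction shifts the 4 pA setpoint to zero.
- A peak is a maximal run of samples **strictly above** 15 pA; boundaries
  walk outward to the zero-crossing or enclosing valley; the apex is the
  earliest maximal sample; width counts samples above half maximum.
- Cluster segmentation: place a unit-height Gaussian (4096 samples full
  width, σ = 4096/6) at every apex, sum, and cut clusters where the sum
  exceeds 0.1. The implementation sums a truncated kernel per apex
  (truncation where the tail is 1e-9 of the threshold, so no threshold
  crossing can move by even one sample); tests verify equivalence with
  the dense brute-force summation and the closed-form single-peak
  half-span σ·√(2·ln 10) ≈ 1465 samples.
- Sub-threshold harvest: local maxima inside a cluster span with amplitude
  in (5 pA, 15 pA] and prominence ≥ 2.5 pA join the cluster flagged
  `subthreshold`. The prominence floor (half the noise floor) is this
  package's choice: without it, baseline-noise wiggles riding on spike
  tails were counted as spikes.

## Feature registry (264)

81 time-domain: 21 per-peak (amplitude, widths, rise/fall, asymmetry,
roughness, moments, slopes, intervals, sub-threshold flag), 40 member
statistics (8 member properties × 5 statistics), 20 cluster-level extras
(counts, rates, occupancies, duty cycle, CVs). 183 spectral: 10-bin peak
FFT, 61-bin cluster FFT, 51-bin wide-band FFT, 61-bin cepstrum. Every FFT
bin set divides 0→Nyquist into equal-width bins of the mean magnitude
(mean removed first, no taper); the 10-bin peak partition therefore puts
7.5–10 kHz in bin index 3. The cepstrum is the magnitude FFT of the power
spectrum, averaged into equal quefrency bins. Cluster- and trace-scope
values are replicated onto member spike rows, so every row carries all
264 columns.

Normalization is per-column standardization (mean 0, sd 1 with ddof = 1);
statistics are always computed on training data only and applied to
held-out rows; constant columns map to 0.

## Filters

- **z-piezo:** Pearson |r| between current and z over the cluster span;
  clusters with |r| > 0.1 are rejected wholesale (every member spike).
  At the default planted contamination this removes ≈10% of peaks
  (10.9–11.5% across seeds; the small upward bias comes from cluster
  merging pulling clean peaks into contaminated clusters).
- **Common-class:** an SVM trained on control runs (analyte standards +
  buffer-only water runs measured on the *same junctions*) scores every
  spike; water-posterior > 0.7 rejects the spike. Sharing junctions
  between calibration and analyte data is deliberate — standards and
  unknowns are measured on the same physical junctions, and cross-junction
  calibration collapsed the filter's precision. At the default 50% water
  mixing this removes ≈48% of spikes.

## Classification protocols

- *Optimistic*: stratified random 10% of all spikes trains; the rest is
  scored. An upper bound (the training set spans every junction).
- *Predictive*: leave-one-junction-out; normalization and (when used)
  feature selection are computed inside each training fold.

Grid search over (C, γ) uses stratified k-fold accuracy with ties broken
toward the smallest C then the smallest γ; posteriors are Platt-scaled.

## Quantitation

Counts per concentration are converted to rates, normalized by the rate at
the highest concentration, and fitted to f(x) = a·bx/(1+bx) by
Levenberg–Marquardt (initialization a₀ = max(y), b₀ = 1/median(x)).
K_d = 1/b; its standard error is delta-method (se(b)/b²) and the 95% CI
uses the t quantile with n−2 df — with ~10 concentration points the normal
quantile under-covered (89–90/100 replicates) while the t interval covers
94/100. A nonparametric bootstrap CI is available. The two-site bound
squares the molar K_d: (4×10⁻³ M)² = 1.6×10⁻⁵ M = 16 µM.

## Acceptance-statistic problem sizes (package choices)

- **t2** (K_d recovery): 100 replicates, 10 concentrations 10 nM–500 µM,
  600 s per point, Poisson counts drawn directly from the rate law.
- **t4** (z-piezo recovery): 120 s traces pooled until ≥ 2000 clusters
  (~25 traces, ~10⁴ peaks), giving a binomial s.e. well inside the ±3 pp
  tolerance.
- **t5** (common-class recovery): pooled over 6 replicate experiments
  (fresh junction-effect draws, 90 s runs, 4 junctions), because a single
  4-junction draw leaves several points of spread in both the detected
  water fraction and the filter's true-positive rate; the calibration set
  is class-balanced (water controls at double duration) so the Platt
  posterior is not biased against the control class.

## Limitations

- The generator's telegraph/lognormal model is a caricature: real RT
  spike trains show heavier-tailed amplitude distributions, baseline
  wander, and junction drift within a run, none of which are modelled.
- Spikes are planted independently per cluster; overlapping clusters of
  different classes merge at detection and their cluster-scope features
  mix, a small (~5%) contamination the filters must absorb.
- The common-class rejection fraction equals the planted fraction only to
  within the filter's true-positive rate (≈0.95–1.0 with the default,
  well-separated water profile); it is a planted-recovery check, not an
  unbiased estimator.
- Classification accuracies on synthetic data are not comparable to
  experimental headline numbers; only orderings (optimistic ≥ predictive)
  and chance-level controls are meaningful.
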