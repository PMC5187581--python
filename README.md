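# rtpipe

Analysis pipeline for recognition-tunnelling (RT) single-molecule
spike-train data, with a matched synthetic-data generator for end-to-end
validation.

In an RT experiment a chemically functionalized tunnel junction produces a
baseline current (~4 pA at the servo setpoint); transient analyte binding in
the junction produces bursts ("clusters") of current spikes whose
amplitudes, kinetics and spectral content depend on the bound molecule.
`rtpipe` turns raw two-channel traces (current + z-piezo servo position)
into per-spike class calls and binding-constant estimates:

1. **Detection** — baseline subtraction, strict 15 pA threshold crossing,
   cluster segmentation by summed unit-height Gaussian windows (4096
   samples full width, clusters where the sum exceeds 0.1), plus harvesting
   of sub-threshold spikes inside cluster spans.
2. **Featurization** — 264 features per spike: 81 time-domain (21 per-peak,
   60 per-cluster) and 183 spectral (10-bin peak FFT, 61-bin cluster FFT,
   51-bin wide FFT, 61-bin cepstrum), all FFT bins equal-width over
   0–25 kHz (20 µs sampling).
3. **Filtering** — clusters whose current correlates with the z-piezo
   channel (|r| > 0.1) are servo artifacts and are dropped wholesale;
   spikes a control-trained SVM assigns to the water/common class with
   posterior > 0.7 are dropped as chemistry-independent background.
4. **Selection** — correlation pruning (|r| > 0.7, one representative per
   connected component), then ranking by out-group/in-group histogram
   fluctuation (L1 distance, 50 bins), then smallest top-k subset within
   0.5 pp of the best cross-validated accuracy.
5. **Classification** — RBF SVM, grid-searched (C, γ), Platt posteriors.
   Two evaluation protocols: *optimistic* (train on a stratified 10% of all
   spikes) and *predictive* (leave-one-junction-out with fold-internal
   normalization — no leakage from the held-out junction).
6. **Quantitation** — spike-cluster rates vs concentration fitted to the
   Langmuir isotherm f(x) = a·bx/(1+bx) by Levenberg–Marquardt;
   K_d = 1/b with delta-method SE and t-based 95% CI.

The synthetic generator (`rtpipe.synthetic`) produces ground-truth-labelled
traces from the same physical picture: Poisson cluster arrivals whose rate
follows a Langmuir isotherm in concentration, two-state telegraph waveforms
with exponential dwells, lognormal amplitudes, class-specific one-pole
spectral shaping, lognormal junction-to-junction effects, a water/common
class mixed into analyte runs, and servo-correlated contaminated clusters
(the z channel tracks the low-passed cluster current).

## Quick start (library)

```python
from rtpipe import (GeneratorConfig, PipelineConfig, generate_trace,
                    detect_events, extract_features, evaluate_optimistic)

cfg = GeneratorConfig(duration=30.0)
trace, truth = generate_trace(cfg, "j0", {"alphaMGlu": 1.0}, seed=1,
                              label="alphaMGlu")
clusters, shifted = detect_events(trace, PipelineConfig())
table = extract_features(trace, clusters, shifted)
print(table.shape)   # (n_spikes, 5 metadata + 264 feature columns)
```

## Quick start (CLI)

```bash
# simulate a 2-junction anomer dataset and run the full pipeline
printf 'generator:\n  duration: 12.0\n  n_junctions: 3\n' > cfg.yaml
rtpipe all --config cfg.yaml --seed 7 --out out/
cat out/evaluation.tsv
```

A run with the config above prints (numbers from an actual run, seed 7):

```
  protocol       scope  accuracy_pct
optimistic         all         81.8
predictive      pooled         79.4
predictive held_out=j0         88.9
predictive held_out=j1         80.0
predictive held_out=j2         65.4
```

Optimistic exceeding predictive is the expected ordering under
junction-to-junction heterogeneity. Individual stages are also exposed:
`rtpipe simulate | detect | featurize | select | train | evaluate |
classify | quantify | make-fixture`; see `rtpipe --help`.

Named dataset presets (`rtpipe make-fixture --preset ...`):
`anomer_pair`, `ten_class_pool` (ten monosaccharide profiles),
`concentration_series`, `contamination_stress`.

## Tests

```bash
python -m pytest -q           # full suite, ~12 min single CPU
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(feature-count contract, K_d CI coverage over 100 replicates, two-site
bound arithmetic, planted-filter recovery, Nyquist/bin contract, property
suites including a brute-force cluster-segmentation oracle).

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

computes the acceptance statistics from scratch (~9 min single CPU) and
writes JSON. Values from an actual run at seed 1:

| id | statistic | value |
|----|-----------|-------|
| t1 | feature columns produced by featurization | 264 |
| t2 | mean recovered K_d over 100 replicates (generating value 0.74 µM) | 0.742 µM |
| t4 | % peaks rejected by z-piezo filter at 0.1 (planted 10% clusters) | ≈11% |
| t5 | % spikes rejected by common-class filter at 0.7 (planted 50%) | ≈49% |

All statistics are seeded; `--seed` changes every random draw. See
`docs/methods.md` for the model, parameter choices and limitations.
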