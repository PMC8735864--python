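# synint

Analysis toolkit for intracellular and extracellular recordings of evoked
synaptic responses, together with a calibrated synthetic-trace generator
that makes every stage of the pipeline verifiable end to end.

The analysis chain covers:

- **Trace conditioning** (`synint.preprocess`) — baseline subtraction,
  zero-phase Butterworth low-pass filtering, trial averaging, dV/dt-based
  action-potential blanking and stimulus-artifact removal by linear
  interpolation.
- **Single-response kinetics** (`synint.kinetics`) — peak amplitude
  (±0.1 ms neighborhood mean), full-width at half-maximum, 20 %-of-peak
  onset latency, 10–90 % rise time, mono/bi-exponential decay fits with an
  amplitude-weighted time constant, and cumulative integrals.
- **Train summation** (`synint.summation`) — expected-linear waveforms by
  superposing the cell's own single-pulse response at each pulse onset,
  per-pulse observed/expected ratios and trough-to-peak amplitudes, tonic
  (DC) extraction by inter-flash interpolation plus 50 ms smoothing, and
  post-train AHP fitting.
- **Minimal stimulation** (`synint.unitary`) — success/failure
  classification against a matched-window noise criterion, failure rate and
  unitary amplitude, Hill intensity–response fits, max/min convergence
  ratios.
- **Dual-pathway integration** (`synint.dual_pathway`) — timing offsets
  from single-pathway kinetics, arithmetic-sum expected waveforms,
  per-pulse and cumulative-integral supralinearity indices, and
  drug/control fraction-remaining comparisons.
- **Extracellular analysis** (`synint.extracellular`) — LFP conditioning
  and 20 %-of-peak onset/slope, MAD-thresholded multiunit detection, PSTH
  construction (100 µs bins, 2 ms smoothing) and conduction-velocity
  arithmetic.
- **Synthetic data** (`synint.synth`) — difference-of-exponentials EPSP
  kernels, smoothstep-rise EPSC kernels with exactly multi-exponential
  decays, resource-depletion depression, Bernoulli/lognormal minimal
  stimulation, NMDA-like slow components, tonic/AHP dynamics, dual-pathway
  interaction gains and click-evoked LFP/MUA traces.  Named presets embed
  target summary values as generator ground truth via oracle calibration.
- **Workbench & CLI** (`synint.workbench`, `synint` command) —
  configuration-driven runs with full manifests, and fixture generation.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the pipeline
invariants, and `tests/test_acceptance.py`, which checks every acceptance
criterion (parameter recovery on calibrated presets, analytic identities,
and the cross-cutting property suite).

## CLI

```bash
synint simulate --preset fig4_20hz --rate-hz 20 --n-pulses 10 --out out/
synint analyze-train --input out/fig4_20hz.csv --out out/
synint analyze-minstim --input out/fig2_minstim.csv --out out/
synint analyze-dual --asc a.csv --desc d.csv --combined c.csv --out out/
synint analyze-extracellular --input out/clicks.csv --out out/
synint run --demo --out demo_run/
synint make-fixtures --out fixtures/
```

Sweep sets are stored as plain CSV matrices (one row per sweep) with a JSON
sidecar (`<file>.csv.json`) holding `dt_ms`, `units`, `t0_ms`, the stimulus
train and per-sweep metadata; `.h5` paths select an equivalent HDF5 layout.
Every analysis writes CSV metrics plus a JSON manifest recording all
parameters and seeds, and re-running a manifest reproduces the outputs
bit-identically.
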