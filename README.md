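# respicall

Tested, reusable pipeline from raw push-mode respirometry traces and call
recordings to resting metabolic rate (RMR), call characteristics, RMR
mixed models, RMR repeatability, and within-individual RMR consistency —
with a first-class synthetic-data generator so every stage is testable
without any field data.

## What it does

1. **Trace model & I/O** (`respicall.model`) — multi-channel respirometry
   traces (O2 %, CO2 %, water vapor pressure kPa, barometric pressure kPa,
   flow ml min⁻¹, active-channel marker) as long-form CSV; multiplexer
   schedule inference (15-min dwells, ≤3 repetitions per chamber,
   baseline chamber = channel 0).
2. **Trace reduction** (`respicall.reduction`) — gas-channel lag alignment
   against the water-vapor channel, drift correction through the empty
   baseline chamber, sign-flip/proportional conversion, the water-vapor
   flow correction `FRd = FR·(BP − WVP)/BP`, and oxygen consumption
   `VO2 = 60·FRd·dO2/(1 − FeO2)` with `FeO2 = FiO2_ref − dO2` (ml h⁻¹).
3. **RMR extraction** (`respicall.extraction`) — MAD-based activity
   screening, then the two-stage window search: the 450-s interval with the
   lowest VO2 standard deviation, the 60-s interval with the lowest mean
   inside it, minimized across the (up to three) repetitions of a trial.
4. **Call features** (`respicall.calls`) — call duration, pulse number,
   dominant frequency, call-by-call rate (reciprocal onset-to-onset
   interval; final call excluded) and call effort (duration × rate) from
   call event tables; per-recording means; inter-observer reliability
   (Pearson r + OLS slope); an optional envelope-threshold segmenter for
   WAV audio.
5. **Statistics** (`respicall.stats`, `respicall.lmm`) — the five
   call-trait mixed models (RMR + temperature + calendar day + mass +
   year, random intercept per individual), the RMR mixed model (linear,
   quadratic-day and log10 variants), adjusted repeatability
   `R = V_ind/(V_ind + V_res)` with parametric-bootstrap CI and
   boundary-corrected likelihood-ratio test, and the first/last
   |ΔRMR|-vs-days consistency regressions (raw and day-residualized).
   The random-intercept model is fit by a fast profiled-REML routine
   (cross-validated against statsmodels MixedLM in the test suite).
6. **Synthetic data** (`respicall.simulate`) — cohorts with known
   mass/day/year effects and variance components, physically inverted
   multiplexed traces (drift, noise, injected lag, labeled activity
   bursts), and mixed-effects call event tables plus optional pulsatile
   audio. Fully deterministic given a seed.
7. **Pipeline & CLI** (`respicall.pipeline`, `respicall.cli`) — YAML
   config, manifest with config hash and output checksums.

## CLI

```bash
respicall simulate --seed 1 --out study/ --write-traces
respicall reduce --trace study/trace_000.csv --out vo2.csv
respicall rmr --vo2 vo2.csv --out rmr.csv
respicall calls --events study/call_events.csv --recordings study/recordings.csv --out features.csv
respicall analyze --trials trials.csv --seed 1 --n-boot 1000 --out analysis/
respicall run --seed 1 --out full_run/          # everything end to end
```

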