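# noisenight

Simulation and analysis pipeline for randomized crossover studies of
night-time traffic-noise exposure. The package covers five stages:

1. **`noisenight.synthetic`** — generators for every pipeline input with
   known ground truth: crossover design assignments over the six condition
   orderings, playback schedules (30 s calibration tone, 40 min silent
   lead-in, 75 s events with 700 s / 575 s gaps for the 30- and 60-event
   conditions), 1 Hz noise + heart-rate night traces with annotated event
   and surge onsets, crossover outcome tables calibrated to condition FMD
   means of 9.35 / 8.19 / 7.73 %, and a 179-protein log2 NPX matrix with a
   responder-associated protein subset.
2. **`noisenight.trace_io`** — validated reading and timestamp-synchronized
   inner-join merging of two-channel 1 Hz trace CSVs (no interpolation of
   missing seconds).
3. **`noisenight.peaks`** — ±350 s moving-average detrending and the
   percentile run-length peak detector: per-night 99th-percentile
   threshold, runs of ≥ 4 consecutive samples strictly above it, peaks
   merged when closer than 75 s. Event-locked responses are summarized as
   heart-rate-peak occurrence in `[t_peak, t_peak + 180 s)` (curtailed 30 s
   before the next noise peak) and as the mean heart-rate change between
   `[t_peak − 120, t_peak − 60)` and `[t_peak, t_peak + 60)`.
4. **`noisenight.crossover`** — mixed models with exposure and period as
   fixed effects and participant as a random intercept: linear mixed models
   for numeric endpoints (model-based condition means, pairwise differences,
   95% Wald CIs), a maximum-likelihood random-intercept logistic model
   (Gauss–Hermite quadrature) for peak-occurrence odds ratios per period and
   overall, the before/after heart-rate delta model, and the
   intervention-vs-none contrast on FMD change.
5. **`noisenight.proteomics`** — pairwise pre/post expression change,
   per-protein Student t-tests (unadjusted P < 0.05, configurable),
   20-vs-20 responder stratification by FMD change, z-normalized group-mean
   clustering (Euclidean, average linkage), PCA scores, and filtering of a
   protein-interaction edge list at score > 0.4.

## CLI

```bash
noisenight simulate night --condition noise60 --seed 1 --out-prefix night60
noisenight simulate cohort --n-participants 74 --seed 1 --out cohort.csv
noisenight merge --noise noise.csv --hr hr.csv --out merged.csv
noisenight detect --trace merged.csv --out detected
noisenight analyze --cohort cohort.csv --outcome fmd_pct --model lmm --out fmd
noisenight proteomics --npx npx.csv --fmd-changes fmd.csv --out-dir prot/
noisenight run-all --seed 1 --out bundle/        # full synthetic study
noisenight report --bundle bundle/
```

`run-all` simulates a complete study (design → nights → detection →
response records → effect tables → responder proteomics) into an output
bundle containing a config echo and a SHA-256 manifest; runs are
bit-reproducible for a fixed seed.

## Layout

```
src/noisenight/    synthetic, trace_io, peaks, crossover, proteomics, cli
tests/             unit + property tests per module, oracles.py (brute-force
                   references), test_acceptance.py (acceptance criteria)
scripts/           acceptance.py
```
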