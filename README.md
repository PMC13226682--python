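# codefrp

Fixation-related potential (FRP) analysis of program-code reading, for
researchers studying how the brain reacts to *confusing* code. In the
underlying experimental paradigm, participants read pairs of semantically
equivalent Java snippets — one containing a small misleading pattern (an
"atom of confusion"), one clean — while gaze (1200 Hz) and EEG (500 Hz,
10–20 montage) are co-registered. The first fixation inside the snippet's
area of interest (the atom's location) time-locks the EEG analysis, and
the hypothesis is a *late frontal positivity* for confusing code roughly
390–660 ms after that fixation.

`codefrp` provides the full analysis chain plus a seeded synthetic-data
generator with ground truth, so every stage is testable by parameter
recovery without any recordings:

- **synthetic**: stimulus layouts, noisy gaze (jitter, drift, calibration
  offset, tracking loss), continuous EEG (1/f noise, fixation-locked
  deflections, an injectable frontal positivity), full study bundles.
- **gaze**: trial quality control (missing-data rules), I2MC-family
  fixation detection, outlier removal, `cluster`/`stretch` line
  correction with informative-only variants, constant-offset removal,
  first-AOI-fixation selection.
- **eeg**: zero-phase 0.05–30 Hz Butterworth band-pass + 50 Hz notch,
  mastoid re-referencing, −300..1000 ms epochs with baseline correction,
  three-criterion artifact rejection (30 µV step, 100 µV range in 0.2 s,
  ±70 µV absolute), participant/condition averaging, 100 Hz bin-mean
  downsampling.
- **cluster**: spatiotemporal cluster-based paired permutation test
  (cluster mass statistic, electrode-adjacency graph, sign-flip null,
  two one-sided tests).
- **design**: a priori paired-t power analysis (noncentral t),
  chance-level correctness, sign-permutation counts, constraint-respecting
  pseudo-randomized presentation orders, counterbalancing.
- **pipeline / CLI**: one-config orchestration with an exclusion ledger.

The statistical model: per participant, the FRP difference wave
d_i(e, t) = confusing − clean average at electrode e and time t. The test
statistic per point is the paired t, t(e,t) = d̄ / (s_d/√n); suprathreshold
points (one-sided p < .05) are clustered over spatial OR temporal
adjacency, each cluster scored by its mass Σt, and significance assessed
against the max-mass null distribution under participant-wise sign flips
(exhaustive up to 2²⁰ assignments, seeded Monte Carlo beyond).

## Worked example

```python
from codefrp import validate_config, run_pipeline

cfg = validate_config({
    "seed": 100,
    "design": {"n_participants": 24, "n_blocks": 3, "trials_per_block": 24,
               "n_pairs": 72, "fixation_cross_s": 0.5,
               "snippet_min_s": 2.5, "snippet_max_s": 4.5},
    "analysis": {"n_monte_carlo": 5000},
})  # defaults elsewhere: 2 µV frontal effect at 390-660 ms, 10 µV noise
report = run_pipeline(cfg, out_dir="runs/demo")
print(report.trials_in, report.trials_excluded, report.trials_used)
print(report.cluster_table[report.cluster_table.significant])
```

prints (abridged):

```
1728 529 1199
  direction  tmin_ms  tmax_ms  n_points                                            electrodes    mass  p_value  significant
0   greater    384.0    654.0       242  C3,CP3,CP4,CPz,Cz,F3,F4,F7,F8,FC3,FC4,FC5,FCz,Fp1,Fz  603.41   0.0004         True
```

Of 1728 simulated trials, 529 were excluded (gaze quality, no AOI
fixation, epoch bounds, artifacts — itemised in `runs/demo/ledger.tsv`),
leaving 1199 accepted epochs. The confusing > clean permutation test
finds one significant cluster (p = .0004) spanning 384–654 ms at frontal
and central electrodes — the pipeline recovers the simulated frontal
positivity at the injected 390–660 ms window. `runs/demo/` also holds the
grand averages, the 50 ms difference topographies, a text report, and a
structured log.

The same stages are scriptable from a shell:

```sh
codefrp power --dz 0.701            # -> 18
codefrp chance --two 21 --three 51  # -> 0.3819
codefrp simulate --config cfg.yaml --out study/
codefrp gaze --config cfg.yaml --study study/
codefrp epoch --config cfg.yaml --study study/
codefrp frp --config cfg.yaml --study study/
codefrp cluster-test --config cfg.yaml --study study/
```

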