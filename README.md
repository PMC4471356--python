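# eegclean

Early-stage EEG preprocessing as a tested library + CLI:

- **Line-noise removal without committing to a filter.**  Deterministic
  sinusoids at the power-line frequency (and harmonics) are estimated by
  multitaper harmonic regression with a Thomson F-test in 4 s sliding
  windows on a *temporary* 1 Hz high-passed copy; the captured noise is
  subtracted from the original, unfiltered signal, so drift and slow
  dynamics survive for downstream users to filter as they see fit.
- **Noisy-channel detection** by four primary criteria — extreme amplitude
  (robust z of the robust SD), low correlation with every other channel,
  poor predictability by spherical-spline RANSAC, and excess high-frequency
  noise — plus NaN / no-data / dropout / low-SNR classes.  All detection
  runs on temporary 1 Hz high-passed (and, where relevant, 50 Hz
  low-passed) copies.
- **Robust average referencing.**  Phase 1 iteratively estimates the mean
  the recording would have had with no bad channels (median start, detect,
  interpolate, re-estimate); phase 2 references by that estimate, detects
  afresh, interpolates the bad channels with spherical splines (Legendre
  degree 7), and stores the reference signal so any user can undo or
  re-reference.
- **Reporting.**  Windowed statistics (robust deviation, 98th-percentile
  absolute window correlations, noisiness z-scores, RANSAC correlations)
  are retained at three stages and condensed into dataset summary measures
  and three issue-flag heuristics; output is machine-readable JSON plus an
  HDF5 result container with full provenance.
- **Synthetic benchmark.**  A seeded generator produces correlated 1/f EEG
  with drift and non-stationary 60 Hz line noise; the benchmark builder
  injects the four canonical bad-channel types (Gaussian noise at 8x SD,
  one-tenth amplitude, temporal shuffle, fully correlated pairs) across
  five 32-channel sessions and scores detection sensitivity/specificity
  over all 160 channel decisions.

## CLI

```sh
# full pipeline: line noise -> robust reference -> report
eegclean run --input session.edf --montage cap.sfp --out-dir out/ --seed 0
# recompute the report from a stored container
eegclean report out/result.h5
# synthetic bad-channel benchmark, 3 replicates
eegclean benchmark --seed 0 --seeds 3 --out-dir bench/
```

Inputs: EDF/BDF, or a `.npy`/text matrix with a JSON sidecar
(`{"fs": 250, "labels": [...], "units": "uV"}`); montages are
whitespace-delimited `label x y z` text (`.sfp` style).  Configuration is a
flat `key = value` file (e.g. `line_noise.tau = 100`); CLI flags override
file values override defaults.

Outputs per run: `result.h5` (processed data, reference signal,
interpolated-channel list and their original signals, three-stage windowed
statistics, config), `report.json` (summaries + issue flags), and
`manifest.json` (everything needed to re-run the identical computation).

## Package layout

| module | contents |
| --- | --- |
| `eegclean.model` | `Montage`, `Recording`, window partitioning |
| `eegclean.params` | parameter dataclasses + flat config (de)serialization |
| `eegclean.filtering` | zero-phase FIR high/low-pass, linear-trend tools |
| `eegclean.linenoise` | Slepian tapers, harmonic F-test, frequency scan, removal |
| `eegclean.noisy` | robust statistics and the criterion battery |
| `eegclean.interpolation` | spherical-spline kernel and channel interpolation |
| `eegclean.reference` | two-phase robust average referencing |
| `eegclean.report` | windowed diagnostics, summaries, issue flags |
| `eegclean.synthetic` | generator, injections, benchmark, scoring |
| `eegclean.io` | EDF/BDF + matrix readers, `.sfp` montages, HDF5 container |
| `eegclean.cli` | `run` / `report` / `benchmark` subcommands |
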