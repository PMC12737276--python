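# ecogsleep

Sleep analysis toolkit for micro-ECoG electrode-grid recordings, built around
a synthetic-data generator that provides ground truth for every stage of the
pipeline:

- **synthdata** — multichannel recordings with stage-dependent spectral
  dominance (delta-dominant NREM, 6.25–9 Hz REM, 8–30 Hz wake) over a 1/f
  background, planted 10–16 Hz spindle bursts, 50/100/150 Hz line noise,
  transient spikes, shared-source channel coupling with a closed-form
  expected coherence, and per-epoch video frames whose blob moves only in
  WAKE epochs.
- **io** — `Recording` / `Hypnogram` / `ElectrodeLayout` / `EventTable`
  containers; native bundle (binary block + JSON sidecar), EDF export,
  hypnogram and event CSVs.
- **staging** — video motion detection (frame differencing + thresholding +
  morphological opening) fused with per-epoch STFT band dominance into 4-s
  WAKE/NREM/REM labels; stage proportions.
- **spectral** — zero-phase notch filters, Welch PSD (2-s windows, 1.75-s
  overlap), band power, dB transform, thin-plate-spline RBF interpolation of
  the 8×8 electrode grid to 100×100, ZT-based segment selection.
- **coherence** — magnitude-squared coherence |Pxy|²/(Pxx·Pyy) after 1–150 Hz
  bandpass + notches, six-band averaging (delta/theta/alpha/beta/gamma1/
  gamma2), pairwise matrices, and Wilcoxon matched-pairs + Benjamini–Hochberg
  FDR change tables.
- **spindles** — despiking (>5 SD, linear interpolation), 1024 Hz polyphase
  resampling, 0.5 Hz high-pass detrend, optional 32-component FastICA,
  fifth-order 10–16 Hz Butterworth bandpass, Hilbert-envelope thresholding at
  mean + 1.5 SD of the NREM baseline with a 0.4–3 s duration gate; amplitude,
  duration, power and density (events per second of NREM) metrics.
- **inference** — REML random-intercept mixed models
  (`value ~ time + (1 | mouse_id)`) and a BH-FDR helper.

## Command line

The `ecogsleep` entry point exposes each analysis plus an end-to-end runner:

```sh
ecogsleep simulate  --config config.json --seed 1 --out simdir
ecogsleep stage     --bundle simdir/recording [--frames frames.npy] --out stagedir
ecogsleep psd       --bundle simdir/recording --out psddir
ecogsleep coherence --bundle simdir/recording --out cohdir --n-segments 12
ecogsleep spindles  --bundle simdir/recording --hypnogram stagedir/hypnogram.csv --out spdir
ecogsleep stats     --before before.csv --after after.csv --out statsdir
ecogsleep run-all   --config config.json --seed 1 --out rundir
```

`run-all` writes the recording bundle, hypnogram CSVs, band-power and
coherence tables, spindle events + summary, a mixed-model effects table, a
manifest (version, seed, config hash) and a log file. Exit codes: 0 success,
2 config error, 3 stage failure.

A minimal config:

```json
{"simulate": {"n_channels": 8, "fs": 1024.0, "duration": 600.0,
              "spindle_rate": 0.08, "coupling_pairs": [[0, 1, 0.8]]}}
```

## Conventions

Time is seconds from session origin; intervals are half-open `[start, end)`;
sample indices are 0-based; amplitudes are arbitrary units (all downstream
metrics are unit-agnostic). The default electrode layout is an 8×8 grid at
600 μm pitch with row-major channel ids `ch00`–`ch63`.
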