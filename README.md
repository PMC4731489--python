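# multierp

A computable testbed for a gamified, three-level visual-oddball EEG paradigm
that elicits ten event-related potentials (C1, P50, MMN, N1, P2, N170, N2pc,
LRP, P300, ERN) in a single session. The package contains:

- **`multierp.schedule`** — seeded generation of the complete trial/block/event
  plan for each game level (`Learn`, `Who`, `Discern`): 16 blocks x
  (25 stimulus + 3 baseline) trials, 80/20 frequent/rare oddball assignment
  with per-type 10% rare totals, paired-tone slots on every 4th stimulus
  trial (80% standard-standard / 10% deviant / 10% silent, second tone
  500 ms after the first), jittered 1200-1900 ms trial durations, response
  rules (passive/active, side report, meaningful/ambiguous with mid-level
  rule reversal), performance feedback messages, and structured event
  markers (>500 distinct codes per full run).
- **`multierp.stimuli`** — programmatic two-tone stimuli: checkerboard masks,
  Kanizsa-style notched-disc figures (canonical and distorted with identical
  ink), synthetic two-tone face stand-ins and their block-scrambled
  counterparts, plus mean-luminance equalization across the set.
- **`multierp.simulate`** — seeded synthetic EEG for a schedule: a 19-channel
  montage, ten condition-dependent Gaussian-envelope component templates
  (stimulus-, tone- or response-locked; corollary-discharge attenuation for
  self-triggered tones; level-scaled N170), a behavioral model (log-normal
  RTs truncated at the response window, level-dependent error rates,
  post-reversal lapses) and 1/f background noise.
- **`multierp.preprocess`** — zero-phase band filtering (0.1-40 Hz),
  epoching (-1 to 2 s stimulus-locked), baseline correction, average
  reference, absolute-threshold epoch rejection.
- **`multierp.erp`** — the ten built-in contrast definitions, condition
  averaging, LRP double subtraction, N2pc contra-minus-ipsi, amplitude
  measures (window mean/peak and matched-filter), one-sample Cohen's d, and
  cross-level complexity comparison.
- **`multierp.spectral`** — Morlet-wavelet ERSP and inter-trial coherence,
  Welch power spectra, sign-flip paired permutation tests, within-unit
  permutation repeated-measures ANOVA, and Benjamini-Hochberg FDR masks.
- **`multierp.cli` / `multierp.io` / `multierp.pipeline`** — command-line
  entry points, TSV/JSON/flat-binary file formats, run manifests, and the
  end-to-end analysis chain.

## CLI

```sh
# 1. generate a schedule (trials TSV + events TSV + stats JSON + manifest)
multierp generate Who --seed 42 --out-dir out/

# 2. simulate a recording for it (float32 binary + JSON sidecar + events)
multierp simulate out/who_seed42_trials.tsv --seed 42 --out out/rec

# 3. run the analysis chain (waveform TSVs, permutation+FDR masks, plots)
multierp analyze out/rec --erp P300 --erp ERN --out-dir out/analysis

# 4. regenerate the markdown report from the analysis directory
multierp report out/analysis
```

`--erp` may be repeated or omitted (omitted = all ten contrasts). A YAML
config file can override any paradigm constant via `--config`.

## Notes

- Simulated component amplitudes/latencies are configuration (ground truth
  for recovery tests), not claims about human data.
- Artifact handling is amplitude-threshold epoch rejection; no ICA/ASR.
- The face stimuli are synthetic stand-ins; no photographic material is
  bundled.
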