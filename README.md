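# gazeqc

Quantify pupil-size-driven apparent gaze shifts and gaze data quality in
eye-tracking recordings. The package provides a complete, tested pipeline:

- **`gazeqc.synthetic`** — simulate bright/dark fixation sessions with known
  ground truth (injected apparent gaze shift, AR(1) gaze noise with
  independently controllable dispersion and sample-to-sample jitter, Poisson
  blinks with optional large entry/exit excursions, pupil traces settling
  near distinct bright/dark diameters), and render scene-camera frames of
  the stimulus display (white/black screen, gray bullseye-crosshair target,
  four green corner markers) with exact projected ground truth.
- **`gazeqc.mapping`** — convert scene-camera gaze pixels to screen-centered
  degrees: marker detection (thresholding, connected components, K-means
  grouping), Brown–Conrady undistortion with iterative inverse, mm-per-pixel
  scaling from known marker spacing, pinhole viewing-distance estimation
  from marker size, arctan conversion to degrees; plus the linear
  pixels-per-degree conversion used by desktop trackers.
- **`gazeqc.preprocess`** — keep the middle 75 % of each measurement window,
  remove valid samples more than 10° from the target, then a single-pass
  3-SD outlier filter; pupil-area-to-mm conversion against an
  artificial-pupil reference. NaN samples are never filtered — they count
  toward data loss only.
- **`gazeqc.metrics`** — accuracy (mean offset from target), apparent gaze
  shift (mean distance between bright/dark centroids over sequential trial
  pairs), STD precision, RMS sample-to-sample precision, and data loss
  (percent invalid before cleaning).
- **`gazeqc.stats`** — paired and one-sample-vs-zero t tests, Bonferroni
  adjustment, paired Cohen's d with interpretation bins
  (negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large), and per-device
  summary tables. Zero-variance cases are flagged degenerate, never
  reported as silent zeros.

## CLI

```bash
# simulate a ground-truth-known session (one CSV per trial phase)
gazeqc simulate --config config.yaml --seed 1 --out session/

# map scene-camera gaze pixels to degrees (PNG frames or a marker CSV)
gazeqc map --frames frames/ --gaze gaze.csv --camera camera.yaml \
           --screen screen.yaml --out mapped.csv

# clean one measurement-phase CSV
gazeqc preprocess --in mapped.csv --target-x 0 --target-y 0 --radius 10 \
                  --sd-k 3 --trim 0.125 --out cleaned.csv --report report.json

# per-trial metrics plus the session's apparent gaze shift
gazeqc metrics --session session/ --out metrics.json

# cohort statistics (paired bright-vs-dark tests, shift-vs-zero tests)
gazeqc stats --metrics cohort.csv --shifts shifts.csv --out report.csv
```

`config.yaml` sections (`device`, `participant`, `schedule`) map directly to
the dataclass fields of `DeviceProfile`, `ParticipantProfile` and
`TrialSchedule`; omitted fields use the defaults (3 trials of 10-s bright
then 10-s dark periods, 5-s adaptation + 5-s measurement phases, pupil
diameters near 2.88/5.05 mm, 476 × 268 mm screen viewed at 930 mm).

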