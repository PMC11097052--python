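# wristgait

Gait-sequence detection (GSD) from wrist-worn triaxial accelerometry, with a
complete, self-contained validation framework:

- **Seven detectors** behind a uniform `Recording -> GSList` contract:
  step-peak detection on the gravity-subtracted acceleration norm (fixed and
  data-adaptive thresholds), sine-template convolution, block-maxima step
  filtering (magnitude / similarity / continuity), scaled-template stride
  matching, still/upright window gating, and activity-count classification.
  Each ships with a *default* and a wrist-*optimized* parameter bank
  (`src/wristgait/data/params.yaml`); thresholds are in g throughout.
- **Synthetic benchmark generator**: long wrist-like recordings assembled
  from scheduled gait / rest / arm-activity segments with exact ground-truth
  gait intervals and step events, slow gravity-axis drift, multi-cohort
  profiles, and a bilateral walking-aid mode that suppresses arm swing.
- **Validation metrics**: 0.1-s window rasterization, TP/FP/TN/FN,
  sensitivity / specificity / PPV / accuracy, gait-sequence count and
  duration relative (absolute) errors.
- **Group statistics**: ICC(2,1) (two-way random, absolute agreement,
  single measure) with reliability bands, a weighted [0, 1] performance
  index over benefit and cost metrics, paired t tests with
  Benjamini–Hochberg adjustment.
- **Grid-search tuning** of any registered detector against an annotated
  corpus, with full leaderboards.

All intervals are half-open `[start_s, end_s)` seconds from the recording
start. Steps or strides are assembled into gait sequences whenever
consecutive events are at most 3 s apart.

## Library quick start

```python
from wristgait import (
    Segment, SimConfig, generate_recording, run_algorithm, evaluate_recording,
)

cfg = SimConfig(
    schedule=(
        Segment("rest", 30.0),
        Segment("gait", 60.0, step_freq_hz=2.0, swing_amp_g=0.4),
        Segment("rest", 30.0),
    ),
    seed=1,
)
ar = generate_recording(cfg)
pred = run_algorithm("paraschiv2019", ar.recording, bank="optimized")
panel = evaluate_recording(pred, ar.truth, ar.recording.duration_s)
print(panel.sensitivity, panel.specificity, panel.gs_dur_rel_err)
```

Registered detectors: `paraschiv2019`, `paraschiv2020`, `iluz`, `gu`,
`karas`, `hickey`, `kheirkhahan`.

## CLI

```sh
wristgait simulate --seed 1 --group HA=2 --group PFF=2 --duration-s 600 --out-dir corpus/
wristgait detect --algorithm paraschiv2019 --bank optimized \
    --input corpus/HA001_acc.csv --output detected.csv
wristgait evaluate --pred detected.csv --ref corpus/HA001_ref.csv \
    --duration-s 600 --output panel.csv
wristgait optimize --algorithm paraschiv2019 --grid grid.yaml \
    --corpus-dir corpus/ --output leaderboard.csv
wristgait compare --panels-a a.csv --panels-b b.csv --output comparison.csv
```

Time series are CSV with header `time_s,acc_x_g,acc_y_g,acc_z_g`; gait
sequences are CSV with header `start_s,end_s`.

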