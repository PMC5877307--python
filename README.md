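# sedmine

Desk-scale toolkit for mining sedentary-behaviour contexts from smartphone-style
sensor streams. It implements a two-stage, duty-cycled recognition pipeline:

1. **Motion stage** — tri-axial accelerometer data is cut into 3-s windows,
   orientation-corrected by estimating gravity as the per-window mean and
   decomposing each sample into vertical/horizontal dynamic components, then
   described by mean / standard deviation / energy (6 features) and classified
   *still* vs *active* with a from-scratch k-nearest-neighbour classifier
   (Euclidean distance, k = 3).
2. **Micro-context stage** — while the user is still, an 8-s audio segment is
   described by MFCC statistics (per-coefficient mean and sd over 25 ms frames,
   26 features) and classified *watching TV* / *working on a PC* /
   *sedentary-unknown*. Audio is only "activated" when stillness begins and is
   re-checked every 15 minutes (duty cycling).

A one-minute epoch state machine drives inference, and an analytics layer turns
epoch timelines into hourly/daily/weekly context totals, short-break detection
and two-period comparisons. Because no public recordings exist, the package
ships a synthetic sensor simulator (`sedmine.sim`) that generates labelled
accelerometer and audio streams with per-minute ground truth, so the whole
pipeline is testable end to end.

## CLI

```bash
# Generate a labelled synthetic recording (accel CSV + WAV + ground-truth JSONL)
sedmine simulate --schedule schedule.csv --seed 42 --out data/

# Train motion + audio models from an annotated recording
sedmine train --accel data/accel.csv --audio data/audio.wav \
    --annotations annotations.csv --seed 42 --out models/

# Run duty-cycled per-minute inference
sedmine run --accel day/accel.csv --audio day/audio.wav \
    --motion-model models/motion_model.json --audio-model models/audio_model.json \
    --out timeline.jsonl

# Behaviour analytics
sedmine report --timeline timeline.jsonl --out summary.json

# Full smoke test: simulate -> train -> run -> report
sedmine pipeline --seed 42 --out pipe/
```

File formats: accelerometer CSV (`time_s,ax,ay,az`), 16-bit PCM mono WAV,
annotation CSV (`label,start_s,end_s` with labels `active`, `still_tv`,
`still_pc`, `still_unknown`), schedule CSV (`label,duration_s`), epoch timeline
JSONL, model-store JSON. A YAML config (see `sedmine.config.RunConfig`) can
override every numeric default; unknown keys are rejected.

## Layout

```
src/sedmine/
  sim.py        synthetic accelerometer/audio simulator + schedules
  prep.py       windowing, gravity estimation, dynamic decomposition, trimming
  features.py   motion statistics and the MFCC pipeline
  knn.py        training stores, k-NN classification, split/evaluate protocol
  engine.py     per-minute duty-cycled recognition state machine
  analytics.py  hourly/daily summaries, short breaks, period comparison
  train.py      annotated-recording -> trained stores protocol
  io.py         CSV/WAV/JSONL/JSON readers and writers
  config.py     single YAML run configuration
  cli.py        click command group
```
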