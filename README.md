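# semgfeat

Sliding-time-window feature extraction for surface electromyography
(sEMG), with deterministic parallel execution and a repetition-split
classification harness.

Myoelectric control pipelines — prosthetic hand controllers, gesture
decoders, offline benchmark studies — almost universally start the same
way: the multichannel sEMG stream is cut into overlapping windows
(typically 200 ms long, advanced by 10 ms) and each window is reduced to
a small vector of signal features per channel. `semgfeat` implements
that front end for Python: windowing, ten classical features, filtering
of windows that straddle a movement boundary, and evaluation of the
resulting feature matrices, plus a synthetic-protocol generator so the
whole pipeline is testable without any recordings on disk.

## Features

For a window *w* of *T* samples *x₁…x_T* (per channel):

| name | definition | values/channel |
|------|------------|----------------|
| `iav`  | integrated absolute value Σ\|xₜ\| | 1 |
| `mav`  | mean absolute value (1/T)Σ\|xₜ\| | 1 |
| `ssc`  | slope-sign changes: strict local extrema with a step ≥ dead zone | 1 |
| `zc`   | zero crossings: strict sign changes with a step ≥ dead zone | 1 |
| `mavs` | MAV slope MAV_{w+1} − MAV_w (across windows) | 1 |
| `rms`  | root mean square √((1/T)Σxₜ²) | 1 |
| `wl`   | waveform length Σ\|xₜ − xₜ₋₁\| | 1 |
| `hist` | amplitude histogram over ±3σ in 20 bins | 20 |
| `mdwt` | marginal DWT: per-level Σ\|detail coefficients\|, db7, 3 levels | 3 |
| `td`   | Hudgins set [MAV, MAVS, ZC, SSC, WL] | 5 |

Output columns are channel-major (all values for channel 0, then
channel 1, …). Windows whose per-sample `stimulus` or `repetition`
labels are not constant are dropped; the retained rows come back aligned
with `featStim`/`featRep` label vectors.

Extraction is dispatched to parallel workers in contiguous chunks of
windows, and the output is **bit-identical for any worker count** —
inter-window terms (the MAV slope used by `mavs`/`td`) are differenced
over the full ordered window table after the parallel pass, so chunk
boundaries can never leak into values.

## Worked example

```python
import semgfeat as sf

# a synthetic acquisition session: 4 movements x 6 repetitions,
# 1 s movement + 0.5 s rest, 4 channels at 500 Hz
cfg = sf.ProtocolConfig(n_movements=4, n_repetitions=6,
                        movement_duration_s=1.0, rest_duration_s=0.5,
                        n_channels=4, sampling_rate_hz=500, seed=21)
rec, truth = sf.generate_recording(cfg)
print(rec.n_samples, rec.n_channels)           # 18250 4

fm = sf.extract_features(rec, sf.ExtractionConfig(
    winsize=100, wininc=25, feature_name="rms", workers=4))
print(fm.feat.shape)                           # (583, 4)

train, test = sf.split_by_repetition(fm)       # reps {1,3,4,6} / {2,5}
summary = sf.evaluate_classification(train, test, n_trees=100, seed=0)
print(round(summary.balanced_accuracy, 3))     # 1.0
```

18 250 samples is 36.5 s of 4-channel signal; 100/25-sample windows
(200 ms / 50 ms) give 727 planned windows of which 583 are pure — the
144 windows overlapping a movement onset or offset are dropped. Because
each synthetic movement drives the channels with a distinct amplitude
pattern well above the noise floor, window RMS separates the 5 classes
(4 movements + rest) perfectly on the held-out repetitions: balanced
accuracy 1.0.

The same pipeline is available from a shell:

```sh
semgfeat synthesize --output rec.mat --seed 5
semgfeat extract --input rec.mat --output rms.mat --feature rms --workers 4
semgfeat validate --features rms.mat --seed 0
```

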