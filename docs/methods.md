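# Methods

## The pipeline

`semgfeat` implements the windowing-based front end of continuous
myoelectric classification. A recording is an `m x n` signal matrix
(rows = synchronized samples, columns = electrode channels) with two
per-sample integer label vectors: `stimulus` (movement id, 0 = rest)
and `repetition` (repeat index, 0 = rest). The pipeline is:

1. **Windowing.** Half-open windows `[s, s + winsize)` with starts
   `0, wininc, 2·wininc, …`; the count is
   `floor((m − winsize)/wininc) + 1` for `m ≥ winsize`, else 0. A
   trailing partial window is dropped. Indexing is 0-based internally;
   outputs are index-free so the convention is invisible to users.
2. **Feature computation** per window and channel (ten features, below),
   dispatched to parallel workers in contiguous chunks of windows.
3. **Purity filtering.** A window is *pure* iff both label vectors are
   constant across all of its samples. Impure windows — those straddling
   a movement onset/offset — are removed from the feature matrix and
   label vectors after feature computation. Purity is decided from the
   label change-points (a window is impure iff a change falls strictly
   inside it), which an exhaustive per-window constancy scan confirms in
   the tests. Rest windows (stimulus 0) are retained as class 0.
4. **Assembly** of `(feat, featStim, featRep)`: rows are the pure
   windows in window-start order; columns are channel-major (all values
   for channel 0, then channel 1, …).

Typical parameters are 200 ms windows advanced by 10 ms (400/20 samples
at 2 kHz, 20/1 at 100 Hz), converted from milliseconds by rounding half
away from zero.

## The features

Let `x₁…x_T` be one channel of one window.

* **IAV** `Σ|xₜ|`, **MAV** `(1/T)Σ|xₜ|`, **RMS** `√((1/T)Σxₜ²)`,
  **WL** `Σ_{t≥2}|xₜ − xₜ₋₁|`: amplitude/complexity summaries,
  absolutely homogeneous of degree 1.
* **SSC** counts strict local extrema (`xₜ` strictly above or below both
  neighbours) whose step to the previous *or* next sample is ≥ the dead
  zone. **ZC** counts strict sign changes between consecutive samples
  with step ≥ the dead zone. Strict inequalities mean zeros and plateaus
  never count. The dead zone is a symmetric amplitude threshold that
  suppresses counts driven by baseline noise; its useful magnitude
  tracks the signal scale (values around 1e−5 suit normalized/rectified
  signals; raw integer-scaled signals need proportionally larger
  values). Comparisons use `≥`.
* **MAVS** is the forward difference of MAV *across* consecutive
  windows, `MAV_{w+1} − MAV_w`. The final window has no successor; its
  MAVS is set to 0 so the feature matrix keeps one row per window and
  stays aligned with `featStim`/`featRep`. MAVS is always differenced on
  the full ordered window table **before** purity filtering — the only
  order in which the formula is well-defined when a neighbour window is
  later discarded — and therefore also independent of worker chunking.
* **HIST** bins the window's samples into `B = 20` equal-width bins
  spanning `[−3σ_c, +3σ_c]` per channel; out-of-range samples are
  clipped into the outermost bins, so counts always sum to T. By default
  σ_c is the window-local population standard deviation (ddof = 0) of
  the channel, matching a window-local reading of the definition; a
  `hist_sigma_scope="recording"` option computes σ_c once over the whole
  recording instead. A flat channel (σ = 0) puts all T counts in the
  central bin rather than erroring, since rectified rest segments can be
  constant.
* **mDWT** decomposes the window with a cascaded two-channel filter bank
  (Daubechies-7 analysis filters, 3 levels, periodic signal extension)
  and returns, per level 1…3, the sum of absolute detail coefficients.
  The approximation band is excluded. Implementation uses PyWavelets'
  `wavedec(mode="periodization")`; the tests verify it against an
  explicit circular-convolution + dyadic-downsampling oracle at 1e−8
  relative tolerance. Windows too short for the requested depth raise an
  error naming the maximum feasible depth.
* **TD** is the Hudgins time-domain set `[MAV, MAVS, ZC, SSC, WL]` per
  channel; ZC/SSC consume the dead zone, MAVS is differenced across the
  window sequence as above.

Counts (ZC, SSC, HIST) are returned as floats so the feature matrix is a
single homogeneous numeric array.

### A note on HIST's σ scope

The two σ scopes differ scientifically, not just numerically. With
window-local σ the histogram is scale-invariant — each window is binned
relative to its own spread — so HIST carries *shape* information only
and is blind to amplitude. On the synthetic recordings (Gaussian noise
whose only class-dependent property is amplitude) window-local HIST
classifies exactly at chance, while the recording-global variant reaches
the same near-perfect accuracy as RMS. Real sEMG windows are not exactly
Gaussian, so window-local HIST is not uninformative there, but pipelines
that rely on HIST for amplitude-coded discrimination should use
`hist_sigma_scope="recording"`. The acceptance script reports both.

## Parallel execution and determinism

Window indices are partitioned into at most `workers` contiguous,
ordered chunks whose sizes differ by at most one; chunks are evaluated
by a joblib thread pool and concatenated in chunk order. Determinism for
any worker count follows from two facts: every feature value is a
per-window reduction (no cross-window arithmetic inside the parallel
pass), and the one cross-window term (MAV slope) is computed serially on
the full ordered MAV table afterwards. The test suite asserts
element-wise bit-identity across workers ∈ {1, 2, 4} for all ten
features. Worker counts beyond the machine's cores are accepted; they
only add scheduling overhead.

Inside each chunk, windows are materialized in batches of 1024 as a
`(batch, winsize, channels)` array so vectorized kernels apply while
peak memory stays near `1024 · winsize · channels · 8` bytes per worker;
batching cannot change values, again because every value is a per-window
reduction.

## Synthetic recordings

The generator emulates a guided acquisition protocol: a leading rest
block, then each movement repeated `n_repetitions` times, each
repetition `movement_duration_s` (default 5 s) followed by
`rest_duration_s` of rest (default 3 s). The signal is envelope-modulated
zero-mean Gaussian noise: per channel, the noise standard deviation is
`noise_floor` (default 0.1) at rest and `noise_floor +
amplitude_matrix[movement, channel]` during a movement interval, with a
50 ms linear ramp at the interval edges. When no amplitude matrix is
given, one is drawn reproducibly from the seed, uniform on [0.5, 2.0] —
a spread ≥ 3× the noise floor between movement rows, which makes window
amplitude features (RMS/MAV) separable by movement. Presets mirror two
common hardware classes: a rectified-envelope 100 Hz, 10-channel setup,
and a 200 Hz, 16-channel armband quantized to 8 bits (signal snapped to
a 256-level grid over ±4× the peak envelope).

`generate_label_jitter` shifts each interval's onset and offset by
independent uniform integer offsets in `[−max_shift, +max_shift]`
(labels only; the signal is untouched), emulating the misalignment
between instructed and executed movement that motivates purity
filtering; shifts that could make intervals collide are rejected.

What the surrogate does **not** emulate: motor-unit action-potential
structure, electrode crosstalk and placement variability, power-line
interference, movement artefacts, within-repetition amplitude drift, or
label noise beyond boundary shifts. Passing tests therefore certify the
*contracts* of the pipeline (geometry, formulas, determinism, filtering,
splitting) and that the harness can recover a separable class structure
— not classification accuracy on real recordings.

## Validation harness

Feature matrices are split by repetition id: train on {1, 3, 4, 6}, test
on {2, 5} by default; rows in neither set are dropped. Rest windows
(repetition 0) inherit the repetition of the nearest following movement
window (trailing rest: the preceding one) so the rest class appears on
both sides; `rest_assignment="drop"` excludes them instead. The
classifier is a 100-tree random forest (pluggable); training rows are
shuffled with a seeded permutation before fitting so accuracy is
invariant to input row order. Reported are plain accuracy and balanced
accuracy — the unweighted mean of per-class accuracies, our reading of
class-balanced evaluation when repetition counts per class differ; it
equals macro-averaged recall and is cross-checked against
scikit-learn's `balanced_accuracy_score` in the tests.

For chance-level checks the stimulus labels of the *entire* feature
matrix are permuted before splitting. Permuting training labels only
would leave test labels correlated with the features and biases balanced
accuracy slightly above 1/K with tiny between-seed variance; permuting
all labels makes the expectation exactly 1/K. Training sets are
subsampled to 5 000 windows per permutation fit — forests on permuted
labels grow deep and slow, and subsampling does not move the chance
expectation.

## Problem sizes

The heavier checks run on: a ~60 s, 12-channel, 2 kHz recording
(≈5 600 windows at 400/20) for the worker-determinism sweep; and an
8-movement × 6-repetition full protocol session (387 s, ≈38 700
windows) for the end-to-end classification harness and the acceptance
script. These sizes exercise multi-chunk parallelism and realistic
window counts while keeping a full run in minutes on one core.

## Known limitations

* HIST with the default window-local σ is scale-invariant (see above).
* MAVS of the last window is 0 by convention, and MAVS differences may
  span a removed (impure) neighbour window — both inherent to keeping
  one row per retained window.
* The file reader targets MAT containers (v5 natively, HDF5-based on
  read); vendor stream formats are out of scope.
* Streaming/online extraction is not supported; recordings are processed
  in memory.
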