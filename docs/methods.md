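# Methods

This note documents the models, conventions and design choices behind
`ecgfuse`, what the synthetic generator does and does not emulate, and
the numerical details a maintainer would need.

## Beat windowing and extraction

A beat window of `L` samples at the target rate `fs_target` must lie in
the physiological band `0.6·fs_target ≤ L ≤ fs_target`, which follows
from the resting heart-rate range 60–100 bpm:
`num_of_sample(f_heart, f_sample) = round(60·f_sample/f_heart)`.
Defaults: `L = 260` at `fs_target = 360 Hz`, split `M = 129` samples
before the annotated R peak, `N = 130` after (`M = ⌊(L−1)/2⌋`). Both
are configurable through `WindowSpec`.

Extraction precedes resampling: for a record at native rate
`fs ≠ fs_target` the window is rescaled to
`L_native = round(L·fs/fs_target)` (same split rule), each beat is cut
at the native rate, then resampled to exactly `L` samples. This keeps
every emitted beat the same length while cutting windows in the
record's own time base. The alternative — resampling whole records
before extraction — gives nearly identical beats; the beat-wise path
was chosen because it touches far fewer samples and makes the
fixed-length guarantee trivial. A ±1-sample fix-up (truncate or repeat
the last sample) absorbs rounding after resampling.

Beats whose window would cross a record boundary are dropped, not
padded, and logged with a reason (`boundary_underflow`/`overflow`);
kept + dropped always equals the number of class-mapped annotations.
Annotation symbols outside the class map (rhythm marks, noise marks,
excluded parent classes) are skipped and tallied per symbol.

Resampling is band-limited polyphase (`scipy.signal.resample_poly`)
with the rational ratio taken from the frequency pair. The signal mean
is removed before filtering and restored afterwards so that DC passes
exactly despite the anti-aliasing filter's finite passband ripple;
output length is `round(len·fs_out/fs_in)`.

## Normalization operators

All operators act on the beat matrix `A` (m beats × n samples) and
preserve shape, labels and provenance. Standard deviations are sample
standard deviations (`ddof = 1`) throughout — columns use denominator
`m−1`, rows `n−1`.

* `standardize` — column z-score; `extremum` — column min–max to
  [0, 1]; `mean` — divide by column mean; `std` — divide by column
  sample std. These remove *positional* scale differences only.
* `self` — row z-score (each beat minus its own mean, over its own
  sample std). Exactly invariant to per-beat affine amplitude changes
  `x ↦ αx + β` (α > 0) and idempotent; this is the operator that
  collapses inter-database and inter-patient gain/offset differences
  while preserving beat morphology.

Degenerate inputs are handled per operator, because one bad beat must
not abort a multi-database build: zero-variance or zero-mean columns
raise a `DegenerateColumnError` naming the columns; constant columns
under `extremum` map to 0 with a warning; flatline beats under `self`
are rejected per beat and recorded in a drop log at the dataset level
(the array-level function raises, listing the rows). Normalization
assertions in tests use a 1e−10 tolerance in double precision.

Column-wise statistics can leak test information if computed on the
pooled matrix. The dataset-level API therefore supports fitting
`ColumnStats` on the training split and applying them to the test
split; passing no statistics reproduces pooled behavior. `self` is
per-beat and leakage-free by construction. The integration entry point
applies operators to the merged dataset before splitting (pooled),
matching the single-pass build flow; the split-aware path is available
for strict protocols.

## Class scheme and splitting

The default 16-class scheme (`hercules16`, shipped as an editable YAML
data file) maps the conventional single-character beat codes
`N f e / j n L R S A J a V E F Q` onto ids 0–15 (normal; fusion of
paced and normal; atrial escape; paced; junctional escape;
supraventricular escape; left/right bundle branch block;
supraventricular premature; atrial premature; junctional premature;
aberrated atrial premature; premature ventricular contraction;
ventricular escape; fusion of ventricular and normal; unclassifiable).
Parent codes that subsume retained subclasses (e.g. the generic bundle
branch block code `B`) and non-beat codes are excluded. Class ids must
be a bijection onto 0..15; duplicate assignments are configuration
errors.

The stratified split draws, per class of size `m_c ≥ 2`,
`max(1, ⌊test_fraction·m_c⌋)` test beats by seeded within-class
shuffle; singletons stay in training. The floor-with-minimum rule is
fixed and documented; the fraction, and the rule's minimum, are
configurable. Splits are reproducible from the single recorded integer
seed.

## Synthetic generator

The generator exists so that every pipeline stage is testable without
multi-gigabyte downloads. One beat is the sum of five Gaussian bumps
(P, Q, R, S, T) with per-class amplitudes/centers/widths (seconds,
relative to the R peak); 16 class templates ship as an editable YAML
file. Templates are deliberately distinct — widened R with discordant T
for the ventricular classes, inverted dominant R for the ventricular
escape class, absent or early or inverted P for the atrial/junctional
classes — with no claim of clinical fidelity. Per-wave jitter (5 %
amplitude, 5 % width, 4 ms timing for non-R waves) makes beats
non-identical; the R bump stays pinned to the annotation sample, so at
zero noise the annotated index is the R extremum by construction.

A `DatabaseProfile` adds what distinguishes one source database from
another:

| parameter | default (db360 / db128 / db257) | meaning |
|---|---|---|
| `fs` | 360 / 128 / 257 Hz | native sampling rate |
| `gain`, `offset` | 1.0, 0 / 0.55, +0.15 / 3.5, −1.0 | device-level affine amplitude distortion |
| `beat_gain_sigma` | 0.15 / 0.15 / 0.45 | per-beat lognormal amplitude scale |
| `beat_offset_mv` | 0.1 / 0.1 / 0.3 | per-beat local baseline shift (slow pedestal, σ = 1.2 s) |
| `baseline_wander_mv` | 0.05 | 0.2–0.5 Hz sinusoidal drift |
| `powerline_mv` | 0.02 | 50 Hz sinusoid |
| `emg_mv` | 0.02 | white noise band-passed 5 Hz–0.95·Nyquist |
| `heart_rate_bpm` | 60–100 | uniform per-beat R-R draw |
| `mixture` | uniform over 8 classes (0, 3, 6, 7, 9, 12, 13, 14) | class proportions |

The third profile's larger gain and per-beat fluctuation mirror the
documented situation where one source database spans an amplitude
range an order of magnitude wider than another. The per-beat
fluctuations are (near-)affine per beat, i.e. exactly the distortion
family that self-processing removes and column-wise operators cannot —
this is what makes the preprocessing comparison meaningful on
synthetic data. The default noise levels are "low noise": visible in
the trace but far from overwhelming the QRS complex.

`zero_noise(profile)` switches off every stochastic distortion (the
three noise processes and the per-beat fluctuation), leaving only
morphology jitter. In that configuration classes are separable by
construction, and a nearest-centroid classifier on self-processed
beats scores ≥ 99 % — the sanity oracle for the whole pipeline.

What the generator does **not** emulate: real QRS morphology (Gaussian
bumps have no notching, no ST segment), rhythm context (R-R intervals
are i.i.d.; no bigeminy, no compensatory pauses), lead-dependent
morphology, non-stationary noise, or annotation errors. Passing tests
therefore demonstrate that the pipeline's transformations are correct
and that its qualitative contrasts (self vs column-wise normalization)
hold under controlled distortions — not that any accuracy figure will
transfer to clinical recordings.

## Record I/O

Two dialects share one API. The WFDB dialect implements the PhysioNet
convention: text header, format-212 signal packing (two 12-bit
two's-complement samples per 3 bytes, physical value =
(adc − baseline)/gain), and the MIT annotation stream (6-bit type code
+ 10-bit time delta per 16-bit word, with the SKIP escape for long
gaps and AUX/NUM/SUB/CHN records tolerated). Amplitudes round-trip
within one quantization step (default gain 200 adu/mV → 0.0025 mV
half-step). The plain-text dialect (`.sig.csv`/`.ann.csv`/
`.meta.json`) stores the same content in full precision for fixtures
and interchange. Annotation indices are 0-based sample offsets
internally. Lead selection is by priority list with a documented
fall-back to lead 0; multi-segment records and formats other than 212
are out of scope.

## Classifiers and training

The layer framework (dense, 1-D convolution via windowed matmul, batch
normalization, inverted dropout, residual blocks, global average
pooling, Adam, softmax cross-entropy) is implemented directly on numpy
arrays with hand-written backpropagation, verified against central
finite differences in the test suite. Everything random — weight
initialization (He), batch shuffling, dropout masks, validation
carve-out — derives from explicit integer seeds, so runs are
bit-reproducible single-threaded.

FC network: input batch-standardization layer, 4 × (dense 256 + ReLU +
dropout 0.30), dense → 16 softmax: 5 weighted layers. ResNet: three
residual blocks (channels 64/128/128; kernels 8/5/3; each convolution
followed by batch normalization, rectifiers inside the block; shortcut
is the identity, or a 1×1 convolution + batch norm when channel counts
differ), a 1×1 stride-2 down-sampling convolution (+BN+ReLU) after each
of the first two blocks, global average pooling and a dense softmax
head: 12 weighted layers by the usual counting convention (shortcut
projections excluded). Down-sampling stride, channels and kernels are
configurable. Training: Adam at learning rate 0.001, cross-entropy,
batch size 300, maximum-epoch budget (no early stopping by default; a
validation fraction can be carved out and is reported per epoch).
Non-finite loss aborts with `TrainingDivergedError`.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
the full suite completes in well under half an hour on one CPU:
corpora of 2–8 records × 60–170 beats per database (≈ 400–4,000 beats
after merging), FC training budgets of 20–30 epochs, and tiny ResNet
configurations for gradient and training checks (the full 12-layer
network at L = 260 is exercised for construction and inference). At
these sizes the FC classifier reaches ≥ 95 % test accuracy on the
default 8-class corpus and the self-processing row of the comparison
harness meets or exceeds the raw baseline's macro recall whenever the
databases carry distinct amplitude distortions.

## Known limitations

* The class-code mapping ships fixed ids; corpora annotated with
  non-standard codes need a user-supplied scheme file.
* The WFDB writer emits format 212 only and clips to the 12-bit range.
* `integrate` holds the merged beat matrix in memory; three full real
  databases (~470k beats × 260 doubles ≈ 1 GB) fit, but much larger
  merges would need chunked builds.
* The comparison harness reports per-seed results; it does not test
  significance across repetitions.
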