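# Methods

## Problem setting

Laparoscopic sacrocolpopexy — the standard operation for vaginal vault
prolapse — divides into five surgical phases: (1) promontory preparation,
(2) dissection of vault and gutter, (3) mesh fixation to vault, (4) mesh
fixation to promontory, (5) peritonealisation.  Phase durations are long and
highly variable (means from ~3.5 minutes to ~65 minutes, standard deviations
of the same order), which makes the usual short-context phase classifiers
fragment badly and motivates a dedicated coarse-level temporal model.

The package works at two resolutions.  Video time is downsampled to 2.4 fps;
16 consecutive frames form a *clip*, labelled by its modal frame label (ties
break toward the lowest label code).  A fine-level classifier is assumed to
supply, per clip, a feature vector and a label estimate; the coarse-level
model refines whole 100-clip windows of these.

Label codes: `0` non-phase (before the first / after the last phase, excluded
from all analysis), `1–5` the phases, `6` transition (between phases, and —
by our convention, since real annotation practice is unspecified — also the
paused spans of a phase).  The transition class is down-weighted 10× in the
loss and excluded from macro-averaged metrics.

## Sequence-to-sequence formulation

A *many-to-many* recurrent model maps the window's feature sequence directly
to one label per clip.  The *seq2seq* models additionally condition on a
*target sequence* of prior label estimates through an encoder–decoder
structure:

* **time-synchronous** (`window_len = out_len = 100`, `shift = 0`): target,
  input and output all cover the same interval; the model acts as a global
  refiner of the fine-level segmentation.
* **time-shifted** (`out_len = 90`, `shift = 10`): the target covers the
  first 90 clips of the window, the output the last 90, so the two spans
  share 80 positions.  Because outputs extend 10 clips past the target,
  whole-video inference needs fine-level labels only for the initial 90
  clips and afterwards feeds its own predictions back as targets,
  window after window.

Geometry invariant: `out_len + shift == window_len`, enforced at
construction.

### Architectures

* `lstm_m2m` — stacked LSTM (3 layers at full scale) over features, linear
  head per step.
* `lstm_seq2seq` — LSTM encoder over the features; its final hidden/cell
  states initialise an LSTM decoder.  Decoder step *k* consumes the embedded
  target label at position *k* concatenated with the feature vector of the
  clip being predicted (position *k + shift*).  The concatenation is a
  deliberate design choice: the encoder summary state alone is a
  `d_model`-dimensional bottleneck that cannot carry per-clip evidence
  across a 100-clip window, and at the small widths used for CPU-scale
  experiments it measurably starves the decoder (held-out accuracy plateaus
  in the mid-80s and the recursive rollout collapses onto a single phase).
  Inputs and outputs still span the same time interval.
* `transformer_seq2seq` — standard encoder–decoder transformer (full scale:
  6 layers, 8 heads, `d_model` 1200, feed-forward width 1000) with
  sinusoidal positional encoding `PE(t, 2i) = sin(t/10000^{2i/d})`,
  `PE(t, 2i+1) = cos(·)`.  The decoder keeps causal self-attention masking
  by default (configurable off); cross-attention provides per-position
  access to the encoded features.

The default network width (`d_model = 1200`) matches the dimensionality of
the fc8 feature vector the fine-level classifier would produce.  Tests and
the bundled experiments use width 32 and 32-dimensional features so the full
stack runs in minutes on one CPU core; this changes capacity, not structure.

Because the models here are small and dense, they are implemented on a
compact NumPy reverse-mode autodiff core (`sacroseg.autodiff`) — a tape of
primitive ops plus one fused backward-through-time op per LSTM layer.  All
gradients are validated against central finite differences in the test
suite.  There is no dropout; regularisation comes from the noised targets
and from sampling many windows per video.

### Loss

Class-weighted cross-entropy averaged over time and batch:

    L(y, x) = −(1/(t·d)) Σ_k Σ_j Σ_i  w_i · y_{i,j,k} · log x_{i,j,k}

with phase weights 1.0, transition 0.1, non-phase positions excluded
(zero weight, but still counted in the `1/(t·d)` normaliser).  At `t = 1`
this reduces exactly to the per-clip classification loss.  Probabilities are
clamped at 1e-12 before the log; clamping is logged.

### Training strategies and sampling

* `baseline` — groundtruth labels as the decoder target (teacher forcing);
  suffers from exposure bias at deployment.
* `noised` — exactly `round(0.4·L)` target positions replaced by labels
  drawn uniformly from phases+transition excluding the original (fresh
  pattern each epoch by default; a frozen-per-window variant is available).
* `pred` — the fine-level classifier's own predictions as target,
  preserving realistic error structure.

From each video a fixed number of evenly spaced windows is sampled
(`start_i = round(i·(n_clips − window_len)/(n_windows − 1))`; 200 per video
at full scale), and each optimisation batch collects the windows with the
same index across all videos — i.e. the same relative position in every
procedure.  Optimisation is Adam; the full-scale recipe (lr 1e-5, ×0.93
decay every 5 epochs) is kept as the configuration default, while the
CPU-scale experiments use lr 3e-3 with faster decay, chosen for the much
smaller models.  Validation micro accuracy (transition and non-phase
excluded) is computed 4 times per epoch and the best parameters seen are
restored at the end.

## Whole-video inference

* *Time-synchronous*: non-overlapping windows tile the video (final partial
  window right-aligned; clips already covered keep the earlier window's
  label), each using the fine-level predictions for its own interval as
  target.
* *Time-shifted*: the working sequence starts as the fine-level labels for
  the first 90 clips; windows advance by `stride = shift` (the only stride
  that reproduces the 80-position target/output overlap while covering
  every clip); each window takes the current working labels as target and
  its 90 outputs are recorded; the working sequence is updated with the
  latest window's predictions (a running-mode update is available behind a
  flag).  Final label per clip = mode over all recorded predictions (ties
  toward the lowest code); clips before the first predicted position keep
  their fine-level labels and are marked `fine_init`.
* *Mode-average baseline*: sliding per-position mode over the raw fine
  predictions, default width 101 clips (the width is our choice; it trades
  boundary lag against burst suppression and is configurable).

## Evaluation

Frame(clip)-based: per-phase precision/recall over the five phases
(computed with scikit-learn), macro-averaged over the phases present in the
groundtruth; transition is excluded from the macro average and non-phase
positions are dropped entirely; F1 = 2PR/(P+R); micro accuracy over
positions whose groundtruth is a phase.  The confusion matrix is 5×5,
row-normalised by each phase's retained sample count.

Event-based (Ward): per class, maximal runs are events; two events overlap
if they share a clip index.  Each groundtruth event is exactly one of
Correct (C), Deletion (D), Fragmented (F), Merged (M), or FM; each predicted
event one of C, Insertion (I′), Fragmenting (F′), Merging (M′), FM′; counts
are summed over the five phases (transition/non-phase stay in the timeline
but are not scored).  The conservation identities
`n_gt = C+D+F+M+FM` and `n_pred = C+I′+F′+M′+FM′` are asserted against an
independent brute-force oracle in the tests.  Event ratio = n_gt/n_pred;
with zero predicted events it is defined as 0 (worst case) unless the
groundtruth is also empty (then 1); ratios above 1 are reported as-is.

## Synthetic study conditions

The simulator draws each phase's active duration from a normal distribution
with the reported per-phase statistics (633±365, 3097±1212, 3888±879,
211±157, 1073±548 s), clamped below at `max(30 s, mean − 2·sd)` — a
truncation floor rather than a resampled truncated distribution, which keeps
the sample mean of the short phase 4 within the recovery tolerance while
preventing non-positive durations.  Phases appear in order 1–5 (variant
1,2,3,5,4 with configurable probability, default 0); transitions are uniform
on 10–120 s (duration statistics for transitions are not reported, only that
they are few and short); each phase pauses once with probability 0.15 for
30–120 s (paused time maps to transition); non-phase lead-in/out is uniform
on 30–120 s.

The feature emitter assigns each label code a fixed random unit-direction
mean scaled by `class_separation = 3.0`, pulls consecutive-phase means
toward each other by `adjacency_shrink = 0.25` (mimicking the observed
confusability of adjacent phases), and adds isotropic Gaussian noise
(sd 1.0).  The class means depend only on the emitter seed — one emulated
fine-level classifier serves all videos — while each video gets an
independent noise stream.  The fine-level label emulator corrupts the
groundtruth with a two-state Markov chain whose stationary error fraction is
`1 − fine_accuracy` (default accuracy 0.69, matching the raw fine-level
accuracy regime the coarse models are designed to refine) and whose error
runs are geometric with mean `error_burst_len = 8` clips, holding one wrong
label (biased toward neighbouring phases) per burst.

What the generator does **not** emulate: visual content and appearance
drift, annotation ambiguity at phase boundaries, surgeon- or case-level
duration correlations, tool-usage signals, and heteroscedastic classifier
confidence.  Passing tests therefore demonstrate that the pipeline's
mechanics (window geometry, recursion, strategies, metrics) behave as
specified and that the models can exploit temporal structure — not that the
reported real-video accuracies transfer.

## Problem sizes used in tests

The acceptance-grade experiments train a 2-layer LSTM seq2seq
(time-synchronous) and a 2-layer/2-head transformer seq2seq (time-shifted),
both with `d_model = 32`, on 8 simulated procedures (~800–2000 clips each),
validating on 2 held-out procedures: 100 windows per video for 5 epochs
(500 optimisation steps).  Duration-recovery statistics use 200 simulated
procedures.  These sizes were chosen so the full suite runs in a few minutes
on a single CPU core.

## Known limitations

* The decoder's feature anchoring (LSTM) means the pure label-only decoder
  of the original formulation is not exercised; at large `d_model` both
  couplings are viable.
* Post-layer-norm transformer blocks can be touchy to train at larger
  depth without warmup; the bundled recipes use 2 layers.
* The Ward implementation scores inclusive integer intervals at clip
  resolution; a frame-level report is obtained by expanding each clip
  `clip_len` times, not by re-scoring at frame resolution.
* `event_ratio` compresses all error categories into one number; it should
  be read alongside the category counts.
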