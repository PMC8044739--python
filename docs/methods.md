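# Methods

## The classification problem

Each training row is one 30-second window of chest-device wearable data,
summarized by the mean, SD, minimum and maximum of 8 channels (ECG, EDA,
EMG, respiration, skin temperature, 3-axis acceleration), giving 32
features, plus a class label for the task the subject was performing
(0 = neutral/baseline, 1 = stress, 2 = amusement). Raw task labels follow
the WESAD convention (1/2/3 for the three tasks; everything else, such as
transient periods, is discarded).

Windows are cut per maximal run of a constant task label, anchored at the
run start, non-overlapping, with a trailing partial window dropped — a
window can therefore never mix two tasks, and two separated runs of the
same task are windowed independently. The SD uses the population divisor n
(configurable to n − 1); windowed summary statistics of physiological
signals conventionally describe the window itself rather than estimate a
population moment.

## Model

A dense network with hidden layers of 12, 10 and 8 units, leaky-ReLU
activations (negative-side slope 0.01), a 3-way softmax output and mean
categorical cross-entropy loss, optimized by Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Features are standardized per column
using statistics fitted on the training rows only; a constant training
column gets scale 1 (with a warning) instead of dividing by zero.
Cross-entropy clips probabilities at 1e-12 to avoid −log 0.

Forward, backpropagation and Adam are written directly in numpy.
Parameters are a flat name → array mapping (`W0`/`b0` … `W3`/`b3`), which
makes federated aggregation an elementwise dictionary mean and lets the
payload audit operate on key names. Weight initialization is
fan-in-scaled uniform, U(−√(6/fan_in), +√(6/fan_in)), with zero biases;
all randomness flows through explicit integer seeds, never global state.
The gradient implementation is checked against central finite differences
(relative tolerance 1e-5) in the test suite and the acceptance script.

### Personalization

A per-subject embedding e_i ∈ R^u is appended to every input row of
subject i and learned jointly with the network — the neural analogue of a
per-subject fixed-effect intercept. u = 2 by default. With embeddings as
the only non-constant input, predictions collapse to one value per
subject, which is the intended degenerate behaviour of a pure fixed
effect. Personalized models refuse to predict for subjects without an
embedding; an explicit `allow_unseen_subjects` flag substitutes a zero
embedding for exploration.

## Training regimes

- **server** — one model on the pooled table; an epoch is one pass over
  the training rows in seeded shuffled order, mini-batch size 32 by
  default (full-batch mode available).
- **individual** — one model and one standardizer per subject; per-user
  init seeds derive from (base seed, subject id) via a CRC-based rule, so
  adding or removing other users never changes a subject's model.
- **federated** — R rounds of: sample m clients uniformly without
  replacement (round RNG derived from (seed, round index)); broadcast the
  shared parameters; each client runs E local optimizer steps on its full
  private batch (local Adam state is reset at each broadcast — clients
  are stateless); the server averages the returned parameters (unweighted
  by default; sample-weighted mode provided) and interpolates toward the
  average by step size η ∈ (0, 1], η = 1 meaning outright replacement.
  Standardization is fitted on the pooled training rows for server and
  federated models, per-subject for individual models.

Two tuned rates exist in the federated regime: the *learning rate* drives
the local optimizer; the *step size* is the server interpolation factor η.
A local "update" is one full-batch optimizer step, so E counts steps, not
epochs. With full participation, one plain-gradient local step, η = 1 and
uniform averaging, a federated round is algebraically identical to one
centralized gradient step on the unweighted mean of per-user mean losses;
the test suite asserts this against an independently coded centralized
oracle to 1e-8.

In personalized federated training each client also updates its own
embedding locally, but the embedding never enters the transmitted payload;
the per-round audit log stores the payload key names (never values, and
not cohort membership — participation timing is itself sensitive, so
recording cohort ids requires an explicit debug flag).

## Study protocol

Within each (subject, task) block, ordered by window index: the last
⌊n/3⌋ rows are the test set and the rest train (blocks under 3 windows go
wholly to training with a warning). Hyperparameters are tuned by 3-fold
cross-validation with contiguous-in-time folds per block (adjacent windows
are autocorrelated; contiguous folds avoid train/validation leakage), or
by a trailing-third holdout. Grid search scores each combination by mean
validation accuracy, breaking ties toward fewer epochs, then smaller
learning rate, then listing order. The comparison harness trains all five
regimes with seeds 1..15, reports per-seed test accuracies with
median/mean/SD, and includes the majority-class baseline. Test accuracy
is pooled over all test windows (per-user accuracies are also reported).

## Synthetic cohort

The generator emulates the study's data shape: 15 users × 72 windows,
class proportions 0.5345 / 0.2999 / 0.1656, feature vectors
x = μ_k + b_i + ε with per-user offsets b_i ~ N(0, τ²I) and noise
ε ~ N(0, σ²I). Per-user class counts use deterministic largest-remainder
apportionment (a multinomial mode exists behind a flag) so split
arithmetic is exactly testable; with proportions above and 72 windows the
counts are 38/22/12. Per-user sub-seeds derive from (seed, user index),
so extending the cohort never reshuffles existing users' rows.

Class means default to a fixed sparse pattern — class k raises features
j ≡ k (mod 3) by a shift δ — giving equal pairwise class separation with
no random draw. The shift was calibrated once, by scanning δ against the
pooled server model's held-out accuracy at the default τ = 1, σ = 1, and
frozen at **δ = 0.9**, where the server model sits near 0.9 accuracy —
the difficulty regime the analysis is designed around. At these defaults
personalization buys a few accuracy points and the federated model trails
the server model slightly; with τ = 0 the two coincide to well within
0.05.

An optional `user_effect_rank` confines the offsets to an r-dimensional
subspace (orthonormal loadings scaled to preserve each feature's marginal
offset SD). The embedding-dimension recovery check plants r = 2 with
τ = 6 and 48 windows per user — heterogeneity strong and exactly
two-dimensional, so u = 1 underfits and u = 3 pays a small-sample cost —
and grid search over u ∈ {1, 2, 3} recovers u = 2 in most replicates.

What the generator does **not** emulate: physiological waveform structure,
temporal autocorrelation between adjacent windows, class-dependent
covariance changes, or label noise. Passing tests on synthetic data show
the machinery (splits, training loops, aggregation, payload boundary) and
the qualitative personalization/heterogeneity story are correct; they do
not certify accuracy levels on real recordings.

## Problem sizes and numerical choices

Tests and the acceptance script use the default cohort (1080 windows,
15 users) with 10–15 seeded repetitions per regime, and 5–6-user
miniatures for exact algebraic checks — sizes chosen so the whole suite
runs in a few minutes on one CPU while keeping every assertion
statistically comfortable. Ties in largest-remainder apportionment break
toward the lower class index; grid-search ties as described above;
degenerate inputs (empty windows, single-class users, constant columns,
empty clients) warn or raise per their contracts rather than silently
proceeding.

## Known limitations

- Real chest-device recordings must be exported to the documented CSV
  layout (one column per channel plus `label`); the original per-subject
  serialized records are not parsed directly.
- The federated simulation is sequential and in-memory; it enforces the
  payload boundary but does not model communication failures, stragglers,
  or secure aggregation.
- Batch size, initialization scheme and the local-optimizer choice are
  exposed configuration with conventional defaults; published studies of
  this design rarely state them, so exact replication of any particular
  run requires matching these settings.
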