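# Methods

## The problem and the pipeline

CAP (cyclic alternating pattern) scoring assigns every second of NREM
sleep to either a transient activation (A phase) or background (B phase),
groups valid A+B pairs into cycles and runs of ≥ 2 cycles into sequences,
and summarizes sleep instability as the CAP rate (CAP time / NREM time).
`capsleep` estimates all of this from one EEG monopolar derivation with
two per-second binary classifiers run in parallel — A/not-A and
NREM/not-NREM — followed by a deterministic correction and an FSM that
encodes the scoring rules. Everything downstream of the classifiers is
rule-based and auditable; everything upstream is standard signal
processing.

## Coordinate conventions

Time is 0-based seconds; intervals are half-open `[onset, onset+dur)`;
epoch `i` covers `[i, i+1)`. A phases label an epoch by *any* overlap
(short events must not vanish between grid points); sleep stages label an
epoch by its midpoint (stages are long blocks, so midpoint sampling is
stable). These two rules remove every off-by-one ambiguity in the
label/interval round trips, which the tests exercise.

## Preprocessing

Decimation to 100 Hz uses the classical scheme: Chebyshev type I low-pass
(order 8, 0.05 dB passband ripple, normalized cutoff 0.8/r) followed by
keeping every r-th sample; `scipy.signal.decimate`'s IIR default is
exactly this filter, applied zero-phase. Non-integer ratios (e.g.
512 → 100 Hz) cannot be pure decimation; they fall back to polyphase
rational resampling (`resample_poly`, up 25 / down 128 for 512 Hz),
trimmed to `round(N · 100 / fs)` samples, with a logged notice.
Standardization subtracts the mean and divides by the *population*
standard deviation — the n vs n−1 distinction is irrelevant at record
length but is fixed for test determinism. Records are then cut into 1 s
epochs of 100 samples (trailing partial second dropped).

Overlapping windows for the CNN put the labeled second at the first,
central, or last position of a `W = 2·O + 1` s window; the record is
zero-padded at the edges so that every epoch owns a full window and label
alignment with the annotation stream is preserved. Time-step sequences for
the LSTM are causal: the labeled epoch is the *last* of its T steps, so no
future signal leaks into a decision; the first T−1 epochs left-replicate
the earliest item.

## Features

The symbolic-dynamics features bin each standardized sample against
thresholds that are multiples of the record-level standard deviation σ
(−5σ, −4σ, −3σ, −2σ, −σ, 2σ, 3σ, 4σ), emitting nine symbols by first
match; the per-epoch symbol counts are A1..A9 and always sum to 100 (a
partition — property-tested). σ is whole-record, not per-epoch, so after
standardization σ = 1. The amplitude-variation metric is computed exactly
as `A(E) = max(E) + max(E−2) − max(E−1)`; the first two epochs replicate
the earliest epoch maximum for the missing predecessors.

Band powers use Welch's method per 100-sample epoch: Hann window, segment
length M = 50, 50 % overlap — the segment-count expression
`floor((P − φM)/((1 − φ)M))` is then a positive integer (3). Band edges
(delta 0.5–4, theta 4–8, alpha 8–12, sigma 12–15, beta 15–30 Hz) are the
conventional sleep-EEG definitions and are configurable; band values are
*sums* of density bins — the absolute scale cancels both in the
amplitude/power ratios and in feature standardization, so sums vs means is
a free choice. Ratios guard the denominator at 1e−12 so a silent channel
cannot produce infinities.

## mRMR

Relevance and redundancy use a plug-in discrete mutual-information
estimator in bits (the log base only rescales scores, never reorders
them). Continuous features are discretized by 10-bin equal-frequency
binning fit on training data with edges frozen for reuse. Ranking is the
greedy incremental scheme: the first feature maximizes MI with the class;
step k maximizes relevance minus mean MI with the already-selected set.
Exact optimization of the set-level criterion is exponential; the greedy
form is the standard one. Ties break by original column order so the
ranking is deterministic.

## Classifiers and training

Three families, all ending in a 2-unit soft-max read out by
`argmax` (ties at p = 0.5 go to the positive class):

* **FFNN** — one tanh hidden layer (100–400 units in the search grid).
* **1D-CNN** — GofLayer groups: convolution (kernel 2, stride 1, ReLU) →
  max-pool (2/2) → 10 % dropout, then one ReLU dense layer and the output.
* **LSTM** — 1–5 (bi)directional recurrent layers sharing their hidden
  width, 10 % dropout, an optional dense layer of half/same/twice the
  recurrent width (floor(Nh/2 + 1/2) for "half"), then the output. The
  pre-output dense activation is ReLU (unspecified upstream; chosen to
  match the CNN's dense layer).

The networks are implemented in float64 numpy (`capsleep.nn`) with
reverse-mode gradients verified against central differences in the tests.
Dense weights initialize from a seeded normal with scale 1/√fan-in;
convolutional and recurrent weights use a symmetric uniform of the same
scale; the LSTM forget-gate bias starts at 1 (standard stabilizer).
Dropout is inverted and active only during training, so inference is
deterministic.

Training: Adam (lr 0.001), class-weighted cross-entropy with
inverse-frequency weights `w_c = n/(2·n_c)` (cost-sensitive learning for
the strong A/not-A imbalance; the exact cost ratio is this package's
choice), batch size 1024, at most 50 epochs, early stop once validation
AUC fails to improve by 0.01 *absolute* within 5 consecutive epochs
("1 %" of an AUC read as 0.01). At desk scale the pipeline caps the
effective batch at `n_train/16` so tiny cohorts still get a meaningful
number of optimizer steps per epoch; the 1024 default is sized for
full-night cohorts (hundreds of thousands of epochs).

## HOSA

Both searches enumerate a level, train and score every candidate (mean
validation AUC over the configured repeats — 10 under the full protocol,
1 for smoke runs), and deepen until the new level's best beats the
previous by ≤ t_r = 0.01, returning the better of the two levels' bests.
CNN levels add GofLayer groups whose kernel counts multiply the previous
group's by a uniform factor in {1, 2} (linear growth of the level size);
first-layer kernels are 2^M for M = 4..7; dense units 50/100/150; overlaps
O ∈ {0, 1, 3, 5, …, 17} (window steps of 4 s up to a 35 s window), where
O = 0 contributes one scenario and O > 0 three (first/central/last). LSTM
levels are the product T ∈ {5, 15, 25, 35} × Nh ∈ {100..400} ×
{uni, bidirectional} × four dense options — 128 per depth, 256 over two
depths. The depth-stopping comparison is global per level by default; a
per-(T, Nh) variant can be expressed by running the search per pair. A
failing evaluation skips that candidate with a logged error rather than
aborting the search, and a saved trace can seed a resumed run.

## Post-processing and CAP scoring

Correction is exactly two stages with no re-iteration: (1) a single
simultaneous pass flips isolated epochs (`101→111`, `010→000`, first/last
epochs untouched, all decisions made against the unmodified input); (2)
A-labels are cleared wherever the NREM classifier says not-NREM, since CAP
is only defined in NREM. Before the FSM, consecutive A phases separated by
less than 2 s are combined (iterated to a fixed point — a chain of close
phases collapses to one).

The FSM encodes the scoring rules as named predicates: phases valid at
2–60 s; the B phase between consecutive valid A phases valid when it lasts
2–60 s and contains only NREM epochs; a cycle is an A plus its following
valid B; a sequence is a maximal run of ≥ 2 consecutive cycles (sequences
begin with an A and end with a B; the closing A after the final B has no
valid B of its own and is not counted as CAP — a documented, switchable
reading). CAP rate divides CAP epochs by NREM epochs — predicted NREM for
the pipeline, annotated NREM for ground truth.

Before scoring predictions, the pipeline majority-smooths the predicted
NREM stream with a 31 s median filter. Sleep macrostructure changes on the
scale of the clinical 30 s staging epoch, so per-second stage flickers are
classification noise, and the strict all-NREM B-content rule would
otherwise veto cycles on single flickered epochs. The NREM metrics in the
report are computed on the raw classifier output; only CAP scoring sees
the smoothed stream.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the pipeline assumes,
seeded and reproducible (per-subject seed = cohort seed + subject index):

* background: order-2 autoregressive noise (poles 0.92, 0.35) with an
  approximately 1/f-tilted spectrum, scaled to 20 µV RMS;
* macrostructure: alternating WAKE/NREM/REM blocks (uniform lengths
  10–60 / 180–420 / 30–120 s) with stage-dependent spectra — NREM gains a
  delta-band component, REM is attenuated with a theta tinge, WAKE is
  attenuated with an alpha component — because in real EEG the stages are
  spectrally distinguishable, and an undetectable macrostructure would
  make the CAP-rate task meaningless by construction;
* A phases: band-limited additive bursts with 0.5 s cosine on/off ramps
  (deliberately ambiguous onset/offset at low snr). A1 boosts delta, A3
  boosts beta at half amplitude, A2 mixes both; subtype mix 0.61/0.21/0.18;
  durations truncated-normal (mean 13 s, sd 5 s) clipped to [2, 60] s;
  intra-sequence gaps truncated-normal (10, 5) on [2, 60] s; runs of
  n+1 phases yield n cycles, separated by 65–120 s so sequences stay
  distinct; the event budget is `a_event_rate` (default 2/min) per NREM
  minute;
* ground-truth CAP intervals are derived by feeding the true labels
  through the *same* FSM used for scoring — generator and scorer cannot
  disagree about the rules.

Not emulated: sleep spindles, K-complexes, artifacts (movement, ECG
field), inter-subject physiology, or realistic transition dynamics.
Passing tests on this generator demonstrate that the pipeline's machinery
is correct and that the end-to-end estimate recovers a known truth under
detectable-signal conditions — not that the classifiers would reach any
particular performance on clinical recordings.

## Problem sizes and numerical choices

The default study conditions for end-to-end runs are 5 subjects × 10 min
at 100 Hz with snr 3 — large enough for every pipeline stage to engage
(multiple CAP sequences per record, both stages present), small enough
that the full FFNN run takes seconds and the toy HOSA search (O ∈
{0, 1, 3}, K ∈ {16, 32}, one dense size; 14 level-1 candidates) about a
minute on one CPU. The full-scale CNN preset (64/128 kernels over 19 s
windows) builds and runs forward but is not trained in the routine test
suite — pure-numpy convolution training at that size belongs to real
experiments, not unit tests. Float64 is used throughout; determinism is
end-to-end given the seed (generator, initialization, batching, dropout).

## Known limitations

* EDF support is single-channel 16-bit writing and mne-based reading; no
  EDF+ embedded annotations.
* The numpy networks are CPU-bound and meant for desk-scale experiments
  and search-logic validation, not full-night training runs.
* The Wilcoxon comparison switches from the exact to the tie-corrected
  normal distribution at a combined n of 20; with heavy ties at small n
  the approximation is the best available.
* A-phase *subtypes* are generated but not classified; subtype-aware
  scoring is out of scope.
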