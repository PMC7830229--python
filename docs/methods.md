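# Methods

## Model

The classifier is a fully connected sigmoid network applied to the time-delay
representation of a multivariate series: windows of length *w* samples and
stride *s* over *C* channels, flattened channel-major (all *w* lags of
channel 0, then channel 1, …) into vectors of length *w·C*.  Windows use
0-based, half-open coordinates `[i·s, i·s + w)`; windows and mini-batches
that would run past the end of the data are dropped rather than padded.
Either convention (channel- or time-major, padding or dropping) would work —
the first connection is fully connected — but one has to be fixed for
reproducibility, and these are the ones fixed here.

Mini-batches are a second sliding window, size *B*, stride `B/2` by default,
over the data-vector sequence.  The 50 % second-stage overlap mirrors the
overlap commonly used at the window level; overlapping batches make the
learned features less dependent on where a pattern falls inside a batch, at
the price of an unequal per-vector contribution (each vector appears between
1 and ⌈B/stride⌉ times), which washes out over the batch collection.
Instances inside a batch keep natural time order — concatenation is only
meaningful on consecutive rows — while whole batches are shuffled each epoch
to shatter the long-range label sequence.

Each of the *L* hidden layers is followed by a concatenation sublayer that
joins *TS* consecutive activation rows into one instance of width *TS·n*;
the next connection's weights attach there, so its fan-in carries the *TS*
factor.  The input layer is **not** concatenated: the time-delay vectors
already encode input-level context, and the complexity figures of the
matched plain networks are only reproduced under this placement.  Per-class
label counts (initialised to the per-window label tallies, which sum to *w*)
are pooled — summed over the same *TS* rows — at every concatenation, and a
majority vote over the terminal pooled counts yields the hard one-hot
training target of each surviving row; ties are broken uniformly by a
dedicated seeded generator, independent of the shuffling stream.  Voting
early (per window, or per concatenation) would discard the class-proportion
information that the counts carry, so it is deferred to the final
classifier.  Count-proportional soft targets are available behind
`TrainConfig.soft_targets` but are not the default.

## Learning

The backward pass is standard softmax-cross-entropy backpropagation except
at the concatenation sublayers, which are not differentiable.  There the
incoming delta matrix (one row per concatenated instance, *TS·H* columns) is
**split** into its *TS* column blocks of width *H*, each block is **slid**
to its pre-concatenation row offset (block *j*, row *r* belongs to input row
*r + j*), and overlapping values are **added**.  This split-slide-add rule
is precisely the linear adjoint of the concatenation operator; consequently
it conserves the total delta exactly, and the analytic gradient of the whole
network agrees with central finite differences (checked to relative error
below 1e-5 at TS ∈ {1, 2, 3}; tolerance chosen for ε = 1e-5 central
differences in double precision).  At TS = 1 every operation — forward,
backward, pretraining — reduces bit-for-bit to the plain DBN-DNN / MLP
computation, which the tests assert against independently written textbook
routines.

Weight updates are plain mini-batch gradient descent with optional classical
momentum; no adaptive optimizer is used.  Defaults: learning rate 0.2,
momentum 0.5, sigmoid hidden units.  Momentum 0.9 was observed to stall in a
saturated plateau on the synthetic task (epoch loss pinned near 0.71), so
0.5 is the shipped default.  Softmax is computed with max-subtraction and
cross-entropy probabilities are clipped at 1e-12; a non-finite loss raises
immediately (the usual symptom of a too-large learning rate).  Training
refuses mini-batches smaller than 8 when TS > 1 (too few rows survive the
concatenations to be meaningful) unless explicitly overridden; the hard
floor for a forward pass is `B ≥ L·(TS−1) + 1`.

Pretraining is greedy, pair-wise, forward-only contrastive divergence
(CD-1 by default, *k* configurable).  The first RBM has Gaussian visible
units on the standardized input (unit variance assumed — standardize first);
deeper RBMs have Bernoulli visibles on the concatenated mean-field hidden
probabilities — the RBM sits between the concatenation sublayer and the next
hidden layer, where the weights actually live.  Propagation between levels
uses probabilities, never samples; the softmax connection and the labels are
never touched.  Default schedule (5 epochs at learning rate 0.05 per
connection) was tuned on the synthetic generator: on paired runs it improves
held-out accuracy by several points on average over random initialisation.

Model complexity is reported as the **weights-only** parameter count (biases
excluded); this is the convention under which the widened plain networks
(hidden widths 23/23/20 and 31/31/20 against base 20/20/20 at TS = 2 and 5)
match the published totals 6181 and 8565 exactly.  `equivalent_dbn_config`
widens all but the last hidden layer to a common width and returns the width
whose count is closest to the target, ties toward the smaller count.

## Synthetic data

The generator emulates a per-sample-labelled physiological recording: a
K-state latent Markov chain with geometric dwell times (mean `mean_dwell`
samples; switches jump uniformly to another state, so the stationary law is
uniform) drives, per channel, an AR(2) process whose resonance (pole radius
0.95) sits at a class- and channel-specific frequency (classes spread over
0.05–0.35 cycles/sample, ±0.01 across channels); coefficients are
cross-faded over 5 samples around each switch to avoid discontinuities.
White Gaussian noise is added with per-channel variance `var(signal)/snr`.
Defaults (14 channels, 15 000 samples, 2 classes, dwell 300, snr 4) emulate
a consumer-EEG-like recording.

What the generator does *not* emulate: physiological volume conduction and
channel correlation, 1/f background spectra, artifacts (blinks, motion),
non-geometric dwell distributions, and label noise.  Passing tests therefore
demonstrate the mechanics and the qualitative value of temporal context on
regime-switching signals, not performance on real EEG/HAR recordings.

Because dwell times are long relative to the window, consecutive windows
usually share a latent state, so evidence aggregated across windows — the
property the concatenation sublayers exploit — is genuinely informative when
a single window is not decisive.

## Evaluation protocol

Cross-validation folds are contiguous blocks of the mini-batch sequence,
fixed before shuffling, so no mini-batch spans the train/test boundary.  Per
fold: per-feature standardization fitted on training batches only (constant
features pass through), pretraining, fine-tuning, then accuracy measured as
the percentage of surviving terminal rows whose softmax argmax equals their
voted target — the denominator has to be defined somehow, and surviving rows
is the natural unit at TS > 1.  All per-fold randomness derives from
`(seed, fold)`, making results deterministic and independent of fold
execution order.

The TS-ordering study (`paired_ts_study`) compares TS=2 against TS=1 on ten
seed-matched synthetic records.  Conditions: 6 channels, 2 classes, 12 000
samples, dwell 200 ≫ w = 16 (stride 8), snr 1.0, hidden widths (8, 8, 8),
B = 18, 5 folds, 40 epochs.  The 0 dB noise level and the deliberately
narrow hidden layers (~8 % of the 96-dimensional input) are the point of the
design: at high snr a single window is already almost perfectly separable
and the comparison degenerates into optimization noise, whereas at 0 dB the
per-window evidence is partial and the decision benefits from context
spanning several consecutive windows.  The narrow-hidden choice mirrors the
reference protocol of evaluating concatenation on a deliberately
under-provisioned network.  These sizes also keep the full 10-seed study
around six minutes on one CPU.

## Known limitations

- Sigmoid hidden units only (chosen for Bernoulli-RBM compatibility); no
  ReLU option is wired in.
- No GPU path; everything is double-precision BLAS through numpy.
- The statistical invariant "label marginals match the stationary law" is
  tested on thinned subsamples (spacing ≫ dwell): a χ² test on the raw,
  strongly autocorrelated label sequence would be miscalibrated.
- Subject-wise fold splits are possible only when group metadata exists;
  the built-in splitter is contiguous-block only.
- ARFF support covers the common numeric-attributes + nominal-class layout,
  not the full ARFF grammar.
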