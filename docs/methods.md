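# Methods

`simondecode` implements a complete single-trial EEG decoding study of the
Simon task: synthetic cohort generation with known ground truth, ERP-style
preprocessing, a compact convolutional classifier evaluated with
leave-one-subject-out (LOOS) cross-validation against per-subject binomial
chance thresholds, gradient saliency maps, an RBF-SVM baseline, and
repeated-measures behavioral statistics.

## The task and the four classes

In the Simon task a letter cue determines the responding hand while the
irrelevant screen side of the letter either matches the responding hand
(non-conflict) or mismatches it (conflict). Crossing hand × conflict gives
four trial classes; the stimulus side is a pure function of the two factors
(same side as the hand on non-conflict trials, opposite on conflict trials).
The behavioral signature is the Simon effect: slower (+37 ms planted:
430 vs 393 ms) and more error-prone (9.6% vs 3.4%) responses under conflict.

## Synthetic EEG generator

Each subject is a continuous multichannel recording (default 60 channels at
500 Hz; desk-scale runs use 16 channels at 250 Hz) with one event per trial,
trials separated by the response–stimulus interval drawn uniformly from
2000–2500 ms. Background noise is synthesized per channel in the frequency
domain with a 1/f power spectrum and mixed across channels by a
distance-decay kernel on the electrode sphere (σ = 0.5 rad, rows normalized
to preserve per-channel variance), then scaled to `noise_scale` (default
10 µV). Three class-informative components — Gaussian-windowed half-sine
bumps, peak at the window center — are added per trial:

| component | channels (weight) | window | class dependence | default peak |
|---|---|---|---|---|
| N1-like | PO9/PO10 (1.0), PO3/PO4 (0.6); ipsilateral side ×0.4 | 190–250 ms | lateralized contralateral to stimulus side | 12 µV |
| conflict negativity | FC1 (1.0), F8 (0.8), FC2 (0.5) | 300–400 ms | full amplitude on conflict, ×0.35 otherwise | 10 µV |
| motor | C3 or C4 contralateral to hand (1.0), Cz (0.2) | RT−250 … RT+50 ms | lateralized to responding hand | 7 µV |

All components are negative-going. Response times are lognormal
(shape 0.12) with class-dependent means and a small hand effect (5 ms);
correctness is Bernoulli with the class-dependent error rates. Cohorts add
between-subject variation: a common lognormal amplitude gain (σ = 0.2) and
a normal RT shift (σ = 15 ms); per-subject seeds derive deterministically
from the master seed. Misses are not simulated; error trials exist only to
exercise the correct-only filter.

The component amplitudes are free parameters of the generator — real
single-trial ERP amplitudes and SNR are not constrained here — and the
defaults are calibrated so that the decoding problem is clearly solvable at
desk scale, which is what the parameter-recovery tests require. What the
generator deliberately does not emulate: ocular/muscle artifacts,
volume-conduction forward modeling, non-stationary noise, or any
trial-history structure. Passing tests therefore demonstrate that the
pipeline recovers planted structure, not that real EEG would decode at these
accuracies.

## Preprocessing

Fixed order: band-pass filter → segmentation (correct trials only) →
artifact rejection → current source density → baseline → crop.

- **Filter**: 4th-order Butterworth band-pass 0.5–20 Hz applied
  forward-backward (zero phase); the two passes give an effective roll-off
  of ≈48 dB/octave.
- **Segmentation**: −100 … 1500 ms around stimulus onset (800 samples at
  500 Hz); epochs exceeding the recording are dropped with a warning.
- **Artifact rejection** (on microvolt data, windows sliding
  sample-by-sample): voltage step > 50 µV/ms between successive samples;
  peak-to-peak range > 200 µV in any 200 ms window; a channel whose
  peak-to-peak stays < 0.5 µV in every 100 ms window (flat-line detector,
  the standard reading of a "lowest allowed activity" criterion).
- **CSD**: spherical-spline surface Laplacian (m = 4, λ = 1e−5, 50 Legendre
  terms — the canonical defaults of the CSD literature), implemented as a
  precomputed channels × channels operator; reference-free and linear by
  construction. Output values are in surface-Laplacian units on the unit
  sphere (proportional to µV/cm²; no head-radius rescaling is applied, which
  is irrelevant downstream because the classifier is scale-adaptive).
- **Baseline**: mean over −100…0 ms subtracted per trial and channel,
  applied after CSD, mirroring a pipeline that baselines as its final step.
- **Crop**: the classifier consumes 0–1500 ms (750 samples at 500 Hz).

## The classifier

A compact two-block convolutional network. Block 1: temporal convolution
(F1 filters of width 64 samples, same padding, no bias) → batch norm →
depthwise spatial convolution spanning all channels (D filters per temporal
map) → batch norm → ELU → average-pool 4 → dropout. Block 2: separable
convolution (depthwise temporal width 16, pointwise to F2 = F1·D) →
batch norm → ELU → average-pool 8 → dropout → flatten → dense softmax over
the four classes. Pooling floors odd lengths (750 → 187 → 23), giving 368
flattened features and 3540 trainable parameters for (F1, D) = (8, 2),
C = 60, T = 750. Both published filter-count options, (4, 2) and (8, 2),
are supported; `select_filter_config` picks the one with the higher mean
LOOS accuracy.

The implementation is pure NumPy with hand-derived backpropagation. The
wide temporal convolution runs in the frequency domain (real FFT), which on
one CPU is several times faster than im2col because it touches each sample
once instead of 64 times. Gradients — including the input gradient used for
saliency — are verified against central finite differences in float64.

Training: ADAM (lr 1e−3, default moments), batch 32, class-weighted
cross-entropy with weights max(counts)/counts (majority class at 1),
dropout p = 0.25, max-norm constraints 1.0 (depthwise) and 0.25 (dense),
batch-norm momentum 0.99 / ε = 1e−3 (the reference implementation's
defaults). After every epoch the unweighted validation cross-entropy is
recorded and the weights with the lowest validation loss are kept
(best-checkpoint early stopping; up to 500 epochs at full scale). All
randomness (init, shuffling, dropout) is generator-seeded; training is
bit-reproducible.

## Evaluation

LOOS: each subject serves once as the test set; validation subjects
(default 4; desk-scale cohorts of 6 use 1) are drawn uniformly without
replacement from the remainder, independently per split from a seeded
generator. Per-subject significance uses the binomial inverse CDF:
threshold(n, c, α) = binoinv(1−α, n, 1/c)·100/n, the smallest accuracy
whose exceedance is improbable under guessing. "Above chance" is a strict
inequality. The cohort summary reports mean accuracy, the count and
fraction of above-chance subjects, the mean accuracy-minus-threshold margin
with a descriptive one-sample t-test over above-chance subjects, and the
trial-weighted pooled confusion matrix (row-normalized). Permutation
testing is intentionally not implemented; the binomial route is equivalent
for test sets larger than ~100 trials and is the sole significance method.

For the full-size design (186 subjects, test sizes ≈ 346 ± 30), the mean
per-subject threshold computes to ≈28.9%; `scripts/acceptance.py`
reproduces this number from scratch.

## Saliency

For each trial the gradient of the pre-softmax score of the trial's own
class is taken with respect to the input; absolute values are averaged over
all trials of a class and min–max normalized to [0, 1] (a constant raw map
raises instead of dividing by zero). Signed averaging before rectification
is available behind a flag; rectified averaging is the default, following
the convention of gradient-saliency maps. Cohort-level maps average subject
maps with equal weight and renormalize. `feature_ranking` groups
supra-quantile cells into 4-connected clusters ranked by mass, and
`top_mass_cells` returns the peak set holding a given share of total mass.

Ground truth for localization tests is defined in the representation the
classifier sees: `planted_cells` is the compact support (smallest cell set
holding 80% of expected squared signal) of the noise-free injected
components after the CSD transform, marginalizing the response-locked
component over the RT distribution. The surface Laplacian provably
redistributes a focal source onto flanking channels, so defining ground
truth before the transform would mislabel genuinely signal-bearing cells.
Under the default desk-scale geometry this support covers 4.8% of cells.
Input-gradient attribution spreads beyond the planted windows by roughly
the temporal kernel (64 samples) and the 32× pooling granularity; the peak
mass of the class-averaged maps nevertheless falls overwhelmingly inside
the planted support, and the global maximum lands inside it for every
class.

## SVM baseline

An RBF-kernel SVM under byte-identical LOOS splits (same seed path). The
input representation — epochs decimated in time (default factor 5),
flattened, standardized with training-set statistics only — is a repository
choice; the reference analysis does not state one. Hyperparameters are
selected per split on the validation subjects over C ∈ {0.01, 0.1, 1, 10,
100} and γ ∈ {0.1, …, 0.9, 1, 2, …, 10} (ties → smallest C, then smallest
γ), refit on the training subjects, and applied to the test subject.
Multi-class handling is one-vs-one.

## Behavioral statistics

The 2×2 within-subject ANOVA is computed from per-subject contrast scores:
each 1-df effect (hand, conflict, interaction) is a paired t-test on its
contrast with F = t², p from F(1, n−1), and partial η² =
SS_effect/(SS_effect+SS_error) = t²/(t²+n−1). Sphericity correction is
vacuous for 1-df effects and is omitted. Post-hoc paired t-tests (Simon
effect per hand, hand difference per condition) are reported uncorrected
with an additional Bonferroni column. The implementation is cross-checked
in tests against a full sums-of-squares decomposition and against an
independent rm-ANOVA implementation.

## Problem sizes used by the test suite

The default end-to-end study ("desk scale") is 6 subjects × 200 trials,
16 channels at 250 Hz, with the (8, 2) network trained for 30 epochs and
one validation subject per split — small enough to run a full LOOS in a few
minutes on one CPU while leaving all pipeline stages, shapes and contracts
identical in kind to the full design. A 500 Hz variant was measured and
behaves identically (same accuracies and saliency structure) at twice the
cost. Type-I calibration uses 40 null subject-folds (5 cohorts × 8
subjects, 60 trials, 8 channels, 125 Hz, 5 epochs): with no planted signal
the above-chance fraction stays at the nominal α = 0.05.

## Numerical choices and edge cases

- Convolution padding follows the framework convention for even kernels
  (31 left / 32 right for width 64).
- Pooling truncates remainders (floor division); the dense layer carries a
  bias; convolutions do not (batch norm follows immediately).
- The binomial threshold at loose α can sit below 100/c when the discrete
  CDF hits 1−α exactly (e.g. n = 1, c = 4, α = 0.25); at conventional
  α ≤ 0.1 the threshold is always ≥ 100/c.
- Degenerate inputs raise: empty baseline window, crop outside the epoch
  span, montages under 8 channels for the CSD spline, missing classes in a
  training set, constant saliency maps, zero class counts, incomplete ANOVA
  cells (naming the subject).
- float32 is the working precision of the network (float64 available for
  verification); preprocessing runs in float64; HDF5 stores float32.

## Known limitations

The generator's linear superposition of fixed-topography bumps is far
simpler than cortical dynamics; CSD units are unscaled by head radius;
saliency localization is assessed against the injected support, which is
only meaningful for synthetic data; the SVM baseline's feature
representation is a design choice that bounds, not characterizes, what an
SVM could achieve; and accuracies obtained here say nothing quantitative
about real EEG.
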