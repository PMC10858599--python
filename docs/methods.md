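# Methods

`harshift` studies a concrete transfer problem in wearable-sensor
analytics: an activity classifier is trained on wrist+ankle
accelerometry from healthy, young subjects and must recognize walking,
sitting and standing in recordings from people with Parkinson's disease
(PwPD), whose movement signatures differ systematically (tremor,
bradykinesia, different sensor mounting) and whose class distribution
is heavily imbalanced. The package implements the full pipeline —
synthetic cohort generation, data preparation, augmentation, manual
axis reorientation, a small 1D-CNN family, leave-one-subject-out (LOSO)
evaluation, cross-domain testing and adversarial domain adaptation —
so that every stage is testable at desk scale without any data
downloads.

## Synthetic cohorts

Real recordings are replaced by a harmonic-plus-noise generator. Each
activity contributes a contiguous labeled segment per subject:

    x_c(t) = b_c + Σ_{h=1..H} (a_c s_c / h) sin(2π h f t + φ_{c,h}) + ε_c(t)

per channel c, with gravity baseline b, fundamental f (0 for static
postures), per-channel amplitudes a, subject-specific log-normal
amplitude scales s ~ exp(N(0, σ_subj)), uniform phases φ and Gaussian
noise ε. This is deliberately not a biomechanical model: it only needs
to produce learnable, subject-heterogeneous class structure with the
right sampling rates, axis conventions and imbalance.

Two features make the cross-domain problem non-trivial:

* **Axis conventions.** Each dataset has a fixed signed permutation of
  the six channels relative to a canonical frame, emulating different
  sensor coordinate conventions. Cross-testing without reorientation
  faces scrambled channels.
* **Mounting rotation.** Each subject additionally receives a small
  random 3D rotation per sensor block (axis uniform on the sphere,
  angle uniform within ±10° for the healthy presets, ±25° for the
  Parkinson-like preset), constant over the recording. Nominally
  identical placements always differ continuously in practice; this
  residual orientation shift is exactly what a signed-permutation
  reorientation cannot remove, and the reason rotation augmentation
  earns its keep. Without it, a correct reorientation removes the
  orientation shift entirely and augmentation has nothing to do.

The Parkinson-like phenotype adds a resting-tremor sinusoid at 5 Hz
(clinical 4–6 Hz band; 0.6 m/s² on the wrist, half on the ankle),
multiplies the dynamic component by a gait attenuation of 0.55
(bradykinesia) and inflates between-subject variability by 1.5.

Presets: `mhealth-like` (10 subjects, 7 activities, 60 s each, 50 Hz),
`pamap2-like` (8 subjects, 7 activities, 168 s each, 100 Hz),
`pd-like` (14 subjects, walking/sitting/standing, 128 Hz). The pd-like
per-activity durations are calibrated so that the standard pipeline
yields exactly 654 walking, 2,843 sitting and 3,042 standing windows
(6,539 total): a run of 11 + 3k seconds survives resampling and
trimming with a one-second margin and yields exactly k windows. The
implied session length is longer than a realistic clinic visit; window
counts, not session time, are what the downstream metrics care about.

## Data preparation

The pipeline order is fixed: drop invalid (null-class or NaN) samples →
resample to 50 Hz (polyphase anti-aliased decimation; labels by nearest
original sample; upsampling refused) → unit conversion (g → m/s² by
9.80665) → trim 5 s from both ends of every labeled activity run →
segment into 150-sample (3 s) windows drawn inside single-label runs,
non-overlapping by default (the most conservative choice; the step is
configurable) → optional activity mapping (the PD activity names map
onto the common inventory, e.g. ambulation → walking, drinking →
sitting) → per-channel z-scoring. Normalization is always fitted on the
training side only — per fold in cross-validation, after augmentation
when augmentation is on — and cross-domain testing applies the
*source*-fitted statistics to the target. Channels with vanishing
variance are clamped to σ = 1e-8 with a warning rather than producing
infinities.

## Augmentation

Each training window spawns eight combined copies (rotation → scaling →
jitter, independent draws per copy): a proper random rotation per
sensor block (uniform axis, angle uniform in ±90°), one amplitude
scalar ~ N(1, 0.1²) per window, and i.i.d. N(0, 0.05²) jitter.
Composition order is a design choice — jitter last keeps its standard
deviation interpretable in output units. Whether both sensor blocks
share one rotation is exposed as a flag (default: independent blocks).
Augmentation applies to training folds only; a held-out or target set
is never augmented.

## Models

The base classifier is deliberately tiny: conv1d(16×3, stride 1) →
maxpool(2, stride 1) → conv1d(32×3) → maxpool(2, 1) → global average
pooling → 50% dropout → softmax, totalling 2,103 trainable parameters
for 7 classes — small enough to resist overfitting LOSO folds of a few
hundred windows. A five-level complexity family (level 1 = base, up to
~323k parameters) stands in for heavier literature architectures; the
registry is extensible. Training uses Adam (lr 0.001), batch 64, 60
epochs, categorical cross-entropy and L1+L2 (0.001 each) on conv
weights; optional validation-based early stopping is off by default.
The training engine is written directly on numpy with hand-derived
backpropagation; every gradient is tested against central finite
differences, and all randomness flows through seeded generators, so
training is a pure function of (data, seed).

The penultimate representation ("features") is whatever feeds the
softmax head — the 32-dim GAP output for the base model, the last
hidden dense layer for deeper family levels.

## Evaluation

LOSO cross-validation holds out each subject in turn; the remaining
subjects split 80/20 at subject granularity for tuning. The best fold
model (highest held-out accuracy, ties to the lowest fold index) and
its normalizer are what cross-testing uses. For matching label sets,
accuracy and macro-F1 are reported; for the 3-activity PD-style target,
per-activity one-vs-rest binary accuracy and F1 (averaged over
activities) handle both the imbalance and predictions outside the
target's label set — any such prediction counts as negative for every
activity, which pins a completely foreign predictor at exactly 2/3
average binary accuracy and 0 F1 regardless of class proportions. F1
is defined as 0 in the degenerate no-positive case.

## Domain adaptation

The DANN couples a shared encoder to a label head (50% dropout +
softmax, trained on labeled source windows) and a domain head
(dense-32 ELU → sigmoid) through a gradient-reversal layer (identity
forward, gradient × −λ backward; verified against a finite-difference
oracle). Defaults follow the study protocol: λ = 0.1 constant, Adam
lr 0.01, batch 32 source + 32 target per step, mean-squared-error task
loss on one-hot targets (switchable to cross-entropy), domain head
trained with binary cross-entropy, 100–350 epochs with plateau
detection on the domain loss (patience 20 after a 50-epoch minimum,
both configurable). The adaptation API is structurally incapable of
receiving target labels. Warm-starting from a trained classifier
(`from_classifier`) mirrors loading the best cross-validation model
before adapting.

Adversarial training at desk scale is visibly unstable: the target-side
quality of the label head oscillates between adjacent epochs, and the
domain-head accuracy wanders around chance. This mirrors the known
behaviour of DANN-style optimization (which real deployments also
show as occasional collapsed runs); the harness therefore treats
adaptation outcomes as seed-level samples and reports them per seed
rather than pretending a single run is definitive. The instability is
much worse under the MSE task loss: squared error on softmax outputs
has no log-barrier, so a few adversarial steps can silence the label
head entirely. The shipped directional experiments therefore run the
adaptation with the cross-entropy task-loss switch and a fixed
100-epoch budget, while MSE remains the library default for protocol
fidelity.

## Experiment grid and problem sizes

`run_grid` executes (architecture × augmentation × reorientation ×
adaptation) × seeds end to end, writing percent-scale CSV tables with
one row per cell, confusion matrices and a provenance log (config
hash, seeds, versions). Every stage derives its seed from the master
seed and the stage name, so any cell can be re-executed in isolation.

The shipped tests run scaled-down study conditions chosen once:
source cohorts of ~5 subjects at half-length sessions (~30 windows per
subject), a 4-subject Parkinson-like target at 5% session scale
(~327 windows), 25–60 training epochs. These sizes keep full
directional experiments (reorientation benefit, augmentation benefit,
adaptation benefit across 10 seeds) in the minutes range on one CPU
core while leaving the qualitative structure of the problem intact.

## What passing tests do and do not show

The generator produces exactly the statistical structure the methods
assume — periodic limb signals, gravity baselines, convention and
mounting shifts, tremor-band noise, class imbalance. Real accelerometry
adds nonstationarity, activity transitions, sensor drift, label noise
and within-subject medication-state variation, none of which are
modelled. Directional conclusions (reorientation helps under
convention shift; augmentation helps under mounting shift; adaptation
helps under large uncorrected shift) are therefore statements about
the modelled mechanisms, not clinical claims.
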