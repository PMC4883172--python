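# Methods

This note documents the model, the numerical conventions, the synthetic
data the package is validated on, and the design choices made where the
method description leaves the design open.

## Signal model and preprocessing

The analysis trace is a single time series in μV, obtained by averaging
the channels on which the spikes are evident (typically the channels the
expert annotated, e.g. T4/F8).  Conditioning has three steps:

* **Mains notch** — zero-phase IIR band-reject at 50 Hz (quality factor
  30, configurable).  The notch is applied at the *original* sampling
  rate, before decimation: at the 100 Hz working rate 50 Hz sits exactly
  at Nyquist, where a band-reject filter is degenerate, so removing mains
  first and then decimating is the well-posed realisation of the same
  intent.
* **Decimation** — rational-rate polyphase resampling with an FIR
  anti-alias filter (zero-phase), default 500 → 100 Hz.  At 100 Hz the
  301 ms candidate window spans exactly 31 samples, the ambient
  dimensionality of stage 2.
* **Baseline correction** — means of overlapping segments (1.0 s, 50 %
  overlap) assigned to segment centres, smoothed by a 5-point centred
  moving average, linearly interpolated to every sample and subtracted.
  This zero-centres the local EEG average, which the absolute amplitude
  thresholds of stage 1 presuppose.  Signals shorter than one segment
  fall back to global mean subtraction.

All filtering is forward–backward, so event latencies are preserved —
essential because detections are scored by a ±50 ms coincidence window.

## Stage 1: half-wave shape analysis

Primary vertices are local minima (negative-going spikes; an `invert`
flag serves positive-going montages) with topographic prominence
≥ 10 μV, thinned so that surviving vertices are ≥ 100 ms apart (the
deeper of two close minima wins; ties go to the earlier sample).  The
prominence floor operationalises "ignore small peaks near larger ones";
no specific value is prescribed by the method, and 10 μV is the package
default (configurable).

For each vertex, the waveform from 100 ms before to 200 ms after is
extracted (candidates without full context are dropped).  The two
half-waves run from the vertex to the closest local maximum on each
side; when no interior local maximum exists within the window, the
segment's maximum sample serves as surrogate — the sensitivity-preserving
choice, keeping otherwise-valid candidates alive.  Features are A = max −
vertex (μV) and D = index distance / rate (ms).  Threshold comparisons
are inclusive (also the sensitivity-preserving reading).  The preceding
half-wave is indexed 1 and the following 2, matching the narrative order
"before and after the minimum".

One consequence of the window geometry is worth stating: because the
feature window begins only 100 ms before the vertex, a measured D₁ can
never exceed 100 ms, so the D₁ ≤ 200 ms bound cannot bind at feature
level — it is vacuous under the stated window.  The synthetic generator
therefore does not use a D₁ violation in its default distractor mix.

## Stage 2: embedding and classification

**Intrinsic dimensionality.**  The Levina–Bickel maximum-likelihood
estimator with neighbourhood sizes k ∈ [6, 12] (the estimator authors'
recommended range).  Local inverse estimates
(1/(k−1)) Σ_{j<k} log(T_k/T_j) are averaged over points and over k and
then inverted (the corrected averaging-of-inverses form), and the result
is rounded to the nearest integer ≥ 1.  Coincident points would produce
zero distances; they are floored at machine precision with a warning.

**Locality preserving projections.**  The affinity graph is symmetric
k-NN (k = 7, edge if either endpoint lists the other) with heat-kernel
weights exp(−‖xᵢ−xⱼ‖²/t), t defaulting to the mean squared k-NN
distance.  Neither the graph construction nor the weighting is fixed by
the method description; these defaults follow the LPP literature and are
fully configurable, and binary weights are available.  The generalized
eigenproblem X L Xᵀ α = λ X D Xᵀ α is solved densely (d ≤ a few tens, so
a dense symmetric solver is both exact and cheap); the l eigenvectors of
*smallest* eigenvalue form the map — the standard locality-preserving
convention for the reading of "ordered according to the corresponding
eigenvalues".  Eigenvectors are normalised to αᵀ(X D Xᵀ)α = 1 with the
first non-negligible component positive, making fits reproducible
bit-for-bit.  If X D Xᵀ is singular (always true when m ≤ d), its
diagonal is ridged by 1e-9 · trace/d with a warning.

**Training mode.**  The embedding can be learnt transductively
(train+test waveforms concatenated) or inductively (training data alone,
applied to new data through the exact linear out-of-sample map
Y_new = Aᵀ X_new).  The default is inductive, which keeps
cross-validation leak-free; the transductive mode is available as a
flag.

**Kernel width.**  γ = 1/(k·l·log l)² with the log taken as *natural*
(a package convention — the description does not fix the base;
log₁₀ is available and the choice is recorded in run metadata).
"Fraction of training samples contained in the kernel" is
operationalised on pairwise distances: the fraction of training pairs
(i, j) with ‖yᵢ−yⱼ‖ ≤ 1/√γ should equal the target (default 20 %).
Since the kernel radius r = k·l·log l is a strictly monotone function of
k, the fixed point is obtained directly as the empirical 20 % quantile
of the pairwise distances (equivalent to bisection on k, exact to
quantile resolution); the achieved fraction is verified to ±0.01 and a
degenerate distance distribution is an error.  l = 1 is rejected
(log 1 = 0 makes the formula undefined).

**Classifier.**  An RBF-kernel soft-margin SVM with per-class penalties
C₁/C₂ equal to the inverse training class-size ratio (scikit-learn's SVC
is the solver; the penalty rule, the γ calibration and the model
serialisation are the package's own).  The trained decision function is
extracted into an explicit JSON-portable expansion
Σ coef_s·exp(−γ‖v_s−y‖²) + b, so prediction is deterministic and
independent of the solver object; tests verify the stored expansion
against the library decision function to 1e-10.

## Evaluation protocol

Manual markers are first re-aligned to the deepest trace minimum within
±50 ms (ties to the earliest sample).  Matching of detections to markers
is one-to-one and greedy in order of increasing |Δt| among all pairs
within the 50 ms latency; leftovers are FP (detections) and FN
(markers).  Greedy matching can in principle be suboptimal on
adversarial configurations (a detection claiming the only marker another
detection could match); on random event lists it agrees with the optimal
assignment, which the tests check by brute force at small n.  Metrics:
sensitivity TP/(TP+FN), selectivity TP/(TP+FP), FP/min, F-score
2TP/(2TP+FP+FN); 0/0 ratios resolve to 0.

Stage-2 ground truth labels a candidate positive iff it lies within the
latency of a (re-aligned) marker; everything else that passed stage 1 is
the negative class.  Cross-validation is stratified (the method is
silent on stratification, but with ~2 % positives unstratified folds
could be positive-free) with a fixed seed; embedding, γ and classifier
are re-learnt per fold.  Whether to pool confusion counts across folds
or average per-fold metrics is left open by the protocol; both are
reported, with pooling as the headline.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical setting of a whole-night
single-channel recording at desk scale: 30 minutes at 500 Hz (the
clinical acquisition rate), AR(2) background with innovation SD 5 μV
(coefficients 0.5, −0.2 — a gently low-pass spectrum at tens of μV
peak-to-peak, the amplitude scale of scalp EEG), optional 50 Hz mains
and slow drift, 20 planted spikes with half-wave parameters drawn inside
the threshold pass region (A₁ ∈ [35, 150] μV, A₂ ∈ [65, 150] μV, D ∈
[30, 80] ms), and 20 distractors, each constructed to violate exactly
one threshold bound.  Spike templates are piecewise raised-cosine and
strictly monotone between extrema, so planted half-wave amplitudes are
recovered exactly and durations to one sample period.  The d2 distractor
deserves a note: its 250 ms repolarising flank puts the true following
maximum outside the 200 ms window (measured D₂ = 200 ms > 150 ms), and
its modest A₂ = 60 μV keeps any noise-induced premature maximum below
the 50 μV A₂ floor, so it is rejected robustly rather than only in
expectation.

For stage-2 studies a separate constructor emits a labeled candidate
population (default 300 spikes among 2000) in which negatives are
narrower, shallower, more asymmetric transients — separable by shape, as
the manifold assumption requires.

What the generator does **not** emulate: sleep-stage dynamics, eye/EMG
artifacts, electrode pops, inter-patient morphology variability, or the
empirical abundance ratio of the clinical benchmark (99 true among 4708
candidates).  Passing tests on this data therefore demonstrates the
correctness and internal consistency of the machinery — recovery of
planted truth, metric arithmetic, leak-free cross-validation — not
clinical-grade performance on real EEG, which requires annotated
recordings.

## Problem sizes and numerical conventions

Test and acceptance runs use 30-minute recordings, candidate sets of up
to 2000 waveforms and dense m × m graphs, which a laptop handles in
seconds; all matrices are double precision.  Sample/time conversion is
always index = round(time·rate), 0-based.  Amplitudes are μV everywhere;
EDF physical units are converted on read.  The built-in EDF writer
stores 16-bit integer records, so EDF round trips are exact to the
quantization of each channel's physical range (delimited-text round
trips are exact).  Annotation times are collapsed when equal to within
1 ms.  All randomness flows through explicit integer seeds; identical
(input, config, seed) gives bit-identical results throughout.

## Known limitations

* Single-channel analysis only; no spatiotemporal fusion across
  electrodes.
* Spikes and sharp waves only — no polyspike or spike-and-slow-wave
  complex modelling.
* The D₁ duration bound is vacuous under the stated feature window (see
  above).
* Greedy latency matching is not provably optimal in rare adversarial
  configurations.
* LPP is the only embedding back-end shipped; the stage-2 interface
  accepts any fitted linear map, which is the extension point for
  alternatives (PCA, NPE, …).
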