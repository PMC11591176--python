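# Methods

`beatwise` studies a question from ECG-based heart-failure screening: when a
1D convolutional network detects reduced left-ventricular ejection fraction
(LVEF < 50%) from a 12-lead ECG, *where* in the signal does the usable
information live?  The package compares classifier performance across ECG
representations (3 s strips vs single-beat vs two-beat tensors), across lead
subsets, and across intra-beat segments.  Because the clinical ECG/
echocardiography cohorts this kind of study uses are private, the package
ships a synthetic-cohort generator with a *planted*, fully known
discriminative signal, and the experiments are validated as recovery tests:
the pipeline must find the signal where the generator put it, and must find
nothing when nothing was planted.

## Synthetic cohort model

Each record is 10 s of 12-lead ECG at 500 Hz (12 × 5000 samples,
millivolts).  Morphology is a sum of five Gaussian wavelets per beat — one
per P, Q, R, S, T wave — each with an amplitude (mV), width (Gaussian σ,
ms) and latency relative to the R peak (ms).  Defaults (P: 0.12 mV, 22 ms,
−170 ms; Q: −0.12, 9, −32; R: 1.10, 11, 0; S: −0.25, 10, +32; T: 0.35, 55,
+240) give ordinary-looking complexes with a QT around 400 ms.  The wavelets
live on three latent source channels (frontal dipole x, y and a precordial
component z), each wave having a fixed dipole direction, and are projected
to the 12 leads through a fixed Dower-style 12×3 matrix.  Leads I, II and
V1–V6 use Dower-like coefficients; III, aVR, aVL and aVF are derived
algebraically from I and II, so limb-lead closure (III = II − I,
aVR = −(I+II)/2, …) holds exactly in the noise-free signal.  Baseline
wander (default 0.05 mV at 0.25 Hz) is added on the source channels — hence
it also respects closure — while measurement noise (default 0.01 mV white
Gaussian) is per-lead and does not.

Beats are placed at RR-jittered times (heart rate per case ~ N(70, 8²) bpm,
RR jitter σ = 20 ms); the first R peak sits at 0.3·RR so the 250 ms
pre-beat window always fits.  Atrial-fibrillation mode zeroes the P
amplitude and draws RR i.i.d. uniform on [0.65, 1.35]·RR.  LVEF is drawn
uniformly within the class interval (pEF [50, 75], mrEF [40, 50),
rEF [15, 40)) and the class label is derived from it.  Because the signal
is analytic, every record carries exact truth fiducials: the R sample, QRS
onset (Q latency − 2.5 σ_Q), ST junction (S latency + 2.5 σ_S) and T end
(T latency + 2.5 σ_T).

**Planted effects.**  An effect spec rescales the amplitude and/or width of
one wave group (P, QRS or ST-T) on a chosen lead subset for chosen LVEF
classes.  Since the per-lead signal is a linear combination of per-wave
components, the multiplier acts exactly, and recovery tests can assert
exact ratios.  Per-lead effects are applied after projection; an effect
restricted to a limb lead therefore deliberately breaks the algebraic
closure for that lead (closure is only asserted on effect-free signals).
The default recovery effect — ST-T amplitude × 0.4 in mrEF/rEF — is a
stand-in, not a physiological claim: the real waveform features encoding
LVEF are unknown, which is exactly why the analysis localises rather than
assumes them.

**What the generator does not emulate**: real QRS morphology variety
(bundle-branch blocks, pathological Q waves), ectopy, electrode artefacts,
muscle noise, drift nonstationarity, or any validated electrophysiology.
Passing recovery tests shows the *pipeline* can localise a class-dependent
morphological signal under realistic timing jitter and noise; it does not
show that real LVEF signals would be found with the same ease.

## Preprocessing

All intervals are 0-based, half-open sample indices at 500 Hz.

* **Delineation** is a Pan–Tompkins-style detector on lead II (5–20 Hz
  band-pass, derivative, squaring, 150 ms moving-window integration,
  20%-of-max threshold with 250 ms refractory), refined to the argmax of
  the mean absolute band-passed signal across all leads within ±60 ms.
  QRS onset and ST junction are where the integrated energy envelope falls
  below 5% of its R-peak value (bounded to −100/+140 ms); the T end uses
  the tangent method on a 10 Hz low-passed lead II (steepest post-peak
  slope extrapolated to the local baseline).  Flat or beat-free records
  return an empty list.  On noise-free cohorts ≥99% of truth beats are
  recovered within ±20 ms; ≥95% at 0.02 mV noise (both asserted in tests).
* **3 s strips** (12 × 1500): per record, the class- and split-dependent
  number of strips — train ×4/×7/×6 and dev/test ×4/×16/×11 for
  pEF/mrEF/rEF — at endpoint-inclusive, evenly spaced start offsets over
  the 3500 admissible samples (n = 4 → {0, 1167, 2333, 3500}).  The
  oversampling rebalances the rarer reduced-EF classes.
* **Single beats** (12 × 375): window [R − 250 ms, R + 500 ms); samples at
  or past the T end are replaced by the T-end value per lead; beats whose
  window leaves the record are dropped and logged.
* **Partial segments**: boundaries b = QRS onset − 100 ms, j = ST
  junction, t = T end, in window coordinates; spans P = [0, b),
  QRS = [b, j), QRST = [b, t), PQRS = [0, j), PQRST = [0, 375).  Samples
  outside the span are constant-continued with the nearest span boundary
  value, so every segment kind keeps the 375-sample input size (the
  alternative — variable-length inputs — would confound segment content
  with architecture changes).  Note the "QRS" span includes 100 ms of
  pre-onset signal by construction of b.
* **Two-beat tensors** (24 × 375): beat i stacked channel-wise with beat
  i+1; the final beat wraps to the first, so counts are preserved.
* **Standardisation** is a single global scalar mean/SD computed over all
  training samples of all channels; dev/test reuse the training statistics
  unchanged (asserted by recomputation in tests).

## Classifier

A stack of convolutional blocks — 1D convolution (stride 1, length-
preserving padding), batch normalisation, ReLU, non-overlapping max
pooling — followed by global average pooling, one fully connected layer and
a softmax over {preserved, reduced}.  The default configuration has 9
blocks (filters 16→64, kernels 7/5/3, pools 2 then 1) plus the fully
connected layer: 10 weighted layers.  The same stack serves every channel
count from 1 to 24; only the first convolution's input channels change.

Forward/backward passes are written directly in numpy (im2col
convolutions, float32); optimisation is Adam (default lr 1e-3).  The loss
is class-weighted cross-entropy with a 1:2 weight for preserved vs reduced
EF, matching the roughly 2:1 class imbalance the oversampling leaves; under
MixUp (Beta(α, α) convex combinations of a batch with a permuted copy of
itself, α = 0.2, one λ per batch) the soft labels weight linearly, i.e. a
sample's weight is the label-weighted mixture of the class weights.  MixUp
is disabled for reduced-lead runs.  When a development set is provided, the
epoch checkpoint with the best development AUC is restored after training.
Gradient correctness is checked against finite differences in the tests.

## Evaluation

Cases are split at case level into five disjoint subsets, stratified by EF
class (round-robin after a seeded shuffle, so per-class proportions match
within one case).  One subset is the fixed test set shared by all four
folds; the other four rotate as the development set.  Disjointness is
asserted at runtime in every fold.

AUC — the primary metric — is the Mann–Whitney concordance probability
with ties counted ½, computed from midranks and verified against an O(n²)
pairwise oracle to 1e−12.  Accuracy/sensitivity/specificity use a 0.5
probability threshold (Youden-on-dev available).  Case-level scores are the
mean of per-tensor reduced-EF probabilities over a case's strips or beats
(median/majority available); reduced-lead analyses evaluate at data level
instead.  Two configurations are compared by Student's t on per-fold AUCs;
three or more by one-way ANOVA with Tukey-HSD contrasts (α = 0.05);
chi-square and Kruskal–Wallis helpers cover categorical and non-normal
variables.

The per-lead contribution is the mean metric over evaluated lead sets that
contain the lead minus the mean over sets that lack it.  Exhaustive
enumeration of non-empty lead subsets gives 2¹² − 1 = 4095 combinations
(the sum Σₖ C(12,k) is sometimes misquoted as 40,955); the desk-scale
ensembles are singles (12), leave-one-out (13) and a seeded uniform sample
over sizes.

## Problem sizes and controls

Desk-scale defaults are chosen so the whole suite runs on one CPU:
recovery cohorts of 100 cases (60/20/20 pEF/mrEF/rEF), control cohorts of
400 cases (240/80/80) — larger because chance-level AUC estimates need a
small standard error — a 3-block network (8/16/16 filters), ≤6 epochs, and
up to 4 beats per record.  Two negative controls guard against optimistic
bias: a **null cohort** (no planted effect) must give mean AUCs in
[0.4, 0.6] for every representation, and a **label-permutation null** —
binary labels shuffled among cases consistently across train/dev/test, so
the class balance survives but every label–signal association is
destroyed — must give mean AUC in [0.45, 0.55] over 10 permutation seeds.
Permuting at case level across all splits (rather than permuting training
labels only) matters: with a planted amplitude effect, even a
label-agnostic network's scores correlate with the amplitude cluster with
an arbitrary sign, so a train-only permutation yields bimodal AUCs rather
than a chance-level concentration.

## Known limitations

* The delineator is tuned for the generator's morphology family; real ECGs
  with low-amplitude or fragmented QRS would need a validated delineator.
* The synthetic planted effect is linear and stationary; interactions
  (e.g. rate-dependent repolarisation changes) are out of scope.
* The two-beat representation's advantage over single beats depends on
  inter-beat information in the cohort; with a purely morphological planted
  effect, two-beat and single-beat models perform equivalently.
* Sensitivity/specificity at the fixed 0.5 threshold are reported but not
  calibrated; no probability calibration is attempted.
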