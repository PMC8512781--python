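# Methods

This package implements an imagined-vowel EEG decoding pipeline built around
the CNNeeg1-1 architecture: adaptive-projection multivariate empirical mode
decomposition (APIT-MEMD) as a narrowband filter, electrode-pair spectral
difference images as the feature representation, a one-vs-one ensemble of ten
small convolutional networks as the classifier, and class-activation maps for
introspection. This note records the model assumptions, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## Signal model and synthetic EEG

Real imagined-speech EEG is not bundled; the synthetic generator
(`vowelbci.synthetic`) produces data with the same structure as the
50-subject acquisition design it emulates: per subject and vowel, a
continuous session of `n_trials_per_vowel` cycles of 4 s cue-on (imagination)
and 3 s cue-off (rest) at 128 Hz on a 14-channel montage labelled E1..E14
(25 cycles per vowel, 50 subjects, by default). A 15-subject/6-channel
variant is expressible through the same configuration.

Each vowel class is defined by narrowband *signatures* — (channel, center
frequency, bandwidth, amplitude) tuples. The defaults place each vowel on a
distinct channel/band combination chosen to echo the qualitative
electrode-pair activations reported for imagined Spanish vowels (e.g. /a/
contrast involving E1 in the beta band); amplitudes are free parameters
because no quantitative effect sizes are available for the real recordings.
The background is 1/f^beta noise plus a weak white sensor floor
(`white_sd = 0.05`). `beta` defaults to 1.5: with that slope the first two
intrinsic mode functions of the background land at center frequencies of
roughly 29 and 14 Hz, matching the ~30/15 Hz the decomposition exhibits on
real resting EEG, and consistent with measured resting-EEG PSD slopes
(steeper than classic 1/f). `snr` is the RMS ratio of signature to noise;
`snr = 0` removes the signatures entirely (pure noise, the chance-level
control) and `snr = inf` removes the noise.

Subject effects are per-subject log-normal channel gains (sd 0.1) and a
uniform +/-2 Hz signature-frequency offset; they are what makes the
inter-subject protocol genuinely harder than the intra-subject one when
classes are coded by frequency.

Randomness is counter-based: a master seed plus `SeedSequence` spawn keys
per (subject, vowel, trial), so identical configurations are bit-identical
and any subset of the dataset is reproducible in isolation.

What the generator does **not** emulate: ocular/muscle artifacts (the
emulated acquisition explicitly minimized them), volume-conduction mixing,
nonstationary band power, electrode drift. Passing tests on this data shows
the pipeline's machinery is correct and recovers planted structure; it does
not certify real-data accuracy.

## APIT-MEMD

Multivariate EMD represents an n-channel signal as a sum of intrinsic mode
functions (IMFs) obtained by sifting: project the signal along K unit
directions on the (n-1)-sphere, find each projection's local maxima,
interpolate the full multivariate signal at those instants (cubic splines,
mirror boundary extension of two extrema per end), average the envelopes
over directions, subtract. The adaptive-projection variant recomputes, at
every sift, the first principal eigenvector w1 of the channel covariance
(mean-centered; sign fixed so the first nonzero component is positive) and
relocates the half of a uniform Hammersley direction set nearest w1 toward
w1 — and the other half toward -w1 — via `(p + alpha*anchor)/||...||`.

Parameter choices (all exposed in `SiftConfig`):

- `n_directions = 64`: standard MEMD practice (even, well above the channel
  count). The Hammersley set is mapped to the sphere through the Gaussian
  inverse CDF, which preserves its determinism and low discrepancy.
- `alpha = 0.5`: relocation density. `alpha = 0` reduces exactly to
  uniform-direction MEMD (`memd()` keeps that as an independent code path
  and the equivalence is tested).
- Sift stop: `SD = sum(m^2)/sum(d^2) < 0.05`, hard cap 100 sifts (an error
  with diagnostics if hit); a fixed-sift-count mode exists for strict
  reproducibility studies.
- Decomposition stops at `max_imfs = 8` or when every direction's
  projection has fewer than 3 maxima (the residue condition). Constant or
  monotone inputs are residues by definition — no oscillation is extracted.

The residue is constructed by telescoping, so completeness
(`sum(IMFs) + residue == input` to ~1e-16 relative) holds by construction
and is asserted at 1e-8 in tests. The downstream filter keeps IMF1 + IMF2,
whose center frequencies on the EEG-like background sit near 30/15 Hz (the
dyadic filter-bank behaviour of EMD). "Center frequency" is measured as the
peak of the channel- and realization-averaged Welch spectrum — the quantity
one reads off a spectral plot; a power-weighted centroid would sit ~10 Hz
higher for an octave-wide mode under a 1/f-type spectrum and is used only
for the monotone frequency-ordering invariant.

Whether decomposition runs per trial or per 64-sample window is
configurable at the pipeline level; the default decomposes whole trials and
windows afterwards.

## Spectral images

Trials of one (subject, vowel) are concatenated and cut into 64-sample
windows at 85% overlap. The stride is
`64 - round(0.85*64) = 10`; this integerization is the only reading that
reproduces the documented image counts (25 trials x 512 samples -> 12,800
samples -> floor((12800-64)/10)+1 = 1274 windows per vowel, 6370 for five).
Per window, `|FFT(Ei) - FFT(Ej)|` (complex subtraction before magnitude;
a magnitude-difference variant is available behind a flag) is evaluated for
all C(n,2) electrode pairs in lexicographic order and restricted to DFT
bins 0-31 (0-62 Hz at 128 Hz; a bins-1-32 alternative is selectable). Each
image is min-max normalized to [0,1] individually; a constant matrix maps
to zeros. Canonical storage is lossless (HDF5); JPEG export exists only as
an optional dialect because lossy compression breaks exactness.

A consequence of 85% overlap worth knowing: adjacent windows share 54 of 64
samples, so a *window-level* random split leaks noise realizations between
train and test and inflates accuracy even for pure noise. The evaluation
protocols implement the published window-level splits faithfully; the
package's own chance-level and parameter-recovery checks use
`trial_disjoint_trialsets`, which splits at the trial level so train and
test windows never overlap.

## The binary CNN and the one-vs-one ensemble

Each binary model is: 25% input dropout -> conv(50 filters 5x5) -> batch
norm -> ReLU -> max-pool 2x2 -> conv(60 filters 11x11) -> batch norm ->
ReLU -> max-pool 2x2 -> batch norm (BN_3) -> fc(60) -> fc(2) -> softmax
cross-entropy. For 32 x 91 x 1 inputs the activation shapes are 28x87x50,
14x43x50, 4x33x60, 2x16x60, a 1920-long flattened vector, and 480,082
trainable parameters; `propagate_shapes` reproduces this arithmetic with no
learning backend and doubles as the feasibility check.

The layer stack, backpropagation and SGD-with-momentum optimizer are
implemented in NumPy (`vowelbci._nn`): im2col convolutions chunked over the
batch, input gradients via per-offset accumulation, exact manual gradients
(verified against finite differences and a naive convolution in the test
suite). Training defaults follow the published recipe: learning rate 0.01,
50 epochs, stratified 70/30 split. Choices the recipe leaves open:

- momentum coefficient 0.9 (the referenced toolbox default);
- batch size 128;
- Glorot-uniform initialization, batch norm initialized to identity;
- dropout semantics: "exact-count" masking (exactly floor(0.25*N) pixels
  zeroed per image) as the wording implies, with a Bernoulli mode
  available; inactive at inference; no rescaling in exact-count mode — the
  following batch-norm absorbs the scale;
- stratified splits with floor-based per-class train sizes
  (`floor(0.7*n)` per class);
- after the last epoch, batch-norm running statistics are replaced by
  population statistics computed in a dedicated pass over the training
  images. Momentum-averaged running estimates are far from converged after
  the few dozen updates of a small training run, which silently breaks
  inference; reference CNN trainers finalize statistics the same way.
- narrow inputs (e.g. 32 x 15 from a 6-channel montage, where the second
  11x11 kernel does not fit the post-pool 14x5 map): kernels *and* pool
  windows are clamped per dimension to the available extent when
  `adapt_narrow_input=True`, with a loud warning. The published variant for
  narrow inputs is unstated; this is the package's choice.

The ensemble trains one binary model per unordered vowel pair (C(5,2) = 10;
C(k,2) for k classes), each on its two classes' images only. Prediction
tallies one vote per model; the winner is the argmax. Each class appears in
4 pairs, so tallies sum to 10 and no class can exceed 4 — and a 4-4 tie is
impossible (two classes tied at 4 would both have to win their
head-to-head pair). Reachable ties (3-3) are broken by the larger summed
softmax confidence across the tied classes' classifiers, then by fixed
vowel order. Any scikit-learn binary classifier can be substituted through
`base_estimator`.

## Evaluation protocols

Intra-subject: per subject, stratified 70/30 split, ensemble trained on the
70%, scored on the 30%; mean and SD reported over subjects. Inter-subject:
leave-one-subject-out; per fold the ensemble trains on a random 70% of the
pooled other-subject images and is scored on a random 30% subsample of the
held-out subject's images — the subsampling mirrors the published protocol
even though scoring on all of it would be more conventional
(`test_fraction=1.0` switches). Train/test disjointness is by construction
and asserted in tests via fingerprinting.

## Class-activation maps

The head has two fully connected layers, so classic CAM (which requires
global average pooling directly into the classifier) does not literally
apply at BN_3. The first implementation candidate — Grad-CAM's channel
weights as the spatial mean of the class-score gradient — was tested against
an ablation oracle on planted-signal data and *mislocated* the evidence:
with a fully connected head there is no spatial weight sharing to justify
averaging gradients across grid cells. The shipped formulation is
element-wise: `relu(sum_c dL/dA[p,q,c] * A[p,q,c])` on the 2x16 BN_3 grid —
the first-order contribution of each cell to the class logit — bilinearly
upsampled to the 32x91 image grid and min-max scaled to 0-255 (constant
maps to zeros). The 2-cell vertical resolution cannot separate bands that
straddle the row-15/16 boundary; localization tests plant bands away from
it.

## Problem sizes

Tests and the acceptance script run the study-shaped configurations where
counts are the claim (25 trials/vowel, 14 channels for the 1274/6370 image
counts and the 32x91 geometry) and reduced configurations where behaviour
is the claim: parameter recovery uses ~200 images/class and 2-3 epochs —
the planted classes are blatantly separable, so convergence is fast — with
8-channel montages (32x28 images) for the SNR ladder and protocol
comparisons and the full 14-channel geometry for the headline recovery run.
These sizes are the package's chosen desk-scale study conditions; accuracy
at chance for snr=0 and >= 0.9 for structured data is invariant to them.

## Known limitations

- The synthetic classes are far more separable than real imagined-speech
  EEG; absolute accuracies here say nothing about real-data accuracy.
- APIT-MEMD envelope interpolation uses projection maxima only (as the
  algorithm specifies); signals with long flat stretches degrade to the
  residue path early.
- The NumPy engine is single-threaded and CPU-oriented; it is sized for
  desk-scale experiments, not for 50-subject full training runs.
- Benchmark architectures (Shallow CNN, EEGNet) are not reimplemented; the
  `base_estimator` hook accepts published implementations.
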