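# Methods

This note records the models implemented by `eegstream`, the assumptions
behind them, and the reasoning for every numerical choice that the interface
exposes.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scalp-grid representation

An EEG cap is modelled as a montage: each of the `n` channels occupies one
cell of a `d × d` grid that preserves left/right and anterior/posterior
adjacency (row 0 is the frontal row).  The bundled DEAP montage places 32
channels on a 9×9 grid; it ships as a plain TSV table
(`eegstream/data/deap_9x9.tsv`) so other caps can be added without code
changes.  Channel indexing is 1-based at the interface (cap convention) and
converted once at array boundaries.  Only seven electrode names are attached
(CP1, PO3, Oz, Pz, Fp2, CP2, PO4) — the names that are unambiguous for this
layout; the rest are positional, and EDF-by-name loading therefore requires
a user-supplied fully named montage table.

## Normalization

Each channel is z-scored per subject over all of the subject's retained
samples (baseline trimmed first, so pre-trial samples never enter any
computation).  Per-channel scope is what makes frame values comparable
across electrodes; per-subject scope preserves trial-to-trial amplitude
differences within a subject, which is where class information lives.  A
channel whose pooled standard deviation is below 1e-12 is zeroed with a
logged warning rather than amplified by a near-zero division.

## Gaussian RBF densification

A sparse frame is densified by scattered-data interpolation with the
Gaussian kernel `φ(r) = exp(−ε²r²)`: solve the collocation system
`Φλ = v` at the electrode coordinates, then evaluate
`f̂(x) = Σ λ_i φ(‖x − x_i‖)` on a uniform query grid spanning
`[0, d−1]²` with inclusive endpoints.  Choices:

* **Collocation weights.**  A plain superposition of kernels centred at the
  electrodes without solved coefficients cannot reproduce the measured
  values at the electrodes; solving for λ is what makes the surface honor
  observations while filling gaps, which is the representation's stated
  purpose.
* **ε = 1.0 by default**, in grid-cell units: kernel width on the order of
  inter-electrode spacing.  Smaller ε flattens the surface and eventually
  makes Φ numerically singular — fits reject condition numbers above 1e12
  with advice to raise ε or add the optional ridge term (default 0, i.e.
  exact interpolation).
* **Query grid spans the montage square** so electrodes are interior points
  and no extrapolation-margin convention is needed.
* **Resize strategy.**  `direct` (default) evaluates the interpolant
  straight on the 64×64 output grid — one interpolation, no compounding.
  `two_stage` evaluates on the native 9×9 grid and bilinearly resizes, for
  ablation against pipelines that resize images after interpolation.  At
  native output size the two modes coincide exactly.
* `FrameMaker` caches the Cholesky factor of Φ and the query kernel, so
  densifying a w-sample window is two matrix products; output matches the
  one-shot path to solver round-off.

## Streams and labels

Windows are non-overlapping by default (`stride = window`): 60 streams per
60-s trial at `w = 128` forces this; an optional stride exists for
experimentation.  Ratings at exactly 5 are "high" (inclusive threshold).
Quadrant labels concatenate the arousal and valence binaries
(e.g. HALV = high arousal, low valence).  The 4-class task is single-label
4-way classification.  Dominance and liking ratings are carried through the
containers but never used for labels.

## Network architectures

Both classifiers default to 7×3×3 kernels padded 3×1×1 (resolution
preserving): EEG streams are long in time (128) and small in space (64), the
opposite of natural video.

**C3D-style.**  Five blocks of [conv → batchnorm → ReLU → max-pool], channel
progression 64, 128, 256, 256, 256, then two FC blocks and a classifier.
Unstated details resolved as follows: pooling is 2×2×2 in every block
(symmetric halving is the simplest reading of one 3D max-pool per block;
128×64×64 input yields a 4×2×2 map after five poolings), and the FC width
defaults to 4096 (the C3D convention), both configurable.  Under these
defaults the network has 44.4M parameters; the originally reported 53.15M
cannot be derived without the unstated pooling and FC widths, so the count
is exposed (`count_parameters`, `eegstream inspect`) rather than asserted.

**R(2+1)D-style.**  Stem: spatial convolution (45 channels, 1×3×3) then
temporal convolution (64 channels, 7×1×1), each with batchnorm + ReLU.  The
stem's 45 is the printed constant inherited from the original factorized
design, not the mid-channel formula (which would give 8 for a 1→64 layer).
Four residual blocks `z_i = z_{i−1} + F(z_{i−1})` follow — the standard
causal form of the recurrence.  F is two factorized (2+1)D layers; both use
the intermediate width

    mid(in, out, t, d) = max(1, ⌊ t·d²·in·out / (d²·in + t·out) ⌋)

(each computed from its own in/out), the width at which the spatial+temporal
pair spends the same parameter budget as the full t×d×d kernel.  Flooring
with a minimum of 1 is the conservative rounding of a generally non-integer
formula.  Blocks 2–4 downsample by stride 2 on all three axes (spatial
stride on the spatial convolution, temporal stride on the temporal one) with
a 1×1×1 stride-2 projection shortcut + batchnorm.  Head: global average
pooling, FC 512, FC classes.  Convolutions followed by batchnorm carry no
bias (redundant with the batchnorm shift; this affects parameter counts).
Under defaults this network has 33.5M parameters.

Both builders accept arbitrary channel lists, kernel depths in {3,5,7,9,…}
(padding auto-set to (t−1)/2) and input shapes, which is how the kernel-depth
and stream-size sweeps are expressed.

## Numerical engine

No deep-learning framework is used: `eegstream.nn` implements the layers and
their exact backward passes in float32 numpy.  Convolution is evaluated
either by one im2col unfold plus a single BLAS product (when the unfolded
matrix fits in a 192 MiB budget — the regime of reduced-scale training) or
by kernel-offset decomposition (full-size inference), and the two paths
agree to float32 round-off; tests check both against finite differences.
Max-pool breaks ties toward the first element in the 2×2×2 cell; odd
trailing samples are dropped (floor semantics).  Batch normalization uses
biased batch variance in training and running statistics (momentum 0.1) at
evaluation.  Dropout is inverted (scaled at train time) with *keep*
probability 0.5 in the C3D FC blocks.  Weights are He-initialized from a
seeded generator; one master seed fans out to initialization, shuffling,
augmentation and dropout, making runs bit-reproducible on a fixed BLAS.

## Training protocol

Plain SGD (momentum 0 by default, configurable), batch 16, cross-entropy
over logits (standard choice for these architectures; binary tasks use a
2-way softmax), learning rate `0.01 / 10^⌊epoch/10⌋`, 30 epochs.  Gaussian
noise (zero mean, σ = 1) is added to training minibatches only.  Folds are
drawn at random over streams — faithful to the protocol being reproduced,
and knowingly leakage-prone since streams of one trial can span folds; a
trial-grouped split (`groups=`) and a stratified option are provided for
leakage-safe evaluation.  Class imbalance is not reweighted.

## Synthetic data

The generator emulates the preprocessed-DEAP layout (32 subjects × 40
trials × 32 channels × 63 s at 128 Hz, 3-s baseline, 4–45 Hz band) with
zero-phase band-pass-filtered white noise (order-6 Butterworth, fixed design
for cross-platform reproducibility) plus plantable class effects:
high-arousal trials add a beta-band (13–30 Hz) oscillation of amplitude
`effect_size` on frontal-row electrodes; the valence class flips the sign of
a left/right alpha-band (8–13 Hz) amplitude asymmetry.  Placements follow
conventional emotion-EEG intuition (frontal beta arousal, alpha asymmetry
valence) but serve purely as controllable separability — no biological
fidelity is claimed.  Per-subject gain (uniform ±20%) mimics inter-subject
amplitude variability; ratings are independent across trials, drawn
uniformly on [1,9] or from a specified quadrant mix.  What the generator
deliberately does not emulate: ocular/muscle artifacts, volume-conduction
correlation structure between channels, non-stationarity within a trial,
and rater biases (an optional per-subject rating bias hook would model the
latter).  Passing tests on this data therefore demonstrate that the
pipeline and optimizers recover planted spatio-spectral structure — not
that real-EEG accuracies transfer.

## Reduced-scale evaluation

CPU-scale checks use 200 streams of 32×16×16 (4 subjects × 5 trials ×
2.5 s, window 32, frame 16), `effect_size = 6` (a deliberately strong
planted effect), and narrow models (C3D blocks 8/16, FC 64; R(2+1)D blocks
8/16 with an 8/8 stem, FC 512→32; temporal kernel depth 3).  At this scale
the full-size regularizers starve learning — dropout 0.5 on a 64-wide FC
layer, σ = 1 augmentation, and a 10× learning-rate cut after only 100
optimizer steps leave both networks near chance — so the reduced runs use a
constant learning rate 0.01 with momentum 0.9 and no dropout/augmentation
for 15 epochs.  All of these are exposed configuration knobs, not code
changes.  Under this recipe both architectures exceed 90% 5-fold CV
accuracy and a label-shuffled control stays at chance within 5 points (the
test suite computes these).

## Known limitations

* The exact ε of the original pipeline, its resize strategy (9×9-then-
  resize vs direct evaluation), the C3D pooling/FC widths, and fold
  stratification are unstated in the source protocol; this package exposes
  each as a parameter with the defaults argued above.
* The numpy engine is single-threaded BLAS-bound; full-size training is out
  of scope (inference on the default 1×128×64×64 stream takes tens of
  seconds per model on one CPU).
* Stream-level cross-validation overestimates generalization on real data;
  use the grouped split for honest subject/trial-level claims.
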