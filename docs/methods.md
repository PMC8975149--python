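# Methods

## Problem and model

`canet` classifies lung nodules as benign or malignant from 3-D,
nodule-centred CT crops, optionally using the same nodule at several
annual screening intervals (t0, t1, t2).  The central idea is to make
2-D convolutional backbones — including ones pre-trained on natural
images — usable on volumetric data through *slice-wise attention
pooling*:

1. every axial slice of the crop is encoded by a shared 2-D CNN into a
   feature vector f_i (the per-slice features form the D×N matrix
   F = [f_1 … f_N]);
2. a single shared affine scorer with tanh activation assigns each
   slice an importance score s_i = tanh(w·f_i + b), strictly in
   (−1, 1);
3. the scores are softmax-normalised into attention weights α, and the
   volume descriptor is the weighted sum d = Fα.

The descriptor has length D independent of the slice count, the
mechanism costs exactly D + 1 trainable scalars, and because softmax is
permutation-equivariant the descriptor is invariant to slice order.
Since all scores live in (−1, 1), no attention weight can exceed e²
times another — attention reweights slices, it cannot hard-select one
to the exclusion of numerical mass elsewhere.

For longitudinal classification, one branch (backbone + attention) is
applied per screening interval with *shared weights* (a Siamese
arrangement); the per-interval descriptors are concatenated and fed to
a fully-connected classifier.  The hidden classifier width is 128 units
for a single time point and 2^(6+M) units for M ≥ 2 branches (256 for
pairs, 512 for triplets).

Two baselines ship for comparison: a convolutional-recurrent network
(CRN) that replaces attention pooling with a GRU over the slice
sequence (final hidden state as the volume feature — order-sensitive,
unlike attention), and a 3-D CNN that is the volumetric analogue of the
reference backbone (3×3×3 kernels, same channel progression, each axis
pooled while its extent permits, two 128-unit FC layers,
Glorot-initialised).  At the reference scale the attention model has
roughly a third of the 3-D network's parameters (the 3-D classifier
must ingest the full flattened feature map; the attention model ingests
one D-vector).

## Backbones and numerical choices

* `reference_vgg16`: the standard 13-conv/5-pool stack.  At the default
  64×64 slice input the final pooled map is 2×2×512, flattened to a
  2048-length per-slice feature (the flattened reading is adopted
  because 2048 = 2·2·512 exactly).
* `tiny_test`: three conv blocks (8, 16, 16 channels), two 2× max pools
  and a final 4× *average* pool, feature length 64.  It exists so that
  training-based tests run on one CPU in minutes.  The final pool is
  average rather than max because the discriminative signal in the
  synthetic task is areal (nodule cross-section), which max pooling
  discards.
* Networks are implemented in a small NumPy toolkit (`canet.nn`) with
  reverse-mode gradients: shift-and-matmul convolutions (BLAS-bound, no
  im2col buffer), max/average pooling, dense layers, a GRU, batched
  slice attention, fused softmax cross-entropy and Adam.  All gradients
  are verified against central finite differences in the test suite;
  convolution forwards are verified against `scipy.ndimage.correlate`.
* Initialisation is Glorot-uniform throughout.  Softmax is computed
  max-subtracted.  A fixed input standardisation ((x − 0.125) · 4) sits
  at the front of every network: a lung-windowed crop is dominated by
  parenchyma near 0.11, and without recentring the early optimisation
  stalls at the trivial-classifier plateau.
* "Pretrained" initialisation is an adapter that loads a named-array
  `.npz` into the backbone; no test depends on downloaded weights.

## Preprocessing

Crops are cubes of 80 mm physical edge centred on the annotated nodule
(air-padded, −1000 HU, where the cube exits the scan), trilinearly
resampled to (4.0, 1.25, 1.25) mm so the default grid is 20×64×64, then
intensity-windowed from HU [−1000, 400] onto [0, 1].  Coordinates are
(slice, row, col) with voxel centre i at (i + 0.5)·spacing; crops are
half-open intervals.  The pipeline is deterministic (bitwise-identical
reruns) and metadata-preserving.  Volumes are stored as NIfTI next to a
CSV manifest (patient_id, interval, label, volume_path, centre
coordinates in mm); rows are grouped by patient into interval-sorted
longitudinal series, and duplicate (patient, interval) rows or unknown
label tokens are rejected.

## Training protocol

Patients are assigned to k = 5 stratified folds by greedy round-robin
within each class (grouping by patient ID so no subject appears in both
train and test).  Per CV round, three folds train, one validates, one
tests.  Single-time-point models treat every interval's volume of a
training nodule as an independent sample and are evaluated per interval
(or pooled); multi-branch models use consecutive-interval pairs or the
triplet.  Optimisation is Adam (default learning rate 1e-4, the rate
used with the full-size networks; the tiny profile uses 1e-3) on
cross-entropy, batch 32, early-stopped when validation loss fails to
improve for 10 evaluations (the best-validation weights are restored).
Augmentation draws one geometric transform per longitudinal tuple —
in-plane flips (p = 0.5 each), shifts up to ±10 % of the extent,
rotations up to ±15° — applied identically to every member so the tuple
stays aligned, plus independent per-volume Gaussian noise (σ = 0.01
normalised units); all-zero magnitudes give the exact identity.  No
class reweighting is applied by default.

Metrics: ROC-AUC as Mann–Whitney concordance with ties credited ½;
average precision as the step-wise sum Σ (R_n − R_{n−1}) P_n over
descending unique score thresholds (no interpolation); NLL as the mean
negative log-probability of the true class, clipped at 1e-12.  Both
rank metrics report NaN with a diagnostic on single-class sets; NLL is
still computed.  For radiologist-scored cohorts a manifest-preparation
helper derives labels from median malignancy scores (< 3 benign, > 3
malignant, median 3 dropped).

## Synthetic phantoms

The generator emulates the statistical structure of a longitudinal
screening cohort, not its anatomy: each volume is a soft-edged
(1-voxel sigmoid), mildly anisotropic ellipsoid of soft-tissue density
(+20 HU) on lung-parenchyma background (−850 HU) textured with smoothed
Gaussian noise (60 HU) and a low-frequency intensity ramp, synthesised
directly as an 80 mm crop on a native grid of (2.5, 0.7, 0.7) mm.
Diameter at the k-th scan is baseline + k·growth with one growth draw
per series; the centre is jittered per interval (σ = 1.5 mm) to mimic
imperfect alignment.  Benign subjects get three annual scans, malignant
two or three.  Default cohort scale is 650 benign + 207 malignant
series.  Diameter defaults (benign ≈ N(6, 1.5²) mm, growth ≈ N(0,
0.3²); malignant ≈ N(8, 2²) mm, growth ≈ N(2.5, 0.75²) mm/interval) are
qualitative stand-ins at realistic nodule scales, flagged as such and
fully configurable.  Output is fully determined by the seed.

The `matched_growth_task` variant draws both classes' baselines from
one shared distribution and gives every subject three scans, so only
growth separates the classes: a single-time-point classifier evaluated
at t0 has no exploitable signal, while a multi-time-point classifier
does.  Nodule size is measured as the sphere-equivalent diameter of the
blob thresholded at the parenchyma/nodule midpoint.

What passing tests on phantoms do and do not show: they demonstrate
that the architecture wires and trains correctly, that attention
localises informative slices, and that the Siamese pairing recovers
temporal signal that is absent at a single time point — on a task whose
discriminative feature (size/growth) is known.  They say nothing about
performance on real CT, where texture, spiculation, vessels and
scanner effects carry much of the signal.

## Benchmark experiments (`canet.experiments`)

Both seeded experiments use the tiny profile: phantoms preprocessed to
10×32×32 (8 × 2.5 × 2.5 mm over the 80 mm crop), `tiny_test` backbone,
Adam 1e-3, noise-only augmentation (geometric augmentation adds little
for centred phantoms and dominates CPU time).

* *Separable cohort* (80 series): benign 5 ± 0.75 mm stable vs
  malignant 10 ± 1 mm growing 2.5 mm/interval — a ~2.9 σ baseline gap,
  chosen so that class overlap in the drawn diameters is negligible and
  held-out discrimination measures the model, not the draw.  One CV
  round trains a single-time-point CAN; the held-out fold is scored
  pooled over intervals, and the trained attention is checked for
  localisation (highest-α slice within 2 slices of the nodule's central
  slice).
* *Matched-growth cohort* (100 series): the single-time-point CAN is
  trained in every CV round and its t0 test predictions are pooled
  out-of-fold, so the chance-level check uses all 100 subjects (the
  null sampling σ of AUC at n = 100 balanced is ≈ 0.06; a single
  20-sample fold would be noisier than the effect being tested).  The
  two-branch CAN gets the same training budget on round 0 and is
  evaluated on its test fold's consecutive pairs.

## Known limitations

* The NumPy networks are CPU-bound; the reference-scale models are
  built for parameter accounting and single forward passes, not
  training.
* Phantoms carry no anatomy (no vessels, pleura, spiculation) and no
  scanner physics; absolute metric values on phantoms do not transfer
  to real data.
* The CRN's recurrent module is a single unidirectional 128-unit GRU;
  the historical architecture it stands in for is not fully specified,
  so it is a representative, not exact, baseline.
* Mid-run checkpoint resume is not implemented; checkpoints capture
  final (best-validation) weights plus the model configuration.
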