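# Methods

This note records the scientific and numerical choices behind `scintiseg`:
what the pipeline assumes, what the defaults mean, and what the synthetic
experiments do and do not demonstrate.

## Problem setting

A whole-body bone scan is a pair of planar count images (anterior and
posterior views, 1024×256 each) of tracer uptake.  Metastatic lesions
appear as focal hotspots, but so do normal skeletal structures (spine,
joints), benign processes and artifacts (bladder activity, the tracer
injection site).  The pipeline frames lesion segmentation as three-class
pixel classification — air background (BG), non-metastatic body (NM),
metastasis (M) — on a merged, normalized 640×512 image covering both views
above the knees.

The rationale for the third class: with only BG and M, everything that is
not lesion (air *and* body) is lumped together, and the decision boundary
must absorb the full variability of healthy anatomy.  Supervising NM
separately, and excluding the uninformative air class from the loss,
concentrates learning on the clinically relevant distinction.

## Preprocessing conventions

* **Body detection** finds the contiguous row/column span whose projection
  profile exceeds a noise floor.  The floor defaults to 1% of the maximum
  profile sum (configurable); the clinical sources do not state a value.
* **Cut-and-center** places the detected body on a 950×256 canvas.
  "Centering" is realized as an integer horizontal shift moving the
  intensity-weighted centre of mass to the canvas midline; intensity
  weighting makes the estimate insensitive to sparse air noise.  No
  rescaling or interpolation is applied anywhere in the chain, so pixel
  values and lesion geometry are preserved exactly.  Bodies taller than
  950 rows are bottom-truncated with a logged warning.
* **Brightness normalization** multiplies the image by
  `10.5 / current mean` (the band midpoint over the current mean), clips to
  [0, 255], and repeats until the mean lies in the open band (7, 14) or the
  iteration cap is hit.  The transform is a single linear gain per pass;
  clipping is the only nonlinearity and only triggers for extreme inputs.
  The mean is taken over the whole image (air included) by default, with a
  body-only option for sensitivity analysis.  The band is treated as open
  at both ends.  Because the above-knee crop can move the mean of the
  merged image slightly, the chain re-applies one gain pass on the merged
  image when needed, keeping the end-to-end transform linear.
* **Row conventions** are 0-based half-open: "above the knees" keeps rows
  [0, 640).

## Label construction

* **Otsu route.**  The threshold maximizes between-class variance on the
  256-bin integer histogram of the 8-bit image; ties resolve to the
  smallest maximizer.  NM = pixels above threshold minus the annotated M
  mask.  The threshold is computed by cumulative moments (exact, O(256)
  after the histogram); the test suite checks it against exhaustive search.
* **Mining route.**  A two-class model trained on positive samples only is
  run over lesion-free images; every predicted-M pixel there is a false
  positive by construction and becomes NM.  On positive samples the
  annotated M regions are subtracted first (realized as a set subtraction
  of the ground-truth mask, which is the same operation a manual exclusion
  performs).  Binarization is the class argmax; no extra confidence
  threshold.  Inside cross-validation the miner is trained per fold on that
  fold's training positives only, so mined labels never see test data.
* No morphological cleanup is applied to NM masks by default.

## Losses

Per class channel `c`, with `y` one-hot truth and `p` SoftMax probability:

* Dice loss `1 − (2Σyp + s) / (Σy + Σp + s)`;
* focal Tversky loss `(1 − TI)^γ`,
  `TI = (Σyp + s) / (Σyp + αΣ(1−y)p + βΣy(1−p) + s)`,
  with α = 0.3 (false-positive weight), β = 0.7 (false-negative weight),
  γ = 0.75 (easy-example down-weighting).

Sums run over all pixels of one image; batches average per-image losses;
the multi-class loss is the unweighted mean over non-excluded classes
(sum-vs-mean is not pinned by the sources; the mean keeps magnitudes
comparable across class counts).  The smoothing term defaults to `s = 1e-6`
so empty-class images remain finite; oracle tests use `s = 0` to match the
printed formulas exactly.  Excluded classes (default: BG) contribute no
term, so the loss gradient with respect to the BG channel is identically
zero; BG probabilities are still constrained implicitly through the
SoftMax.

## Network

The modified Double U-Net chains two U-Net-style encoder–decoders.
Sub-network 1 uses an atrous pooling bottleneck (parallel 3×3 convolutions
at dilation rates 1/2/4, summed); its SoftMax output gates the input by the
foreground probability `1 − p(BG)` before sub-network 2 — with a
multi-class head there is no single sigmoid channel to multiply by, and the
foreground probability is the natural generalization.  Sub-network 2's
decoder concatenates skip features from both encoders.  Both heads emit
n-class SoftMax maps; the second head is the final prediction, and
supervision of the first head is available behind `dual_output` (default:
final head only).

The implementation is a compact numpy reverse-mode autodiff engine
(`scintiseg.nn`): same-padded dilated convolution evaluated as
kernel-offset matmuls, 2× max-pooling and nearest-neighbour upsampling,
instance normalization, channel SoftMax, and Adam.  Instance normalization
after every internal convolution is load-bearing: without it, deep relu
stacks saturate the SoftMax head early and the rare M class can die.
Weights are He-initialised from a per-model seed; every forward pass is
deterministic.

The default input scale maps 8-bit intensities to [0, 1].  The `tiny`
preset (64×64 input, widths 8/16/32) exists so the full pipeline trains in
tens of seconds on one CPU core; the full-size preset (640×512, widths
32/64/128) uses the same code path.

## Experimental harness

Cross-validation partitions the positive samples into k disjoint test sets
(default k = 10), splits each fold's remainder 8:1 into training and
validation, and — when negative augmentation is on — appends *all* negative
samples to every fold's training set, leaving test sets untouched.
Validation loss selects the best checkpoint when a validation set is used.
The training iteration count is interpreted as epochs by default, with a
steps mode for desk-scale runs.  The optimizer is Adam (the sources name
none; Adam is the de-facto default for this architecture family), at
learning rate 1e-4 for full-scale settings.

Transfer learning pre-trains once on the full pre-training cohort (Otsu
labels, negatives included, no inner cross-validation — the single-pass
reading of an ambiguous protocol) and initializes every fine-tuning fold
from the pre-trained weights.

All randomness (fold splits, initialisation, shuffling, phantom content)
derives from one master seed by fixed integer arithmetic; identical seeds
give bit-identical runs.

**Collapse restarts.**  Tiny overlap-trained networks occasionally fall
into a degenerate basin where the M probability is confidently zero at
every lesion pixel (observed at roughly one unlucky initialisation in
four on hard folds; learning-rate and loss changes do not rescue it once
locked, because the saturated SoftMax yields vanishing gradients).  The
harness detects this signature — zero predicted-M overlap on the fold's own
training positives — and retries the fold from a new derived seed, at most
twice.  The retry is deterministic and logged.

## Phantoms and what the synthetic experiments show

The generator emulates the *statistical structure* of clinical scans, not
scanner physics: a connected, horizontally centred body silhouette over
Poisson air noise (counts), skeleton-like high-uptake structures, additive
Gaussian-profile lesions with random eccentricity and exact ground-truth
masks, and optional bladder / injection-site hotspots at anatomically
plausible locations.  Two presets matter:

* **default / high-contrast** (lesion amplitude 150–230 over body 80–130):
  lesions are unambiguous; used for overfit sanity checks and oracle tests.
* **clinical-difficulty** (`clinical_like_config`: amplitude 50–140,
  overlapping the bright skeletal structures, confounders on): the
  background-interference regime in which the three-class protocol has
  something to contribute.

Desk-scale experiment settings: 64×64 phantoms, the tiny network, batch 4,
learning rate 3e-3 (the tiny preset needs a larger step than full-scale
training), 100–200 optimiser steps, 2 folds over 10–12 positives.

On clinical-difficulty cohorts the three-class Otsu protocol's test F1
exceeds the two-class baseline's *on average over seeds* (mean advantage
around +1 F1 point over three seeds in the shipped configuration), but the
per-draw delta is noisy (roughly −0.5 to +2.6 across cohort draws).
Passing this check shows the pipeline reproduces the *direction* of the
protocol effect under controlled conditions; it says nothing quantitative
about clinical images, whose anatomy, artifact spectrum and annotation
noise the phantoms do not model.  The published clinical per-fold tables
are used only to verify metric and aggregation arithmetic, never as a
reproduction target.

## Known limitations

* The phantom silhouette is a fixed geometric family; no patient-to-patient
  anatomical variability beyond noise, lesion placement and confounders.
* No attenuation, scatter, or camera response; counts are idealized
  Poisson.
* The numpy engine is CPU-bound and single-threaded beyond BLAS; full-size
  (640×512) training works but is slow — the package's experiments are
  designed for the tiny preset.
* The mining route inherits the quality of the positives-only miner; with
  very short training budgets its NM masks can be nearly empty.
* Aggregate F1 is the harmonic mean of mean precision and mean sensitivity;
  recomputed summary values can differ from independently rounded published
  rows by ±0.01.
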