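# Methods

This note documents the models and procedures implemented in `punctaseg`,
the parameter choices that matter, and what the synthetic benchmark does
and does not demonstrate.

## Synthetic stack generator

Every quantitative claim in this package is measured on images from
`punctaseg.synthetic`, which emulates a two-channel confocal stack of a
single labelled neuron.

**Geometry.** The neurite is a tube of radius `neurite_radius` (default
2 voxels) around a polyline through the volume; the tube (with a one-voxel
soft edge) forms the cytoplasmic channel. The rasterised polyline is also
the ground-truth skeleton, a single unbranched chain rooted at the first
control point (the soma end). Axis order is (Z, Y, X) with 0-based voxel
indices; rendering treats the grid as isotropic, while anisotropic voxel
spacing is carried as metadata and honoured by the quantification stage
(arc lengths, nearest-node distances, volumes).

**Puncta.** Each punctum is an isotropic Gaussian blob of amplitude
`peak − background` with σ = radius/2, centred on a neurite voxel; its
ground-truth label is the noiseless support at or above half peak (radius
≈ 0.59 × the nominal radius). Under the default non-overlap placement,
centres are rejected until all half-peak supports are separated by more
than a voxel diagonal, so the truth has exactly `n_puncta` 26-connected
components; if bounded retries fail, the generator raises with the count
achieved. Clutter blobs drawn from the same intensity distribution are
placed at least three tube radii from the skeleton to mimic
autofluorescence from other tissue — they are absent from the truth and
exist to be rejected by the neurite mask.

**Presets.** Four regimes fix radius band and contrast: small puncta
(radius 1–3 voxels) at nominal SNR 3 (`small_low_snr`, peak 160 over
background 100, noise SD 20) or SNR 20 (`small_high_snr`, peak 400, noise
SD 15); `medium` (radius 3–10); `diffuse` (radius > 10). SNR is defined
as (peak − background)/noise SD. The default study condition used by the
tests and the acceptance script is `small_high_snr` with 20 puncta in a
16×80×80 stack — small and clearly detectable puncta, the regime in which
count recovery is a meaningful end-to-end measure. Noise levels are a
design choice of this package; they are not calibrated to any particular
microscope or strain.

**What the generator does not model:** the point-spread function
(blobs are Gaussian by construction, not by convolution), depth-dependent
attenuation, anisotropic optical resolution, body curvature, multiple
animals per field, or structured background. Passing the synthetic
benchmarks therefore demonstrates the correctness and internal
consistency of the pipeline, not segmentation accuracy on any real
reporter strain.

## Two-layer synapse pixel classifier

**Features.** Nine per channel (synapse always, cytoplasmic when
present): raw value; in-plane Sobel gradient magnitude; difference of
Gaussians at scale pairs (1,2) and (2,4) voxels; Laplacian of Gaussian at
scales 1 and 2 (corrected so the truncated kernel is exactly zero-sum on
flat fields); local mean and standard deviation in a 3×3×3 window;
grayscale erosion with a 3×3×3 structuring element. Sobel/DoG/LoG are
applied slice-wise (puncta are small in z and slices are the natural
plane of the data); mean/SD and erosion are fully 3D. Scales {1, 2, 4}
bracket the small-punctum radius band and are configurable per preset.
Boundaries are reflected. Features are standardised by a scaler fitted on
the training pixels.

**Patch sampling.** Training pixels are restricted to the in-plane
patches containing positive labels. The patch side is twice the square
root of the mean per-slice connected-label area (8-connectivity in-plane),
rounded, floored at 3.

**Layer 1, step 1.** All positive pixels plus negatives sampled from a
2-voxel dilation band around the positives, at 3 negatives per positive.
Both the band width and the ratio are configurable; training only on
near-positive negatives keeps the initial set small but biases the
classifier toward false positives.

**Layer 1, step 2 (hard negatives).** The step-1 classifier predicts over
patches 10× the sampling side; negatives it marks positive are added to
the training set (capped at 30 000, seeded subsample beyond that) and the
classifier is retrained. A `harvest="false_negative"` flag implements the
alternative reading (adding missed positives) for comparison; the default
harvests false positives, the choice consistent with correcting a
type-I-error-prone first pass.

**Layer 2.** Each training pixel's feature vector is extended with the
layer-1 probabilities of its six face neighbours (out-of-volume
neighbours inherit the centre pixel's probability), and a classifier of
the same family is trained on the extended vectors. This encodes the
prior that synapses are larger than one pixel: a pixel adjacent to
confident foreground is more likely foreground than an isolated
look-alike.

**Model selection.** Hyperparameters are grid-searched with five-fold
cross-validation at each fit. Default grids: random forest with
{100, 300} trees × max depth {none, 16}; SVM C ∈ {1, 10}; MLP (one
hidden layer of 50) alpha ∈ {1e-4, 1e-3}. The grids are deliberately
small — the procedure matters more than their extent — and configurable.
All stochastic steps take an explicit seed (default 0); the scaler is
fitted once on the step-1 pixel set so layer-1 probabilities remain
consistent across the two steps.

**Prediction.** With a neurite mask, only mask pixels are classified and
the prediction is a subset of the mask by construction; without one, the
whole volume is scanned. The binary call is probability ≥ 0.5. An
overlay volume (prediction outlines burned into the raw channel) supports
visual review, and `edit_labels` applies add/remove voxel corrections so
corrected predictions can be fed back as training labels.

## Neurite U-Net

**Architecture.** Input is a chunk of 7 consecutive slices; the target is
the centre slice. The depth axis is collapsed by the first convolution
(slices enter as channels), after which the network is a standard 2D
encoder–decoder: per level two 3×3 conv + ReLU, 2×2 max pooling,
nearest-neighbour upsampling with skip concatenation, 1×1 output head.
Defaults are 3 levels starting at 8 feature maps — sized for the
synthetic tubes and single-CPU training; levels, width and chunk depth
are configurable. The implementation is pure numpy with hand-written
backpropagation, gradient-checked against central finite differences.

**Training.** Loss `L = L_IoU + L_CE` with the soft Jaccard loss over
the foreground (exactly 0 for a perfect one-hot match; defined as 0 when
both target and prediction are empty). Adam at learning rate 1e-3, batch
size 8, at most 200 epochs with early stopping (patience 20, best-weights
restore) on validation loss; random flips and 90° rotations each epoch.
Stacks are standardised per image (zero mean, unit variance) at training
and inference. Random tiles are sampled per image (200 by default) and
near-blank tiles discarded by a mean-intensity threshold (default 0 =
keep everything; the useful value depends on the data's background
level). Per-epoch metrics (loss, and precision/recall/F1/IoU of the
neurite class plus overall accuracy) are recorded in the model history.

**Inference.** Chunks are depth-padded by mirror reflection at the z
boundaries (a single-slice stack yields seven copies of that slice) and
laterally tiled; when the frame is not a multiple of the stride the last
tile is boundary-aligned and stitching keeps the first-written value, so
every voxel is predicted exactly once. The probability map is thresholded
at 0.5 by default. Optional soma removal excises, per slice, the voxels
within the soma radius of any point whose in-plane thickness exceeds the
soma diameter — thin neurites never enter the core, so a tube attached to
a cell body survives while the body is cut out. Removal is off by
default.

## Quantification

Puncta are connected components of the prediction (26-connectivity by
default; 6 and 18 available, and the choice changes counts for touching
puncta). Volume is voxel count × voxel volume; intensity statistics come
from the synapse channel. Skeletons are read from SWC (single root
required; the root is the soma unless a type-1 node exists) with
arc lengths accumulated along spacing-weighted edges. Each punctum maps
to the Euclidean-nearest node of its centroid, with exact ties broken
toward the soma for determinism. In `per_voxel` mode, puncta of at least
the voxel count of a radius-10 sphere (~4 169 voxels, the boundary of the
"diffuse" regime) are mapped voxel-by-voxel instead, smoothing the
contribution of large unresolved blobs. Normalisation is either by total
neurite length (0 = soma, 1 = furthest terminal) or by the synapse
domain, which maps the extreme occupied nodes to exactly 0 and 1; a
degenerate zero-length domain maps to 0.5.

Population densities pool all worms: positions weighted by voxel counts,
histogram divided by (total pooled synaptic volume × bin width), so the
density integrates to 1 regardless of binning. A `per_worm_average` flag
instead averages each worm's unit-integral density, weighting animals
equally rather than by synaptic volume. Per-image summaries report count,
total/mean volume, mean intensity, synapse-domain length, and count and
volume densities over the domain; a single-punctum image has a zero-length
domain and densities are reported as undefined (None/NaN), never infinite.
An empty image yields an all-zero summary row.

## Evaluation protocol

IoU between two empty volumes is defined as 1 (perfect agreement on
absence). The training-size benchmark trains on every combination of the
dataset at each size, capped at 50 seeded-subsampled combinations, and
scores hold-outs per image then averages (pooled-voxel IoU is not used;
per-image averaging weights small and large images equally). The
inter-annotator benchmark is the mean off-diagonal of the pairwise IoU
matrix.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at
desk scale, a deliberate design point of this package: 16×80×80 stacks
with 20 puncta, U-Net training on 10 stacks with 6 random 64×64 tiles
each for ≤50 epochs (10:2:4 train/val/test split), benchmark combination
caps of 2–3, and 5–10 seeds per stochastic measurement. These sizes keep
a full from-scratch reproduction under ~10 minutes on one CPU while
leaving every procedure identical to its full-scale form.

## Known limitations

- The numpy U-Net is single-threaded and sized for small tiles; real
  256×256 chunks and deeper networks would want a GPU framework.
- Only unbranched skeletons are generated synthetically; branched SWC
  trees are supported in quantification, but the bundled mask
  skeletonizer (`skeletonize_tube_mask`) handles tube-like masks only.
- SVM and MLP families are functional but less exercised than the random
  forest default; SVM probability estimates make its two-layer variant
  comparatively slow.
- Pixel-level scores on the synthetic truth are bounded by the half-peak
  label convention: dim blob skirts are genuinely ambiguous, so IoU
  around 0.7–0.75 on small puncta reflects the label definition as much
  as classifier quality; punctum counts are the more robust end-to-end
  readout.
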