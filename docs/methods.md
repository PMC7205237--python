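# Methods

This note documents the models, parameter choices, numerical details and
known limitations of the vegseg pipeline.

## Data model and preprocessing

Imagery is handled as `Raster` objects: an (H, W, C) value grid, channel
names, a boolean nodata mask and the source bit depth. A pixel masked in
any band is masked in all derived products. Digital numbers are scaled
by 1/(2^bits − 1) before any index computation. Ratio indices (NDVI, CI,
VARI) are invariant to that scaling; EVI and SAVI are not, because of
their additive constants, so fixing the convention matters and it is
fixed here: **all indices are computed on [0, 1]-scaled values.**

Large scenes are processed as 800×800 tiles (row-major, 0-based origin
offsets). Partial edge strips are processed like full tiles. Masking
runs on the whole scene, not per tile: the 2-cluster NDVI split adapts
to the full NDVI distribution of the analyzed extent, so changing the
extent changes the mask — a boundary-condition sensitivity users should
be aware of.

I/O is multiband TIFF through `tifffile`, with channel names, nodata
value, bit depth and the (opaque) georeferencing record carried in a
JSON ImageDescription tag. Round-trips through the package are
bit-exact for integer sources; foreign GeoTIFF tags are not parsed.

## Index formulas and the dialect switch

Two spellings of EVI, ARVI and VARI circulate: the classical ones and a
variant in which one denominator sign flips (ARVI: NIR + 2R **+** B;
VARI: G + R **+** B; EVI: **+**7.5B). The package computes the variant
spelling by default (`formula_dialect="as_printed"`) and provides the
classical one (`"canonical"`); the dialect in force is stamped into
every stack and report. For non-negative reflectances the printed
dialect keeps VARI within [−1, 1] and every denominator positive.

Division guards: denominators get an additive ε = 1e-9; pixels whose
unguarded denominator would vanish are counted per index
(`ChannelStack.degenerate_counts`) rather than becoming NaN, so
downstream clustering needs no imputation. SAVI uses L = 0.5, the
canonical intermediate-vegetation value; SAVI reduces exactly to NDVI at
L = 0.

## Clustering engines

Pixels are clustered in the 10-channel space. Raw bands (0–255 before
scaling) and indices (−1..1) live on different scales, so per-channel
standardization (zero mean, unit variance over the clustered pixels) is
applied by default; a switch reproduces raw-space behavior, and a test
documents that the toggle changes assignments on mixed-scale data.

**k-means** is Lloyd's algorithm with k-means++ seeding (first centroid
uniform, subsequent ones ∝ squared distance to the nearest chosen
centroid), Euclidean distance, k = 5, ≤ 20 iterations, convergence when
the largest centroid shift drops below 1e-4. Emptied clusters are
reseeded at the point farthest from its centroid; assignment ties break
toward the lowest label. Lloyd converges to local optima, so
`n_init = 10` independent seedings are run and the lowest-inertia
solution kept — without restarts, recovery of planted scene structure
was seed-dependent (observed failure modes: merging soil with the
"other" cover, splitting the shadow cloud).

**Gaussian mixture**: EM with full covariances, k = 5, ≤ 20 iterations.
Convergence is tested on the posterior probabilities themselves — EM
stops when no responsibility changes by more than 1e-4 — rather than on
the likelihood bound. Covariances get δ = 1e-6 on the diagonal each
M-step. Initialization: k-means++ seeds for means, pooled sample
covariance, uniform weights; `n_init = 10` seedings, best final
log-likelihood kept (EM has the same local-optimum behavior as Lloyd).
The log-likelihood trace is recorded and non-decreasing within a run.

**Secondary class membership.** A pixel assigned to water/shadow still
carries posterior mass in every other class; the runner-up reveals the
cover beneath shadow. When segments have been assigned land-cover
classes (several segments may share one class — class assignment is
per-segment naming, and merging is allowed), responsibilities are summed
per class first, so "second most likely class" means the runner-up
land-cover class, not another segment of the same class.

## The unsupervised CNN

A small NumPy CNN: three 3×3 convolution layers (100 filters each, ReLU
then batch normalization) and a 1×1 classification head with batch
normalization; per-pixel argmax over the 100 response channels gives the
current labels. Each update: (1) forward pass and argmax labeling;
(2) SLIC superpixel majority refinement (ties to the lowest label);
(3) softmax cross-entropy between the response map and the refined
labels, backpropagated with SGD (lr 0.1, momentum 0.9). Training stops
when the surviving-label count is ≤ 5 or after `max_updates` (default
100). The label count starts at tens of groups on textured scenes and
collapses as the network self-trains.

Numerical choices: He initialization under the run seed; float32
arithmetic; batch-norm uses training-mode statistics throughout (the
single-image setting has no separate inference phase); masked pixels are
excluded from the loss and carry −1 in the output; the trace records
per-update loss and label count. Runs are deterministic for a fixed
seed on one platform.

SLIC comes from scikit-image, applied by default once to the input
stack (`slic_target="input_stack"`); a `"feature_map"` mode recomputes
superpixels on the evolving response map each update. For multispectral
input the channels are standardized so the published compactness scale
(10) keeps its meaning. SLIC is grid-initialized and deterministic; the
`seed` field is recorded for interface uniformity but has no effect.
The defaults (10,000 superpixels for an 800×800 tile ≈ 64 px per
superpixel) scale down proportionally on smaller scenes in tests and in
the acceptance script (e.g. 256 superpixels at 128×128), keeping the
spatial granularity of the published protocol.

## Evaluation machinery

**Davies–Bouldin:** DBI = (1/K) Σᵢ maxⱼ≠ᵢ (sᵢ + sⱼ)/dᵢⱼ with sᵢ the mean
Euclidean distance of cluster i's members to their centroid. Lower is
better. Coincident centroids raise an error naming the pair. The
implementation is verified against a literal brute-force evaluation (to
1e-12) and scikit-learn's.

**Confusion and metrics:** rows are predicted, columns true. Overall
accuracy = trace/total; per class, recall = diagonal/column sum,
precision = diagonal/row sum, F1 their harmonic mean; zero denominators
yield 0 with a flag. Full precision is kept internally; display rounding
(round vs truncate, 2 decimals) is configurable because published
two-decimal tables are not always consistent about which was applied.

**Label matching:** unsupervised labels are arbitrary, so accuracy is
computed after optimal one-to-one Hungarian matching on the
(predicted × true) contingency table; surplus labels stay unmatched.
For engines with variable label counts (the CNN), per-segment majority
naming (`majority_mapping`, merging allowed) is used instead, mirroring
manual class assignment.

**Gini channel importance** is concretized as the normalized
impurity-decrease feature importances of a seeded
`RandomForestClassifier` (50 trees, ≤ 50,000 sampled pixels) predicting
the final segment labels from the 10 channels; surrogate descriptor and
seed are stamped into the report. Coefficients sum to 1.

## Synthetic scenes

The generator paints geometric primitives (rectangles, ellipses, lobed
blobs, a meandering river strip) with per-material 4-band signatures,
then applies, in order: linear spectral mixing within
`boundary_mix_width` pixels of class borders; multiplicative shadow
darkening (factor 0.55 by default) of the underlying cover; per-class
Gaussian scatter plus additive band noise (σ = 0.01); clipping to
[0, 1]; 8-bit quantization (on by default, matching NAIP's depth).
Truth planes carry the 5-class label, a pervious flag (False for
impervious surfaces and pure open water — the covers masking must
drop; shadowed vegetation and sediment-mixed river water stay
pervious), a shadow flag and the substrate class beneath shadow.

Default signatures satisfy NIR(tree) > NIR(grass) > NIR(soil) >
NIR(water) and NDVI ordering tree > grass > soil > impervious > water,
with pervious covers at NDVI ≥ 0.37 and impervious near 0.03 so the
NDVI field is strongly bimodal, as it is over real urban scenes where
this masking strategy works. Covariances are isotropic sensor noise
(sd 0.012 ≈ 3 DN) plus a rank-one brightness term (β·mean)(β·mean)ᵀ
modeling within-class illumination variation — physically, sun-angle
and canopy self-shading, which scale all bands together and therefore
leave ratio indices untouched. Canopy gets the largest β (0.10 by
default; 0.22 in the `shadow_river` scene's mature riparian stand).
This term is what makes shadow physically continuous with dark canopy,
so that a mixture model's secondary membership under shadow points back
to the substrate.

Canned scenes: `five_class_easy` (all five pervious classes ≥ 2% each
plus a road; class separation ≥ 4× the noise scale), `shadow_river`
(tree stand casting shadow, sediment-mixed river strip that survives
masking, pure-water pond and road that do not), `mixed_boundary` (a
grass/soil split with a 3-pixel mixing zone and zero scatter — a pure
mixing-model diagnostic). Scenes regenerate bit-identically from
spec + seed.

**What passing on synthetic scenes does and does not show.** The scenes
exercise the mechanisms the pipeline relies on — NDVI bimodality,
spectral separability, multiplicative shadows, mixed pixels,
quantization — but real imagery adds inter-class spectral overlap,
within-class trends, texture, georegistration error and label noise that
the generator does not emulate. Synthetic recovery rates (masking
≈ 99.8%, k-means ≈ 0.97) are therefore upper bounds on real-scene
behavior, not forecasts; the published real-scene accuracies
(k-means ≈ 0.80 overall) indicate the realistic range.

## Problem sizes

The test suite and acceptance script run scaled-down instances chosen to
exercise every mechanism at desk scale: 192×192 scenes for the
end-to-end clustering checks, 128×128 for the CNN engine (with 256
superpixels, preserving superpixel density), 48×48 with 24 filters for
CNN unit tests. The acceptance script completes in about a minute on a
single CPU; the full test suite in about two.

## Known limitations

- The GMM is the slowest engine and, as documented in the evaluation
  tests, the weakest at hard classification; its value is secondary
  membership.
- Per-segment class naming requires either reference labels or a manual
  mapping; the package does not attempt spectral rule-based naming.
- The CNN engine's final label count is emergent: it can stop below 5
  labels on low-diversity scenes (the stopping rule is ≤ min_labels).
- SLIC's `seed` is accepted but inert (grid initialization).
- Georeferencing is carried as opaque metadata; no reprojection,
  mosaicking or atmospheric correction.
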