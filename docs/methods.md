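# Methods

## Weak labeling model

The central modeling assumption is that the per-patch mean of the
propidium-iodide fluorescence channel is a mixture of two Gaussian
components: a low-intensity component over patches dominated by live cells
(intact membranes exclude PI) and a high-intensity component over patches
dominated by dead cells. The mixture is fitted to the per-patch means of a
*reference condition* — one with a roughly balanced live/dead composition —
by expectation–maximization: 10 independent k-means-initialized restarts
with convergence tolerance 1e-6, keeping the restart with the highest
log-likelihood (all candidate log-likelihoods are retained in the model's
diagnostics). Components are mapped to classes strictly by sorted mean
(low = live), never by fit order.

Labels follow a one-standard-deviation rule: patches with mean below
`mu_live + sigma_live` are live, above `mu_dead - sigma_dead` dead, and the
closed band between the two cut-offs is discarded as ambiguous (boundary
values are discarded — the conservative choice). The same thresholds,
fitted once on the reference condition, are applied unchanged to all
conditions, so labels remain comparable across treatments. Thresholds are
pure arithmetic on the fitted parameters and carry no tolerance. With the
package's default mixture parameters (means 224.51/550.44, standard
deviations 34.46/153.55) the cut-offs are 258.97 and 396.89.

Mean fluorescence is always computed on the raw 16-bit intensity scale.
The 8-bit conversion (`round(v/257)`, half away from zero) is a display and
classifier-input convenience; collapsing to 8 bits before labeling would
saturate the high component (the default dead-component mean, 550, exceeds
the 8-bit maximum).

## Patch geometry

Crops are 224x224 (the standard input size of common pretrained backbones)
on a sliding grid with stride 112 by default — 50% overlap, which augments
the patch count; the overlap fraction is a package choice. When the grid
does not land on the far edge, one trailing patch flush with the border is
added per axis so no pixel is lost. Coordinates are 0-based, top-left
origin, half-open intervals. Patch counts are therefore deterministic:
e.g. a 1344x1024 capture yields 6x5 = 30 patches at stride 224 (the y axis
needs a trailing row) and 11x9 = 99 at stride 112.

## Empty-patch curation

Patches are summarized by the globally average-pooled output of the last
convolutional layer of a frozen backbone (global average pooling is the
package's choice of spatial reduction). The detector is a supervised
two-class SVM (RBF kernel, features standardized, class weights balanced)
trained on labeled sets of empty and properly captured patches; although
the task is often phrased as outlier detection, labeled examples of both
classes are available, which a supervised SVM exploits directly. A
one-class (novelty-detection) mode fitted on non-empty features only is
kept as a config option. The f1 score of the empty class is the curation
metric.

The shipped feature extractor is a fixed-seed random-weight convolutional
network with the same 224x224 -> pooled-vector contract as a pretrained
backbone's final convolutional block. Random convolutional features retain
the intensity/texture statistics that distinguish background-only patches
from patches containing cells; any pretrained network exposing
`feature_dim`/`features()` can be dropped in for real data.

## Splitting and imbalance

Patches from one raw capture are near-duplicates of their neighbours
(overlapping crops, shared illumination), so partitioning is at the
raw-image level: a greedy allocator takes groups largest-first (ties broken
by a seeded shuffle) and assigns each to the partition furthest below its
target patch share, approaching 80/10/10 despite unequal patches per image.
Discard-band patches are removed before splitting. The no-leakage property
(no raw image in two partitions) is exact by construction and checked
exhaustively in tests.

Class weights are unnormalized inverse class counts; the with-replacement
sampler normalizes them per draw, giving each class an expected draw
frequency of 1/2 regardless of imbalance.

## Classifier and training loop

Training minimizes softmax cross-entropy under Adam with betas (0.5,
0.999), weight decay 1e-5, batch size 4, and dihedral-group augmentation
(the 8 rotation/flip symmetries, which preserve both the pixel multiset
and the label). Inputs are 8-bit patches scaled to [0, 1] then normalized
as (x - 0.5)/0.25. Model selection keeps the weights of the epoch with the
best validation balanced accuracy. The score reported everywhere is the
softmax probability of the live class, so a well-trained model's scores
correlate *negatively* with fluorescence.

The default backbone, `tiny_test` (three strided conv blocks, global
average pooling, linear 2-way head; <10k parameters), is implemented on a
small numpy layer stack with explicit forward/backward passes (im2col
convolution, ReLU, GAP, linear, Adam). Keeping the gradient machinery
explicit makes intermediate-layer gradients — required by Grad-CAM —
directly accessible, and the whole pipeline trains in seconds to minutes on
one CPU core. The default learning rate follows the transfer-learning
regime (1e-5); desk-scale runs that train `tiny_test` from scratch use
1e-3, since without pretraining the tiny network needs larger steps to
converge within tens of epochs. Large pretrained architectures are
deliberately not bundled: `residual18`, `squeeze` and `inception_v3` are
registrable names for user-supplied implementations (an inception-style
backbone would additionally need 299x299 inputs, i.e. a resize at load
time).

Determinism: all randomness (sampler, augmentation, initialization) flows
from the config seed through one generator, so a fixed seed reproduces the
training history bit-for-bit in single-threaded CPU execution.

## Evaluation

Balanced accuracy — the mean of per-class recalls — is the headline metric
because it cannot be inflated by siding with the majority class. Its 95%
confidence interval is a percentile bootstrap over resampled test indices
(2000 resamples by default, seeded; resamples that lose a class are
redrawn, capped at 100 attempts). The bootstrap method is a package choice.
AUC is computed from the ROC curve and equals the pairwise concordance
probability with ties counted one half; tests verify this against a
brute-force all-pairs oracle at 1e-12. The fluorescence–score association
is a Pearson correlation with a two-sided p-value, computed on the test
partition only.

## Interpretation

Embeddings are the globally pooled last-convolutional activations (the
layer feeding the classification head). t-SNE projects them to 2-D
(perplexity 30 by default, PCA initialization, fixed seed; the projection
requires n > 3·perplexity). Grad-CAM weights each activation channel by the
spatial mean of the target-class logit's gradient at the last convolutional
layer, rectifies the weighted sum, bilinearly upsamples to the patch size
and min-max normalizes per map (identically zero maps stay zero). The
pre-normalization map at conv resolution is kept on the result object so it
can be checked against a closed-form computation on a one-convolution
network.

## Synthetic data: what it emulates and what it does not

The generator partitions each image into a grid of patch-sized regions.
Each region is empty with probability `frac_empty_regions`, otherwise dead
with probability `frac_dead_cells`. Per-region mean fluorescence targets
are drawn from the configured two-component mixture (live/empty regions
from the low component; dead regions from the high component, realized as
per-cell bright Gaussian blobs whose amplitude is solved so the region mean
hits its target). Bright-field morphology follows the field's descriptions
of the two states: live cells are rendered as mostly uniform gray ellipses
with small dark nuclei and sharp contours, dead cells as larger, strongly
blurred dark halos. Cell rendering is procedural — only the statistical
contract matters for testing, not photorealism. Default mixture weights:
0.5 live for balanced "no treatment"-style data, 0.08 live for
"treated"-style imbalance; the condition tag and all parameters are
recorded in the dataset's JSON config, and generation is bit-reproducible
from (seed, image index).

What passing the synthetic benchmark shows: every pipeline stage composes
correctly, the threshold rule recovers the generating mixture, grouped
splitting is leakage-free, the weighted sampler balances classes, a small
CNN can exploit consistent morphological differences, and the inverse
fluorescence–score relationship emerges. What it does not show: performance
on real micrographs. Real cultures have irregular cell contours, touching
and overlapping cells, illumination gradients, debris, focus drift and
residual fluorescence bleed — none of which are modeled. Numbers obtained
on synthetic data (e.g. AUC ≈ 0.98 in the README example) characterize the
pipeline, not the biological difficulty of stain-free classification.

## Problem sizes and numerical choices

Tests and the worked example run the generator at reduced geometry
(672x448 or 448x224 images, tens of captures, hundreds of patches) and
train `tiny_test` for 10–30 epochs; these sizes were chosen so the whole
suite completes quickly on a single CPU core while leaving every statistical
check comfortably powered (binomial 3-sigma checks, 3-combined-standard-
error mixture recovery at n = 20,000, bootstrap coverage over 200
simulations). EM uses scikit-learn's Gaussian mixture with `reg_covar`
at its default 1e-6, which bounds fitted sigmas away from zero on
degenerate (constant-cluster) inputs. Degenerate inputs are refused
loudly: fewer than 10 values for a mixture fit, a non-positive discard
band, single-class training sets, zero-variance correlation inputs.

## Known limitations

* Patch-level labels inherit the weak-label error of the threshold rule:
  patches mixing live and dead cells near the band edges are noisy even
  after discarding the band.
* The tiny backbone's capacity bounds what the interpretability surface
  can reveal; embeddings are 32-dimensional rather than 2048.
* The empty-patch detector is only as good as its labeled examples; the
  synthetic benchmark's empty/non-empty contrast is sharper than real
  out-of-focus or debris-laden patches.
* Per-cell labeling is out of scope by design — irregular contours of
  adherent monolayers make automatic single-cell segmentation unreliable,
  which is the reason the pipeline operates on patches.
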