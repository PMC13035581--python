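# Methods

## Stimulus geometry and rasterization

All stimuli live on a 300 × 300 8-bit canvas with binary shades (white
255 / black 0; the foreground is always the opposite of the background).
Rasterization is analytic and anti-aliasing is off: a pixel is foreground
iff its center lies inside the primitive's footprint (within
stroke_width/2 of a stroke's segment; inside the disk and outside the
mouth wedge for a pac-man). This makes rendering a pure function — the
same parameters always produce a bit-identical raster — which the
downstream similarity measures and the reproducibility contracts of the
pipeline rely on. The cost is the usual staircase edge, which is
irrelevant here because both measures compare activations of images
rendered under the same rule.

Angles are degrees, counterclockwise-positive as displayed, 0° pointing
up; angles are reduced mod 360 before any trigonometry so that full
turns are exact identities (a disordered figure with a 360° local
rotation is pixel-identical to its aligned counterpart). Stroke width
defaults to 2 px — unspecified by the stimulus design, chosen so the
shortest 3 px fragments remain visible at 300 × 300 — and is
configurable. A primitive that would cross the canvas border raises an
error rather than being truncated: the grids' center positions,
(150, 150) and (134, 134), were chosen precisely so that every figure
fits, and silent truncation would corrupt the measured quantity. The
full grids render clip-free, which the test suite verifies exhaustively.

## Triangle grids

The triangle is equilateral with vertices pairwise 116 px apart
(circumradius 116/√3), rotated rigidly about the image center by
θ_global ∈ {0°, 15°, …, 105°} (a 120° rotation maps the triangle onto
itself, so the 8 levels tile the symmetry group's fundamental domain
densely). Corner fragments are the two 90°-free arms of length
`edge_length` ∈ {3, 8, 13, 18, 24, 29} px running from each vertex along
the two incident sides; disordered fragments are additionally rotated by
θ_local ∈ {72°, 144°, 216°, 288°} about their own vertex. The Kanizsa
variant replaces fragments with pac-men: filled disks with a 60° mouth
(the triangle's interior angle) facing the centroid (valid) or rotated
by θ_local (invalid). The mouth angle and the disk radius are not fixed
by the published design; we set radius = edge_length, which preserves
the six-level size factor and keeps the removed wedge congruent with the
triangle's corner, and both are configurable. The "complete" condition
is the outline triangle in both variants, so the two variants share
reference images and differ only in their incomplete figures.

## Square (configural-effect) grids

Four components sit at the corners of a square of side 95 px
(vertex-to-vertex for line segments, disk-center-to-disk-center for
Kanizsa squares), rotated by θ_global ∈ {0°, 11.25°, …, 78.75°} (90°
would reproduce 0°). The two *base* components occupy one diagonal and
differ between the two images of a pair: in the "c" images they close
the square (arms along the sides; 90° mouths facing the square's
center), in the "d" images each is rotated 180° in place — about the
fragment's centroid, or the disk's center — which keeps its centroid
fixed while breaking the closing configuration. The two *appended*
context components on the other diagonal are identical across the pair,
and the base images are simply the composites minus the context, at
unchanged positions. The published design leaves open whether one or
both base components differ and what the differing transformation is;
rotating both by 180° makes the base pair clearly discriminable and the
"d" composite maximally non-closing, in the spirit of classic
configural-superiority designs.

Because the appended context is pixel-identical and spatially disjoint
from the base components at every grid point (verified exhaustively in
the tests), the pixel-space difference images of the two pairs are
identical, so the raw-raster configural effect is *exactly* zero for
every set. This constructional null is the design's key control: any
nonzero CE measured downstream is attributable to the feature
extractor, not the stimuli.

Edge lengths {5, 10, 14, 19, 24, 29, 33, 38, 43} px map to removal
fractions (95 − 2e)/95 — the portion of each square side not covered by
the two adjacent arms — which rounds to the scale 0.9, 0.8, …, 0.1 and
is exact at 0.6 (e = 19) and 0.2 (e = 38). Note the printed scale
matches the *removal* fraction, not the literal edge/side ratio; the
implementation follows the numbers.

## Feature extraction

An extractor is any object mapping a grayscale image to a fixed-length
finite vector. The registry of nine pretrained ImageNet CNNs records
the extraction layer per model (last convolutional layer for VGG16,
SqueezeNet V1.1, ShuffleNet V2, MobileNet V3; the final MBConv block for
EfficientNet B0; Mixed_7c for Inception V3; the final average pool for
ResNet-50; the final dense block for DenseNet-121; the last
fully-connected layer for AlexNet, which we read as the 1000-unit
pre-softmax layer). Adapters preprocess by resizing to the model's
canonical input size, replicating grayscale to three channels and
applying ImageNet normalization — the models' own training pipelines,
since the benchmark design does not specify preprocessing — and flatten
activations row-major over (channel, height, width). They are an
optional extra and download weights; nothing in the core package or the
test suite touches them.

The built-in toy extractor block-averages the image to a 60 × 60 grid
(5 px blocks — fine enough that every distinct stimulus in the grids,
including the radius-5 inducers, yields distinct inputs), scales to
[0, 1], and applies a fixed Gaussian random projection drawn once from
the seed. In its linear form the map has no bias, so it provably
inherits the raster-level CE null (the pair difference vectors are
identical, and a linear map preserves that); with `nonlinear=True` a
fixed bias and rectification are added, breaking the null the way real
network layers do. The toy extractor is a test stand-in, not a vision
model: passing grids through it validates the machinery (pairing,
measures, statistics, determinism), and says nothing about what
pretrained networks perceive.

## Measures

Similarity-based closure uses cosine similarity on activation vectors.
Each of the 768 disordered figures is matched with the aligned figure
sharing (θ_global, edge_length, background, center) and the complete
figure sharing (θ_global, background, center); 768 records is the only
granularity at which θ_local — one of the regression's predictors — is
defined. The score is the aligned-minus-disordered difference of the
two similarities to the complete figure; it lies in [−1, 1] whenever
activations are componentwise nonnegative (true after rectification,
not guaranteed for e.g. a pre-softmax layer — the range assertion in the
tests is conditioned accordingly). The CE score is the normalized
difference of the two pair distances; it is antisymmetric under
exchanging the pairs, invariant to global rescaling of the four vectors,
and undefined (an error naming the set) when both distances vanish.
Zero activation vectors are an error naming the offending stimulus
rather than a silent NaN. All arithmetic is double precision, with no
normalization beyond what the formulas specify.

## Statistics

The closure regression is OLS with edge length continuous and
θ_global, background, center and θ_local dummy-coded (first level as
reference — the edge-length slope is invariant to that choice, which a
test asserts by relabeling). A rank-deficient design is an error naming
the collinear columns; a constant response is flagged degenerate rather
than fit. The CE t-tests are one-sample tests against 0 per edge length
(n = 32, df = 31 on the full grid), one-sided ("greater") by default
since the hypothesis is directional, with two-sided available; no
multiple-testing correction is applied across the nine levels, matching
the reporting convention the benchmark mirrors (a Bonferroni-minded user
can pass a smaller alpha). Alpha defaults to 0.05 and is recorded in
every verdict.

Verdicts: on the similarity route, closure is present when the
edge-length slope is positive and significant, with effect size
moderate-to-large above adjusted R² .40, small below .30, and
"small-to-moderate" in the gap. On the CE route, closure is present
when any edge length has a significantly positive mean CE, and the
verdict carries the removal fraction at the smallest such edge length.
The CE route has no adjusted-R² analogue, so its thick/thin grading is
our own convention: moderate-to-large when the largest significant mean
CE is at least 0.1, small otherwise.

## Verification strategy and problem sizes

Every statistical routine is checked against an independent oracle in
the tests: OLS against a from-scratch normal-equations solver, t-test
p-values against numerical quadrature of the t density, the pacman
rasterizer against an oversampled pixel count, the toy extractor
against an explicit matrix multiply. Monte-Carlo checks (99% CI
coverage over 200 replicates of the full 768-row grid; planted-slope
sign recovery over 100 replicates) use fixed seeds. The full grids —
992 images per triangle variant, 288 sets per square condition — are
rendered exhaustively in the suite; they are small enough that nothing
needs downscaling, and the complete suite runs in well under a minute.

## Known limitations

* The toy extractor is not a model of vision; green tests demonstrate
  the harness, not perception. Conclusions about real networks require
  the pretrained adapters and downloaded weights.
* Pac-man radius = edge_length is an interpretation; other radius
  mappings would change the Kanizsa grids' retinal statistics.
* The base-pair transformation (180° rotation of both diagonal
  components) is one of several defensible readings of the design.
* External benchmark comparisons (e.g. cortical predictivity scores)
  and transformer architectures are out of scope.
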