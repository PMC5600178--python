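# Methods

## Silhouette extraction

An RGB photograph is converted to luminance (weights 0.2989, 0.5870,
0.1141 — rounded so they sum to exactly 1 and white maps to 255),
downscaled so the longer side is at most 1024 px (shape information
survives far below camera resolution), and segmented:

1. Canny edges (σ = 2 px, hysteresis thresholds 0.1/0.2 of the intensity
   range). Edge maps rarely close on their own, so the map is dilated by
   one pixel before hole filling and eroded once after.
2. The filled region still contains the one-pixel Canny ridge, which sits
   on the intensity midpoint of the blade/background ramp; left alone the
   mask boundary is biased roughly half a pixel outward — about 5 % of the
   area for a blade of ~8,000 px. When foreground and background levels
   are clearly separated (median difference > 10 % of the range), the
   pixels of the filled candidate region are therefore re-assigned by
   thresholding at the midpoint of the two levels, which recovers the
   50 %-coverage contour of an anti-aliased edge. Low-contrast images keep
   the purely morphological mask.
3. Components smaller than 5 % of the largest (a relative threshold, so
   behaviour is resolution-independent) are discarded, the largest is
   cropped to its bounding box plus a 2 px margin, remaining holes are
   filled, and the boundary is traced as a closed 8-connected Moore chain,
   oriented counter-clockwise in the x = col / y = −row frame. Ties
   between equal-area components go to the topmost-leftmost bounding box.

The silhouette is taken as whatever the photograph contains; no petiole
removal or illumination correction is attempted.

## Morphological descriptors

Area is the foreground pixel count; perimeter is chain-code length (1 per
axial step, √2 per diagonal); the diameter is the exact maximum pairwise
contour distance (computed via the convex hull, which contains the
farthest pair); *L* and *W* are the major/minor axis lengths of the
ellipse with the region's normalized second central moments (the
regionprops convention — note a w×h rectangle then has L·W = 4wh/3, so its
rectangularity is exactly 3/4). Convex area converts the hull polygon area
to the pixel-count convention via the Pick-style rim correction
(+P_hull/2 + 1) so convex masks score solidity ≈ 1. The fifteen derived
ratios live in a registry (`msd.FORMULAS`) so an alternative reading of a
descriptor name can be swapped without touching callers; "entirety" is
read as blade-to-bounding-box ratio to keep it distinct from solidity.

Chain-code length is a property of the pixel boundary: under 2×
nearest-neighbour pixel doubling the estimator sees the (now resolved)
staircase rather than the underlying curve, so perimeter-based ratios are
*not* stable under that operation (+8–15 % measured). They are stable
(≤ 3 %) under genuine re-rendering at doubled scale, which is what the
scale-stability tests check; the pixel-doubling check covers the
moment/area-based ratios only.

## HOG

Gradients are half-differences ((f(x+1) − f(x−1))/2, replicated edges);
orientation is the angle of (Gx, Gy) folded to [0°, 180°). The printed
convention θ = arctan(Gx/Gy) found in parts of the literature is the
transpose of this; the two differ only by a relabeling of bins. The ROI
crop is letterboxed (aspect-preserving, centred) into a 128×128 window
with background forced to the background level; only foreground-mask
pixels vote, with hard assignment into nine 20° bins per cell of the 3×3
grid. Block normalization is V = V_K/√(‖V_K‖² + ε²) with ε = 10⁻⁵ of the
unit intensity range; the scale-inconsistent variant without the square
root is available as `norm="paper"`, and `norm="none"` returns raw votes
(used by the vote-conservation check: the 81 raw entries sum to Σ|G| over
masked pixels). HOG is computed on the masked grayscale crop by default;
`on_mask=True` uses the binary silhouette.

## Hu moments

Moments are computed over foreground pixels with unit weight — or, if a
float array is supplied, with per-pixel weights, which is how the
invariance oracles use anti-aliased coverage maps. Normalization is
η_pq = μ_pq/μ00^((p+q)/2+1). The default formulas are the canonical 1962
set; a literal transcription variant (`paper_literal`) reproduces two
common misprints (Hu4 with (η30 + 3η12)² and a sign/index slip in Hu7) and
agrees with the canonical set on fully symmetric shapes. Because the raw
invariants span ~10 orders of magnitude, the feature vector is
log-compressed (sign(h)·log10|h|, |h| floored at 10⁻³⁰); raw values are
available.

## Zernike moments

The radial polynomial is evaluated from its factorial coefficient sum
(precomputed per index; no recurrence needed at order 8). The silhouette
maps to the unit disk at its (weighted) centroid. The disk radius is a
weighted 20-power-mean of pixel distances, with the few pixels beyond it
clipped to the rim (r = 1): the literal circumscribing radius — the
maximum pixel distance — jumps by up to a pixel between rasterizations of
the same shape, and that jitter is amplified roughly eightfold at order 8,
which alone breaks 2 %-level rotation/scale reproducibility (errors up to
~150 % were measured on small magnitudes). The power-mean radius is smooth,
rotation-invariant and scale-covariant; the circumscribing convention
remains available (`radius="extremal"`). Only magnitudes are kept (the
rotation-invariant part) for b ≥ 0, giving 25 descriptors at order 8, each
normalized by the area m00.

## Feature selection

* **ReliefF** — all instances are used (deterministic; the seed argument
  exists for interface symmetry and neighbour ties break by sample
  index); features are min-max scaled internally; Manhattan distance;
  k = 10 neighbours, reduced per class with a warning when a class is
  smaller than k+1. Miss contributions are weighted by P(c)/(1 − P(class)).
  A feature identical to a two-class label attains weight 1.
* **CFS** — feature–class correlation is the same one-vs-rest max-|Pearson|
  measure the PCC scorer uses; the greedy forward search continues past
  the merit peak so every feature gets an inclusion rank and any retention
  fraction can be honoured. Zero-variance features correlate 0 and rank
  last; ties break by feature index.
* **PCC** — max over one-vs-rest class indicators of |Pearson r|.

Retention counts use round-half-to-even, so 133 × 0.4 = 53.2 → 53.

## Classifiers

All six sit behind one adapter that z-scores features on training
statistics (descriptor scales span ~10 orders of magnitude). ann is a
single-hidden-layer network (100 units, ≤ 500 epochs, early stopping on a
10 % validation carve-out with patience 50 — with 24-sample validation
sets the conventional patience of 10 stops on noise); rf uses 100 trees;
svm is one-vs-all RBF with C = 10 and γ = 1/n_features; knn defaults to
k = 1; lda is standard. The DAG MLSTSVM node for classes (+, −) solves,
with E = [A 1], F = [B 1],

    (FᵀF + (1/c1) EᵀE) z₊ = −Fᵀ1      (EᵀE + (1/c2) FᵀF) z₋ = +Eᵀ1

(c1 = c2 = 1, ridge 10⁻⁸ I for solvability); a point is assigned to the
nearer plane by perpendicular distance. For mirror data B = −A the
solutions satisfy (w₋, b₋) = (w₊, −b₊) — the negative plane is the point
reflection of the positive one through the origin. The DAG starts at the
(first, last) node in sorted class order and eliminates one class per
node.

## Synthetic leaf generator

The blade outline is a polar radius function: an ellipse of the requested
aspect ratio, multiplied by an apex/base taper factor
(1 + t·cos φ)/(1 + |t|), a lobe term (1 − d·sin²(kφ/2)), plus harmonic
margin serration; a rectangular petiole stub (half-width 0.03 of the blade
radius — narrower stubs fall below render resolution) anchors slightly
inside the actual blade base radius so it always overlaps the blade.
Rendering is polygon rasterization at 2× supersampling (4× or more for
the anti-aliased coverage maps used by the moment oracles), downsampled to
coverage; the ground-truth mask is coverage > 0.5. The whole outline is
scale-capped to fit the canvas with a margin — silent clipping at the
border would change the shape. Blade colour is dark green (≈ 0.25 of the
intensity range) with ±0.05 multiplicative texture noise, the background
light (≈ 0.95), plus mild additive sensor noise, so edge detection always
fires. Default canvas is 256×256 px.

Datasets draw class-mean parameters around a mid-range centre; the
`separation` knob in [0, 1] scales how far the means spread (0 = identical
classes, a chance-level problem). Render scale grows with √aspect,
emulating frame-filling acquisition where narrow blades are photographed
closer (herbarium light-box protocols use different box sizes for
small and large leaves). Within-class jitter (default 0.04 of each
parameter range, plus orientation and size jitter) models leaf-to-leaf
variation. The `mydaun_like` preset fixes 45 classes × 30 leaves = 1,350
images.

What the generator does *not* emulate: venation, colour/texture variation
beyond noise, compound leaves, specular highlights, shadows, or damaged
blades. Tests passing on these renders therefore validate the geometry of
the pipeline — segmentation accuracy, descriptor correctness and
invariance, selection and classification mechanics — not photographic
robustness on field images.

## Evaluation protocol

Stratified random 80:20 splits (round(0.8·n_c) per class — unstratified
splitting can empty a class's test set at 30 samples/class), 10 repeats
with seeds base_seed…base_seed+9, plain top-1 accuracy averaged over
repeats. Feature selection, when configured, is refit on the training
split of every repeat; a test asserts the selector never sees test rows.

## Reference problem sizes

The bundled study conditions are sized for a single CPU: the reference
classification dataset is 10 classes × 30 leaves at separation 0.9
(accuracy claims: hybrid ANN ≥ 0.90; the hybrid within 0.02 of every
single family; Relief at 40 % retention within 0.03 of the full hybrid),
and the integrity check generates the full 1,350-image preset and
verifies every image yields a single-component, hole-free ROI within 5 %
of the ground-truth area. Invariance oracles use smooth, strongly
asymmetric blades of ≥ 20,000 px rendered at 8× supersampling; thin
appendages (petiole stubs) rasterize too noisily for 2 %-level moment
comparisons and are omitted from those shapes.

## Known limitations

* Segmentation assumes one leaf on a uniform light background with clear
  contrast; the intensity-refinement step disables itself below 10 %
  contrast but no multi-leaf or cluttered-scene handling exists.
* Chain-code perimeter overestimates smooth curves by ~5 % uniformly;
  ratios built on it are consistent but not estimates of the true
  continuous perimeter.
* Hu invariants 5–7 are high-order cancelling combinations; on small or
  thin-featured silhouettes their relative reproducibility degrades well
  before the low-order invariants.
* The log-compression of Hu values maps near-zero invariants to large
  magnitudes of flipped sign; after z-scoring this is harmless for
  classification but the compressed values are not metrically meaningful
  near zero.
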