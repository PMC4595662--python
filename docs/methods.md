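# Methods

## The model

`ehmax` implements a feedforward, biologically inspired image-categorization
hierarchy in two variants.

**Baseline hierarchy (oHMAX).** A grayscale channel (we use the L* plane of
the Lab conversion) is filtered by a bank of Gabor simple cells

    G(x, y) = exp(−(x0² + γ² y0²) / (2σ²)) · cos(2π x0 / λ),
    x0 = x cos θ + y sin θ,   y0 = −x sin θ + y cos θ,

at 4 orientations (0°, 45°, 90°, 135°) and 16 scales, giving 64 S1 response
maps (|convolution|, symmetric border padding so every map keeps the image
size).  θ labels the carrier direction: the 0° kernel's cosine varies along
x, so it matches gratings whose wave vector is horizontal.  The scale table
(filter sizes 7–37 px with matched σ and λ, γ = 0.3) is the standard
published table.  C1 complex cells max-pool each pair of adjacent scales over
an L×L neighborhood (L = 8…22 px, stride L/2, overhanging windows dropped),
giving 32 C1 maps in 8 scale bands.  S2 units compare every C1 window against
M randomly sampled C1 prototypes with a Gaussian-like tuning
exp(−β‖X − P‖), and C2 takes each prototype's global maximum over positions
and bands — an M-vector per image.

**Enhanced hierarchy (eHMAX).**  Three changes:

1. *Bottom-up saliency (S1).*  With 12 orientations on the L channel, the
   orientation saliency map is the summed fine-minus-coarse contrast
   SFM_O = Σ_{s=1..4} Σ_θ (FM^{s,θ} − FM^{s+4,θ}) over the first 8 scales
   (scale interval 4).  The color saliency map is the per-pixel squared
   deviation of the Gaussian-blurred (σ = 1 px) Lab channels from their
   global means, summed over channels.  Both maps are standardized to zero
   mean / unit variance and fused as SFM = 0.4·SFM_O + 0.6·SFM_C; all pixels
   are then ranked by fused saliency (ties row-major).

2. *Unsupervised prototype learning (C1 band 1).*  D (labeled discovery
   images) and N (natural-world backgrounds) are split into disjoint halves.
   S initial patches per size n ∈ {16, 28} (band-1 C1 units) are sampled at
   the most salient points of D₁ and at random in N₁, both under the overlap
   constraint that centers stay ≥ n/4 apart.  Each patch is reduced to a
   descriptor: 3×3 half-overlapping blocks (side n/2, stride n/4), each block
   an O-bin orientation-energy histogram, L2-normalized, concatenated
   (9·O = 108 values for O = 12); optionally a 2×2-block RGB histogram
   (8 bins per channel per block, L2 per block) over the patch's image
   footprint is appended.  k-means partitions the S patches into S/5
   clusters (clusters below 3 members drop).  Each iteration then, per
   cluster: train a weighted linear SVM (members vs. random N patches), mine
   hard negatives by densely scanning N₁ (stride n/4, scores > −1, top 10
   per image), retrain, and refresh the member set with the top q = 5
   detections (scores > 0, within-image spacing ≥ n/4) in the *other*
   discovery half; fewer than 3 detections deletes the cluster.  The halves
   swap every iteration; clusters whose member sets coincide merge; the loop
   stops when every surviving cluster repeats its member set (same-parity
   comparison, since members alternate between the halves) or after
   max_iterations = 5.  Surviving clusters are ranked by
   score = purity~ + λ₃·discri~, where purity is the mean SVM score of the
   cluster's top r = 10 dense-scan detections in D, discri =
   FireNum_D / (FireNum_D + FireNum_N) counts detections above the decision
   boundary, ~ is standardization across the clusters of one patch size, and
   λ₃ = 1.  Finally, redundant clusters are suppressed (below) and the top
   Γn per size form the bank Ω (Γ = Γ16 + Γ28).

3. *Detector S2 and position-encoded C2.*  Every cluster classifier slides
   (stride 1) over the descriptor field of each of the 8 C1 bands; each S2
   unit is an SVM score.  C2 keeps, per cluster, the global maximum over
   bands and positions plus its relative coordinates (x_max/W, y_max/L) in
   the winning map — 3Γ values per image.  A softmax (multinomial logistic)
   head on standardized C2 features performs the categorization.

## Redundant-cluster suppression

Refresh is a winner-take-all step: several k-means seeds can converge to the
same image regions, and on small fixture sets the duplicates of one dominant
part would otherwise fill the entire top of the ranking.  After scoring,
clusters are visited in descending score order and dropped when either
(a) their classifier weight vector is nearly parallel (cosine > 0.5) to a
kept cluster's — the same appearance template even if its detections happen
to land on different images — or (b) more than 1/3 of their firing
detections (the same detections FireNum counts) lie within n/2 cells of a
kept cluster's firings in the same image, i.e. their footprints share at
least half their extent.  Both signals say the detector encodes memory the
bank already holds.  This mirrors the duplicate pruning that unsupervised
mid-level patch-discovery methods apply after ranking.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| saliency weights (orientation, color) | 0.4, 0.6 | — | fixed fusion weights of the model |
| saliency scale interval | 4 | scale index | fine-minus-coarse contrast offset |
| color blur σ | 1.0 | px | "Gaussian filtering" width; exposed in config |
| patch sizes n | {16, 28} | C1 cells | mid-level part extents (desk preset: {16}) |
| initial patches S | 2000 | patches/size | k-means pool; S/5 clusters (preset: 200) |
| refresh q / purity r | 5 / 10 | detections | member refresh cap; purity pool (r > q) |
| λ₃ | 1.0 | — | weight of selectivity in the cluster score (never published; exposed) |
| min cluster size | 3 | members | deletion threshold |
| max iterations | 5 | — | refinement budget (converges in ~4–5) |
| SVM C | 20 | — | see "Numerical choices" |
| hard-negative threshold / cap | −1 / 10 per image | margin | margin violators only |
| detection threshold | 0 | margin | natural decision boundary for firing/refresh |
| redundancy cosine / coverage | 0.5 / 1/3 | — | duplicate-detector suppression |
| oHMAX β | 1.0 | 1/distance | tuning sharpness; preset 0.01 ≈ 1/median best-match distance on 128-px scenes |
| Γ16, Γ28 | 500, 100 | clusters | published best configuration (preset: Γ16 = 30) |

## Numerical choices

- **Weighted SVM.**  Per-sample weights are 1/(2·n_class), so each class
  carries total weight 1/2 — inversely proportional to class size and
  exactly invariant to duplicating either class.  With this normalization
  the conventional setting "C = 0.1 with unnormalized balanced weights at a
  ~200-sample pool" corresponds to C ≈ 20, which is the default; much
  smaller values collapse all margins (the hard-negative threshold of −1
  then never binds) and flatten the detectors.  liblinear primal
  (dual=False), tol 1e−8, deterministic.
- **Degenerate standardization** (constant raster or constant score vector)
  returns all-zeros rather than raising: a blank map has no structure and
  the pipeline proceeds.
- **Ties.**  Salient-point ordering and C2 argmax resolve row-major; the C2
  global maximum prefers the lowest band; select_top prefers the lower
  cluster id.  All orderings are deterministic.
- **Position convention.**  x = column/W, y = row/L, zero-based argmax,
  where (L, W) are the winning S2 map's (rows, cols).
- **Bands too small for a patch size** contribute no S2 map and are skipped
  by the C2 maximum; a cluster with no map at all is an error.
- **All-zero descriptor blocks** stay zero (no division by zero).
- **Requesting more top clusters than survive** returns all survivors with a
  warning and records the adjusted count.

## The synthetic scenes

The fixture generator emulates the discovery/natural structure of the
training data: each 128×128 discovery scene plants exactly one colored,
oriented motif — a "critical part" (cross, ring, stripe grating, or corner;
~48 px; flat saturated color) — at a random position on a near-achromatic
textured background (smooth value noise or an oblique gray grating), with a
pixel-exact support mask; natural scenes are motif-free backgrounds with
clutter.  Design choices that the tests rely on:

- *Orientation jitter ±5°* — half the 15° orientation-channel spacing — so a
  motif remains a single appearance mode; larger jitter legitimately splits
  a motif into several clusters, which the recovery ground truth does not
  model.  Scale jitter is ±10%, about what one band of C1 pooling absorbs.
- *Distinct dominant channels per class*: base orientations (0°, 90°, 45°,
  135° for cross, ring, grating, corner) are assigned so no two classes
  share their strongest edge-orientation channel.
- *Clutter in N*: bars, parallel-bar pairs, arc fragments and blobs in muted
  and saturated colors.  Every individual low-level feature (one color, one
  orientation, one curve) occurs in the natural world; only the motif's
  conjunction of features is specific to a class.  Without clutter no
  detector ever fires on N, FireNum_N ≡ 0, and the selectivity term of the
  cluster score is inert.
- *Shared-motif scenes* place the shared part and the class-unique part in
  complementary image halves with a ≥12 px gap, so the shared part's patch
  context is identical across classes.
- The desk preset enables the optional RGB histogram block: the motifs are
  color-coded parts, and the near-isotropic ring is not reliably separable
  from textured backgrounds by orientation histograms alone.

What passing these tests does *not* show: performance on natural images.
The scenes have flat-colored parts, statistically simple backgrounds, no
occlusion, no lighting or viewpoint variation, and one part per class;
published accuracies on real benchmarks are not reproduced here.

## Study sizes used by the tests and the acceptance script

Saliency localization: 100 single-motif scenes.  Recovery: 20 learning runs
(10 in the script), each K = 3 classes × 12 images + 20 natural, S = 200,
patch size 16, Γ = 30 requested (3–6 survive suppression).  Shared-part
co-clustering: 2 classes × 12 images.  End-to-end: 3 classes × 30 images
(20 train / 10 test per class) with the same learning configuration.  These
sizes are a desk-scale analogue of the published 10-class, 30-image
protocol.

## Known limitations

- Eq-style purity averages each cluster's *own* SVM margins; scores are not
  strictly comparable across clusters, and standardization only removes the
  population shift.  Ranking quality therefore leans on the selectivity
  term and the redundancy suppression.
- The baseline's Gaussian tuning sharpness β must be matched to the C1
  distance scale of the data; the package default (1.0) is a placeholder
  that practically requires adjustment (the preset uses 0.01).
- With few survivors, Γ is data-bound: the requested top-cluster counts are
  upper bounds, not guarantees.
- Learning uses only band-1 C1; scale invariance during discovery is limited
  to what one band's pooling absorbs (encoding scans all 8 bands).
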