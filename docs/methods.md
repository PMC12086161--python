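# Methods

This note documents the models and procedures `greenprompt` implements,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Vegetation index and cover-green confidence

The Excess-Green index is computed as ExG = 2G − R − B on raw 8-bit
channels (the classical un-normalized form; a chromaticity-normalized
variant `2g − r − b` is available via `exg_variant="normalized"`). The raw
form is invariant to adding a constant to all three channels, which makes
it robust to the gray illumination gradients typical of rack lighting.

Binarization uses classical 256-bin histogram Otsu: the ExG map is
linearly rescaled to [0, 255], quantized, and thresholded at the argmax of
between-class variance. Otsu is computed **once globally** per image, not
per box; per-box counts are then taken inside each (clipped) box under the
half-open pixel convention (a pixel at integer index x belongs to
[x_min, x_max) iff x_min ≤ x < x_max). A constant ExG map has no defined
threshold; in pipeline mode it yields an all-background mask with a
warning, in strict mode an error.

NCGI normalizes each box's raw green-pixel count by the maximum count over
its overlap set. The overlap set is **self-inclusive**, so NCGI ∈ [0, 1]
always and every overlap cluster's largest-count box scores exactly 1; a
cluster whose counts are all zero maps to 0. "Overlapping" means strictly
positive intersection area — boxes sharing only an edge do not overlap.

Known limitation: global Otsu needs a non-negligible foreground class.
Below roughly half a percent of vegetation pixels the between-class
variance of the true vegetation/substrate split can fall under that of a
split inside the background noise, and the threshold collapses into the
background distribution. The default scene battery (5–12 plants on a
256² canvas, 1–5% vegetation) sits well clear of this regime.

## VC-NMS

Stage 1 replaces every score by the composite β·NCGI + (1−β)·s (an
in-place update applied once per box, before any attenuation), then sorts
by descending composite and applies the overlap-count attenuation
(1 − oven_i/max_oven) to any box i that has a later-ordered box j with
RIoU(b_i, b_j) ≥ N_t and **strictly more** overlaps (oven_i > oven_j).
Design choices here:

- *Once per box, not once per pair.* The attenuation is a single piecewise
  reassignment of s_i, triggered by the existence of a qualifying j. A
  per-pair variant (multiply once per qualifying pair) is available as
  `per_pair_attenuation=True` for sensitivity studies.
- *Strict overlap-count comparison.* With ≥ instead of >, every member of
  an equal-count duplicate stack except the last in composite order would
  be attenuated, systematically promoting the stack's worst box. The
  strict gate leaves equal-count stacks to the stage-2 decay and reserves
  the attenuation for boxes that genuinely overlap more than their
  neighbours — multi-plant union boxes. The ≥ variant remains available
  as `oven_gate="geq"`.
- *max_oven = 0* (no overlaps anywhere) skips attenuation entirely.

Stage 2 iteratively selects the max-score box and decays the remainder by
exp(−RIoU²/σ); boxes whose working score falls below
`final_score_threshold` are reported as suppressed (with reason
"below-threshold" if they entered stage 2 that way, "decayed" otherwise).
Ties everywhere resolve to the larger area, then the lower box id, which
makes the output invariant to input ordering.

Parameters and defaults: β = 0.7 (weight of vegetation cover against
detector confidence; raise it for dense late-growth canopies), N_t = 0.7
(RIoU gate — only highly overlapping pairs can trigger attenuation),
σ = 0.5 (Gaussian decay scale, the Soft-NMS convention; the method's
source does not state one), box_threshold = 0.1 (detector confidence
pre-filter), final retention threshold = 0.1 (unstated in the source;
set equal to box_threshold). The kept boxes report their working
(composite, attenuated, decayed) score.

A consequence worth knowing: with σ = 0.5 and retention threshold 0.1, a
second *exactly coincident* full-vegetation duplicate survives whenever
its composite exceeds e² · 0.1 ≈ 0.74 (one full-overlap decay multiplies
by e⁻² ≈ 0.135). Duplicate removal therefore relies on duplicates either
containing measurably less vegetation (nested partial crops) or carrying
low detector confidence — which is what real open-set detector stacks
look like, and what the synthetic pathology model generates.

Degeneracy checks used as oracles: with β = 0, attenuation off, and IoU
substituted for RIoU, VC-NMS is score-for-score identical to
Soft-NMS-Gaussian; with σ → 0 stage 2 converges to hard suppression of
any positively-overlapping box.

## Point prompts

The final box with the highest composite score is the reference plant.
Its cropped region is embedded on a feature grid; the reference vector is
the mean of grid cells whose centers fall in the region's ExG/Otsu
foreground (mask-weighted pooling is available via `pooling="weighted"`).
Each box region's cells are scored by cosine similarity against this
vector, zero-norm cells scoring 0, and the grid-resolution map is
bilinearly upsampled to pixel resolution.

Base points are the similarity argmax (positive) and argmin (negative);
inside `build_prompt_set` the argmax is restricted to the region's
vegetation foreground and the argmin to its background whenever those are
non-empty, so positive points always sit on vegetation and negative
points on substrate. Enhanced points are chosen by the max-distance
criterion: the allowed-region pixel maximizing the (minimum) Euclidean
distance to the already-selected points of the same label — iterated
farthest-point sampling for counts beyond 2, though the default is
2 positive + 2 negative, the configuration the method's ablation found
optimal. Ties resolve to the smallest row-major index. Degenerate cases:
a constant similarity map falls back to box center (positive) and corner
(negative); an empty foreground falls back to box center + similarity
argmax for positives; an empty background reduces the negative count with
a warning (unreachable for non-constant regions, since Otsu always leaves
both classes non-empty).

## Evaluation metrics

Matching is greedy, score-descending, one-to-one against the
highest-IoU unmatched ground truth at or above the threshold, over box or
mask IoU. AP uses 101-point interpolation of the score-swept P-R curve
(the COCO convention; all-point integration available), averaged over IoU
thresholds 0.5:0.95 in steps of 0.05 and pooled across images.
Recall@{10,100} is the COCO-style averaged recall at bounded per-image
detection counts. Size strata split on ground-truth box diagonal:
small < 32 px ≤ medium < 96 px ≤ large; the 32 px small bound is the
method's stated convention, the 96 px medium/large bound is this
package's documented choice.

Dice is 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks, and satisfies
Dice = 2·IoU/(1+IoU). ECE pools pixels dataset-wide: predicted class
p ≥ 0.5, confidence max(p, 1−p), ten equal-width bins over [0.5, 1],
ECE = Σ |B_m|/n · |acc − conf|. Binning and pooling are interpretation
choices (the source does not state them) and are configurable. The
structure measure S_m = α·S_object + (1−α)·S_region (α = 0.5) and the
weighted F-measure (β² = 1, distance-weighted errors with a 7×7 Gaussian
of σ = 5 and exponential distance down-weighting) follow their original
published definitions exactly, with N−1 variance normalization; empty
ground truths fall back to 1 − mean(pred) for S_m and to 0 (with a
warning) for the weighted F.

## Synthetic scenes and mock backends

The generator emulates stacked-rack hydroponic imagery: plants as
clusters of 4–7 overlapping green ellipses (leaf color bands R 25–85,
G 150–230, B 25–95) confined to a disk of radius 10–22 px, placed by
rejection sampling with a minimum 4 px gap on a 256×256 canvas; granular
substrate (base color (120,105,95), gray noise ±22 which ExG cancels,
chromatic noise ±8), an optional ±30 linear illumination gradient, and
optional global red/purple channel gains mimicking auto-white-balance
drift. Rendering is integer-valued with no anti-aliasing, so fixed seeds
give byte-identical scenes across platforms. Ground-truth masks and tight
boxes are exact by construction, and plant/substrate channel statistics
guarantee the ExG margin that makes Otsu separation a generator property
rather than an empirical hope.

The proposal generator reproduces the detector pathologies the method
targets: per plant one slightly expanded outer box (each side pushed out
by up to 8%, guaranteeing IoU ≥ 0.7 with the plant while enclosing all its
vegetation) and three nested partial crops cutting 10–30% of each side;
plus union boxes over the closest plant pairs. Scores are
clip01(base + area_bias · area/max_area + noise) with base ~ U(0.16,
0.30), area_bias 0.2 and noise sd 0.025 — low confidences just above the
0.1 detector threshold, with union boxes outscoring tight boxes
essentially always at the defaults.

The mock embedder's per-cell features are 3×3-smoothed block means of
[ExG⁺/255, R/255, G/255, B/255, 0.15·x_norm, 0.15·y_norm]: vegetation
dominates the cosine direction so green cells of different plants are
mutually similar and substrate cells are not. The mock segmenter returns
the union of 8-connected vegetation components inside the box that
contain a positive point and no negative point, with confidence equal to
the covered fraction of the box's foreground, honoring the
one-mask-per-prompt contract.

What passing tests on this substrate do and do not show: the scenes
exercise redundancy pathologies, scale variation, lighting gradients and
color casts, but the plants are simple convex blobs on a clearly
non-green substrate — there is no leaf-level texture, no canopy merging
between neighbouring plants (default density keeps instances disjoint),
no specular highlights, and the mock segmenter cannot hallucinate beyond
the vegetation mask. Results here validate the *algorithms* (scoring,
suppression, prompt placement, metrics), not segmentation quality on real
imagery with foundation-model backends.

## Problem sizes

The benchmark battery is 50 scenes of 5–12 plants each (≈ 420 ground-truth
instances), which keeps the full suite and the reproduction script in the
seconds-to-a-minute range on a single CPU while leaving each scene enough
box redundancy (≈ 30–50 proposals) for the suppression pathologies to be
non-trivial. The β sweep uses a 10-scene subset per β value.
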