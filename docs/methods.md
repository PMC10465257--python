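# Methods

This note documents the models, conventions and design choices behind
`annotqc`, in the spirit of a statistical package's methods appendix. It
states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Study model

A *study* is a set of greyscale B-scans, each with its own physical
scaling (µm/px laterally and axially — clinical scans vary slightly, so
scaling is per-image, not global), and one filled binary mask per
(image, rater, round), with each rater labelled `expert` or `junior`.
Rounds are 1 or 2; a rater who annotated once contributes that round
wherever a "last round" or "round 2" is required. Intensities are
normalised by the container dtype maximum (255 / 65535), never by the
per-image maximum, so intensity statistics are comparable across scans.
Masks are tolerant-read (any nonzero pixel is foreground), strict-write
(0/255 PNG). Coordinates are row-major and 0-based; X is columns
(lateral), Y is rows (axial).

## Consensus

Ground truth is a pixelwise majority vote over the consensus raters'
last rounds. With two experts a "majority" is ambiguous at ties, so both
rules are implemented and recorded in provenance:

- `strict_majority` (default): votes > n/2 — the intersection for n = 2.
  A ground-truth pixel is one *both* experts marked; this is the
  conservative reading of a two-expert consensus.
- `at_least_half`: votes ≥ n/2 — the union for n = 2.

Voting is unweighted. Probabilistic fusion (STAPLE-style) is out of
scope.

## Agreement metrics

All metrics derive from exact pixel tallies. A metric whose denominator
is zero is *undefined* (NaN), excluded from means with the exclusion
count reported — never coerced to 0 or 1. Cohen's κ uses the standard
two-marginal chance term and is symmetric in (pred, ref).

Gwet's AC1 is computed in two variants because the binary-case chance
term admits two readings: the *annotator-marginal* form
p_e = p₊² + p₋² with p₊ = (TP+FP)/N (which uses only the annotator's own
marginals and is therefore asymmetric in pred/ref), and Gwet's standard
form p_e = 2π(1−π), π = ((TP+FP)/N + (TP+FN)/N)/2, which is symmetric.
Both are always reported; the asymmetric variant is symmetrised in
pairwise matrices by averaging the two orientations, and the
symmetrisation is noted here rather than hidden. On heavily imbalanced
masks (mostly background) the two diverge strongly — the reason both are
surfaced rather than resolved.

Two aggregation modes are reported side by side, because "averaged
across all annotations" can mean either: (a) metrics on confusion counts
pooled over all pixels per (rater, round), and (b) the mean of
per-region metrics. Every table row carries its `aggregation` label.

### Per-region evaluation

The consensus mask is decomposed into 8-connected components (freehand
annotation strokes have thin diagonal necks that 4-connectivity would
split; connectivity is configurable). Each rater component is matched to
the consensus region it overlaps most; unmatched rater components count
as false-positive areas. Each consensus region is scored inside its
bounding box dilated by 10 px (configurable) so per-region TNR is
well-defined without distant background dominating; pixels of *other*
consensus regions are excluded from the window so neighbours cannot
contaminate the tallies.

Pairwise inter-rater matrices pool confusion counts over all images per
rater pair by default (per-image averaging is a flag), and are symmetric
with unit diagonal.

## Image-property battery

**Boundary bands.** The inner band is the region minus its 1-px erosion,
the outer band its 1-px dilation minus the region, both with the 3×3
square structuring element (consistent with 8-connectivity) and clipped
at image borders. Fluid is dark and tissue bright, so a well-placed
annotation has a large outer−inner mean-intensity difference; dilating
an annotation into tissue moves the inner band into bright pixels and
shrinks the difference — the image-side signature of oversegmentation.
Per-rater summaries average per-region means by default (pixel-pooled,
area-weighted means are a flag).

**Speckle noise.** Noise is modelled as count noise,
pixel ~ Poisson(λ·clean)/λ: mean-preserving, with variance clean/λ, so λ
is identifiable from the variance/mean slope. The estimator computes,
in overlapping 8×8 tiles (stride 4), the tile median intensity and a
noise-variance estimate from horizontal and vertical first differences
(differencing cancels smooth signal; a difference of two i.i.d. noise
pixels has twice the noise variance). The slope is the median of
per-tile variance/mean ratios — robust to the minority of tiles
straddling region edges — and λ̂ = 1/slope. Tiles with near-zero median
(< 10⁻³) carry no slope information and are dropped; a constant image
or a nonpositive slope raises an estimation error. The estimator's
contract is *parameter recovery* on the generator (median λ̂ within 20%
across λ ∈ [5, 80], rank-monotone), not a particular numeric path.
Images are binned low/medium/high at λ = 20 and 40; the printed bin
edges overlap at exactly 20 and 40, resolved here as half-open
intervals [0, 20), [20, 40), [40, ∞).

**Zones.** Regions are binned by |centroid column − width/2| · scale_x
at 0.5, 1.5 and 3.0 mm from the geometric image centre (not the fovea —
foveal registration is out of scope). A region straddling a cut belongs
to its centroid's zone; centroids beyond 3.0 mm fall in no zone and are
reported separately (zone 0 in tables). Stratified tables give mean, SD
and n of last-round per-region IoU per (tier, stratum).

## Synthetic phantoms and simulated annotators

The phantom is schematic, not OCT physics: a dark "vitreous"
(intensity 0.04) above and below a brighter three-band "retina"
(0.85–1.15 × the 0.5 tissue level, transitions smoothed), with dark
(0.05) elliptical fluid regions placed by rejection sampling in the
central tissue band; overlapping ellipses merge into one truth region.
Defaults mirror a typical clinical B-scan: 732×428 px at 10.5 / 3.8
µm/px. Ellipse semi-axes are drawn in microns (25–120 µm), so regions
are roughly round physically and vertically elongated in pixel space.
Edges get a 0.8-px Gaussian blur before noise, emulating optical blur.
The default study uses 10 phantoms whose λ values span the three noise
bins 5/3/2 — the distribution of the clinical study being emulated —
and 12 regions per image, enough to populate all three zones.

Simulated annotators perturb each true region independently through its
signed Euclidean distance map: output = {d + bias + η ≥ 0}, where a
positive `boundary_bias_px` reproduces dilation by a disc of that radius
(the oversegmentation habit being modelled) and η is a smooth Gaussian
random field (correlation length 3 px) scaled to `jitter_sd_px`.
Regions are missed with probability `miss_rate`, Poisson-many small
spurious ellipses are added in the tissue band at rate `spurious_rate`,
and jitter/miss are multiplied by `zone_decay`^(zone−1) so errors grow
away from the centre. Default profiles are two careful experts
(bias ≈ 0, jitter ≤ 0.5 px, no zone decay) and three juniors with
graded severity (bias 1.5–3 px, jitter 1.2–2.2 px, miss 8–15%, zone
decay 1.4–1.9). These presets are *directional*, chosen once so the
synthetic study lands in the qualitative regime of a real grading study
(expert IoU ≫ junior IoU, junior quality decaying with zone, junior
annotations brighter than expert ones); no quantitative annotator-error
model was available to calibrate against. Annotator error is
deliberately independent of image noise, which provides the null for
the noise-stratification check.

All randomness descends from one root seed; per-(rater, image, round)
sub-seeds come from a SHA-256 hash of the key, so adding a rater or an
image never changes other masks. Rounds are i.i.d. draws — the emulated
study found little systematic change between rounds, and no
round-effect model is imposed.

What passing tests on phantoms do *not* show: realistic coherent-imaging
speckle (true OCT speckle is correlated and multiplicative-like),
anatomical layer structure, vessel shadows or other IRF mimics, or
human behaviour such as fatigue and training effects. The battery
validates the *pipeline's* measurements against known truth, not
clinical conclusions.

## Numerical and interface choices

- Result CSVs use a stable column order and 6-significant-digit float
  formatting, so re-runs are byte-identical; NaN renders as an empty
  cell. Displayed tables round to 4 decimals; full precision is kept
  internally.
- Evaluation itself draws no random numbers; (study, config) fully
  determine all outputs, and the config hash is recorded in provenance.
- Manifest validation is schema-level (pydantic models; a JSON schema
  file ships in `src/annotqc/schemas/`) plus referential integrity:
  undeclared images or raters, duplicate (image, rater, round) keys,
  unknown tiers and unknown consensus raters are all rejected.
- The round-delta table compares pooled metrics (IoU, DSC, TNR, TPR,
  precision) between rounds per two-round rater; "same" means
  |Δ| < 10⁻¹².
- Problem sizes in the test battery (20 seeds of the 10-image default
  study; 10 seeds per λ in the recovery sweep) were chosen as the
  smallest sizes at which the directional contrasts are far from their
  decision boundaries.

## Known limitations

- With only two consensus raters, the experts are scored against a
  ground truth they helped build; their scores are optimistically
  biased. A leave-one-out consensus would remove this and is not
  implemented.
- The annotator-marginal AC1 variant is asymmetric; matrix entries
  average both orientations, which has no published interpretation.
- λ estimation assumes spatially uncorrelated count noise; on data whose
  noise is smoothed or correlated the variance/mean slope is biased low
  (λ̂ biased high).
- Zone assignment is centroid-based; pixel-wise splitting of straddling
  regions is not supported.
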