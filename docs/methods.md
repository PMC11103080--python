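# Methods

This note documents the models, rules and numerical choices behind
`sonoagree`, and what the synthetic-data generator does and does not
emulate.

## Study model

A study is a manifest (annotators, scans, structures) plus one annotation
per annotator, scan and structure. The default protocol is a 19-expert
human panel plus one AI annotator, six block regions (interscalene ISB,
axillary AxB, erector spinae plane ESPB, rectus sheath RSB, adductor canal
ACB, popliteal sciatic SNB) with five scans each, and 20 quantitative
structures. Arteries, muscles and nerves are closed outlines ("region"
kind, compared by Dice); fascial/serosal planes are open polylines ("line"
kind, compared by Hausdorff). Two structure pairs are analysed as single
grouped units — the C5+C6 nerve roots and the anterior+posterior layers of
the rectus sheath — because the AI predicts them jointly; grouping merges
components and statuses, so 20 structures become 18 analysis units (90 per
annotator over 30 scans). The pleura is carried in the manifest for the
qualitative assessment only and is excluded from the quantitative set.

Coordinates are continuous pixels, origin top-left, x rightward, y
downward, polygons implicitly closed. They are stored to 0.01 px: enough
for sub-pixel annotation fidelity, coarse enough that serialisation
round-trips are exact.

## Metrics

**Dice** is computed on rasterized masks at native scan resolution, not on
polygon areas: the AI overlay is raster-native, and rasterization makes
area and overlap unambiguous for hand-drawn, possibly self-intersecting
outlines. A pixel (row *i*, col *j*) belongs to a mask iff its centre
(*j*+0.5, *i*+0.5) lies inside the outline under the even-odd rule; the
even-odd rule handles small stylus crossings deterministically. Grouped
region structures are compared as the union of their component masks.

**Hausdorff** uses the max-of-min point-set distance on polylines densely
resampled at 0.5 px arc-length spacing, so the point-set distance
approximates the curve distance to sub-pixel accuracy regardless of how
sparsely vertices were placed (drawn-vertex-only comparison is available by
resampling with a large spacing). The symmetric form (max of both directed
distances) is the default because it is the standard metric; a flag
restores the one-directional variant. The distance is normalized by the
larger image side by default — an image-diagonal denominator is provided,
under which the score cannot saturate — and clamped at 1. Grouped line
structures are compared as pooled point sets.

**Empty annotations.** A pair in which exactly one annotator marked the
structure "not visible" scores the worst value (Dice 0, Hausdorff 1):
one-sided disagreement is real disagreement, and it is what drives the
0.00 minima that dominate pooled ranges. A pair in which *both* marked it
absent expresses mutual agreement that nothing is visible, but has no
defined geometric score; such pairs are excluded from pooled statistics
and reported as a separate count by default, with a "perfect"-scoring
policy available for sensitivity analysis.

## Curation

Rules are applied per human annotator and scan, on grouped units:

* if nothing on the scan was annotated (all absent or explicitly skipped),
  the whole image is assumed skipped in error and all its entries are
  excluded, counted per grouped structure;
* wrong-geometry-kind annotations (an enclosure for a line structure, or
  vice versa) are excluded individually — detected at load time by
  comparing the drawn feature type against the declared kind, with only
  the flag retained;
* a structure left unannotated while others on the scan were annotated is
  kept as an explicit empty "not visible" annotation;
* the AI annotator is exempt: an empty AI output is a genuine
  "not highlighted" prediction and scores as absent.

Excluded entries are not deleted; their status is rewritten
(`image_skipped` / `invalid_geometry`) and downstream analysis ignores
everything but present/absent. This makes curation idempotent, preserves
the provenance of every exclusion, and keeps the audit arithmetic —
`analysed = grouped_potential − skips − invalid` — checkable on the
returned collection itself.

## Summaries

All raw pairwise values of a structure are pooled across scans into a
single distribution (not per-scan means averaged): pooled raw pairs are
what produce min–max ranges that reach 0.00. The reported sd is the sample
standard deviation (n−1), flagged undefined for a single pair; the median
of an even pool is the midpoint of the central pair; scopes with zero
poolable scores yield explicit rows with undefined statistics rather than
disappearing. Values are rounded only at presentation (2 decimals).

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
not ultrasound appearance. Ground truth per scan: each region-kind
structure is a rotated ellipse with a random low-order harmonic boundary
perturbation (64 vertices), placed near a fixed per-structure anchor with
class-specific size ranges (arteries small and round, muscles large and
elongated, nerves small); each line-kind structure is a smooth open curve
spanning most of the image width. Default image size is 512×384 px,
landscape, ultrasound-like.

Each annotator redraws the truth through a profile: Gaussian translation
jitter (default σ = 2 px), log-normal area-scale jitter (σ = 0.05),
and smooth boundary noise (σ = 1.5 px) generated as a Fourier series of
orders 1–6 along the outline parameter — with 64 vertices the shortest
noise period exceeds four vertices, so outlines stay smooth and do not
self-intersect at default amplitudes; radial excursions are clipped at
80 % of the local radius as a guard. Boundary and translation noise scale
linearly with the structure's rms radius relative to a 20 px reference,
so a profile expresses *relative* sloppiness: without this, the Dice of
large structures would be dominated by their size rather than by how
difficult they are. Per-class difficulty multipliers (artery 0.7 <
muscle 1.0 < fascia 1.2 < nerve 2.5) scale each annotator's sigmas and
omission rate, so the artery > muscle > nerve agreement ordering emerges
from the noise model instead of being hard-coded.

Error processes: per scan, a whole-image skip with probability 2/570; per
structure, omission ("not visible") with probability 0.03 × difficulty and
a wrong-geometry-kind error with probability 26/1900. The skip and
wrong-kind rates equal the frequencies observed in the replica accounting
(2 skipped scans among 19 × 30; 26 wrong-kind among 1900); the omission
rate is a realistic few-percent choice, as no "not visible" count is
published. The AI annotator is one more profile — lower boundary noise
(0.8 px), a larger translation component (3 px), no omissions or skips —
so AI–human comparisons inherit slightly lower means with smaller spread.

All randomness derives from one master seed via spawned per-scan and
per-annotator seed sequences; identical configurations serialize to
byte-identical studies.

A deterministic *replica fixture* reproduces the published annotation
accounting exactly — 19 × 100 = 1900 potential annotations, 1710 after
grouping, one annotator skipping one ISB scan (3 grouped units) and one
ESPB scan (2), 26 wrong-kind events on distinct (annotator, scan, group)
triples, leaving 1679 analysed. The audit totals are invariant to where
the 26 events are placed; placement is seeded and avoids the skipped
scans.

**What passing simulated tests does not show.** The generator draws
annotator errors independently across structures, annotators and scans;
real panels show correlated behaviour (systematically conservative or
generous experts, scan-specific ambiguity affecting everyone at once,
confusion between neighbouring structures rather than random jitter). It
produces star-convex blobs and gentle curves, not the concave, branching
or broken outlines real anatomy can require, and no B-mode texture at
all, so nothing here validates image *interpretation* — only the
measurement pipeline downstream of it.

## Numerical choices

* Rasterization is an exact vectorized crossing-number test per pixel
  centre, restricted to the polygon's bounding box; it matches an
  exhaustive point-in-polygon oracle pixel for pixel.
* Directed Hausdorff distances are delegated to
  `scipy.spatial.distance.directed_hausdorff` and verified against a
  brute-force double loop in the tests.
* Rasterized Dice of two offset disks agrees with the analytic
  circle-lens Dice to < 0.01 at 200×200 px with radius-20 disks (the
  discretization gap shrinks with resolution); this closed form,
  integrated over a Rayleigh-distributed centre offset, is also the
  semi-analytic expectation used to calibrate translation jitter.
* Polyline resampling keeps endpoints exactly and places points at
  uniform arc-length intervals ≤ the spacing, so resampled points lie on
  the original curve and the curve is nowhere farther than half the
  spacing from them.
* Degenerate inputs fail loudly: empty chains and sub-minimal vertex
  counts are argument errors at the metric level (empties are a policy
  question and are resolved upstream); both-empty Dice returns the
  configured value rather than dividing by zero.

## Problem sizes

The test suite runs reduced panels (4–6 humans, 1–2 scans per region) for
pipeline and ordering checks, 100–110 simulated pairs per noise level for
the monotonicity property, 500 replicates for the jitter calibration and
300 scenes for the bounds sweep; the full suite completes in well under a
minute. The acceptance script runs the replica accounting and a
full-scale 19-expert, 30-scan simulated study (≈16 500 pair scores) in a
few seconds.

## Known limitations

* Dice on rasterized masks is resolution-dependent for very small
  structures (a few pixels across); the scan dimensions in the manifest
  should be the native annotation resolution.
* The Hausdorff normalizer treats all scans of a region as comparable;
  mixing very different image sizes within one pooled scope changes the
  meaning of the normalized score.
* Vote maps and the pairwise machinery assume annotations are positioned
  in the same pixel frame; no registration between annotators is
  performed.
* Qualitative aggregation reproduces proportions from counts; it does not
  model inter-expert agreement on those judgments (no kappa statistics).
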