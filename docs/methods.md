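# Methods

This note records the scientific and numerical choices behind `capscore`:
what is fixed by the published rubric, what is a convention of this package,
and what the synthetic cohorts do and do not establish about real data.

## The ordinal rubric

Five categories are scored 0/1/2 per capillary.  The numeric anchors
(thickness cuts 100 and 200 nm, reduplication cuts 2 and 4 layers,
ensheathment cuts 5 and 7 processes, TRI count/size thresholds) come from
the published rubric; everything below is how this package resolves points
the rubric leaves qualitative.

- **Band convention.**  All bands are half-open on the right:
  score 1 ⇔ cut₁ ≤ x < cut₂, score 2 ⇔ x ≥ cut₂, so "200+" includes exactly
  200 nm.  This makes every scorer monotone and boundary behaviour
  unambiguous (the original readers' handling of exactly-100 or exactly-200
  nm membranes is unrecorded).
- **Sub-50 nm membranes** score 0.  The 50–100 nm band describes the normal
  range; thinner-than-normal is not pathological *thickening*.
- **Endothelial activation** ("increased area and/or organelles") accepts
  either an explicit visual grade (none/mild/marked → 0/1/2) or a raw pair:
  endothelial cross-sectional area banded as a ratio to a reference area
  (defaults: < 1.5× → 0, 1.5–3× → 1, > 3× → 2; reference 5 µm², a plausible
  healthy capillary endothelial cross-section), combined with the organelle
  prominence level by a max rule.  All three numbers are configuration, not
  recovered values.
- **Ensheathment size caveats** ("not only focal and small", "also
  depending on size") are encoded as a prominence qualifier; processes that
  are only focal and small demote the count-derived score by one level.
  When no qualifier is recorded, ordinary prominence is assumed.
- **TRI size classes** are diameter conventions: small < 300 nm, medium
  300–800 nm, large > 800 nm (configurable).  A *single* small inclusion
  scores 0 — the rubric's score-1 clause starts at "2 small or 1 medium",
  and the gap below it is resolved downward.  Mixed observation lists take
  the maximum applicable score.
- **Degraded capillaries** (the near-empty BM "sack") are scored on
  whatever remains measurable; unmeasurable categories are recorded as
  missing and contribute 0 to the four-category sum, with a logged warning.
  Only a capillary with *all four* summed categories missing is dropped
  from its case's N.  This keeps AS well-defined without discarding
  partially readable capillaries.

## Case and group statistics

AS is the per-case mean of the four-category sum; ACS_c the per-case mean
of one category; by construction AS = Σ_c ACS_c exactly.  Group summaries
report mean, sample SD (n−1 denominator — the usual convention for
"± SD" in clinical tables; the original denominators are unstated), min and
max of per-case AS plus mean ACS per category.  A single-case group reports
SD 0 with an explicit flag.

Case ordering for the report figure uses VAS ascending, then AS ascending,
then case id (the published figure's sort direction and tie-breaks are
unstated; direction is switchable, the id tie-break is always ascending so
the order is deterministic).  Histological pattern labels (MMCP etc.) are
*inputs* throughout; nothing in the pipeline infers them.

## Morphometry

Annotations are closed polygons in nm in the section plane ((x, y), origin
top-left, y down; pixel-unit files are scaled by the pixel size, default
7.3 nm, on import).

- **BM thickness** is measured with 36 equally spaced radial rays from the
  lumen centroid; per ray, the length of the ray inside the union of the BM
  layer polygons; the per-capillary value is the median over rays that hit
  (mean and max are selectable, and the choice should be reported — how the
  original readers assessed "thickness" visually is unknown; the median is
  robust to focal bulges).  For non-star-shaped lumina whose centroid falls
  outside, the ray origin falls back to the pole of inaccessibility
  (logged).  The ray fan is anchored to the annotation's own first lumen
  vertex rather than the world x-axis, which makes measurements invariant
  under rigid motion of the annotation (at the cost of a benign dependence
  on vertex ordering, which is deterministic for any given file).
- **Layer count** is the number of nested BM rings; non-nested overlapping
  rings are an annotation error.
- **Processes** count if they intersect a peri-capillary annulus
  (default width 1000 nm) outside the outermost BM; prominence is banded on
  the fraction of 720 probe directions that meet a counted process
  (< 25% focal/small, 25–75% prominent, > 75% very prominent).  Annulus
  width and coverage bands are conventions, config-exposed.
- **Endothelial area** is outer endothelial area minus lumen area
  (shapely's exact polygon areas), reported in µm².

Expected accuracy, verified by the test suite on constructed phantoms:
thickness within 2% (polygon-discretisation error at 192–256 vertices is
≲ 0.1%; the 2% budget covers oblique rays on eccentric contours), areas
within 1%, counts exact.

## Synthetic cohorts

No per-capillary human scores are published, so the generator emulates the
*printed* group structure rather than resampling real data:

- **Composition.**  29 sections: 12 MMCP + 6 non-MMCP SSc biopsies, 8
  dermatomyositis + 2 anti-synthetase disease controls, 1 non-diseased
  control; 100 capillaries per section except eight randomly chosen
  sections with U{40..99} (the real sub-100 counts are unpublished).
- **Scores.**  Per group, marginal probabilities (p0, p1, p2) per category,
  chosen once by moment matching so the implied expected AS equals the
  published group mean: MMCP 2.35, non-MMCP 4.2, DM 1.45, anti-synthetase
  3.555 (midpoint of the two published cases), control 0.08.
- **Case heterogeneity.**  A proportional-odds case effect
  δ ~ N(0, σ) shifts all cumulative logits of a case; σ per group (MMCP
  0.7, non-MMCP 0.8, DM 0.5, anti-synthetase 0.8, control 0) is set so the
  per-case AS spread is of the order of the published group SDs.  The
  baseline cut-points are re-calibrated numerically (41-node Gauss–Hermite
  quadrature + Brent root-finding) so the δ-marginal probabilities equal
  the stated p exactly; the case effect therefore widens the spread without
  biasing the group mean.  Categories are independent given δ (no joint
  data are published to calibrate more).
- **TRI** is case-level: a case harbours TRI-bearing capillaries with a
  group-specific probability (1/12 for MMCP, matching the single reported
  MMCP case with TRI); i.i.d. per-capillary TRI would make nearly every
  100-capillary case TRI-positive.
- **Feature inversion.**  Every drawn score is inverted into a raw feature
  sampled uniformly inside its rubric band (score-2 thickness U[200, 400)
  nm, etc.), so re-scoring the feature table reproduces the drawn scores
  *exactly*; values are written at full float precision because rounding
  could cross a band edge.
- **Covariates.**  VAS ~ truncated normal on [0, 10] (group means 3 / 7 /
  5 / 6 / 0.2); light-microscopy subscores Binomial(3, VAS/10); CK
  log-normal moment-matched to the published mean ± SD (MMCP 1325 ± 1791,
  non-MMCP 2536 ± 2068 U/l); age truncated normal; cutaneous subtype and
  organ-involvement flags Bernoulli at the published group percentages.
  These covariates are decoration for the report and IO paths; nothing
  statistical depends on them.
- **Determinism.**  A master seed drives a `SeedSequence` spawn per case;
  identical config + seed gives byte-identical output tables.

**What passing tests show — and don't.**  The generator matches marginal
per-category frequencies, per-case AS spread and group AS means/ranges.  It
does *not* model spatial correlation between neighbouring capillaries,
within-case category correlation, reader disagreement, or annotation noise;
calibration tests therefore validate the pipeline's statistics, not any
biological claim.  In particular the published group AS values themselves
are calibration constraints here, not independently reproducible results —
the underlying per-capillary human scores are not available.

**Geometry phantoms** are perturbed-ellipse lumina (eccentricity ≤ 0.08)
with radially offset endothelium/BM rings (192 vertices; the offset is
solved from a polar-fan quadratic so the constructed endothelial area hits
its target to ≲ 0.1%), wedge-shaped processes realising a target angular
coverage, and TRI marks with diameters drawn strictly inside the size-class
bands.  Because all rings are radial offsets of the same angular sampling,
radial-ray thickness is exact up to chord error, which keeps the 2%
round-trip budget honest rather than tautological.

## Problem sizes

The statistical checks run at: 10,000 random cases for the AS/ACS identity,
a ~52,000-combination grid for batch–scalar equivalence, 1,000 replicates
of N = 100 for parameter recovery, 500 random phantoms for count recovery,
and 200 cohort replicates for group-mean calibration — sizes at which the
binomial margins of the pass criteria (≥ 99% within 4 SE, ≥ 95% in range)
are comfortably resolved on a single CPU in a few minutes.

## Known limitations

- The morphometry engine measures annotations; it does not detect or
  segment capillaries, TRI or nuclear inclusions in images.
- The activation area bands, TRI diameter classes, annulus width and
  coverage bands are conventions; analyses comparing absolute ACS values
  across labs should report their config hash (the manifests record it).
- The thickness summary statistic changes results on irregular membranes;
  median is the default and the choice is configurable and logged.
- Proportional-odds case effects are symmetric on the logit scale; real
  case-severity distributions may be skewed.
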