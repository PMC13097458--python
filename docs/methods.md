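# Methods

`skinoverlap` quantifies how much human skin colour varies *within*
self-identified ethnic groups and how much the groups' colour
distributions *overlap*, working throughout in the CIE 1976 L\*a\*b\*
(CIELAB) space. This note records the models, the numerical choices, and
what the synthetic validation does and does not establish.

## Colour representation

All statistics operate on CIELAB triples (L\*, a\*, b\*): lightness,
red–green, yellow–blue. Two derived quantities matter:

* **Chroma** C\* = √(a\*² + b\*²), the distance from the neutral axis.
* **Colour difference** ΔE\*ab = ‖(L₁\*,a₁\*,b₁\*) − (L₂\*,a₂\*,b₂\*)‖₂,
  the classic perceptual difference measure. ΔE\*ab ≈ 2 is adopted as the
  perceptibility threshold (PT): a suprathreshold just-noticeable
  difference for skin, above the replica-study thresholds of ≈1.1–1.6
  reported for lighter/darker skin. PT is a configurable constant
  (`ThresholdConfig`, default 2.0, strict `<`; a flag switches to `≤`
  for sensitivity analysis).

Input colour may be given as CIELAB directly, as XYZ tristimulus values
(converted with the standard cube-root L\*a\*b\* transform; linear
segment below t = (6/29)³), or as reflectance spectra. Spectral
integration uses a 10 nm rectangular rule over 400–700 nm, renormalized
so the perfect reflector maps to the illuminant white with Y = 100.
The default illuminant/observer pair is D65 with the CIE 1964 10°
observer, a common choice in skin colorimetry; both are configurable.
Colour-matching functions are evaluated from the published analytic
multi-lobe fits (Wyman, Sloan & Shirley), accurate to about 1% of peak;
illuminant D65 is the standard 10 nm relative-power table bundled as
CSV, and illuminant A is computed from its defining Planck formula
(T = 2848 K, c₂ = 1.435×10⁻² m·K). Spectrum-derived conversions use the
white point derived from the same tables, so spectra and their Lab
values are mutually consistent; data supplied as XYZ use the published
white-point constants (D65/10°: 94.811, 100, 107.304). L\* is never
clamped: out-of-[0, 100] values raise a warning naming the records, so
implausible measurements surface instead of being silently truncated.

## Data model and filters

A dataset is one row per measurement: subject id, group code (CA, CN,
JP, SA, AF, IQ, TH, AB), gender, optional age, body site from a
controlled 13-name vocabulary, and the CIELAB triple. Ear-lobe and
ring-finger measurements are excluded by default (incomplete coverage
across collection sites); the filter is configurable, never hard-coded.
The site vocabulary deliberately accepts all 13 archive site names even
though the archive describes "twelve positions" — the count discrepancy
is a data-entry question the schema does not resolve.

## Within-group variation

Per group: mean and sample SD (ddof = 1) of L\*, a\*, b\* and of
per-sample chroma, plus the mean and SD of the ΔE\*ab between each
sample and the group's mean colour (a perceptually meaningful dispersion
measure). A two-way fixed-effects ANOVA (ethnicity × gender with
interaction) is fitted per attribute via ordinary least squares; Type II
sums of squares by default (main effects not biased by the interaction
under unbalanced designs), Type III with sum-to-zero contrasts behind a
flag. Effect sizes are partial η² = SS_effect / (SS_effect + SS_resid).
Measurements are treated as independent observations, matching the
per-measurement analysis convention, although subjects contribute ~10
sites each; a `per_subject` flag aggregates to subject means first for
sensitivity checks. The defaults therefore overstate effective sample
size in the ANOVA p-values — the effect sizes, not the p-values, are
the quantity of interest at n ≈ 14 000.

## Individual-level overlap

For each sample of a reference group, the minimal ΔE\*ab to any sample
of a comparison group is found exactly with a k-d tree (ΔE\*ab is
Euclidean, so spatial indexing is exact; equality with exhaustive search
is asserted in tests). The overlap percentage is the share of reference
samples whose minimum falls strictly below PT. The 8×8 matrix has
reference groups as rows; its diagonal is 100 by definition and is
excluded from medians and correlations. The matrix is asymmetric by
construction: a tight group nested inside a broad one overlaps it almost
fully, not conversely.

## Group-level (gamut) overlap

Each group's point cloud is voxelized into 3×3×3 CIELAB unit cubes on a
global grid anchored at the origin with half-open cells
[3k, 3(k+1)); negative coordinates floor rather than truncate, keeping
cells uniform across zero. The 3-unit edge keeps adjacent cube centres
beyond the perceptual threshold. Two single-pass morphological
refinements, both evaluated on a snapshot of their input (no
cascading), encode an assumption of skin-colour continuity:

1. remove isolated cubes (all six face-adjacent neighbours empty);
2. fill gaps (empty cubes whose six face neighbours are all filled).

Removal runs first; the passes are not iterated to a fixpoint. Overlap
of reference A with comparison B is 100·|cubes(A) ∩ cubes(B)|/|cubes(A)|
on refined gamuts (refined-for-both). The shared count is symmetric, so
pct(A→B)·|A| = pct(B→A)·|B| exactly — asserted as an invariant. Grid
anchoring is a convention: cube counts are sensitive to it at the few-
percent level, which is why reproduction tolerances on volumes are
proportional rather than absolute.

## Robust summaries

Overlap percentages are skewed, so central tendency is the median of
the 56 ordered off-diagonal cells, with a percentile bootstrap CI
(1000 resamples of the original size, 95%). The resampling unit is the
cell — the overlap results being summarized — not the underlying
measurements; percentile rather than BCa intervals for simplicity.
Even-length medians are the mean of the two central order statistics.
Agreement between the individual and gamut matrices is Pearson's r over
the paired off-diagonal cells; when either matrix has zero off-diagonal
variance (e.g. the fully-identical diagnostic scenario) the correlation
is reported as *undefined*, not NaN-propagated, and with only two
groups (two cells) it is likewise undefined.

## Synthetic data generator

Each subject draws a trivariate Gaussian (L\*, a\*, b\*) deviate from
the group's location and covariance; each of their ~10 site
measurements adds an optional per-site offset, an optional gender
offset, and isotropic within-subject noise with per-axis σ = 0.5/√3
(RMS ΔE\*ab displacement 0.5 — small against between-subject SDs of
2–7). The `issa_like` preset uses the published eight-group CIELAB
means/SDs with diagonal covariance (only marginal moments are
published; an optional L\*–b\* coupling imitates the banana-shaped
L\*C\* cloud), archive gender ratios, and subject counts of one tenth
of each group's measurement count so generated sample sizes match the
archive's overlap denominators. `identical` and `two_group_partial`
share a single draw across groups, translated to each group's mean — a
common-random-numbers design under which full overlap is exact for
identical locations and both overlap statistics respond monotonically
to mean separation alone; `disjoint` spaces tight groups 30 L\* units
apart. Gaussian tails are not truncated, preserving the configured
moments (consistent with the no-clamp rule above).

What passing synthetic tests shows: the statistics recover known
overlap structure, respect their invariants, and are calibrated
(bootstrap coverage ≈95%). What they do not show: the real archive's
values. The simple Gaussian model under-disperses relative to real skin
clouds — on the `issa_like` scenario the individual-overlap median
computes to roughly 63–65%, below the ~89% published for the real
archive — so reproducing the published numbers requires the archive
itself (see the reproduction section of the README). The within- vs
between-subject variance split of the real archive is unpublished; the
default split (nearly all variance between subjects) is a modelling
choice.

## Numerical and reproducibility choices

* One seeded `numpy` generator per run; the seed is serialized into the
  output bundle, and identical config + seed reproduces a byte-identical
  bundle (sha256 manifest; the run log carries no timestamps).
* CSV outputs at 6 significant digits; percentages rounded to 1 decimal
  only at reporting, full precision internally.
* "Identical colour" comparisons use 1e−12 absolute tolerance.
* Degenerate inputs fail loudly with the offending group/row named:
  empty groups, single-sample groups, empty gamuts after refinement,
  missing gender cells, non-PSD covariances.
* Problem sizes in the test suite (point sets ≤ 500×500 for oracle
  equality, 500 bootstrap replications, 10⁴ samples/group for moment
  recovery) are chosen so the whole suite settles in seconds while
  keeping Monte-Carlo tolerances at ≥4 standard errors.

## Known limitations

* Alternative colour-difference formulas (CIEDE2000, CMC) are out of
  scope; ΔE\*ab is the measure throughout.
* The analytic colour-matching fits are ~1% accurate; pipelines that
  start from XYZ (the normal case) are unaffected.
* No mixed-effects modelling of the subject/site nesting; no convex-hull
  gamut volumes (rejected as outlier-sensitive and concavity-blind).
* Voxel statistics depend on the grid anchoring convention at the
  few-percent level; comparisons should hold edge and anchor fixed.
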