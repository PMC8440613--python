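# Methods

## Colour quantification

An image's pixels are treated as coordinates in the sRGB cube. Each channel
is divided into `bins_per_channel` equal half-open intervals (`[0, 85.33)`,
`[85.33, 170.67)`, `[170.67, 256)` for 3 regions), and a pixel's bin is the
triple of its per-channel region indices — 3³ = 27 possible bins for
organism images, 4³ = 64 for seascape surveys. A bin's representative
colour is the **mean sRGB of its own pixels**, not the geometric bin
centre, so the representative tracks the image's actual hues. Bins holding
less than 1 % of the pixels are excluded before classification; this is the
safeguard against compression artefacts, crop-edge fringes and small
residual shadows, and it also means no special-casing of JPEG decoding
noise is needed. After exclusion the surviving proportions are renormalized
to sum to 1 (required downstream, where earth-mover's-distance signatures
must carry unit mass; the category set extracted for hue profiling is
unaffected by renormalization). Fully transparent pixels, and pixels
matching an optional background sentinel colour, are masked out before
binning.

### ISCC-NBS classification

The Level-3 ISCC-NBS system partitions colour space into 267 named
categories whose centroids are defined in Munsell space. The bundled
resource `src/coralhue/data/iscc_nbs_level3.csv` lists all 267 categories
with an approximate sRGB rendering of each centroid (names follow the
published listing; the 8-bit channel values are approximate conversions of
the Munsell centroids and a few may deviate by small amounts from other
published renderings). Classification is nearest-centroid: the query sRGB
value and all centroids are converted to CIELAB (D65, via scikit-image) and
the category with the smallest Euclidean distance wins; ties break to the
lowest category index for determinism. CIELAB is used because its
approximate perceptual uniformity matches the Munsell-block intent of the
system better than raw sRGB distance; a plain sRGB-Euclidean mode is
available through `colour_space_for_matching` for sensitivity checks. All
267 bundled centroids are mutually distinct and self-classify under both
metrics. Note that the original published sRGB→ISCC-NBS allotment reaches
260 of the 267 categories; nearest-centroid classification is one of
several defensible realizations of that mapping, and the number of
categories reachable from the sRGB cube is checked only as ≤ 267.

Hex codes (`srgb_to_hex`) are the interchange format for bin colours;
non-integer channel values (bin means) are rounded half-up first.

## Ecoregion aggregation

Coral richness is a presence-matrix column sum. Hue diversity is the size
of the union of the hue profiles of the species present — a deliberately
set-valued summary: two coral species sharing a colour add it once. If a
species has several images, the union of their profiles is used rather
than silently dropping data. Fish richness (total and per family) is
supplied per ecoregion; the assembler validates id consistency across all
four inputs and fails listing the offending ids. Ocean-region membership is
an input column, not hard-coded, since the regional grouping is data.
Assembled fish counts are kept numeric (not coerced to integers) so that
exact-valued synthetic inputs round-trip unchanged.

## Regression suite

All linear models are ordinary least squares with intercept (statsmodels).
Second-order coral terms are fitted on an orthonormal polynomial basis
(QR of the Vandermonde matrix, as R's `poly()`): at coral richness values
of several hundred, the raw `x, x²` basis is poorly conditioned. Fitted
coefficients are mapped back to the raw basis exactly (`Z = V C` gives
`β_raw = C β_orth`), and both parameterizations are reported.

- Degrees of freedom follow the term counts: F(1, n−2) linear,
  F(2, n−3) quadratic, F(3, n−4) for the combined hue + coral-poly2 model.
- The hue-saturation model is a **saturating logistic growth curve**
  `H = A / (1 + exp(−k (S_c − x₀)))` fitted by nonlinear least squares
  with four heuristic starting points (asymptote near the hue maximum,
  steepness scaled to the richness span, midpoints at the quartiles); the
  best residual sum of squares wins, and failure from every start raises a
  diagnostic error. The response is a bounded count that plateaus, so a
  growth curve — not binomial regression — is the appropriate reading of
  a "logistic" relation here. Its adjusted R² uses 3 parameters; the F
  statistic compares against the mean-only model with (2, n−3) df.
- AIC uses the least-squares convention `n·log(RSS/n) + 2k` with
  `k` = number of coefficients + 1 (error variance). This differs from the
  Gaussian-likelihood AIC by `n(log 2π + 1)`, a constant within a fixed
  dataset, so AIC *differences* — the only quantity used for selection —
  agree with likelihood-based implementations (asserted in the tests).
  Ties break to the first-listed model.
- Per-family comparisons fit hue-only (linear), coral-only (quadratic
  polynomial) and combined models and rank families by combined adjusted
  R². A family with constant richness (e.g. absent everywhere) yields NaN
  statistics with a `degenerate response` note instead of an exception.
- Regional fits rerun the combined model within each ocean region. Regions
  with n ≤ 4 cannot support the 4-coefficient model and are returned as
  NaN fits with a `degenerate` note; regions with n < 6 are fitted but
  flagged `underpowered`. A region in which hue is constant (fully on the
  saturation plateau) is likewise reported degenerate rather than raising.

## Reef colour dissimilarity

Seascape signatures use 4 regions per channel (64 bins) to accommodate the
higher hue diversity of whole-reef scenes, with the same 1 % exclusion
rule. The earth mover's distance between two unit-mass signatures is the
optimal transportation cost with ground distance Euclidean between bin
centroids in sRGB (a CIELAB ground space is configurable); the
transportation problem is solved exactly as a linear program with HiGHS
(`scipy.optimize.linprog`). With a metric ground distance EMD is a metric:
symmetry, identity, and the triangle inequality are property-tested, as is
invariance under splitting a bin into co-located halves. The distance
matrix is ordered for display by average-linkage agglomerative clustering
on the EMD matrix (the linkage choice is a display convention only; any
ordering that places similar reefs adjacently would serve).

## Effect-size synthesis

Hedges' d with the usual small-sample correction
`J = 1 − 3/(4 df − 1)`, `df = n_t + n_c − 2`, and sampling variance
`(n_t+n_c)/(n_t n_c) + d²/(2(n_t+n_c))`. Pooling is DerSimonian–Laird
random effects: τ² estimated from Cochran's Q and truncated at zero,
pooling weights `1/(v_i + τ²)`; a fixed-effect mode sets τ² = 0. Random
effects is the default because heterogeneity across independent bleaching
studies is expected a priori. Comparisons with zero pooled SD have an
undefined standardized difference and are dropped with a warning.
Comparisons published only as test statistics are out of scope — the
record schema requires group means, SDs and ns.

## Synthetic data

Two ecoregion generators cover different needs:

- `make_ecoregion_dataset` builds the full object chain (presence matrix,
  per-species hue profiles, fish tables). Coral richness follows a
  strictly increasing gradient over ecoregions ending at the full species
  pool, with *nested* presence (a poorer ecoregion's species are a subset
  of any richer one's). Species are assigned categories in nesting order
  so that the cumulative unique-category count after the first r species
  equals the rounded logistic of r — hue diversity therefore sits exactly
  on the configured saturating curve at every realized richness. This
  exactness is what makes the pipeline-closure test sharp. Its flip side:
  on the plateau, hue is (nearly) constant, which makes the hue term
  degenerate *within* the richest region.
- `make_regression_table` generates (coral, hue, fish) tables directly,
  sampling hue around the logistic with Gaussian scatter (default SD 6
  categories, reflecting ecoregion-level variation in colour composition
  at a given coral richness). It is the generator for model-recovery and
  regional-fit simulations, where within-region hue variation is needed.

Default scale mirrors the study design: 74 ecoregions, 784 coral species,
25 families, four ocean-region labels assigned as contiguous richness
blocks with the richest block labelled Western Pacific. The fish truth
model is `S_f = 150 + 2 H + 3 S_c − 0.002 S_c²` with residual SD 280
species — the residual scale at which the combined model explains roughly
74 % of variance at n = 74, matching the fit quality of the global reef
gradient this emulates — and the logistic truth is A = 180, k = 0.015,
x₀ = 150 (plateau ≈ 180 unique colours, reached beyond ~300 coral
species). Noisy fish values are rounded to non-negative integers (richness
is a count); in the explicit zero-noise regime values are left unrounded
so that truth coefficients remain identifiable to numerical precision.

Image fixtures are vertical-stripe compositions (proportions exact to one
pixel column) at category-centroid colours. For exact image-level ground
truth the categories are drawn from an *image-safe pool*: categories whose
centroids self-classify and occupy distinct histogram bins, so binning
cannot blend two intended colours into a spurious third. Contaminant
stripes below the 1 % threshold verify the exclusion rule end to end.

The meta-analysis generator draws each comparison's true effect from
`N(d_class, τ²)` and then *samples actual group observations* around it,
so observed effects carry realistic sampling error; the default shape is
133 comparisons across 8 studies and four response classes.

What the generators do **not** emulate: real photographic noise
(illumination gradients, white-balance drift, chromatic aberration),
spatial autocorrelation among ecoregions, taxonomic error in presence
data, and publication bias in the extracted comparisons. Passing tests
therefore demonstrate correctness of the computational pipeline under the
stated statistical structure, not robustness to those field realities.

## Problem sizes

Simulation-based checks use 74-row tables with 500 replicates for
coefficient recovery, 100 for asymptote recovery and AIC selection;
pipeline closure runs at 8 ecoregions × 20 species with 32 × 32-pixel
images; oracle checks use ≤ 64 × 64 images, ≤ 5-bin signatures, n ≤ 50
regressions and 100 random effect-size records. These sizes give stable
rates while keeping the whole suite fast.

## Known limitations

- The bundled centroid table is an approximate sRGB rendering; analyses
  that depend on the exact identity of individual categories (rather than
  counts of distinct categories) should verify the specific centroids.
- The published F statistic for the hue-saturation relationship implies a
  df accounting that neither a growth-curve nor a binomial reading
  reproduces; adjusted R² is the comparison surface for that model. One
  published regional fit reports F(4, 9), implying a fourth predictor the
  methods do not name; the standard 3-predictor model is fitted and the
  discrepancy is surfaced here rather than guessed at.
- EMD on 64-bin signatures solves a dense LP per pair; for panels much
  larger than tens of reefs a specialized transport solver would be
  preferable.
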