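# Methods

This note records the models, conventions and numerical choices behind
the package, including the points where the underlying procedure is
genuinely open and a choice had to be made.

## Contours and sections

A fruit image is a polar contour: 360 radii indexed by integer degree,
measured from the contour centroid delivered by the upstream
segmentation. Degree 0 points right (+x), degree 90 up (+y); on side
views the stalk end points up. This orientation is a declared convention
— the segmentation that produces the contours does not prescribe one —
and it fixes the "upper quarter" used for stalk removal to degrees
[45, 135).

Sections are half-open degree intervals: quarters A.R = [0, 90),
A.L = [90, 180), B.L = [180, 270), B.R = [270, 360); halves and full
sections are unions of quarters, so the quarters partition the circle
with no double-counted boundary degree.

**Stalk removal.** Within the upper quarter, radii strictly above the
Tukey fence Q3 + 1.5·IQR of that quarter's stored radii are masked.
Computing the fence from the stored (not already-masked) radii makes the
operation exactly idempotent; strict inequality leaves constant contours
untouched. Masked degrees are excluded from every downstream statistic
rather than imputed.

**Size filter.** Side views whose maximum Cartesian extent is below
150 px are discarded (such fruits are too small for reliable
segmentation).

## The feature grammar

Feature names compose six tokens: tree level {Av, SD} × fruit level
{Top, SAv, SSD} × data type {Pol, X, Y, XY, Hue, Sat} × calculation ×
section × feature type. Which combinations exist is governed by an
explicit block-inclusion table (`shape_features.SHAPE_BLOCKS` /
`COLOR_BLOCKS`), the single source of truth for every downstream column
set:

| block | calculations | sections | feature types | fragments |
|---|---|---|---|---|
| polar absolute | Abs | 4 quarters | Av SD Max Min Q25 Q50 Q75 Area RatM | 36 |
| quarter pairs | Av, SD | A.LR, B.LR | same 9 | 36 |
| full contour | Abs | AB | same 9 | 9 |
| top/bottom combine | Sum.Av Sum.SD Rat.Av Rat.SD | AB.LR | same 9 | 36 |
| whole-fruit symmetry | Av, SD | LR, AB | Sym.abs | 4 |
| half symmetry | Av, SD | A, B, L, R | Sym.abs, Sym.rel | 16 |
| Cartesian | Abs | A, B (X and Y) | Av SD Max Min Q25 Q50 Q75 RatM MaxR | 36 |
| cross-axis | Sum, Rat | A, B | same 9 | 36 |

209 shape fragments × 6 aggregation levels = 1,254 shape/size features;
the color grammar is the full cross {Av,SD} × {SAv,SSD} ×
{Red,Brown,Yellow,Low,Medium,High} = 24 names. The published feature
table this grammar reproduces prints slightly different totals (1,248
and 20); its layout is ambiguous about exactly which symmetry kinds
attach to the whole-fruit sections and which tree×fruit-level color
combinations exist, and no defensible reading of the table reproduces
both printed totals exactly. The enumeration above is the closest
consistent reading (within one fragment block of the shape total) and,
decisively, generates every one of the 24 printed selected feature
names verbatim.

Conventions inside a fragment (the procedure is open on all of these;
each is fixed once here):

- Quantiles: linear interpolation at rank h = (n−1)p; SDs are sample
  (n−1) SDs throughout.
- Section area: Σ ½·r²·(π/180) over retained degrees — the
  circular-sector approximation of the enclosed area (within 0.1% of the
  closed form for smooth convex contours), not a bare radius sum.
- RatM = Max/Min (undefined marker when Min ≤ 0), MaxR = Max/Av.
- AB.LR combinations: the statistic is computed per quarter; the top
  quarter is summed with, or divided by, the bottom quarter on each side
  (A.L⊕B.L, A.R⊕B.R), then the two sides are averaged (`.Av`) or their
  sample SD taken (`.SD`). Ratios are top over bottom.
- Symmetry: matched degree pairs are mirror images (vertical mirror
  d ↔ 180−d for LR/A/B; horizontal mirror d ↔ −d for AB/L/R); the
  statistic is the mean or sample SD of |r₁ − r₂| over retained pairs
  (absolute, not signed, differences). Sym.rel divides by the section
  area, making it scale as 1/length.
- Cartesian features use signed coordinates relative to the contour
  center (translation-invariant); XY-Sum = stat(x) + stat(y),
  XY-Rat = stat(y)/stat(x), i.e. the length axis over the diameter axis
  — the classic length/diameter shape index generalised over statistics.
- Undefined values (RatM at Min ≤ 0, SSD from fewer than two side views,
  tree SD from one fruit) propagate as missing data, never as zeros.

Aggregation: camera correction happens at the image level *before* view
aggregation. Shape features aggregate side views as SAv (mean of 4) and
SSD (sample SD of 4, needs ≥ 2), plus the Top value; color features use
all five images for SAv/SSD and have no top-only level. Tree level is
the mean (Av) and sample SD (SD) over the up-to-five fruits.

## Color phenotyping

Peaks are estimated once on a training pass — genotype-average side-view
histograms, Ward-linkage hierarchical clustering (Euclidean distance on
the 36-vector) cut at three clusters, the maximum-mass bin center of
each cluster average — and then frozen for per-image extraction. Hue is
circular (red sits at the 0/1 seam); peak labelling orders hue peaks by
circular distance from 0 (Red, Brown, Yellow) and saturation peaks by
position (Low, Medium, High). Green is deliberately not a feature: green
fruit does not form its own histogram peak in this crop. The windowed
feature is the *mean* (not sum) of bin masses whose centers fall within
±0.05 of the peak — invariant to window size and histogram scale — with
hue windows wrapping at the seam. Ties for a histogram maximum take the
lower bin (logged); a degenerate clustering (identical histograms) is
split deterministically from the lowest indices to keep three clusters.

## Statistical backbone

**Camera correction.** `y_ijkl = C_l(j) + ε_ijkl` is a one-way
fixed-effects fit per year, so residuals are values minus their
camera-within-year cell mean; corrected cell means are exactly zero.

**Outliers.** Values outside median ± 15·IQR are set missing. The
published rule ("15 times the interquartile range") names no anchor;
the median is used for robustness, quartile-anchored fences being the
noted alternative. A zero IQR disables the rule (logged).

**Adjusted means vs heritability.** The tree-level model
`y_ijk = G_i + Y_j + R_k(j) + ε_ijk` is fitted twice, reconciling its
two uses. (1) Fixed genotype, ordinary least squares: the adjusted mean
of genotype i is its least-squares mean — the fitted value averaged
equally over year levels and over replicate levels within year.
Features sharing a missingness pattern share one pseudoinverse, so the
1,278-feature matrix fits in a handful of factorizations. Replicate
labels are block labels reused across genotypes (randomized complete
block design), not unique tree identities. A genuinely confounded
(rank-deficient) design falls back to raw genotype means with a
warning. Note one consequence of least-squares means: adding a constant
to all observations of one year shifts every adjusted mean by the same
amount (genotype contrasts are exactly preserved); no averaging
convention can keep the absolute level fixed.
(2) Random genotype, REML: variance components σ_g², σ_ε² come from a
profiled REML fit of the single-random-intercept model, written here
directly via the group-mean/within-deviation decomposition — for a
variance ratio λ the GLS fit is an OLS on within-group deviations plus
group means weighted n_g/(1 + λn_g), and the REML criterion is evaluated
in closed form from its residual sum of squares, leaving a
one-dimensional optimisation (grid bracketing + bounded scalar search in
log λ, boundary λ = 0 checked explicitly). This is two orders of
magnitude faster than a general mixed-model fitter at identical
estimates (the test suite verifies agreement with statsmodels' MixedLM
to four decimals). H² = σ_g²/(σ_g² + σ_ε²/n̄_r) with n̄_r = total
observations / number of genotypes, clamped to [0, 1].

**Selection and PCA.** Heritability filters are strict inequalities
(H² > 0.4 before PCA, H² > 0.6 before selection). Correlation pruning is
greedy: while any pair has |r| ≥ 0.75, drop from the worst pair the
member with the larger mean absolute correlation against the surviving
set (ties drop the later column); the post-condition (all surviving
pairs |r| < 0.75) is asserted. Correlations are pairwise-complete; PCA
uses complete-case genotypes, unit-variance scaling (features have
heterogeneous units), drops zero-variance columns, and fixes component
signs by making each component's largest-magnitude loading positive.
PCs are retained to the smallest count reaching 80% cumulative variance
(configurable; capped at 7 for GWAS).

## GWAS

Dosages are treated additively (0/1/2 numeric, no dominance term).
Markers below MAF 0.05 are dropped; the Bonferroni denominators use the
post-filter marker count of each scan. Structure is controlled by the
top three PCs of the centered dosage matrix.

The single-marker scan is OLS `y ~ 1 + PCs + dosage` with a two-sided
t-test on the dosage coefficient, vectorised over markers through the
Frisch–Waugh projection (covariates are QR-projected out once).
Collinear markers get p = 1 and are flagged.

The multi-locus scan iterates: (1) rank markers by current p; (2) walk
the ranking, keeping markers whose r² with every kept marker is below
0.7 — eligibility requires passing the Bonferroni 5% candidate
threshold, because promoting sub-threshold markers lets the model-size
selection chase selection-biased noise and destroys the scan's null
calibration; (3) choose how many leading candidates (0–20) become
pseudo-QTN covariates by BIC (exact fits are floored at machine noise
relative to the total SS so the penalty term decides); (4) rescan all
markers with the retained pseudo-QTNs appended to the covariates,
excluding for each tested marker any pseudo-QTN with r² ≥ 0.7 to it and
the marker itself. Iteration stops when the pseudo-QTN set repeats or
after 10 rounds (non-convergence returns the last scan, flagged). With
the pseudo-QTN budget at zero the scan reduces bitwise to the
single-marker scan. All thresholds (LD r², budget, candidate α) are
configuration, not assertions about the original software; numerical
parity with the published BLINK implementation is explicitly not a goal
— the scan is validated by its calibration (null family-wise error,
uniform null p-values) and recovery (planted QTNs) contracts instead.

Variance partitioning enters significant SNPs in decreasing −log10(p)
order into one OLS and reports sequential (type-I) sums of squares as
percentages of the total corrected SS; the residual closes the sum to
100. The percentages are invariant to affine rescaling of the
phenotype; a collinear marker contributes zero sequential SS (flagged).

## Multilocus genotypes and co-localization

SNPs on one chromosome chain into a physical-linkage group when
consecutive sorted positions are within 0.1 Mbp (single-linkage, so
chains are transitive; pairwise-only grouping differs just in edge
cases and chaining is the documented choice). Per-trait groups (all
SNPs associated with one PC or feature) reuse the same collapse: each
genotype's dosages over the group's markers, in genome order, join into
a digit string; the census of distinct strings is the set of multilocus
genotypes present.

Averaged contours pool all side-view images of all genotypes sharing a
string. Absolute mode averages raw radii per degree (with per-degree
SD). Relative mode first standardizes each fruit's 360 radii to mean 0,
SD 1, then shifts its minimum to 0, then averages — per fruit before
averaging, making the profile invariant to per-fruit affine radius
transforms; constant contours cannot be standardized and are skipped
with a warning.

Chromosome segments divide each chromosome into thirds by its last
marker's position, half-open with boundary points escalating to the
later segment. Published loci co-localize with a hit when on the same
chromosome within 0.1 Mbp (strict), or by segment identity when the
catalog gives only a segment.

## Synthetic data generator

The generator emulates the structure of a two-year replicated orchard
imaging trial; its defaults are the study design: 500 genotypes, 17
chromosomes × 118 markers, two years with roughly one third of the
genotypes phenotyped in year one and nearly all in year two (so most
year-one genotypes repeat), two replicate trees per genotype and year,
five fruits per tree, five cameras per fruit.

**Genotypes.** Two founder pools (24 founders each) draw allele
frequencies from a Balding–Nichols model (Fst 0.15) around shared
ancestral frequencies, creating two subpopulations. Founder haplotypes
carry local LD via an allele copy-chain (copy probability 0.7 per
adjacent marker). Individuals are two founder-mosaic haplotypes
switching founders with probability 0.02 per marker (always at
chromosome starts); the switch probability controls population LD decay
from block-length, and zero switching with a small founder pool yields
median adjacent r² above 0.5 while full switching collapses LD to the
between-chromosome baseline. Dosages are complete by construction.

**Latent traits.** Six genotype-level latents (size, elongation,
conicity, asymmetry, redness, ground color) are additive QTN sums plus
a polygenic normal term. QTNs are drawn from intermediate-frequency
markers spread over chromosomes; effects are sized as
β = √(share / 2p(1−p)) so each QTN contributes its configured share of
the latent variance. A separate helper builds a genotype-level GWAS
phenotype with an exact heritability budget (default five QTNs of 8%
each, h² = 0.6) for recovery experiments.

**Rendering.** Side-view radius =
S · superellipse(1, E) · (1 + C·sin d) · (1 + A·cos d) ·
(1 + smooth 2nd–4th-harmonic noise) · camera bias; the top view is a
circle with left/right asymmetry only. The superellipse exponent
(default 2 = ellipse) flattens the fruit ends when raised, covering the
round → conical → cylindrical vocabulary with four parameters. Size acts
on a log scale (base 180 px, genotype scale 0.10) with year (SD 0.04),
tree (0.03) and fruit (0.03) log-effects; camera biases are
multiplicative radius factors nested in year (SD 0.03) — exactly the
structure the camera correction removes, so that stage is testable for
full recovery. Hue histograms are circular-Gaussian mixtures at red /
brown / yellow centers weighted by the redness and ground-color latents;
saturation is a single bump tracking redness; camera effects enter as
small per-camera channel shifts nested in year.

`SimConfig.implied_clonal_h2()` converts the variance components into
the clonal-mean H² expected for a pure size feature
(σ_g² = 0.10², σ_ε² = σ_tree² + σ_fruit²/5, n̄_r ≈ 2.6 → H² ≈ 0.96); the
test suite checks the statistics stage recovers it within ±0.1 from
rendered contours.

**What the generator does not emulate** — and hence what passing tests
do not show about orchard data: real segmentation artefacts (partial
occlusion, specular highlights, mis-centered contours), non-elliptical
shape families (ribbed or crowned fruit), genotype-by-year interaction,
spatial field effects, missing-at-harvest patterns correlated with the
phenotype, pedigree-structured relatedness beyond two subpopulations,
and linkage between shape and color loci. Results on synthetic data
validate the machinery (estimator calibration, recovery, invariances),
not biological effect sizes.

## Problem sizes and tolerances

The validation suite runs the calibration checks at the sizes the
contracts name: null family-wise error over 200 replicates of 1,000
markers × 120 individuals (bound 0.10 at Bonferroni 5%); H² recovery on
500 genotypes × 2 years × 2 trees × 200 features (tolerance ±0.05);
planted-QTN recovery at 500 genotypes × ~2,000 markers, five QTNs of
≥ 5% variance each at h² = 0.6 (at least 4/5 QTN regions, where a region
counts as recovered when a significant marker has r² ≥ 0.5 to the
planted QTN). The end-to-end pipeline demonstration uses 80–120
genotypes with the full marker panel — image rendering and feature
extraction dominate runtime and more genotypes add nothing to what the
run verifies. Geometric identities are asserted near machine precision;
the sector-area closed forms at 0.1% (the discretization error of
360 one-degree sectors); symmetry-vanishing at 1e−9.

## Known limitations

- The printed feature-table totals (1,248 / 20) are not exactly
  reproduced; see the grammar section. All printed selected-feature
  names are.
- The multi-locus scan is an independent reimplementation of the
  published algorithm's outline; p-values will not match the original
  software bitwise, and the pseudo-QTN set can oscillate between two
  states on correlated traits (the scan then returns the last iteration,
  flagged).
- Adjusted means are least-squares means under treatment coding with a
  pseudoinverse; in severely unbalanced designs close to confounding
  they are reported but increasingly model-dependent.
- REML variance components assume a single random intercept; no
  genotype-by-year random term is fitted.
- Co-localization against segment-only catalog entries is necessarily
  coarse (a third of a chromosome).
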