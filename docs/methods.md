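# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions, and the deliberate design choices behind `leafqtl`.

## Study design being modelled

The package targets an outbred full-sib (F1) mapping population of a
heterozygous tree cross. Markers are SNPs placed on a genetic map of linkage
groups with centimorgan positions. Two segregation configurations occur:

* **pseudo-testcross** (`testcross2`): heterozygous in one parent, offspring
  split into two genotype classes with expected 1:1 ratio;
* **inter-cross** (`intercross3`): heterozygous in both parents, three
  classes with expected 1:2:1 ratio.

Phenotypes are 14 quantitative leaf traits in three modules — size (LA, LP,
LL, LW), shape (LLo, AR, P_L, P_LW, Rect, Cir) and color (R, G, B, CV). A
named color-chart trait is out of scope; the composite CV is the color value
carried downstream. Two further rows sometimes seen in published summary
panels (a column of zeros and an unlabelled dispersion row) have no defined
meaning and are excluded from the summary schema rather than guessed.

## QTL scan

**Model.** Phenotype of an individual in genotype class *j* at a marker:
y ~ Normal(μ_j, σ²), common σ². ML estimates under the alternative are the
class means and the pooled residual variance with divisor n; under the null,
the grand mean and total variance with divisor n. The statistic is
LR = 2(ℓ₁−ℓ₀) = n·ln(RSS₀/RSS₁), which is algebraically n·ln(1/(1−R²)) with
the one-way between-class R²; PVE = 100·(1−RSS₁/RSS₀). The trait is mapped
univariately (the variance term is a scalar per trait), matching the
per-trait structure of QTL tables in this design. The scan evaluates marker
positions only; no interval imputation is done between markers.

**Effects.** Two classes (declared order aa, ab): Δ = μ_ab − μ_aa. Three
classes (declared order AA, Aa, aa): additive a = (μ_aa − μ_AA)/2 and
dominance d = μ_Aa − (μ_AA + μ_aa)/2.

**Eligibility.** A marker is fit only if, after dropping missing phenotypes
and missing genotype calls, at least two classes remain and every observed
class has ≥ `min_class_n` individuals (default 5 — small enough to keep
1:2:1 minority classes at n≈179, large enough for a stable class mean).
Skipped markers are reported with a reason (`sparse_class`, `monomorphic`,
`not_in_map`), never silently dropped. A marker whose alternative fit has
zero residual variance gets an infinite-LR flag and is excluded from
permutation maxima.

**Permutation threshold.** The phenotype vector is permuted against whole
individuals, preserving the marker-to-marker linkage structure; per
permutation the genome-wide maximum LR is recorded, and the threshold is the
⌈(1−α)·N⌉-th order statistic of the N maxima (α = 1 degenerates to the
minimum). Thresholds are per trait; no across-trait multiplicity correction
is applied, mirroring per-trait scan practice. With N permutations and the
unpermuted scan exchangeable under the null, the achieved size is close to —
slightly above — α (≈ ⌈αN⌉+1 out of N+1), which the calibration test brackets
with a Monte-Carlo band.

**Co-location.** A QTL call is a marker with LR ≥ the trait's threshold.
Across traits, calls co-locate when they hit the same marker (window 0) or
fall within a configurable cM window on one linkage group (merged by
union-find). Module-level Venn counts are computed over distinct co-location
clusters per module and their pairwise/triple intersections. Test-cross and
inter-cross markers are accounted separately in scan outputs via the
`seg_type` column.

## Synthetic data

The generator's defaults are the study conditions the package is built
around: **179 progeny** and **20 linkage groups**. Marker density defaults
to 100 markers per group at 1 cM spacing (2 000 markers) as a desk-scale
map; denser maps (e.g. the ~9 600 SNPs of a full RAD-seq map) are supported
by configuration. The test-cross fraction among markers defaults to 0.5 and
the informative parent of each test-cross marker is drawn at random (0.5),
both configurable — real designs vary and no canonical proportion exists.

**Recombination.** Gametes follow a two-state Markov chain along each
linkage group with Haldane switch probability r = (1 − e^(−2d/100))/2 —
no crossover interference. Haldane was chosen over Kosambi as the simplest
standard model; the spacing-to-r mapping is a single function (`haldane_r`)
so an alternative map function is a one-line change. Test-cross markers are
phase-coupled within their informative parent, so dependence between linked
markers decays as 1−2r; markers informative in different parents are
independent, as in a real pseudo-testcross.

**Planted QTLs.** A trait value is the sum over planted QTLs of the class
mean at the individual's genotype plus Normal(0, σ²) noise. The truth record
stores the theoretical PVE = between-class variance under expected Mendelian
class frequencies / (genetic + residual variance). The canonical calibration
setting — testcross means (0, 2) with residual sd 2 — gives between-class
variance 1, total 5, hence PVE 20%.

**Leaf images.** The outline is the polar curve
ρ(θ) = E(θ)·(1 + α·|cos(kθ/2)|^p), E the ellipse with semi-axes L/2 and W/2,
so k equals the visible lobe count — the single parameter maps directly onto
the manually counted lobe trait. α is capped below 0.6 to avoid
self-intersection. Ground truth (area, perimeter, axis extents and all
derived indices) is computed from a 4096-gon of the same curve by shoelace
and polyline length; the raster is the filled polygon at the requested
pixel scale (≥ 200 px on the long axis enforced), interior colored with
per-pixel Gaussian noise on a white background. Default dimensions and
colors sit at the population means of the reference study (≈15.5 × 13.5 cm,
RGB ≈ (57, 74, 36)).

**Expression.** Clustered genes share a log2 tissue template (base 5, ±3 in
up/down tissues — FPKM 256/32/4) with additive Gaussian noise on the log2
scale, i.e. multiplicative log-normal noise on FPKM; background genes get
independent random profiles. This emulates block-correlated tissue-specific
clusters, not library-size effects, count noise, or dynamic-range extremes
of real RNA-seq.

**Seeding.** One global seed plus a CRC32 hash of the stage name feeds a
per-stage `numpy` generator, so each stage is independently reproducible.

*What passing tests show:* recovery and calibration results hold under
Mendelian segregation, Haldane linkage, Gaussian residuals and planted
single-marker effects. They do not certify behaviour under segregation
distortion, genotyping error, epistasis, non-Gaussian traits, or
genotype-by-environment structure — none of which the generator emulates.

## Morphometrics

* Area = foreground pixel count × scale². Masks are hole-filled first;
  more than one connected component is an error (listing component sizes).
* Perimeter is a sub-pixel outline length: the mask is smoothed with a
  Gaussian (σ = 2 px) and the 0.5 iso-contour traced marching-squares style,
  then measured as a polyline. Boundary-pixel counting would overestimate
  smooth perimeters by ~8–10% and bias circularity; the smoothed contour is
  accurate to well under 1% on discs and ellipses at ≥ 200 px, at the cost
  of slightly rounding sharp corners (a rasterized square reads Cir ≈ 0.799
  vs the exact π/4 ≈ 0.785).
* Length/width are extents of foreground pixels projected on the principal
  axes of their coordinates (+1 px footprint), width ≤ length. Principal-axis
  (oriented bounding box) extents were chosen over image-axis extents to make
  the measurement rotation-invariant and consistent with rectangularity's
  bounding-rectangle meaning; the convention is recorded in the run manifest.
* Lobe count is always supplied by the caller (manual counts in the field
  protocol); automated lobe detection is deliberately not implemented.
* Shape indices are exact arithmetic on the size primitives; color traits
  are masked channel means, with CV computed from the fractional means.

Measured size traits agree with generator ground truth to within 2% at
≥ 200 px resolution, and the error shrinks with resolution (tested).

## Summary statistics and networks

Conventions: sample standard deviation (n−1), moment skewness g1 = m3/m2^1.5
and excess kurtosis m4/m2² − 3 (both biased/moment versions, consistent with
published panels whose kurtosis is negative), CV = 100·sd/mean, SE = sd/√n.
Constant traits report zero skewness/kurtosis and are flagged. Pearson
p-values use the exact t transform t = r√(n−2)/√(1−r²) with two-sided
tails — the simplest standard choice; Fisher's z is not used.

The trait network keeps pairs with |r| ≥ 0.10 **and** p ≤ 0.05 on
pairwise-complete observations, with no multiple-testing correction (the
thresholds are themselves the display filter). At n ≈ 178 the p-condition
implies |r| ≥ 0.147, so the retention probability under independence equals
the p ceiling exactly; calibration tests therefore check the rate against
the ceiling within Monte-Carlo error rather than strictly below it. The
co-expression network uses |r| ≥ 0.95 **and** p < 0.001 across tissue
samples — implemented literally even though at five or six samples the
p-condition is the stronger one (p < 0.001 needs |r| ≳ 0.98). Note the
t-based p assumes approximately normal samples: on heavily skewed raw FPKM
rows at tiny n the null p-values are anti-conservative, which is a
limitation of the correlation test, not of the filter.

Clustering standardizes log2(FPKM+1) per gene (z-score) before average-
linkage Euclidean agglomeration — a declared, configurable default chosen to
cluster tissue profiles rather than absolute abundance. Gene order is fixed
lexicographically so dendrogram tie-breaks are deterministic.

2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt relative to the
calibrator sample, fold change 2^−ΔΔCt; invariant to any global Ct shift.

## Problem sizes in the validation suite

The calibration and recovery studies use 179 progeny on 20 linkage groups ×
20 markers at 5 cM (400 markers), 300 permutations, with 200 null replicates
for type-I calibration and 100 replicates for parameter recovery — sizes
chosen so the whole validation runs in a couple of minutes while leaving
Monte-Carlo error well inside the asserted bands. The LR kernel is
vectorized over markers and permutations (class-mask matrix products), so
full-density maps remain practical.

## Known limitations

* No genotyping error, segregation distortion, or missing-call model in the
  generator (missing data are handled by the scan, but not simulated).
* No interval mapping, composite-interval mapping, or epistasis scans.
* The leaf model is star-convex by construction; deeply incised or compound
  leaves are outside its family.
* Correlation p-values assume near-normal marginals (see above).
* Lobe counting is manual by design.
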