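# Methods

## The model and procedure

The pipeline treats "epigenetic context" as chromatin accessibility measured
over a fixed set of genomic regions across tissues and life stages, and asks
three linked questions: which regions shift accessibility between fetal and
adult tissue (and, nested inside those, between young and old adults);
whether those region classes differ in evolutionary constraint; and whether
variants near them differ in aggregate disease association.

### Differential accessibility

Counts are modelled on the log scale after library-size normalization:
`log2((count + c) / (libsize + 2c) * 1e6)` with pseudocount c = 0.5. Each
region is fit by least squares against a shared design — intercept, a
stage indicator, and additive tissue dummies — so the tested coefficient is
the pan-tissue stage shift; per-tissue contrasts run the same engine on
sample subsets. Per-region residual variances sᵢ² (dᵢ df) are shrunk toward
a prior s₀² on d₀ df estimated by moment-matching the scaled-F distribution
of the sᵢ² on the log scale (digamma/trigamma matching, with the trigamma
inverse solved by Newton iteration). The moderated statistic is

    t̃ᵢ = β̂ᵢ / (uᵢ · s̃ᵢ),   s̃ᵢ² = (d₀s₀² + dᵢsᵢ²)/(d₀ + dᵢ),

on d₀ + dᵢ df (capped at the pooled residual df). Two degenerate limits are
exact and tested: d₀ = 0 reproduces the ordinary per-region t; d₀ → ∞ with
fixed s₀² reproduces a pooled-prior-variance t. A unit test cross-checks
the whole fit — prior estimates, t, p — against the Bioconductor limma
implementation to ~1e-8 relative.

Benjamini–Hochberg is applied across regions (and re-applied within the
restricted family for the nested young/old contrast). Calls at FDR < 0.05
are partitioned by coefficient sign into adult-/fetal-biased (or
old-/young-biased) sets. The directionality question is a Pearson
chi-square (1 df) on the 2×2 table of direction labels over regions
significant in both contrasts; Yates correction is off by default (a flag
enables it) so the statistic convention is fixed and reproducible.

Optional precision weights follow the mean–variance-trend idea: a lowess
fit of √(residual sd) against mean log-cpm, evaluated per region, raised to
the −4 power. Weights default off for accessibility (the moderated prior
already absorbs most of the trend) and on for the expression age contrast,
where count dynamic range is larger.

### Peak consolidation

Replicate peak calls are consolidated per tissue/stage group by per-base
support counting: a base survives if covered by ≥ `min_support` replicates
(default 2) in at least one group; surviving bases are unioned across
groups and merged. Counting support per base (rather than per whole peak)
keeps partially overlapping replicate peaks exactly where they agree.

### Evolutionary characterization

Per-region conservation is the arithmetic mean of covered bases; track gaps
are skipped, never zero-filled, and the covered fraction is reported so a
low-coverage mean can be discounted. Class comparisons use two-sided
Mann–Whitney with the common-language effect size. Overlap enrichment is
per-bp: observed = overlap/target-bp, null from shuffles that re-place each
interval uniformly on its own chromosome (length-preserving, optional
exclusion mask by rejection sampling). The empirical p doubles the smaller
add-one tail — (1 + #{null ≥ obs})/(n+1) against its ≤ counterpart — so
depletion and enrichment are both detectable and p ≥ 1/(n_perm+1) always.

The distribution-shift test for variant scores inside a gene-locus family
fits a normal (location/scale) to the baseline population and applies a
one-sample KS test of the target vector against that normal; fold-change is
the ratio of −log10 p to the same test run on the full baseline, which
makes the all-variants-vs-itself fold exactly 1. A z-test of the mean was
the other natural reading; KS was chosen because it keeps the self-test
fold well-defined and is sensitive to shape as well as location.

### Cross-disease aggregation

Per disease, two-sided p becomes unsigned evidence zᵢ = Φ⁻¹(1 − pᵢ/2);
per variant, z_cross = (Σzᵢ − n·E₀)/(√n·SD₀) with E₀ = √(2/π),
SD₀ = √(1 − 2/π), i.e. a Stouffer-style sum of |Z| standardized to N(0,1)
under the global null. Signs are not aggregated because effect directions
are incommensurable across traits; a `mean_neglogp` alternative is exposed
in config. Missing diseases are dropped per variant with n adjusted;
the default `min_diseases` is complete-case. p = 0 is clamped to the
smallest positive float with a warning. Per-disease enrichment of strong
variants (default p < 1e-5) near a region set is an exact hypergeometric on
the tested universe; the smaller tail is reported as signed −log10 adjusted
p (BH across diseases), positive meaning enrichment.

### Gene prioritization and linking

Gene score per disease = minimum p over SNPs in the locus window
(TSS ± `locus_window`) union any capture-linked regions for that gene;
genes with no candidate SNP are flagged and ranked after all scored genes
at the average of the trailing tied positions, which preserves invariance
to monotone transforms of p. Aggregation is the geometric mean of
per-disease ascending ranks (ties averaged). Gene-set significance is a
permutation test against same-size uniform draws from the ranked universe
with the add-one estimator. Region→gene links are the union of three
rules — filtered promoter-capture pairs (reproducible in ≥ 2 tissues),
promoter-window overlap (TSS ± 1 kb), and optional precomputed
regulatory-domain intervals — with a flag to restrict to any subset; union
was chosen because the linking sources are complementary, not redundant.

### Expression

Fetal/adult expression calls use a lenient cross-tissue consistency rule
rather than a formal per-tissue test: adult-up requires log2FC ≥
`min_logfc` (default 1) in ≥ `min_tissues` (default ⌈T/2⌉) tissues and in
no tissue below −`min_logfc` (a veto), symmetric for fetal-up. This is the
package's own rule, designed for settings with too few adult replicates
per tissue to power a fit; its thresholds are all config. Genes below
1 cpm in more than half the samples are excluded and counted. The adult
young/old contrast reuses the moderated engine unchanged (an identity a
test asserts).

## The synthetic-data generator

The generator emulates the statistical structure of a multi-tissue
DNase-I study, not its biology: negative-binomial counts (gamma–Poisson,
dispersion 0.1) around log-normal per-region baselines (median ≈ 100
reads); planted stage shifts of |log2 FC| = 2 in 15% + 15% of regions
applied in every tissue; within dev-altered regions, 40% carry a nested
young/old shift of |log2 FC| = 1.5 whose direction matches the
developmental one 80% of the time — this is what makes the
directionality chi-square positive by construction. Samples are 3 tissues ×
2 stages × 4 replicates with adult ages alternating 30/40/60/70 so the
age-50 split is balanced. The desk-scale genome is two 500 kb chromosomes
with 300 × 400 bp regions on a jittered grid.

Conservation is per-bp Gaussian noise (sd 1, phyloP-like units) with the
fetal-biased class mean shifted up by 0.5; conserved elements are merged
runs above the 90th percentile of emitted scores. Variants (4 000) are
uniform with MAF ~ Beta(0.6, 2.2)/2 (appreciable mass on both sides of the
0.05 common-variant threshold). 2% are pleiotropic: re-placed near a small
number (6) of adult-biased "hub" regions and given |Z| with mean 3 in 70%
of the 50 diseases (sign random per disease — harmless because
aggregation is unsigned); 1% mirror annotated clinical variants with the
same boost but random placement. Allele age is Gamma with mean 1.0,
replaced by a younger Gamma (mean 0.3) with probability 0.7 for variants
inside conserved elements; the functional score simply reads the
conservation track at the variant base. Core genes are defined by
placement: any gene whose locus window contains a planted pleiotropic
variant. Where the emulated study's true effect sizes are unknown the
values above are exposed as `SimConfig` fields rather than asserted as
realistic.

What the generator does **not** emulate — and therefore what passing tests
cannot vouch for on real data: linkage disequilibrium among variants (each
variant is independent), realistic genome sequence or gene density,
GC/mappability structure, batch effects beyond the tissue covariate,
correlated noise across regions, and disease-specific genetic
architectures. Results on real data additionally depend on peak-calling
and track quality upstream of this package.

## Numerical choices and degenerate inputs

- Residual variances ≤ 1e-12 (constant regions) are an error, not a
  silent skip; rank-deficient designs and empty age groups likewise.
- The trigamma inverse uses limma's Newton scheme with asymptotic
  endpoints (y > 1e7, y < 1e-6).
- Empirical p-values use add-one estimators and can never be 0.
- Zero-margin directionality tables return `statistic=None` with a reason
  instead of a spurious value.
- Interval coordinates are 0-based half-open everywhere; book-ended
  intervals merge; a point at `end + window` is outside.
- Shuffling with an exclusion mask rejection-samples up to 1 000 tries per
  interval and raises rather than silently accepting a masked placement.

## Problem sizes

Default test and demo sizes (300–2 000 regions, ≤ 10⁴ variants × 100
diseases, 20-seed calibration loops, 999 rank permutations) were chosen so
that the full suite and the demo each complete in a couple of minutes on a
single CPU while leaving the planted effects comfortably resolvable;
every threshold that matters scientifically (FDR 0.05, MAF 0.05, age split
50, promoter ± 1 kb, capture ≥ 2 tissues) is independent of these sizes.

## Known limitations

- The "nearby" proximity rule is a single configurable window (default
  10 kb) applied uniformly; no decay or annotation-aware weighting.
- Backgrounds are matched on chromosome and length only (no GC or
  feature matching).
- The cross-disease score treats diseases as independent; genetic
  correlation between panels would inflate |z_cross| for null variants.
- No LD clumping: dense local signal can dominate a gene locus score.
- The consistency expression rule trades power for robustness and has no
  error-rate guarantee; it is deliberately descriptive.
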