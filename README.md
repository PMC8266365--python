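# epicontext

Tools for asking how a *shifting chromatin-accessibility context* — regions
that open or close as tissues mature from fetal to adult form, and again
between early and late adulthood — modulates evolutionary constraint and
disease-risk associations of the regulatory variants that sit inside or near
those regions.

The package is aimed at regulatory-genomics analysts who have (or want to
emulate) multi-tissue DNase-I/ATAC count matrices, GWAS summary statistics
for many diseases, conservation tracks and promoter-capture interactions,
and who want a tested, seedable pipeline from region calling through to
gene-locus prioritization. A built-in generator simulates every input with
planted ground truth, so each stage of the analysis can be validated against
a known answer before it touches real data.

## What it computes

**Stage-biased region calling.** Per-region accessibility counts are
normalized to log2 counts-per-million and fit with a shared linear design
(intercept + stage + tissue). Residual variances are shrunk towards an
empirical-Bayes prior estimated across regions,

    s̃ᵢ² = (d₀·s₀² + dᵢ·sᵢ²) / (d₀ + dᵢ),

and each region's stage coefficient is tested with a moderated t on
d₀ + dᵢ degrees of freedom (the prior (d₀, s₀²) is moment-matched to the
scaled-F distribution of the sample variances). Regions significant at
Benjamini–Hochberg FDR < 0.05 are partitioned into *adult-biased*
(more accessible in adults) and *fetal-biased* sets; the same engine run on
adult samples split at age 50 yields nested *old-* and *young-biased* sets,
and a chi-square test asks whether developmental and ageing shifts share
direction.

**Evolutionary characterization.** Per-region mean conservation from
bedGraph-style tracks, rank tests between region classes, per-bp overlap
enrichment of each set against features (conserved elements, accelerated
regions, chromatin states) using length- and chromosome-matched shuffled
backgrounds with add-one empirical p-values, and common-variant
(MAF ≥ 0.05) density comparisons.

**Cross-disease GWAS aggregation.** For each variant, two-sided per-disease
p-values are converted to unsigned normal deviates zᵢ = Φ⁻¹(1 − pᵢ/2) and
summed; the sum is standardized by the mean and sd of |N(0,1)| so the
global null gives z_cross ~ N(0, 1). Per-disease hypergeometric tests score
enrichment or depletion of strong variants near a region set.

**Gene-locus prioritization.** Each gene receives its best nearby SNP
p-value per disease (TSS ± window, extended by promoter-capture links),
genes are ranked within disease and aggregated by geometric-mean rank, and
candidate gene sets are tested against same-size random draws.

## Worked example

```bash
epicontext run --config configs/demo.yaml
```

simulates a study (two 500 kb chromosomes, 300 regions, 3 tissues × 2
stages × 4 replicates, planted |log2 FC| = 2 shifts, 4 000 variants,
50 diseases, 200 genes) and runs every stage. The report
(`epicontext_results/report.yaml`) from that run includes:

```yaml
diffacc:
  n_adult_biased: 45
  n_fetal_biased: 49
  recovery: {n_called: 94, sensitivity: 1.0, empirical_fdr: 0.043}
  nested:
    directionality_chi2: 15.11
    directionality_p: 0.000101
evo:
  conservation_fetal_vs_adult: {U: 2128.0, p: 8.6e-15, effect_size: 0.965}
gwas:
  group_means: {adult_biased: 1.60, fetal_biased: 0.34, unaltered: 0.51}
generank:
  core_gene_set: {observed_mean_aggregate: 34.6, null_mean: 87.3, empirical_p: 0.001}
```

Read: the moderated model recovered every planted stage-biased region with
an empirical FDR near the nominal 0.05; development and ageing shifts share
direction (chi-square p ≈ 1e-4); fetal-biased regions are more conserved
than adult-biased ones (rank-test p ≈ 1e-14); variants near adult-biased
regions carry more cross-disease signal than those near fetal-biased or
unaltered regions; and the planted core genes rank far better across
diseases than random gene sets (p = 0.001 at 999 permutations).

Each stage is also available as a library call (`epicontext.diffacc`,
`.evo`, `.gwas`, `.generank`, `.gene_links`, `.expression`) and as an
individual CLI subcommand.

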