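# Bundled demo: desk-scale study with planted ground truth.
# Run:  epicontext run --config configs/demo.yaml
seed: 42
outdir: epicontext_results
simulate:
  n_chrom: 2
  chrom_len: 500000
  n_regions: 300
  n_tissues: 3
  replicates_per_group: 4
  effect_logfc: 2.0
  n_variants: 4000
  n_diseases: 50
  n_genes: 200
n_perm_enrichment: 100
n_perm_generank: 999
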