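# Seeded end-to-end demonstration: a simulated multigenerational cohort
# (~2100 phenotyped individuals in 76 families) with one planted variant
# at 50 cM explaining 15% of the trait variance under a 0.29-heritability
# polygenic background.
simulate:
  n_families: 76
  n_variants: 300
  map_length_cM: 100.0
  chrom: "15"
  h2: 0.29
  qtl:
    - cM: 50.0
      var_frac: 0.15
  seed: 11
seed: 11
grid_step_cM: 2.0
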