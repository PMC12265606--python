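# pedlod

Variance-components linkage scanning and conditional-LOD fine-mapping for
quantitative traits in extended pedigrees.

`pedlod` is for statistical geneticists working with family cohorts — the
setting where a trait such as Trail Making Test part B (a timed
executive-function score, in seconds) is measured across multigenerational
pedigrees and the question is *which genomic region, and then which
sequenced variants, drive the familial signal*.  It provides, as one
tested pipeline:

* **Polygenic and linkage models.**  Within each family
  `y ~ N(Xb, s2_q*Pi_c + s2_a*2Phi + s2_e*I)`, with `Phi` the pedigree
  kinship and `Pi_c` the expected IBD-sharing matrix at map position `c`.
  `LOD(c) = [loglik(full) - loglik(null)]/ln 10`, maximum likelihood with
  profiled fixed effects; heritability `h2 = s2_a/(s2_a+s2_q+s2_e)` from
  the polygenic null.
* **Multipoint IBD.**  An exact inheritance-vector hidden Markov model
  (Lander–Green) with Haldane transitions for small pedigrees, plus exact
  truth-IBD from the bundled gene-dropping simulator for any size, and
  0.5 cM marker thinning by founder heterozygosity.
* **Fine-mapping logic.**  Pedigree-specific LODs (additive contributions
  at the global optimum) define *linked* (LOD > 0.1) and *top-linked*
  (ranked LODs summing to ≥ 6) family sets; kinship-adjusted mixed-model
  association under the 1-LOD support interval; per-variant conditional
  LOD drops; nomination by the three-part rule (P < 1e-4 in ≥ 1 set,
  P < 0.05 in both, drop > 0.5 in both); stepwise joint selection
  (enter P < 0.1, stay P < 0.05) and joint conditional LOD with percent
  of peak explained.
* **A gene-dropping simulator** producing pedigrees, phased-descent
  genotypes, genetic maps, covariates and a trait with configurable
  heritability (default 0.29) and planted QTL variants — with full
  inheritance-label ground truth for testing.

File formats are the field's: PED/FAM, VCF (via cyvcf2), genetic-map TSV,
phenotype TSV; results are TSV + JSON.  See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

`examples/demo.yaml` simulates a 76-family, ~2100-person cohort with one
planted variant at 50 cM explaining 15% of the trait variance on a
0.29-heritability polygenic background, then runs the full analysis:

```bash
pedlod run --config examples/demo.yaml --out demo_out
pedlod report demo_out/report.json
```

which prints:

```
status:        ok
heritability:  0.4169
peak LOD:      3.8299 at 46.00 cM (chr 15)
families:      28 linked, 20 top-linked
nominated:     15:49966964
stepwise linked: ['15:49966964'] LOD 9.90 -> 1.71 (82.7% explained)
stepwise top_linked: ['15:49966964'] LOD 8.12 -> 0.38 (95.3% explained)
```

Reading this: the genome scan found a significant peak (LOD 3.83 ≥ 3)
within 4 cM of the planted variant; 28 families carry the signal
(pedigree LOD > 0.1), and among them the linkage peak rises to LOD 9.90.
The nomination filter recovered exactly the planted variant
(`15:49966964`), stepwise selection kept it, and conditioning on it
collapses the peak (LOD 9.90 → 1.71 in linked families, 8.12 → 0.38 in
top-linked — the peak "disappears"), explaining 83% and 95% of the
respective peaks.  The null-model heritability (0.42) exceeds the
simulated 0.29 because the unmodelled QTL variance is absorbed by the
polygenic component, as expected.

The same stages are available as library calls (`pedlod.vclinkage`,
`pedlod.relatedness`, `pedlod.mixed_assoc`, `pedlod.finemap`) and as
subcommands (`simulate`, `kinship`, `ibd`, `linkage`, `assoc`, `finemap`,
`run`, `report`).

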