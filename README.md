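# twasmr

Kinship-adjusted transcriptome-wide association, bidirectional
cross-cohort replication, and Mendelian randomization for quantitative
immune traits — built around the question of which whole-blood
transcripts are associated with circulating IgE concentration, and which
of those associations are plausibly *causal*.

The package is aimed at statistical geneticists who want to run (or
stress-test) this inference chain end to end. Because individual-level
IgE/expression/genotype data from family cohorts are access-restricted,
`twasmr` ships a first-class synthetic-cohort generator with known causal
structure, so every stage can be exercised against ground truth at desk
scale.

## The inference chain

1. **Discovery TWAS.** For each gene *g*, a linear mixed model

   expr_g = β₀ + β₁·log₁₀(IgE) + γ·covariates + u + ε,
   u ~ N(0, σ²_g K), ε ~ N(0, σ²_e I)

   where K is the pedigree kinship matrix (unit diagonal, 0.5 for full
   sibs). REML is profiled over the variance ratio δ = σ²_g/σ²_e after a
   one-time spectral decomposition of K; the Wald test on β₁ gives the
   per-gene p, and Benjamini–Hochberg FDR controls multiplicity across
   the transcriptome.

2. **Replication + meta-analysis.** Unrelated replication cohorts are
   analysed with ordinary per-gene linear models (adjusting for age,
   sex, and expression principal components), then combined by the
   weighted inverse-normal (Stouffer-type) method:
   z_s = sign(β_s)·Φ⁻¹(1 − p_s/2), w_s ∝ √n_s,
   z_meta = Σ w_s z_s with Σ w_s² = 1.
   A discovery-significant gene *replicates* when its meta p falls below
   α/m, m being the discovery-significant genes actually testable in
   replication; running the protocol in both directions and intersecting
   gives the bidirectionally replicated set.

3. **Bidirectional one-sample MR (2SLS).** Forward: the gene's top
   cis-eQTL instruments its expression against the trait. Reverse: a
   six-locus genetic risk score (FCER1A, STAT6, IL13 and HLA-region
   variants) instruments the trait against expression. Instruments with
   first-stage F = (n−2)R²/(1−R²) < 10 are excluded as weak. A gene is
   *putatively causal* when p(mRNA→trait) < 0.05 and p(trait→mRNA) ≥ 0.05.

4. **Two-sample MR** against disease GWAS summary statistics, with
   allele harmonization, the Wald ratio β_gy/β_gx for single-SNP genes
   and fixed-effect inverse-variance weighting for multi-SNP genes.

5. **Over-representation analysis** of the replicated gene set against
   GMT gene sets via the upper-tail hypergeometric test with BH FDR.

## Worked example

Simulate a family-structured discovery cohort (n = 2000, 200 genes, 10
forward-causal with θ = 0.5) plus two unrelated replication cohorts
(n = 610 and 326), and run every stage:

```python
import twasmr as t

cfg = t.PipelineConfig(seed=7, out_dir="demo", n_discovery=2000,
                       n_replication=(610, 326), n_genes=200,
                       n_causal=10, scenario="forward", theta=0.5)
run_dir = t.run_pipeline(cfg)
```

The manifest's row counts for this run:

```
"bidirectional": 10, "replicated_forward": 10, "replicated_reverse": 10,
"mr_tested": 200, "putative_causal": 20, "twas_discovery": 200
```

All 10 truly causal genes replicate bidirectionally and appear in the
putatively causal set with 2SLS estimates near the simulated θ = 0.5
(e.g. `gene00000`: β = 0.455 ± 0.076, p = 2.5×10⁻⁹ forward, p = 0.30
reverse). The other 10 putative-causal calls are the expected nominal
false positives: at α = 0.05 the null rate of the classification rule is
α(1−α) ≈ 0.0475, and 190 null genes were tested. The enrichment stage
ranks the synthetic causal-enriched gene set first
(p = 1.3×10⁻¹³, q = 1.3×10⁻¹²).

The same stages are available as a CLI for user-supplied TSV/VCF inputs:

```sh
twasmr simulate --config sim.yaml --out-dir cohort --seed 3
twasmr twas --expression cohort/expression.tsv \
            --phenotype cohort/phenotype.tsv \
            --kinship cohort/kinship.tsv --out twas.tsv
twasmr meta --studies cohort_a.tsv --studies cohort_b.tsv --out meta.tsv
twasmr replicate --discovery twas.tsv --meta meta.tsv --out replicated.tsv
twasmr mr-2sample --exposure eqtl.tsv --outcome asthma_gwas.tsv --out mr.tsv
```

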