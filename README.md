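# twinase

Bayes-factor screening of phenotype-associated **allele-specific
expression (ASE)** in discordant monozygotic twins, with the downstream
genotype-dependent co-expression screen — as a tested, reusable Python
library with a thin CLI.

## The problem

Monozygotic co-twins are genetically identical, so when exactly one twin
of a pair is affected by a psychiatric phenotype, a *within-pair* shift in
the allelic balance of a heterozygous lncRNA SNP is a genotype-free signal
linking that locus to the phenotype. For twin pair `i` and disease status
`s` (affected = 1), the proportion `p_is` of reads supporting the
alternative allele is modelled on the logit scale and two models are
compared:

```
M1: logit(p_is) = β0 + βs·s + γi        (phenotype fixed effect)
M0: logit(p_is) = β0 + γi               (no phenotype term)
γi ~ Normal(0, σγ²),   alt_is ~ Binomial(n_is, p_is)
```

(or beta-binomial with intra-class correlation ρ for overdispersed
counts). The evidence per SNP-transcript pair is the Bayes factor
`BF = m1/m0` of *fully marginalized* likelihoods — fixed effects, random
intercepts and σγ all integrated under explicit weakly-informative priors
(Normal(0, 3²) on fixed effects, half-Normal(1) on σγ). `BF > 5` calls a
hit. Marginals are computed by per-pair adaptive Gauss–Hermite quadrature
nested inside an exact grid over log σγ, validated against a brute-force
tensor-grid oracle and an importance-sampling oracle (agreement < 0.01
nats on small instances). See `docs/methods.md` for the full account.

Around the model sits the screening cascade: SNP-to-transcript exon
pairing, the heterozygous-in-≥1-pair filter, the
discordant-homozygote exclusion, per-individual signed allelic imbalance
(AAF = (alt−ref)/(alt+ref)), and three-level SNP/transcript/gene hit
tallies. A separate module implements the population-panel screen for
genes whose regression slope on a focal lncRNA is amplified in carriers
of a regulatory allele (|r_het| > 0.5, BH-FDR < 0.05, |β_het| ≥ 2|β_wt|,
|r_wt| ≤ 0.5), plus the pooled positive-correlation screen and
hypergeometric set-overlap enrichment.

A first-class synthetic-data module generates twin cohorts and expression
panels with exactly the statistical structure the models assume, with
recorded truth labels — every downstream stage is testable without any
external download.

## Worked example

```python
from twinase import CohortConfig, simulate_cohort, run_ase_screen, summarize_hits

cohort = simulate_cohort(CohortConfig(
    n_pairs=9, n_snps=80, frac_true_discordant=0.05, betas_true=2.0,
    depth_mean=500, het_rate=0.6, discordant_hom_rate=0.1, seed=7))
result = run_ase_screen(cohort, bf_threshold=5.0)
print(summarize_hits(result))
```

prints (abridged):

```
screening funnel:
  n_pairs_annotated               80
  n_pairs_het_informative         80
  n_pairs_after_discordant_hom    76
  n_hits                          4
hits: 4 SNPs in 4 transcripts (4 genes)
injected SNPs recovered: 4/4; false hits: 0
```

80 simulated SNP-transcript pairs enter; 4 are dropped by the
discordant-homozygote genotype filter; the Bayes factor calls exactly the
4 SNPs that were simulated with a true phenotype-linked allelic switch
(βs = 2, i.e. the affected co-twin's alternative-allele fraction moves
from ~0.5 to ~0.88) and no null SNP. Each script in `examples/` walks one
capability the same way: cohort simulation, a single Bayes factor against
its oracle, the full cascade, the co-expression screen, and the
end-to-end pipeline.

The same stages are scriptable from a shell:

```sh
twinase run --demo --out demo_out/          # full pipeline, bundled config
twinase simulate --config cfg.yaml --out sim/
twinase ase-screen --counts sim/counts.tsv --genotypes sim/genotypes.vcf \
    --variants sim/variants.tsv --annotation sim/annotation.tsv --out screen/
twinase coexpr-screen --expr expr.tsv --genotypes groups.tsv --out co/
```

All interchange is TSV (genotypes alternatively VCF 4.2); every run
writes a resolved-config snapshot that reproduces it exactly.

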