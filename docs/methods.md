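# Methods

## The screening problem

Monozygotic (MZ) co-twins share a genome, so when exactly one twin of a
pair is affected by a psychiatric phenotype, any *within-pair* difference
in allele-specific expression (ASE) at a shared heterozygous SNP cannot be
explained by genotype. `twinase` implements the statistical core of such a
screen for lncRNA loci: genotype-based filtering of candidate
SNP-transcript pairs, a Bayesian mixed-model comparison producing a Bayes
factor per pair, and the downstream population-panel screen for genes
whose co-expression with a focal lncRNA depends on a regulatory genotype.

## Models

For one SNP-transcript pair, let `alt_is` out of `n_is` reads support the
alternative allele in twin pair `i`, member with disease status
`s ∈ {0 = unaffected, 1 = affected}`. With `p_is` the alternative-allele
read proportion,

```
M1:  logit(p_is) = beta0 + beta_s * s + gamma_i
M0:  logit(p_is) = beta0 + gamma_i
gamma_i ~ Normal(0, sigma_gamma^2)
alt_is ~ Binomial(n_is, p_is)            (rho = 0)
alt_is ~ BetaBinomial(n_is, p_is, rho)   (rho > 0)
```

`beta0` is the SNP's baseline allelic bias (mapping bias, cis-regulatory
imbalance shared by both members), `gamma_i` absorbs pair-level shifts,
and `beta_s` is the phenotype-linked allelic switch of interest. The
beta-binomial option uses the (p, rho) parameterization with shapes
`alpha = p(1-rho)/rho`, `beta = (1-p)(1-rho)/rho`, so `rho` is the
intra-class correlation, count variance inflates by `1 + (n-1) rho`, and
`rho -> 0` recovers the binomial.

Evidence is the Bayes factor `BF = m1/m0` of fully marginalized
likelihoods: fixed effects, all `gamma_i`, and `sigma_gamma` integrated
out. `BF > 5` is the stringent call threshold (`BF > 3` already favours
M1). Because marginal likelihoods depend on priors, the priors are
explicit and configurable rather than inherited from any tool's defaults:
`Normal(0, 3^2)` on each fixed effect and half-`Normal(1)` on
`sigma_gamma`. On the logit scale ±3 covers essentially all plausible
allelic imbalances, and `sigma_gamma ~ 1` allows pair effects of the same
order as real biological imbalance without swamping it.

## Computing the marginal likelihood

Three routes, in increasing independence:

1. **`laplace_aghq` (default).** Conditional on the fixed effects and
   `tau = log sigma_gamma`, the `gamma_i` integrals factorize per pair and
   are computed by 15-node adaptive Gauss-Hermite quadrature around each
   conditional mode (a damped Newton step with analytic derivatives for
   the binomial case). The remaining 2-3 dimensional integral over
   `(beta, tau)` is *not* Gaussian enough for a single Laplace step: the
   `tau` marginal carries an exponential lower tail (prior Jacobian
   against a plateauing likelihood), and the conditional spread of the
   fixed effects is likelihood-limited at small `sigma_gamma` but
   prior-limited at large. It is therefore integrated INLA-style: an
   exact trapezoid grid over `tau` (25 points spanning at least ±4 around
   the mode, clipped to `sigma_gamma ∈ [e^-9, e^2.5]`, plus an analytic
   `e^tau` correction for the truncated lower tail), with per-grid-point
   adaptive Gauss-Hermite (7 nodes/dim) over the conditional fixed-effect
   block, recentred and rescaled by a short batched Newton pass at each
   `tau`. All grid points are evaluated in one vectorized batch.
2. **`laplace`.** Same nesting with the cruder classical rules: one-term
   Laplace for each `gamma_i` integral and a Gaussian approximation of the
   `(beta, tau)` block. It under-estimates absolute marginals by up to
   ~0.5 nats on unfavourable instances, but the error is shared by M1 and
   M0 and cancels almost exactly in the Bayes factor. A `bic` (Schwarz)
   mode exists for comparison only.
3. **`brute_force_log_marginal`** — the validation oracle. For instances
   with at most 3 pairs it integrates likelihood x priors on a dense
   tensor grid with log-sum-exp accumulation: fixed effects on a ±12 grid
   whose spacing is an exact multiple of the gamma-grid spacing (so
   `beta0 + gamma` lands on a shared lattice and the per-record likelihood
   is evaluated once and gathered by stride tricks), `sigma_gamma` by
   trapezoid with a scaled Gauss-Hermite rule below 0.05 where the gamma
   grid would under-resolve the Normal kernel. A second, fully
   independent oracle (`importance_sample_log_marginal`) recomputes the
   same integral by importance sampling from an inflated Gaussian
   proposal.

Worst observed |AGHQ - oracle| over randomized small instances is below
0.01 nats; the acceptance suite enforces 0.1.

Two structural facts drove this design. A *joint* Laplace approximation
over `(beta, gamma, sigma_gamma)` — the textbook formula — is unavailable
here: the joint posterior density is unbounded as `sigma_gamma -> 0` with
all `gamma_i = 0`, so there is no usable joint mode. `fit_mode` (used for
effect-size recovery) therefore bounds `sigma_gamma >= 1e-3` and reports
convergence by the projected gradient norm (tolerance 1e-6). Second,
allele relabelling (alt <-> ref on every record) provably leaves the
marginal likelihood unchanged under these symmetric priors; the
implementation canonicalizes record orientation before integrating so the
invariance holds *exactly* in floating point, not merely to optimizer
tolerance.

When `rho_mode="profile"`, `rho` is chosen on a small grid
(0, 0.005, 0.02, 0.05, 0.1, 0.2) by the M0 marginal likelihood and then
held fixed for both models, so the BF compares like with like.

## The screening cascade

1. **Annotation pairing** — a SNP is paired with every transcript having
   an exon containing it. Input coordinates are 1-based inclusive
   (GTF-like); interval arithmetic is 0-based half-open internally.
2. **Het-informative filter** — keep SNPs heterozygous in >= 1 twin pair;
   missing genotypes count as non-het and are never imputed.
3. **Discordant-homozygote exclusion** — drop SNPs where one pair is
   hom-ref and another hom-alt. The two filters are logically independent
   and commute (property-tested).
4. **BF calls** per surviving pair, using only het-pair count records
   (homozygotes carry no allelic signal; ignored records are tallied).
5. **Summaries** — per-individual AAF = `(alt - ref)/(alt + ref)` from
   that individual's summed counts (positive = alternative-haplotype
   dominance; the formula is this package's choice, only the sign
   semantics being fixed by convention), stage retention counts, and
   distinct SNP/transcript/gene tallies among hits.

## Co-expression screen

Samples split at a focal regulatory SNP into WT (hom-ref) and Heter
groups (hom-alt carriers are outside the two-group design). Per gene and
group: Pearson r with its two-sided t-test p-value, and the OLS slope of
gene expression on the focal lncRNA. A gene passes iff `|r_het| > 0.5`,
Benjamini-Hochberg q of the Heter p-value `< 0.05`,
`|beta_het| >= 2 |beta_wt|`, and `|r_wt| <= 0.5`; `fail_reason` records
the first violated rule in that order. Two open choices were resolved as:
slopes compared on absolute value (a sign flip with doubled magnitude
still indicates genotype dependence), and the FDR family is the
Heter-group p-values only — both configurable. Genes constant in either
group are excluded explicitly (`fail_reason="constant"`) and sit outside
the FDR family. The pooled positive-correlation screen keeps genes with
signed `r > 0.3` and `p < 1e-5`. Set-overlap enrichment uses the
one-sided Fisher/hypergeometric upper tail with a Haldane 0.5 correction
of the odds ratio only when a cell is zero.

## Synthetic data: what it emulates and what it does not

The cohort generator forward-simulates exactly the model above: 9 twin
pairs by default, per-SNP `beta0 ~ Normal(0, 0.5^2)`, per-(SNP, pair)
`gamma ~ Normal(0, 0.3^2)`, an exact `round(frac * n_snps)`-sized
discordant truth set carrying `beta_s = 2`, truncated-Poisson depth
(zero-depth observations are invisible in haplotype-TPM space; the
paper-scale bridge `tpm_to_effective_counts` rounds TPM pairs half-to-even
into counts), and counts emitted only for heterozygous pairs. Genotypes
are het with probability `het_rate`, otherwise hom-ref, with a configured
fraction of null SNPs forced into the excluded hom-ref-vs-hom-alt
pattern. Two deliberate couplings keep truth labels meaningful:
truth-discordant SNPs always have >= 1 het pair and never receive the
forced discordant-homozygote pattern — an observable ASE SNP is het by
construction, and without this the end-to-end recovery rate would measure
genotype lotteries rather than the method. Randomness is counter-style
(one SeedSequence stream per (SNP, pair)), so identical configs are
byte-identical and growing the cohort never perturbs earlier draws.

Not emulated: read-level artifacts (mapping bias, FASTQ simulation),
phasing errors, haplotype-quantification (EM) uncertainty, correlated
depths within a sample, linkage between SNPs, and real genotype-frequency
structure. Passing tests therefore demonstrate correctness of the
statistics under the stated generative model, not robustness to upstream
alignment or phasing artifacts.

The expression-panel generator draws WT/Heter labels with the conditional
Hardy-Weinberg het probability given not-hom-alt at minor-allele
frequency 0.25, unit-variance lncRNA expression, and per-gene slopes
`0.3` (WT) vs `0.9` (Heter truth genes) against unit noise. Those values
put the population `r_wt ~ 0.29` and `r_het ~ 0.67` on either side of the
screen's 0.5 rules — i.e. the generated panel is one in which the rule
set is satisfiable, which is what makes recall/FDP against truth labels
interpretable.

## Numerical choices and degenerate inputs

* Optimizer starts: empirical pooled logit for `beta0`, zero for
  `beta_s`, two `sigma_gamma` scales (0.3, 1.0) to sidestep ridges; M1 is
  warm-started from the M0 solution inside `bayes_factor`.
* Zero-depth records are dropped with a warning when siblings exist,
  errors otherwise; all-identical counts, empty cohorts, and genotype
  tables disagreeing between co-twins raise immediately.
* Non-converged fits are flagged (`converged=False`), excluded from
  calls, and counted in screen summaries — never silently numeric.
* BF overflow (`log BF` in the hundreds) reports `bf = inf` with the
  finite `log_bf` retained via the stored marginals.
* Multi-allelic VCF records are skipped with a logged warning; malformed
  VCF/TSV lines raise with their line numbers.

## Problem sizes used in validation

The acceptance script and test suite run the full machinery at sizes
chosen to exercise every property at comfortable statistical resolution:
25 randomized oracle-equivalence instances (<= 3 pairs, depth <= 50), a
1,000-SNP null calibration and 200-SNP-per-point power curve in the test
suite (400 and 100-150 in the faster script variant), 200 recovery fits
at depth 1,000, 50 symmetry instances, the 200-gene default panel, and
the bundled 500-SNP demo run twice for determinism. These are the
package's validation conditions; larger cohorts run the same code paths
unchanged.

## Known limitations

* The BF is prior-dependent by nature; results are comparable only under
  a fixed `PriorSpec`. No attempt is made to mimic any external tool's
  default priors.
* The brute-force oracle refuses > 3 pairs (> 6 integration dimensions);
  validation of the fast path at 9 pairs is indirect (simulation-based
  calibration and power).
* `rho` profiling is a coarse grid, adequate for accommodating
  overdispersion but not for estimating it.
* The screen treats SNPs independently; no linkage-aware multiplicity
  control is attempted beyond the BF threshold itself.
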