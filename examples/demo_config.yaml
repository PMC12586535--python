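# Bundled demo configuration (same as `twinase run --demo`):
# 9 discordant MZ twin pairs, 500 SNPs with 20 injected
# discordant-ASE SNPs at betas=2, Poisson depth 500.
bf_threshold: 5.0
cohort:
  beta0_sd: 0.3
  betas_true: 2.0
  depth_mean: 500.0
  depth_model: poisson
  discordant_hom_rate: 0.05
  frac_true_discordant: 0.04
  het_rate: 0.6
  n_pairs: 9
  n_snps: 500
  rho: 0.0
  sigma_gamma: 0.3
panel:
  beta_het_multiplier: 3.0
  beta_wt: 0.3
  frac_genotype_dependent: 0.1
  maf: 0.25
  n_genes: 200
  n_samples: 200
  noise_sd: 1.0
priors:
  beta_sd: 3.0
  sigma_gamma_prior: 1.0
seed: 20230901
thresholds: {}
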