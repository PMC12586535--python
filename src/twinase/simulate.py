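"""Synthetic twin cohorts and expression panels.

The cohort generator forward-simulates the exact data-generating process the
Bayes-factor models assume: nine discordant monozygotic twin pairs (one
affected, one unaffected co-twin each), per-SNP baseline allelic bias beta0,
a per-(SNP, pair) random intercept gamma_i, and — for a minority of
"truth-discordant" SNPs — a phenotype effect beta_s carried only by the
affected member:

    alt_count ~ Binomial(depth, logistic(beta0 + beta_s*s + gamma_i))

(or BetaBinomial with intra-class correlation rho when rho > 0). Counts are
emitted only for heterozygous pairs: homozygous loci carry no allelic
signal, which is also why the screen's first filter keeps SNPs heterozygous
in at least one pair.

Randomness is counter-style: each (snp, pair) draw owns its own
SeedSequence-derived stream, so enlarging the cohort never perturbs the
draws of earlier SNPs and identical configs are byte-identical.

The expression-panel generator emulates the population datasets used for
the genotype-dependent co-expression screen: samples split into wild-type
(WT, homozygous reference) and heterozygous (Heter) groups at a focal
regulatory SNP, with a subset of genes whose regression slope on the focal
lncRNA is amplified in the Heter group.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import AllelicCountRecord, GenotypeTable

# stream tags keeping the per-purpose RNGs disjoint
_STREAM_TRUTH = 0
_STREAM_SNP = 1
_STREAM_PAIR = 2
_STREAM_PANEL = 3


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic discordant-twin cohort.

    Defaults reproduce the study geometry: 9 twin pairs, a minority of
    discordant-ASE SNPs with a logit-scale phenotype effect of 2, modest
    baseline allelic bias and between-pair spread, and Poisson read depth
    around 200 per observation.
    """

    n_pairs: int = 9
    n_snps: int = 200
    n_transcripts: Optional[int] = None  # default: one transcript per SNP
    frac_true_discordant: float = 0.04
    beta0_sd: float = 0.5
    betas_true: float = 2.0
    sigma_gamma: float = 0.3
    rho: float = 0.0
    depth_mean: float = 200.0
    depth_model: str = "poisson"  # fixed | poisson | negative_binomial
    het_rate: float = 0.5
    discordant_hom_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_snps < 1:
            raise ValueError("n_pairs and n_snps must be positive")
        if self.n_transcripts is not None and self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        for name in ("frac_true_discordant", "het_rate", "discordant_hom_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.beta0_sd < 0 or self.sigma_gamma < 0:
            raise ValueError("beta0_sd and sigma_gamma must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_model not in ("fixed", "poisson", "negative_binomial"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")


@dataclass
class Cohort:
    """A simulated twin cohort: genotypes, allelic counts, truth labels.

    ``truth`` has one row per SNP-transcript pair (label, beta0, betas);
    ``truth_gamma`` the per-(SNP, pair) random intercepts of het pairs.
    ``variants`` and ``annotation`` give each SNP a genomic position inside
    an exon of its transcript so the screening cascade can be exercised
    end to end.
    """

    config: CohortConfig
    genotypes: GenotypeTable
    counts: list  # list[AllelicCountRecord]
    truth: pd.DataFrame
    truth_gamma: pd.DataFrame
    variants: pd.DataFrame
    annotation: pd.DataFrame

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.snp_id, r.transcript_id, r.pair_id, r.member, r.alt_count, r.ref_count)
                for r in self.counts
            ],
            columns=["snp_id", "transcript_id", "pair_id", "member", "alt_count", "ref_count"],
        )

    def discordant_snps(self) -> set:
        return set(self.truth.loc[self.truth["label"] == "discordant", "snp_id"])


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _draw_depth(rng: np.random.Generator, cfg: CohortConfig) -> int:
    """One total read depth, truncated at >= 1 (zero-depth observations are
    invisible in haplotype-TPM space and carry no allelic information)."""
    if cfg.depth_model == "fixed":
        return max(1, int(round(cfg.depth_mean)))
    for _ in range(1000):
        if cfg.depth_model == "poisson":
            n = int(rng.poisson(cfg.depth_mean))
        else:  # negative binomial, shape 5 => variance mu + mu^2/5
            size = 5.0
            n = int(rng.negative_binomial(size, size / (size + cfg.depth_mean)))
        if n >= 1:
            return n
    return 1


def _draw_beta_binomial(
    rng: np.random.Generator, n: int, p: float, rho: float
) -> int:
    """Beta-binomial via its beta-mixture representation;
    alpha = p(1-rho)/rho, beta = (1-p)(1-rho)/rho, so that the intra-class
    correlation is rho and the rho -> 0 limit is binomial."""
    if rho == 0.0:
        return int(rng.binomial(n, p))
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return int(rng.binomial(n, rng.beta(a, b)))


def _snp_ids(n: int) -> list:
    return [f"snp{j:05d}" for j in range(n)]


def _layout(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Deterministic genomic layout: transcript t (two exons) on chr1 at
    base 20000*t; SNP j sits in an exon of transcript j % T. Two
    transcripts share one gene, giving the three-level SNP/transcript/gene
    tallies something to count."""
    n_tx = cfg.n_transcripts or cfg.n_snps
    per_tx = -(-cfg.n_snps // n_tx)  # ceil
    if per_tx > 150:
        raise ValueError(
            f"layout supports at most 150 SNPs per transcript "
            f"({cfg.n_snps} SNPs on {n_tx} transcripts requested)"
        )
    ann_rows = []
    for t in range(n_tx):
        base = 20000 * t
        tx, gene = f"tx{t:05d}", f"gene{t // 2:05d}"
        ann_rows.append((tx, gene, "chr1", base + 1, base + 800))
        ann_rows.append((tx, gene, "chr1", base + 1201, base + 1600))
    annotation = pd.DataFrame(
        ann_rows, columns=["transcript_id", "gene_id", "chrom", "start", "end"]
    )
    var_rows = []
    snp_tx = {}
    bases = np.array(list("ACGT"))
    for j, snp in enumerate(_snp_ids(cfg.n_snps)):
        t = j % n_tx
        k = j // n_tx
        base = 20000 * t
        pos = base + 1 + 5 * k if k < 100 else base + 1201 + 5 * (k - 100)
        rng = _rng(cfg.seed, _STREAM_SNP, j, 999)
        ref, alt = rng.choice(bases, size=2, replace=False)
        tx = f"tx{t:05d}"
        snp_tx[snp] = (tx, f"gene{t // 2:05d}")
        var_rows.append((snp, "chr1", int(pos), str(ref), str(alt)))
    variants = pd.DataFrame(
        var_rows, columns=["snp_id", "chrom", "pos", "ref_allele", "alt_allele"]
    )
    return variants, annotation, snp_tx


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Forward-simulate a discordant-MZ-twin cohort under the logit mixed model.

    Per SNP: beta0 ~ Normal(0, beta0_sd^2); a fixed fraction of SNPs
    (exactly ``round(frac_true_discordant * n_snps)``) are labelled
    discordant and carry betas_true in their affected members. Per
    heterozygous (SNP, pair): gamma ~ Normal(0, sigma_gamma^2); each
    co-twin contributes one count record at the drawn depth. Truth labels
    and latent parameters are recorded for power/FDR evaluation.

    Truth-discordant SNPs are guaranteed at least one heterozygous pair
    and never receive the discordant-homozygote genotype pattern (an
    observable ASE SNP is het by construction; the forced pattern is
    reserved for null SNPs so the genotype filters can be exercised
    without silently deleting injected positives).
    """
    cfg = config
    pair_ids = [f"pair{i:02d}" for i in range(cfg.n_pairs)]
    snp_ids = _snp_ids(cfg.n_snps)
    variants, annotation, snp_tx = _layout(cfg)

    n_disc = int(round(cfg.frac_true_discordant * cfg.n_snps))
    truth_rng = _rng(cfg.seed, _STREAM_TRUTH)
    disc_idx = set(
        truth_rng.choice(cfg.n_snps, size=n_disc, replace=False).tolist()
    )

    genotypes = GenotypeTable()
    counts: list[AllelicCountRecord] = []
    truth_rows = []
    gamma_rows = []
    any_het = False

    for j, snp in enumerate(snp_ids):
        srng = _rng(cfg.seed, _STREAM_SNP, j)
        is_disc = j in disc_idx
        beta0 = float(srng.normal(0.0, cfg.beta0_sd)) if cfg.beta0_sd > 0 else 0.0
        betas = cfg.betas_true if is_disc else 0.0

        # genotype vector: het with prob het_rate, otherwise hom_ref;
        # null SNPs may instead be forced into the excluded
        # hom_ref-vs-hom_alt pattern with prob discordant_hom_rate
        force_disc_hom = (
            (not is_disc)
            and cfg.n_pairs >= 2
            and srng.random() < cfg.discordant_hom_rate
        )
        for _ in range(200):
            het = srng.random(cfg.n_pairs) < cfg.het_rate
            if not is_disc or het.any():
                break
        else:
            het[0] = True  # degenerate het_rate: force observability
        geno = np.where(het, "het", "hom_ref").astype(object)
        if force_disc_hom:
            non_het = np.flatnonzero(~het)
            if non_het.size >= 2:
                a, b = srng.choice(non_het, size=2, replace=False)
            else:
                a, b = srng.choice(cfg.n_pairs, size=2, replace=False)
            geno[a], geno[b] = "hom_ref", "hom_alt"
            het = np.array([g == "het" for g in geno])
        for i, pair in enumerate(pair_ids):
            genotypes.set(snp, pair, str(geno[i]))

        tx, _gene = snp_tx[snp]
        truth_rows.append(
            (snp, tx, "discordant" if is_disc else "null", beta0, betas)
        )
        for i, pair in enumerate(pair_ids):
            if not het[i]:
                continue
            any_het = True
            prng = _rng(cfg.seed, _STREAM_PAIR, j, i)
            gamma = (
                float(prng.normal(0.0, cfg.sigma_gamma)) if cfg.sigma_gamma > 0 else 0.0
            )
            gamma_rows.append((snp, tx, pair, gamma))
            for member, s in (("affected", 1.0), ("unaffected", 0.0)):
                depth = _draw_depth(prng, cfg)
                p = float(expit(beta0 + betas * s + gamma))
                alt = _draw_beta_binomial(prng, depth, p, cfg.rho)
                counts.append(
                    AllelicCountRecord(pair, member, snp, tx, alt, depth - alt)
                )

    if not any_het:
        raise ValueError(
            "uninformative cohort: no SNP has a heterozygous twin pair "
            "(increase het_rate or n_snps)"
        )

    truth = pd.DataFrame(
        truth_rows, columns=["snp_id", "transcript_id", "label", "beta0", "betas"]
    )
    truth_gamma = pd.DataFrame(
        gamma_rows, columns=["snp_id", "transcript_id", "pair_id", "gamma"]
    )
    return Cohort(
        config=cfg,
        genotypes=genotypes,
        counts=counts,
        truth=truth,
        truth_gamma=truth_gamma,
        variants=variants,
        annotation=annotation,
    )


# --------------------------------------------------------------------------
# expression panels for the co-expression screen


@dataclass(frozen=True)
class CoexprPanelConfig:
    """Generative parameters of a samples x genes co-expression panel.

    The defaults describe the emulated population panel: 200 samples split
    WT / Heter by a focal SNP of minor-allele frequency 0.25, 200 genes of
    which 10% are genotype-dependent with a 3-fold slope amplification in
    the Heter group. beta_wt = 0.3 against unit noise keeps the WT
    correlation near 0.29 — inside the screen's |r_wt| <= 0.5 exclusion
    rule — while the Heter slope 0.9 gives r ~ 0.67.
    """

    n_samples: int = 200
    maf: float = 0.25
    n_genes: int = 200
    frac_genotype_dependent: float = 0.1
    beta_wt: float = 0.3
    beta_het_multiplier: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0.0 <= self.frac_genotype_dependent <= 1.0):
            raise ValueError("frac_genotype_dependent must be in [0, 1]")
        if self.beta_het_multiplier < 0:
            raise ValueError("beta_het_multiplier must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class ExpressionPanel:
    """Samples x genes expression with a focal-lncRNA vector and WT/Heter
    genotype grouping; truth labels mark genotype-dependent genes."""

    sample_ids: list
    genotype_group: pd.Series  # "WT" | "Heter" per sample
    lnc_expr: pd.Series
    gene_expr: pd.DataFrame  # samples x genes
    truth_genes: set = field(default_factory=set)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.genotype_group == group).to_numpy()


def simulate_expression_panel(config: CoexprPanelConfig) -> ExpressionPanel:
    """Simulate the two-group panel of the genotype-dependent screen.

    Genotypes are drawn per sample as Heter with the conditional
    Hardy-Weinberg probability 2q(1-q) / ((1-q)^2 + 2q(1-q)) given the
    sample is not homozygous-alternative (the screen's two-group design
    drops hom-alt carriers). Each gene g is
    intercept + slope_g(group) * lncRNA + Normal(0, noise_sd), with
    slope_g = beta_wt in WT and beta_wt * beta_het_multiplier in Heter for
    the genotype-dependent truth genes, equal slopes otherwise.
    """
    cfg = config
    rng = _rng(cfg.seed, _STREAM_PANEL)
    q = cfg.maf
    p_het = 2 * q * (1 - q) / ((1 - q) ** 2 + 2 * q * (1 - q))
    groups = np.where(rng.random(cfg.n_samples) < p_het, "Heter", "WT")
    if (groups == "WT").sum() == 0 or (groups == "Heter").sum() == 0:
        raise ValueError(
            "a genotype group is empty after the draw; "
            "increase n_samples or use a less extreme maf"
        )
    sample_ids = [f"sample{i:04d}" for i in range(cfg.n_samples)]
    gene_ids = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    n_dep = int(round(cfg.frac_genotype_dependent * cfg.n_genes))
    truth = set(
        gene_ids[i] for i in rng.choice(cfg.n_genes, size=n_dep, replace=False)
    )
    lnc = rng.normal(0.0, 1.0, size=cfg.n_samples)
    het = groups == "Heter"
    expr = np.empty((cfg.n_samples, cfg.n_genes))
    for g, gid in enumerate(gene_ids):
        slope = np.full(cfg.n_samples, cfg.beta_wt)
        if gid in truth:
            slope[het] = cfg.beta_wt * cfg.beta_het_multiplier
        expr[:, g] = slope * lnc + rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
    return ExpressionPanel(
        sample_ids=sample_ids,
        genotype_group=pd.Series(groups, index=sample_ids, name="group"),
        lnc_expr=pd.Series(lnc, index=sample_ids, name="lncRNA"),
        gene_expr=pd.DataFrame(expr, index=sample_ids, columns=gene_ids),
        truth_genes=truth,
    )
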