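"""Genotype-dependent co-expression screening.

Samples are split by the genotype at a focal regulatory SNP into a
wild-type (WT, homozygous-reference) and a heterozygous (Heter) group.
Per gene, the correlation and ordinary-least-squares slope of gene
expression on the focal lncRNA's expression are computed within each
group. A gene passes the genotype-dependent screen when

* |r_Heter| > 0.5,
* Benjamini-Hochberg q of the Heter correlation p-value < 0.05,
* |beta_Heter| >= 2 * |beta_WT|  (slope amplification), and
* |r_WT| <= 0.5  (no comparable correlation without the allele).

Slopes are compared on absolute value: a sign flip with doubled magnitude
still indicates genotype dependence. The FDR family is the Heter-group
p-values only; both choices are configurable.

Also provided: the pooled positive-correlation screen (r > 0.3,
p < 1e-5, signed) and the hypergeometric overlap-enrichment statistic
(Fisher one-sided) used to compare gene sets against a background.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenThresholds",
    "CoexprResult",
    "pearson_r",
    "simple_linear_fit",
    "bh_fdr",
    "genotype_dependent_screen",
    "positive_correlation_screen",
    "overlap_enrichment",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Decision thresholds of the co-expression screens."""

    r_het_min: float = 0.5
    fdr_max: float = 0.05
    beta_ratio_min: float = 2.0
    r_wt_max: float = 0.5
    pos_r_min: float = 0.3
    pos_p_max: float = 1.0e-5


@dataclass
class CoexprResult:
    gene_id: str
    r_wt: float
    r_het: float
    p_het: float
    q_het: float
    beta_wt: float
    beta_het: float
    passed: bool
    fail_reason: Optional[str] = None  # first violated rule, or None


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def simple_linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares of y on x; returns (intercept, slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("simple_linear_fit needs two equal-length vectors, n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(lnc: np.ndarray, y: np.ndarray):
    """(r, p, slope) of y on lnc, or None when y is constant in the group."""
    if np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(lnc, y)
    slope = np.polyfit(lnc, y, 1)[0]
    return float(r), float(p), float(slope)


def genotype_dependent_screen(
    panel, thresholds: ScreenThresholds = ScreenThresholds()
) -> list:
    """Per-gene genotype-dependent co-expression verdicts.

    ``panel`` is an :class:`twinase.simulate.ExpressionPanel` (or any
    object with ``lnc_expr``, ``gene_expr`` and ``group_mask``). Genes
    constant in either group are excluded with fail_reason "constant" and
    take no part in the FDR family. ``fail_reason`` records the first
    violated rule in the documented order (r_het, fdr, beta_ratio, r_wt).
    """
    wt = panel.group_mask("WT")
    het = panel.group_mask("Heter")
    if wt.sum() < 3 or het.sum() < 3:
        raise ValueError(
            f"both genotype groups need >= 3 samples (WT={int(wt.sum())}, "
            f"Heter={int(het.sum())})"
        )
    lnc = np.asarray(panel.lnc_expr, dtype=float)
    if np.ptp(lnc[wt]) == 0 or np.ptp(lnc[het]) == 0:
        raise ValueError("focal lncRNA expression is constant within a group")

    genes = list(panel.gene_expr.columns)
    stats_rows = {}
    for gid in genes:
        y = panel.gene_expr[gid].to_numpy(dtype=float)
        s_wt = _group_stats(lnc[wt], y[wt])
        s_het = _group_stats(lnc[het], y[het])
        stats_rows[gid] = (s_wt, s_het)

    valid = [g for g in genes if stats_rows[g][0] and stats_rows[g][1]]
    q_map = dict(
        zip(valid, bh_fdr([stats_rows[g][1][1] for g in valid]))
    ) if valid else {}

    results = []
    th = thresholds
    for gid in genes:
        s_wt, s_het = stats_rows[gid]
        if s_wt is None or s_het is None:
            results.append(
                CoexprResult(gid, math.nan, math.nan, math.nan, math.nan,
                             math.nan, math.nan, False, "constant")
            )
            continue
        r_wt, _p_wt, b_wt = s_wt
        r_het, p_het, b_het = s_het
        q_het = float(q_map[gid])
        fail = None
        if not (abs(r_het) > th.r_het_min):
            fail = "r_het"
        elif not (q_het < th.fdr_max):
            fail = "fdr"
        elif not (abs(b_het) >= th.beta_ratio_min * abs(b_wt)):
            fail = "beta_ratio"
        elif not (abs(r_wt) <= th.r_wt_max):
            fail = "r_wt"
        results.append(
            CoexprResult(gid, r_wt, r_het, p_het, q_het, b_wt, b_het,
                         fail is None, fail)
        )
    return results


def positive_correlation_screen(
    panel, r_min: float = 0.3, p_max: float = 1.0e-5
) -> Set[str]:
    """Genes positively correlated with the focal lncRNA across all samples.

    Signed r > r_min and p < p_max; anti-correlated genes are excluded no
    matter how significant. Constant genes cannot correlate and are skipped.
    """
    lnc = np.asarray(panel.lnc_expr, dtype=float)
    out = set()
    if len(panel.gene_expr) == 0:
        return out
    for gid in panel.gene_expr.columns:
        y = panel.gene_expr[gid].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        r, p = stats.pearsonr(lnc, y)
        if r > r_min and p < p_max:
            out.add(gid)
    return out


def overlap_enrichment(
    set_a: Iterable, set_b: Iterable, background_size: int
) -> tuple[float, float]:
    """Enrichment of the overlap of two gene sets within a background.

    Builds the 2x2 table (k, |A|-k, |B|-k, N-|A|-|B|+k), returns the odds
    ratio (Haldane 0.5 correction when any cell is zero) and the
    upper-tail hypergeometric probability P(X >= k) — the one-sided Fisher
    test.
    """
    A, B = set(set_a), set(set_b)
    N = int(background_size)
    if len(A | B) > N:
        raise ValueError(
            f"background_size {N} smaller than |A ∪ B| = {len(A | B)}"
        )
    k = len(A & B)
    a = k
    b = len(A) - k
    c = len(B) - k
    d = N - len(A) - len(B) + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    p = float(stats.hypergeom.sf(k - 1, N, len(A), len(B)))
    return float(odds_ratio), p
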