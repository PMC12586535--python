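"""Tests of the correlation/FDR primitives and the co-expression screens."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from twinase import (
    CoexprPanelConfig,
    ScreenThresholds,
    bh_fdr,
    genotype_dependent_screen,
    overlap_enrichment,
    pearson_r,
    positive_correlation_screen,
    simple_linear_fit,
    simulate_expression_panel,
)
from twinase.simulate import ExpressionPanel


def brute_force_bh(p):
    """Independent step-up recursion: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 5)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, _p = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r_xy, p_xy = pearson_r(x, y)
        r_yx, p_yx = pearson_r(y, x)
        assert r_xy == pytest.approx(r_yx)
        assert p_xy == pytest.approx(p_yx)
        r_scaled, _ = pearson_r(3.0 * x - 7.0, 0.5 * y + 2.0)
        assert r_scaled == pytest.approx(r_xy, abs=1e-10)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        intercept, slope = simple_linear_fit(x, 3 * x + 1)
        assert (intercept, slope) == (pytest.approx(1.0), pytest.approx(3.0))

    def test_hand_computed_normal_equations(self):
        intercept, slope = simple_linear_fit([0, 1, 2], [0, 0, 3])
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(-0.5)

    @given(st.floats(-10, 10).filter(lambda c: abs(c) > 1e-3))
    def test_scaling_y_scales_slope(self, c):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 0.5, 2.5, 3.0])
        _, slope = simple_linear_fit(x, y)
        _, slope_c = simple_linear_fit(x, c * y)
        assert slope_c == pytest.approx(c * slope, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            simple_linear_fit([2, 2, 2], [1, 2, 3])


class TestBHFDR:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @given(st.integers(0, 2**32 - 1), st.integers(1, 60))
    def test_matches_brute_force_recursion(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.random(m) ** 2  # skew toward small values
        assert bh_fdr(p) == pytest.approx(brute_force_bh(p), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_permutation_equivariance_and_sorted_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(20)
        q = bh_fdr(p)
        perm = rng.permutation(20)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def panel_from_arrays(lnc, genes: dict, groups):
    index = [f"s{i}" for i in range(len(lnc))]
    return ExpressionPanel(
        sample_ids=index,
        genotype_group=pd.Series(groups, index=index),
        lnc_expr=pd.Series(np.asarray(lnc, dtype=float), index=index),
        gene_expr=pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in genes.items()},
                               index=index),
    )


class TestGenotypeDependentScreen:
    def test_constant_gene_excluded_with_reason(self):
        rng = np.random.default_rng(0)
        n = 40
        groups = ["WT"] * 20 + ["Heter"] * 20
        lnc = rng.normal(size=n)
        genes = {"flat": np.r_[rng.normal(size=20), np.ones(20)],
                 "ok": 2 * lnc + rng.normal(0, 0.5, size=n)}
        res = {c.gene_id: c for c in genotype_dependent_screen(panel_from_arrays(lnc, genes, groups))}
        assert res["flat"].passed is False
        assert res["flat"].fail_reason == "constant"

    def test_beta_ratio_rule_rejects_weak_amplification(self):
        # strong correlation in both groups but slope ratio only ~1.5
        rng = np.random.default_rng(1)
        n = 200
        groups = ["WT"] * 100 + ["Heter"] * 100
        lnc = rng.normal(size=n)
        y = np.where(np.arange(n) < 100, 1.0 * lnc, 1.5 * lnc) + rng.normal(0, 0.05, n)
        res = genotype_dependent_screen(
            panel_from_arrays(lnc, {"g": y}, groups),
            ScreenThresholds(r_wt_max=1.0),  # isolate the ratio rule
        )[0]
        assert abs(res.r_het) > 0.9 and res.q_het < 0.05
        assert res.passed is False
        assert res.fail_reason == "beta_ratio"

    def test_wt_correlation_exclusion_rule(self):
        rng = np.random.default_rng(2)
        n = 200
        groups = ["WT"] * 100 + ["Heter"] * 100
        lnc = rng.normal(size=n)
        y = np.where(np.arange(n) < 100, 1.0 * lnc, 5.0 * lnc) + rng.normal(0, 0.05, n)
        res = genotype_dependent_screen(panel_from_arrays(lnc, {"g": y}, groups))[0]
        assert res.fail_reason == "r_wt"

    def test_relaxed_thresholds_pass_every_nondegenerate_gene(self, default_panel):
        relaxed = ScreenThresholds(r_het_min=0.0, fdr_max=1.01, beta_ratio_min=0.0,
                                   r_wt_max=1.0)
        res = genotype_dependent_screen(default_panel, relaxed)
        assert all(c.passed for c in res if c.fail_reason != "constant")

    def test_recovers_truth_genes_on_default_panel(self, default_panel):
        res = genotype_dependent_screen(default_panel)
        passed = {c.gene_id for c in res if c.passed}
        truth = default_panel.truth_genes
        recall = len(passed & truth) / len(truth)
        fdp = len(passed - truth) / max(len(passed), 1)
        assert recall >= 0.8
        assert fdp <= 0.2

    def test_small_group_rejected(self):
        lnc = np.arange(10.0)
        groups = ["WT"] * 8 + ["Heter"] * 2
        with pytest.raises(ValueError, match=">= 3 samples"):
            genotype_dependent_screen(panel_from_arrays(lnc, {"g": lnc}, groups))


class TestPositiveCorrelationScreen:
    def test_sign_matters(self):
        rng = np.random.default_rng(3)
        lnc = rng.normal(size=100)
        genes = {"up": lnc + rng.normal(0, 0.1, 100),
                 "down": -lnc + rng.normal(0, 0.1, 100)}
        panel = panel_from_arrays(lnc, genes, ["WT"] * 50 + ["Heter"] * 50)
        assert positive_correlation_screen(panel) == {"up"}

    def test_thresholds_applied_to_measured_r_and_p(self):
        rng = np.random.default_rng(4)
        lnc = rng.normal(size=120)
        genes = {f"g{i}": w * lnc + rng.normal(0, 1.0, 120)
                 for i, w in enumerate([0.0, 0.2, 0.5, 1.0, 2.0])}
        panel = panel_from_arrays(lnc, genes, ["WT"] * 60 + ["Heter"] * 60)
        got = positive_correlation_screen(panel, r_min=0.3, p_max=1e-5)
        expected = set()
        for gid, y in genes.items():
            r, p = stats.pearsonr(lnc, y)
            if r > 0.3 and p < 1e-5:
                expected.add(gid)
        assert got == expected
        assert expected  # the rule actually selected something

    def test_empty_panel_gives_empty_set(self):
        panel = panel_from_arrays([], {}, [])
        assert positive_correlation_screen(panel) == set()


class TestOverlapEnrichment:
    def test_fixture_odds_ratio(self):
        # 2x2 table (20, 80, 10, 890): OR = 20*890 / (80*10) = 22.25
        background = [f"x{i}" for i in range(1000)]
        A = set(background[:100])
        B = set(background[:20]) | set(background[100:110])
        odds, p = overlap_enrichment(A, B, 1000)
        assert odds == pytest.approx(22.25)
        assert p < 1e-10

    def test_overlap_at_expectation_gives_unit_odds_ratio(self):
        # N=100, |A|=20, |B|=10, k=2 = |A||B|/N -> OR exactly 1
        background = [f"x{i}" for i in range(100)]
        A = set(background[:20])
        B = set(background[:2]) | set(background[20:28])
        odds, _ = overlap_enrichment(A, B, 100)
        assert odds == pytest.approx(1.0)

    @given(st.integers(0, 2**32 - 1))
    def test_p_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 51))
        nA = int(rng.integers(1, N + 1))
        nB = int(rng.integers(1, N + 1))
        universe = list(range(N))
        A = set(rng.choice(universe, nA, replace=False).tolist())
        B = set(rng.choice(universe, nB, replace=False).tolist())
        if len(A | B) > N:
            return
        k = len(A & B)
        _, p = overlap_enrichment(A, B, N)
        # brute-force hypergeometric tail by pmf summation
        from math import comb
        tail = sum(
            comb(nA, x) * comb(N - nA, nB - x)
            for x in range(k, min(nA, nB) + 1)
            if nB - x <= N - nA
        ) / comb(N, nB)
        assert p == pytest.approx(tail, rel=1e-9)

    def test_sets_exceeding_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            overlap_enrichment({1, 2, 3}, {4, 5}, 4)
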