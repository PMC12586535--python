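"""Shared fixtures: random count instances and small simulated objects."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from twinase import AllelicCountRecord, CohortConfig, CoexprPanelConfig
from twinase import simulate_cohort, simulate_expression_panel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def random_instance(rng, n_pairs, max_depth=50, min_depth=5):
    """One SNP-transcript pair's records: two co-twins per twin pair,
    uniform depths and uniform alt counts (deliberately includes extreme
    0/n imbalances)."""
    recs = []
    for i in range(n_pairs):
        for member in ("affected", "unaffected"):
            n = int(rng.integers(min_depth, max_depth + 1))
            a = int(rng.integers(0, n + 1))
            recs.append(
                AllelicCountRecord(f"pair{i:02d}", member, "snpX", "txX", a, n - a)
            )
    return recs


def swap_alleles(records):
    return [
        AllelicCountRecord(
            r.pair_id, r.member, r.snp_id, r.transcript_id, r.ref_count, r.alt_count
        )
        for r in records
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """60 SNPs, 4 injected discordant at betas=2, depth ~500."""
    cfg = CohortConfig(
        n_snps=60,
        frac_true_discordant=4 / 60,
        depth_mean=500,
        het_rate=0.6,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_panel():
    return simulate_expression_panel(CoexprPanelConfig(seed=5))
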