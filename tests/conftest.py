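"""Shared fixtures and brute-force oracles for the test suite.

All fixtures are generated programmatically; oracles here are written
independently of the library code paths they check (plain double loops
and direct formula evaluation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cm3.ld import LdPanel
from cm3.mixture import MixtureParams


@pytest.fixture(scope="session")
def toy_ld_panel() -> LdPanel:
    """Deterministic 12-SNP panel: four 3-SNP blocks of varying LD."""
    rng = np.random.default_rng(42)
    n = 400
    cols = []
    for copy_prob in (1.0, 0.95, 0.7, 0.0):
        k = rng.uniform(0.2, 0.5)
        anc = rng.uniform(size=(n, 2)) < k
        for _ in range(3):
            take = rng.uniform(size=(n, 2)) < copy_prob
            fresh = rng.uniform(size=(n, 2)) < k
            cols.append(np.where(take, anc, fresh).sum(axis=1).astype(float))
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(12)],
            "chrom": "1",
            "pos": np.arange(1, 13) * 5_000,
        }
    )
    return LdPanel(np.column_stack(cols), snps, window_bp=1_000_000)


def brute_force_r2(panel: LdPanel, i: int, j: int) -> float:
    """Independent r^2: plain Pearson correlation of dosage columns."""
    gi = panel.genotypes[:, i]
    gj = panel.genotypes[:, j]
    if gi.std() == 0 or gj.std() == 0:
        return 0.0
    if panel.snps["chrom"].iat[i] != panel.snps["chrom"].iat[j]:
        return 0.0
    if abs(int(panel.snps["pos"].iat[i]) - int(panel.snps["pos"].iat[j])) > panel.window_bp:
        return 0.0
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def brute_force_prune_check(kept: pd.DataFrame, panel: LdPanel, r2_max: float) -> bool:
    """Exhaustively verify the no-pair-above-threshold invariant."""
    idx = [panel.index_of(s) for s in kept["snp_id"]]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if brute_force_r2(panel, idx[a], idx[b]) >= r2_max:
                return False
    return True


@pytest.fixture(scope="session")
def generic_params() -> MixtureParams:
    return MixtureParams(pi1=0.05, sigma0_sq=1.1, sigma1_sq=2e-6, sigma2_sq=1.5e-3)


def random_param_sets(n_sets: int, seed: int = 0) -> list[MixtureParams]:
    """Random but well-conditioned parameter configurations."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        out.append(
            MixtureParams(
                pi1=float(10 ** rng.uniform(-3, -0.5)),
                sigma0_sq=float(rng.uniform(0.8, 1.5)),
                sigma1_sq=float(10 ** rng.uniform(-8, -5.5)),
                sigma2_sq=float(10 ** rng.uniform(-4, -2.5)),
            )
        )
    return out
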