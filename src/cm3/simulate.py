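"""Synthetic sub-study panels, covariates, and block-LD genotype panels.

The generators produce data with exactly the statistical structure the
mixture model assumes: per-SNP standardized effects delta_i drawn from a
two-component zero-mean Gaussian scale mixture whose large-effect
probability can depend on SNP covariates through a logit shift, and
per-study z-scores z_ij = sqrt(n_j) * delta_i + eps_ij with independent
N(0, sigma0^2) noise (no sample overlap between sub-studies).  A simple
block-equicorrelated genotype panel supports the LD operators.  All
generators are byte-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_seedseq
import pandas as pd
from scipy.special import expit, logit

from .ld import LdPanel, heterozygosity
from .mixture import MixtureParams
from .sumstats import SubStudyPanel

#: covariate columns of a synthetic covariate table, in canonical order
COVARIATE_COLUMNS = (
    "exon", "intron", "utr5", "utr3", "up1k", "up10k", "down1k", "down10k",
    "tld", "H", "bip_z2",
)


@dataclass
class TrueEffects:
    """Ground truth of a simulation: component labels and effects.

    ``component`` is 0 (small) / 1 (large); conditional on the label,
    delta ~ N(0, H*sigma1^2) or N(0, H*(sigma1^2+sigma2^2)).
    """

    component: np.ndarray
    delta: np.ndarray
    params: MixtureParams
    H: np.ndarray
    logit_shift: np.ndarray

    @property
    def m(self) -> int:
        return self.delta.size


def simulate_truth(
    m: int,
    params: MixtureParams,
    H,
    pi1_logit_shift=None,
    seed=None,
) -> TrueEffects:
    """Draw per-SNP components and effects from the generating mixture.

    The large-effect probability of SNP i is
    ``logistic(logit(pi1) + shift_i)`` (shift 0 when absent), the
    covariate-modulation mechanism: covariates move the mixture weight,
    not the component variances.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    H = np.broadcast_to(np.asarray(H, dtype=float), (m,)).copy()
    if np.any((H <= 0) | (H > 0.5)):
        raise ValueError("H must lie in (0, 0.5]")
    if pi1_logit_shift is None:
        shift = np.zeros(m)
    else:
        shift = np.broadcast_to(np.asarray(pi1_logit_shift, dtype=float), (m,)).copy()
        if params.pi1 in (0.0, 1.0) and np.any(shift != 0):
            raise ValueError("pi1 of 0 or 1 cannot be shifted on the logit scale")
    rng = np.random.default_rng(seed)
    if params.pi1 == 0.0:
        p_large = np.zeros(m)
    elif params.pi1 == 1.0:
        p_large = np.ones(m)
    else:
        p_large = expit(logit(params.pi1) + shift)
    component = (rng.uniform(size=m) < p_large).astype(np.int8)
    var = H * np.where(
        component == 1, params.sigma1_sq + params.sigma2_sq, params.sigma1_sq
    )
    delta = rng.standard_normal(m) * np.sqrt(var)
    return TrueEffects(component, delta, params, H, shift)


def simulate_substudies(
    truth: TrueEffects,
    n_list,
    seed=None,
    snps: pd.DataFrame | None = None,
) -> SubStudyPanel:
    """Per-study z-scores z_ij = sqrt(n_j) delta_i + eps_ij.

    eps_ij ~ N(0, sigma0^2), independent across SNPs and studies.  If no
    SNP frame is given, a minimal synthetic index (one SNP per 10 kbp on
    chromosome 1) is created.
    """
    n_list = np.asarray(n_list, dtype=float)
    if n_list.size < 2:
        raise ValueError("need J >= 2 sub-studies")
    rng = np.random.default_rng(seed)
    m = truth.m
    sd0 = np.sqrt(truth.params.sigma0_sq)
    z = (
        np.sqrt(n_list)[None, :] * truth.delta[:, None]
        + rng.standard_normal((m, n_list.size)) * sd0
    )
    if snps is None:
        snps = pd.DataFrame(
            {
                "snp_id": [f"rs{i + 1}" for i in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1) * 10_000,
                "a1": "A",
                "a2": "G",
            }
        )
    return SubStudyPanel(snps=snps, z=z, n_eff=n_list)


def simulate_covariates(
    m: int,
    effect_map: dict | None = None,
    noise_sd: float = 0.0,
    seed=None,
    maf_range=(0.05, 0.5),
):
    """Draw a covariate table and the implied per-SNP logit shift.

    Covariates are drawn marginally realistic (sparse nonnegative
    annotation scores, TLD >= 1, H = 2k(1-k) for a uniform MAF, bip_z2
    ~ chi-square(1)); the returned shift is the linear combination of
    standardized covariates given by ``effect_map`` (column -> weight)
    plus N(0, noise_sd^2) noise, centered so the average shift is 0.
    Feed the shift to :func:`simulate_truth` to couple enrichment to the
    covariates; with all weights 0 the covariates are independent of the
    component labels.

    Returns ``(covariates, shift)``.
    """
    rng = np.random.default_rng(seed)
    effect_map = dict(effect_map or {})
    cov = pd.DataFrame(index=pd.RangeIndex(m))
    for cat in COVARIATE_COLUMNS[:8]:
        active = rng.uniform(size=m) < 0.15  # most SNPs tag no category
        cov[cat] = np.where(active, rng.gamma(shape=1.5, scale=1.2, size=m), 0.0)
    cov["tld"] = 1.0 + rng.gamma(shape=2.0, scale=10.0, size=m)
    maf = rng.uniform(*maf_range, size=m)
    cov["H"] = heterozygosity(maf)
    cov["maf"] = maf
    cov["bip_z2"] = rng.chisquare(1, size=m)
    unknown = set(effect_map) - set(cov.columns)
    if unknown:
        raise ValueError(f"effect_map names unknown covariates: {sorted(unknown)}")
    shift = np.zeros(m)
    for col, w in effect_map.items():
        x = cov[col].to_numpy()
        sd = x.std()
        xs = (x - x.mean()) / (sd if sd > 0 else 1.0)
        shift += float(w) * xs
    if noise_sd > 0:
        shift += rng.normal(0.0, noise_sd, size=m)
    shift -= shift.mean()
    return cov, shift


def simulate_ld_blocks(
    m: int,
    block_size: int,
    r2_within: float,
    n_samples: int,
    seed=None,
    maf_range=(0.1, 0.5),
    chrom: str = "1",
    spacing_bp: int = 1_000,
    window_bp: int = 1_000_000,
) -> LdPanel:
    """Block-equicorrelated genotype panel for exercising the LD tools.

    SNPs come in consecutive blocks of ``block_size``; within a block
    every pair has expected r^2 ~= ``r2_within`` and across blocks ~= 0.
    Each haplotype allele copies a block ancestor allele with probability
    ``r2_within ** 0.25`` (pairwise allele correlation q^2, genotype r^2
    q^4), so the target is hit in expectation without inflating MAF
    spread.  Block MAFs are uniform in ``maf_range``.
    """
    if not 0.0 <= r2_within < 1.0:
        raise ValueError("r2_within must be in [0, 1)")
    rng = np.random.default_rng(seed)
    q = r2_within ** 0.25
    n_blocks = int(np.ceil(m / block_size))
    cols = []
    for b in range(n_blocks):
        size = min(block_size, m - b * block_size)
        k = rng.uniform(*maf_range)
        # two ancestor haplotypes per sample
        anc = rng.uniform(size=(n_samples, 2)) < k
        for _ in range(size):
            copy = rng.uniform(size=(n_samples, 2)) < q
            fresh = rng.uniform(size=(n_samples, 2)) < k
            hap = np.where(copy, anc, fresh)
            cols.append(hap.sum(axis=1).astype(float))
    genotypes = np.column_stack(cols)
    snps = pd.DataFrame(
        {
            "snp_id": [f"pv{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing_bp,
        }
    )
    return LdPanel(genotypes, snps, window_bp=window_bp)


def default_study_sizes(J: int, n_range=(1_000, 4_000), seed=None) -> np.ndarray:
    """Heterogeneous per-study effective sizes, log-uniform in a range."""
    if J < 2:
        raise ValueError("need J >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = n_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=J))


@dataclass
class EnrichedDataset:
    """Bundle of a full synthetic study: panel + covariates + truth."""

    panel: SubStudyPanel
    covariates: pd.DataFrame
    truth: TrueEffects
    shift: np.ndarray


def simulate_enriched_dataset(
    m: int,
    J: int,
    params: MixtureParams,
    effect_map: dict | None = None,
    noise_sd: float = 0.0,
    n_range=(1_000, 4_000),
    seed=None,
) -> EnrichedDataset:
    """End-to-end convenience generator: covariates -> truth -> panel.

    Draws covariates and the implied logit shift, then components and
    effects (with H taken from the covariate table), then J sub-study
    z-score panels with log-uniform effective sizes.  Child seeds are
    spawned deterministically from ``seed``.
    """
    ss = as_seedseq(seed)
    s_cov, s_truth, s_panel, s_n = ss.spawn(4)
    cov, shift = simulate_covariates(m, effect_map, noise_sd, seed=s_cov)
    truth = simulate_truth(
        m, params, cov["H"].to_numpy(), pi1_logit_shift=shift, seed=s_truth
    )
    n_list = default_study_sizes(J, n_range, seed=s_n)
    panel = simulate_substudies(truth, n_list, seed=s_panel)
    return EnrichedDataset(panel=panel, covariates=cov, truth=truth, shift=shift)


def truth_frame(truth: TrueEffects) -> pd.DataFrame:
    """Ground-truth table (delta, component, shift) for recovery tests."""
    return pd.DataFrame(
        {
            "delta": truth.delta,
            "component": truth.component,
            "logit_shift": truth.logit_shift,
            "H": truth.H,
        }
    )
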