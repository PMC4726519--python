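"""Scale mixture of two Gaussians for GWAS z-scores.

A SNP's z-score in a study of effective sample size ``n`` is modeled as

    z_i = sqrt(n) * delta_i + eps_i,      eps_i ~ N(0, sigma0^2),

where the standardized effect ``delta_i`` is drawn from a zero-mean
two-component scale mixture: with prior probability ``pi0 = 1 - pi1`` the
effect is "small", delta ~ N(0, H_i * sigma1^2); with probability ``pi1``
it is "large", delta ~ N(0, H_i * (sigma1^2 + sigma2^2)).  ``H_i =
2k(1-k)`` is the SNP heterozygosity for minor allele frequency ``k``, so
common variants carry proportionally more explained variance.  Setting
``sigma1^2 = 0`` recovers the classical two-groups model with a point
null.

This module is purely analytic: component densities, the marginal
mixture density, the local false discovery rate, the posterior mean
effect size (the empirical-Bayes/Tweedie shrinkage estimator), the
conditional replication moments, the finite-sample predicted replication
probability, and the per-stratum prediction lookup table built from
them.  Everything is vectorized over z and computed in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, ndtr

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the two-component scale mixture.

    Attributes
    ----------
    pi1 : float
        Prior probability of the large-effect component, in [0, 1].
    sigma0_sq : float
        Variance of the residual (sampling) noise on the z scale; > 0.
        Values above 1 absorb inflation of the null distribution.
    sigma1_sq : float
        Per-unit-heterozygosity variance of the small-effect component;
        >= 0.  Zero gives a point null.
    sigma2_sq : float
        Additional per-unit-heterozygosity variance of the large-effect
        component (its total effect variance is H*(sigma1_sq+sigma2_sq)).
    """

    pi1: float
    sigma0_sq: float
    sigma1_sq: float
    sigma2_sq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError(f"pi1 must be in [0, 1], got {self.pi1}")
        if not self.sigma0_sq > 0.0:
            raise ValueError(f"sigma0_sq must be positive, got {self.sigma0_sq}")
        if self.sigma1_sq < 0.0 or self.sigma2_sq < 0.0:
            raise ValueError("component variances must be nonnegative")
        for name in ("pi1", "sigma0_sq", "sigma1_sq", "sigma2_sq"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    def as_array(self) -> np.ndarray:
        return np.array([self.pi1, self.sigma0_sq, self.sigma1_sq, self.sigma2_sq])


def component_variances(n, H, params: MixtureParams):
    """Marginal z-score variances (s0, s1) of the two components."""
    n = np.asarray(n, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(n <= 0) or np.any(H <= 0):
        raise ValueError("n and H must be positive")
    s0 = params.sigma0_sq + n * H * params.sigma1_sq
    s1 = params.sigma0_sq + n * H * (params.sigma1_sq + params.sigma2_sq)
    return s0, s1


def _log_norm_pdf(z, var):
    return -0.5 * z * z / var - 0.5 * np.log(var) - _LOG_SQRT_2PI


def marginal_density(z, n, H, params: MixtureParams):
    """Component densities and marginal mixture density of z.

    Returns ``(f0, f1, f)`` where ``f0 = phi(z; 0, sigma0^2 + n H sigma1^2)``,
    ``f1 = phi(z; 0, sigma0^2 + n H (sigma1^2 + sigma2^2))`` and
    ``f = pi0 f0 + pi1 f1``.
    """
    z = np.asarray(z, dtype=float)
    s0, s1 = component_variances(n, H, params)
    f0 = np.exp(_log_norm_pdf(z, s0))
    f1 = np.exp(_log_norm_pdf(z, s1))
    return f0, f1, params.pi0 * f0 + params.pi1 * f1


def log_marginal_density(z, n, H, params: MixtureParams):
    """log f(z), underflow-safe via log-sum-exp."""
    z = np.asarray(z, dtype=float)
    s0, s1 = component_variances(n, H, params)
    lf0 = _log_norm_pdf(z, s0)
    lf1 = _log_norm_pdf(z, s1)
    if params.pi1 == 0.0:
        return lf0
    if params.pi1 == 1.0:
        return lf1
    stacked = np.stack([lf0 + np.log(params.pi0), lf1 + np.log(params.pi1)])
    return logsumexp(stacked, axis=0)


def local_fdr(z, n, H, params: MixtureParams):
    """Local false discovery rate: posterior P(small component | z).

    fdr(z) = pi0 f0(z) / f(z); computed via the posterior-odds logistic
    form so it never degenerates to 0/0 in the tails.
    """
    z = np.asarray(z, dtype=float)
    if params.pi1 == 0.0:
        return np.ones_like(z)
    if params.pi1 == 1.0:
        return np.zeros_like(z)
    s0, s1 = component_variances(n, H, params)
    # log posterior odds of the large component
    log_odds = (
        np.log(params.pi1)
        - np.log(params.pi0)
        + _log_norm_pdf(z, s1)
        - _log_norm_pdf(z, s0)
    )
    # fdr = 1 / (1 + odds)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(log_odds))


def posterior_effect(z, n, H, params: MixtureParams):
    """Posterior mean of the scaled effect, E[sqrt(n) delta | z].

    Mixture form ``z * (A * fdr(z) + B * tdr(z))`` with the per-component
    shrinkage factors A = nH sigma1^2 / (sigma0^2 + nH sigma1^2) and
    B = nH (sigma1^2+sigma2^2) / (sigma0^2 + nH (sigma1^2+sigma2^2)).
    Identical to the Tweedie form ``z + sigma0^2 d/dz log f(z)``.
    """
    z = np.asarray(z, dtype=float)
    s0, s1 = component_variances(n, H, params)
    A = 1.0 - params.sigma0_sq / s0
    B = 1.0 - params.sigma0_sq / s1
    fdr = local_fdr(z, n, H, params)
    return z * (A * fdr + B * (1.0 - fdr))


def posterior_effect_tweedie(z, n, H, params: MixtureParams, h: float = 1e-4):
    """Tweedie-form posterior mean via central differences of log f.

    Kept as an independent route to :func:`posterior_effect`; the two
    must agree, which is a strong end-to-end check of the density layer.
    """
    z = np.asarray(z, dtype=float)
    dlogf = (
        log_marginal_density(z + h, n, H, params)
        - log_marginal_density(z - h, n, H, params)
    ) / (2.0 * h)
    return z + params.sigma0_sq * dlogf


def _component_conditionals(n, n_r, H, params: MixtureParams):
    """Slopes c_k and residual variances v_k of z_r | z_d per component.

    Given a shared effect delta, (z_d, z_r) are jointly Gaussian with
    covariance sqrt(n n_r) H sigma_k*^2, so conditionally on the
    component and on z_d the replication z is Gaussian with mean
    ``c_k z_d`` and variance ``v_k``.
    """
    n = np.asarray(n, dtype=float)
    n_r = np.asarray(n_r, dtype=float)
    if np.any(n_r <= 0):
        raise ValueError("replication sample size must be positive")
    H = np.asarray(H, dtype=float)
    out = []
    for sig_sq in (params.sigma1_sq, params.sigma1_sq + params.sigma2_sq):
        g = H * sig_sq  # per-SNP effect variance scale
        denom = params.sigma0_sq + n * g
        c = np.sqrt(n * n_r) * g / denom
        v = params.sigma0_sq + n_r * g - n * n_r * g * g / denom
        out.append((c, v))
    return out


def replication_moments(z, n, n_r, H, params: MixtureParams):
    """Conditional mean and second moment of the replication z-score.

    ``E[z_r | z_d]   = fdr * c0 z + tdr * c1 z``
    ``E[z_r^2 | z_d] = fdr * ((c0 z)^2 + v0) + tdr * ((c1 z)^2 + v1)``

    where (c_k, v_k) are the component-wise conditional Gaussian slope
    and variance and fdr/tdr weight by posterior component membership
    (membership is shared between discovery and replication).
    """
    z = np.asarray(z, dtype=float)
    (c0, v0), (c1, v1) = _component_conditionals(n, n_r, H, params)
    fdr = local_fdr(z, n, H, params)
    tdr = 1.0 - fdr
    mean = fdr * c0 * z + tdr * c1 * z
    second = fdr * ((c0 * z) ** 2 + v0) + tdr * ((c1 * z) ** 2 + v1)
    return mean, second


def replication_probability(z, n, n_r, H, params: MixtureParams, z_alpha: float):
    """Finite-sample predicted replication probability.

    Probability that an independent sample of effective size ``n_r``
    yields a z-score with the same sign as the discovery z and magnitude
    at least ``z_alpha``:

        repl(z) = Phi((-z_alpha - mu_r0)/sqrt(v0)) * fdr
                + Phi((-z_alpha - mu_r1)/sqrt(v1)) * tdr,

    with mu_rk = -c_k |z| (the component conditional mean oriented
    against the threshold; equivalently P(z_r >= z_alpha | z_d = |z|)).
    """
    if z_alpha <= 0:
        raise ValueError("z_alpha must be positive")
    z = np.asarray(z, dtype=float)
    (c0, v0), (c1, v1) = _component_conditionals(n, n_r, H, params)
    fdr = local_fdr(z, n, H, params)
    tdr = 1.0 - fdr
    az = np.abs(z)
    p0 = ndtr((-z_alpha + c0 * az) / np.sqrt(v0))
    p1 = ndtr((-z_alpha + c1 * az) / np.sqrt(v1))
    return p0 * fdr + p1 * tdr


@dataclass
class PosteriorPrediction:
    """Per-SNP (or per-grid-point) posterior summaries."""

    fdr: np.ndarray
    post_mean: np.ndarray
    repl_mean: np.ndarray
    repl_second_moment: np.ndarray
    repl_prob: np.ndarray

    @property
    def tdr(self) -> np.ndarray:
        return 1.0 - self.fdr


def _h_subsample(H_values, max_points: int) -> np.ndarray:
    """Deterministic quantile subsample of an empirical H distribution."""
    H_values = np.asarray(H_values, dtype=float)
    H_values = H_values[np.isfinite(H_values)]
    if H_values.size == 0:
        raise ValueError("H sample is empty")
    if H_values.size <= max_points:
        return np.sort(H_values)
    q = (np.arange(max_points) + 0.5) / max_points
    return np.quantile(H_values, q)


def predict_grid(
    z_grid,
    n,
    n_r,
    H_sample,
    params: MixtureParams,
    z_alpha: float,
    max_h_points: int = 256,
    density_weighted: bool = True,
) -> PosteriorPrediction:
    """Posterior predictions on a z grid, averaged over an H sample.

    Heterozygosity varies within a stratum; predictions at a grid z are
    averaged over a quantile subsample of the stratum's empirical H
    values.  By default the average weights each H by the marginal
    density f(z; n, H) — the coherent posterior average over H given the
    observed z — with plain (unweighted) averaging available for
    comparison.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    Hs = _h_subsample(H_sample, max_h_points)
    nH = Hs.size
    fdr_mat = np.empty((nH, z_grid.size))
    pm_mat = np.empty_like(fdr_mat)
    rm_mat = np.empty_like(fdr_mat)
    r2_mat = np.empty_like(fdr_mat)
    rp_mat = np.empty_like(fdr_mat)
    w_mat = np.empty_like(fdr_mat)
    for i, H in enumerate(Hs):
        fdr_mat[i] = local_fdr(z_grid, n, H, params)
        pm_mat[i] = posterior_effect(z_grid, n, H, params)
        rm_mat[i], r2_mat[i] = replication_moments(z_grid, n, n_r, H, params)
        rp_mat[i] = replication_probability(z_grid, n, n_r, H, params, z_alpha)
        if density_weighted:
            w_mat[i] = np.exp(log_marginal_density(z_grid, n, H, params))
    if density_weighted:
        norm = w_mat.sum(axis=0)
        # fall back to flat weights where all densities underflow
        flat = norm <= 0
        w_mat[:, flat] = 1.0
        norm = w_mat.sum(axis=0)
        w = w_mat / norm
    else:
        w = np.full_like(fdr_mat, 1.0 / nH)
    return PosteriorPrediction(
        fdr=(w * fdr_mat).sum(axis=0),
        post_mean=(w * pm_mat).sum(axis=0),
        repl_mean=(w * rm_mat).sum(axis=0),
        repl_second_moment=(w * r2_mat).sum(axis=0),
        repl_prob=(w * rp_mat).sum(axis=0),
    )


@dataclass
class LookupTable:
    """Per-stratum grid mapping discovery z to posterior predictions.

    ``strata`` maps stratum index (1-based) to a dict with keys
    ``z`` (grid), ``pred`` (PosteriorPrediction arrays), ``params``
    (MixtureParams) and ``n_snps``.
    """

    n: float
    n_r: float
    z_alpha: float
    strata: dict = field(default_factory=dict)

    def to_frame(self):
        """Flatten to a long-format DataFrame (one row per stratum x grid z)."""
        import pandas as pd

        rows = []
        for s, entry in sorted(self.strata.items()):
            pred = entry["pred"]
            rows.append(
                pd.DataFrame(
                    {
                        "stratum": s,
                        "z": entry["z"],
                        "fdr": pred.fdr,
                        "post_mean": pred.post_mean,
                        "repl_mean": pred.repl_mean,
                        "repl_second_moment": pred.repl_second_moment,
                        "repl_prob": pred.repl_prob,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_lookup(
    stratum_params: dict,
    stratum_H: dict,
    n: float,
    n_r: float,
    z_alpha: float = 1.959964,
    z_max: float = 15.0,
    z_step: float = 0.01,
    max_h_points: int = 256,
    density_weighted: bool = True,
) -> LookupTable:
    """Build the fine-grid prediction lookup table, one grid per stratum.

    Parameters
    ----------
    stratum_params : dict
        Stratum index -> fitted :class:`MixtureParams`.
    stratum_H : dict
        Stratum index -> empirical H values of the stratum's SNPs.
    n, n_r : float
        Discovery and replication effective sample sizes for prediction.
    z_alpha : float
        Replication significance threshold (default: two-sided 0.05).
    """
    grid = np.arange(-z_max, z_max + z_step / 2, z_step)
    table = LookupTable(n=n, n_r=n_r, z_alpha=z_alpha)
    for s, params in stratum_params.items():
        H_sample = np.asarray(stratum_H[s], dtype=float)
        H_sample = H_sample[np.isfinite(H_sample)]
        if H_sample.size == 0:
            warnings.warn(f"stratum {s} has no H values; omitted from lookup")
            continue
        pred = predict_grid(
            grid, n, n_r, H_sample, params, z_alpha,
            max_h_points=max_h_points, density_weighted=density_weighted,
        )
        table.strata[s] = {
            "z": grid,
            "pred": pred,
            "params": params,
            "n_snps": H_sample.size,
        }
    return table


def predict_snps(lookup: LookupTable, z, stratum_index):
    """Interpolate per-SNP predictions from a lookup table.

    Linear interpolation in z on the SNP's stratum grid; z outside the
    grid is clamped to the boundary and flagged.  Returns a DataFrame
    with one row per SNP (NaN rows for SNPs whose stratum is absent).
    """
    import pandas as pd

    z = np.asarray(z, dtype=float)
    stratum_index = np.asarray(stratum_index)
    out = {
        k: np.full(z.size, np.nan)
        for k in ("fdr", "post_mean", "repl_mean", "repl_second_moment", "repl_prob")
    }
    clamped = np.zeros(z.size, dtype=bool)
    missing = np.zeros(z.size, dtype=bool)
    for s, entry in lookup.strata.items():
        mask = stratum_index == s
        if not mask.any():
            continue
        grid = entry["z"]
        zs = z[mask]
        clamped[mask] = (zs < grid[0]) | (zs > grid[-1])
        pred = entry["pred"]
        for k in out:
            out[k][mask] = np.interp(zs, grid, getattr(pred, k))
    known = set(lookup.strata)
    missing = ~np.isin(stratum_index, list(known))
    if missing.any():
        warnings.warn(f"{int(missing.sum())} SNPs in strata absent from lookup")
    df = pd.DataFrame(out)
    df["stratum"] = stratum_index
    df["clamped"] = clamped
    return df
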