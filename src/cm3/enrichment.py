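"""Relative enrichment scores and enrichment strata.

A SNP's association p-value is thresholded (default p <= 1e-3) into a
binary outcome and regressed, by multiple logistic regression, on the
SNP's auxiliary covariates (LD-weighted annotation scores, total LD,
heterozygosity, squared z of a secondary trait).  The fitted probability
P(p_i <= p_thresh | x_i) is the SNP's relative enrichment score; scores
are stratified into K disjoint bins, which downstream stages treat as
approximately exchangeable SNP sets.  The module also produces
conditional Q-Q curves per stratum and decomposes the contribution of
covariate groups by change in Nagelkerke's R^2, AUC, or adjusted R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2

#: default grouping of covariates for importance decomposition
DEFAULT_GROUPS = {
    "Annot": ["exon", "intron", "utr5", "utr3", "up1k", "up10k", "down1k", "down10k"],
    "TLD": ["tld"],
    "H": ["H"],
    "BIP": ["bip_z2"],
}


def threshold_outcome(p, p_thresh: float = 1e-3):
    """Binary outcome Y = 1 iff p <= p_thresh (inclusive)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p must be in (0, 1]")
    if not 0.0 < p_thresh < 1.0:
        raise ValueError("p_thresh must be in (0, 1)")
    return (p <= p_thresh).astype(np.int8)


@dataclass
class EnrichmentModel:
    """Fitted thresholded logistic regression.

    ``beta`` includes the intercept (index "const"); covariates were
    standardized to zero mean / unit variance at fit time when
    ``standardize`` is set (the stored means/sds are applied again at
    scoring time, so scores are invariant to affine rescaling of the
    raw covariates).
    """

    beta: pd.Series
    p_thresh: float
    columns: list
    standardize: bool
    means: pd.Series | None
    sds: pd.Series | None
    llf: float
    llnull: float
    nobs: int
    converged: bool
    training_filters: str = ""

    def design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"covariates missing from X: {missing}")
        M = X[self.columns].to_numpy(dtype=float)
        if self.standardize:
            M = (M - self.means[self.columns].to_numpy()) / self.sds[
                self.columns
            ].to_numpy()
        return np.column_stack([np.ones(len(M)), M])


def fit_enrichment_model(
    Y,
    X: pd.DataFrame,
    p_thresh: float = 1e-3,
    standardize: bool = True,
    training_filters: str = "",
) -> EnrichmentModel:
    """Maximum-likelihood logistic fit of the thresholded outcome on X.

    The caller is responsible for having already excluded the extended
    MHC and pruned the training set (r^2 < 0.8, keeping the smallest p
    per block); record that provenance in ``training_filters``.
    Collinear columns are dropped with a warning; complete separation is
    fatal.
    """
    Y = np.asarray(Y, dtype=float)
    if set(np.unique(Y)) - {0.0, 1.0}:
        raise ValueError("Y must be binary")
    if Y.min() == Y.max():
        raise ValueError("Y must contain both classes")
    cols = list(X.columns)
    M = X[cols].to_numpy(dtype=float)
    means = pd.Series(M.mean(axis=0), index=cols)
    sds = pd.Series(M.std(axis=0), index=cols)
    # drop constant columns outright; they are unidentifiable
    keep = [c for c in cols if sds[c] > 0]
    dropped = [c for c in cols if sds[c] == 0]
    M = X[keep].to_numpy(dtype=float)
    if standardize:
        M = (M - means[keep].to_numpy()) / sds[keep].to_numpy()
    # drop collinear columns via rank-revealing QR on the design
    design = np.column_stack([np.ones(len(M)), M])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    indep = diag > 1e-8 * diag.max()
    if not indep.all():
        collinear = [keep[i - 1] for i in np.flatnonzero(~indep) if i > 0]
        dropped += collinear
        keep = [c for c in keep if c not in collinear]
        M = X[keep].to_numpy(dtype=float)
        if standardize:
            M = (M - means[keep].to_numpy()) / sds[keep].to_numpy()
        design = np.column_stack([np.ones(len(M)), M])
    if dropped:
        warnings.warn(f"dropped constant/collinear covariates: {dropped}")

    model = sm.Logit(Y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises variously
        raise RuntimeError(f"logistic fit failed (separation?): {exc}") from exc
    if np.any(np.abs(res.params) > 50):
        raise RuntimeError(
            "logistic fit diverged; outcome is (quasi-)completely separated"
        )
    beta = pd.Series(res.params, index=["const"] + keep)
    return EnrichmentModel(
        beta=beta,
        p_thresh=p_thresh,
        columns=keep,
        standardize=standardize,
        means=means,
        sds=sds,
        llf=float(res.llf),
        llnull=float(res.llnull),
        nobs=int(res.nobs),
        converged=bool(res.mle_retvals.get("converged", True)),
        training_filters=training_filters,
    )


def enrichment_scores(model: EnrichmentModel, X: pd.DataFrame) -> np.ndarray:
    """Relative enrichment score: fitted P(p <= p_thresh | x), in (0, 1)."""
    design = model.design(X)
    return expit(design @ model.beta.to_numpy())


@dataclass
class EnrichmentStrata:
    """Per-SNP stratum assignment from binned enrichment scores.

    ``bin_index`` is 1..K with bin 1 the least and bin K the most
    enriched; ``edges`` are the K+1 ascending bin boundaries.
    """

    score: np.ndarray
    K: int
    edges: np.ndarray
    bin_index: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_index, minlength=self.K + 1)[1:]

    @property
    def m(self) -> int:
        return self.score.size


def stratify_scores(
    scores,
    K: int = 10,
    mode: str = "equal_width",
    min_bin_warn: int = 0,
) -> EnrichmentStrata:
    """Bin enrichment scores into K disjoint, exhaustive strata.

    ``equal_width`` (default) uses K+1 equally spaced edges spanning the
    observed score range, bins left-closed/right-open with the last bin
    right-closed; ``quantile`` uses score quantiles for near-equal
    counts.  Constant scores cannot be stratified.
    """
    scores = np.asarray(scores, dtype=float)
    if K < 2:
        raise ValueError("K must be >= 2")
    lo, hi = float(scores.min()), float(scores.max())
    if lo == hi:
        raise ValueError("scores are constant; cannot stratify")
    if mode == "equal_width":
        edges = np.linspace(lo, hi, K + 1)
    elif mode == "quantile":
        edges = np.quantile(scores, np.linspace(0, 1, K + 1))
        edges = np.unique(edges)
        if edges.size < K + 1:
            raise ValueError("too many tied scores for quantile stratification")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    idx = np.searchsorted(edges, scores, side="right")
    idx = np.clip(idx, 1, K)  # last bin right-closed
    strata = EnrichmentStrata(score=scores, K=K, edges=edges, bin_index=idx)
    if min_bin_warn:
        small = np.flatnonzero(strata.counts < min_bin_warn) + 1
        if small.size:
            warnings.warn(f"strata with fewer than {min_bin_warn} SNPs: {list(small)}")
    return strata


def conditional_qq(
    p_values,
    strata: EnrichmentStrata | None = None,
    cap_neglog10: float = 7.3,
    min_snps: int = 100,
) -> pd.DataFrame:
    """Per-stratum conditional Q-Q curves on the -log10 p scale.

    For each stratum (plus an "all" curve, stratum 0) returns pairs of
    expected quantiles under Uniform(0,1) at ranks i/(m+1) and observed
    empirical quantiles, truncated at observed -log10 p <= cap to focus
    below genome-wide significance.  Strata with fewer than ``min_snps``
    SNPs are flagged unstable.
    """
    p_values = np.asarray(p_values, dtype=float)
    if np.any((p_values <= 0) | (p_values > 1)):
        raise ValueError("p must be in (0, 1]")
    groups = {0: np.arange(p_values.size)}
    if strata is not None:
        if strata.m != p_values.size:
            raise ValueError("strata and p_values are misaligned")
        for s in range(1, strata.K + 1):
            groups[s] = np.flatnonzero(strata.bin_index == s)
    frames = []
    for s, idx in groups.items():
        if idx.size == 0:
            continue
        obs = np.sort(-np.log10(p_values[idx]))[::-1]
        ranks = np.arange(1, idx.size + 1)
        exp = -np.log10(ranks / (idx.size + 1.0))
        mask = obs <= cap_neglog10
        frames.append(
            pd.DataFrame(
                {
                    "stratum": s,
                    "expected_neglog10p": exp[mask],
                    "observed_neglog10p": obs[mask],
                    "unstable": idx.size < min_snps,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke's R^2 = (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n))."""
    if n <= 0:
        raise ValueError("n must be positive")
    num = 1.0 - np.exp((2.0 / n) * (llnull - llf))
    den = 1.0 - np.exp((2.0 / n) * llnull)
    return float(num / den)


def _fit_stat(Y, X: pd.DataFrame, cols: list, mode: str, standardize: bool):
    """Fit on a column subset, return (stat, llf, df) for the chosen mode."""
    if mode == "adj_r2":
        design = sm.add_constant(X[cols].to_numpy(dtype=float)) if cols else np.ones(
            (len(X), 1)
        )
        res = sm.OLS(np.asarray(Y, dtype=float), design).fit()
        return float(res.rsquared_adj) if cols else 0.0, float(res.llf), len(cols)
    if not cols:
        # intercept-only logistic model
        p = np.asarray(Y, dtype=float).mean()
        n = len(Y)
        llf = n * (p * np.log(p) + (1 - p) * np.log(1 - p))
        if mode == "auc":
            return 0.5, llf, 0
        return 0.0, llf, 0
    model = fit_enrichment_model(Y, X[cols], standardize=standardize)
    if mode == "nagelkerke":
        stat = nagelkerke_r2(model.llf, model.llnull, model.nobs)
    elif mode == "auc":
        from sklearn.metrics import roc_auc_score

        stat = float(roc_auc_score(Y, enrichment_scores(model, X)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return stat, model.llf, len(cols)


def importance_decomposition(
    X: pd.DataFrame,
    Y,
    mode: str = "nagelkerke",
    groups: dict | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Covariate-group importance by full-vs-reduced model comparison.

    For each group g the statistic of the full model (all covariates)
    is compared with the model refitted without g; the difference
    ``delta`` measures g's contribution.  ``mode`` selects Nagelkerke's
    R^2 or AUC of the thresholded logistic fit, or adjusted R^2 of a
    linear regression of z^2 (pass z^2 as Y) on the covariates.  A
    likelihood-ratio chi-square p-value per group is included for the
    likelihood-based modes.
    """
    groups = groups or {
        k: [c for c in v if c in X.columns] for k, v in DEFAULT_GROUPS.items()
    }
    all_cols = [c for cols in groups.values() for c in cols]
    if len(all_cols) != len(set(all_cols)):
        raise ValueError("groups must not overlap")
    extra = set(all_cols) - set(X.columns)
    if extra:
        raise ValueError(f"groups name covariates absent from X: {sorted(extra)}")
    full_stat, full_llf, full_df = _fit_stat(Y, X, all_cols, mode, standardize)
    rows = []
    for g, cols in groups.items():
        reduced = [c for c in all_cols if c not in cols]
        red_stat, red_llf, red_df = _fit_stat(Y, X, reduced, mode, standardize)
        lr = 2.0 * (full_llf - red_llf)
        df = full_df - red_df
        p_lr = float(chi2.sf(max(lr, 0.0), df)) if df > 0 else np.nan
        rows.append(
            {
                "group": g,
                "delta": full_stat - red_stat,
                "full_stat": full_stat,
                "reduced_stat": red_stat,
                "lr_pvalue": p_lr,
            }
        )
    return pd.DataFrame(rows)
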