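"""Random sub-study partitioning and nonparametric replication curves.

The J sub-studies are repeatedly and randomly partitioned into a
discovery subset and its complement; sample-size-weighted meta-analysis
z-scores are computed for both halves, and per-SNP (discovery,
replication) pairs are accumulated into equal-width bins over the
discovery axis.  Each iteration yields unbiased estimates of the
conditional replication moments given the discovery z; averaging over
iterations (count-weighted, i.e. pooling all SNP-iteration pairs) only
smooths out partition noise.  Curves can be computed per enrichment
stratum and smoothed with a count-weighted cubic regression spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import as_seedseq

from .sumstats import SubStudyPanel, p_from_z


@dataclass(frozen=True)
class PartitionScheme:
    """How to split J sub-studies, how often, and under which seed."""

    J: int
    n_discovery: int
    iterations: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_discovery < self.J:
            raise ValueError("need 1 <= n_discovery < J")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def partition_substudies(J: int, n_disc: int, seed=None):
    """Uniform random discovery subset of size n_disc; complement replicates."""
    if not 1 <= n_disc < J:
        raise ValueError("need 1 <= n_disc < J")
    rng = np.random.default_rng(seed)
    disc = np.sort(rng.choice(J, size=n_disc, replace=False))
    repl = np.setdiff1d(np.arange(J), disc)
    return disc, repl


def meta_z(panel: SubStudyPanel, ids) -> tuple[np.ndarray, float]:
    """Sample-size-weighted meta-analysis z over a study subset.

    z_meta,i = sum_j sqrt(n_j) z_ij / sqrt(sum_j n_j) — the
    inverse-variance weighting of standardized effects.  Studies where a
    SNP is missing (NaN) are omitted for that SNP with the normalizer
    adjusted; a SNP missing everywhere yields NaN.  Returns the per-SNP
    meta z and the subset's total effective sample size (the nominal
    sum; per-SNP adjusted sizes only differ under missingness).
    """
    ids = np.asarray(ids, dtype=int)
    if ids.size == 0:
        raise ValueError("study subset is empty")
    z = panel.z[:, ids]
    w = np.sqrt(panel.n_eff[ids])
    if not np.isnan(z).any():
        zm = (z @ w) / np.sqrt(panel.n_eff[ids].sum())
        return zm, float(panel.n_eff[ids].sum())
    present = ~np.isnan(z)
    num = np.nansum(z * w[None, :], axis=1)
    denom_sq = (present * panel.n_eff[ids][None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zm = num / np.sqrt(denom_sq)
    zm[denom_sq == 0] = np.nan
    return zm, float(panel.n_eff[ids].sum())


@dataclass
class BinnedCurve:
    """Equal-width binned summaries over a discovery axis.

    ``value`` holds the per-bin mean (or rate); ``second`` the per-bin
    mean square where applicable.  ``count`` is the number of
    contributing SNP-iteration pairs; empty bins have NaN values.
    """

    edges: np.ndarray
    count: np.ndarray
    value: np.ndarray
    second: np.ndarray | None = None
    smoothed: np.ndarray | None = None

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def nonempty(self) -> np.ndarray:
        return self.count > 0


class _CurveAccumulator:
    """Streaming per-bin count/sum/sum-of-squares over iterations."""

    def __init__(self, edges: np.ndarray, track_second: bool = True) -> None:
        self.edges = edges
        n = edges.size - 1
        self.count = np.zeros(n, dtype=np.int64)
        self.sum = np.zeros(n)
        self.sum2 = np.zeros(n) if track_second else None

    def add(self, x: np.ndarray, y: np.ndarray) -> None:
        ok = np.isfinite(x) & np.isfinite(y)
        ok &= (x >= self.edges[0]) & (x <= self.edges[-1])
        x, y = x[ok], y[ok]
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1,
                      0, self.edges.size - 2)
        self.count += np.bincount(idx, minlength=self.count.size)
        self.sum += np.bincount(idx, weights=y, minlength=self.count.size)
        if self.sum2 is not None:
            self.sum2 += np.bincount(idx, weights=y * y, minlength=self.count.size)

    def curve(self) -> BinnedCurve:
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(self.count > 0, self.sum / np.maximum(self.count, 1), np.nan)
            second = (
                np.where(self.count > 0, self.sum2 / np.maximum(self.count, 1), np.nan)
                if self.sum2 is not None
                else None
            )
        return BinnedCurve(edges=self.edges, count=self.count.copy(),
                           value=value, second=second)


def binned_replication_curves(
    z_disc,
    z_repl,
    n_bins: int = 1001,
    z_range=(-15.0, 15.0),
) -> BinnedCurve:
    """Per-bin mean and mean square of replication z given discovery z."""
    lo, hi = z_range
    if not hi > lo:
        raise ValueError("degenerate z_range")
    acc = _CurveAccumulator(np.linspace(lo, hi, n_bins + 1))
    acc.add(np.asarray(z_disc, dtype=float), np.asarray(z_repl, dtype=float))
    return acc.curve()


def binned_replication_rate(
    p_disc,
    p_repl,
    n_bins: int = 1001,
    neglog10p_range=(0.0, 12.0),
    alpha: float = 0.05,
    sign_consistent: bool = False,
    z_disc=None,
    z_repl=None,
) -> BinnedCurve:
    """Empirical replication rate per bin of discovery -log10 p.

    Rate = fraction of SNP pairs in the bin with replication p < alpha,
    optionally also requiring the replication z to share the discovery
    z's sign (pass both z vectors).  Without the sign requirement a pure
    null replicates at ~alpha per bin; with it, at ~alpha/2.
    """
    p_disc = np.asarray(p_disc, dtype=float)
    p_repl = np.asarray(p_repl, dtype=float)
    hit = (p_repl < alpha).astype(float)
    if sign_consistent:
        if z_disc is None or z_repl is None:
            raise ValueError("sign_consistent requires z_disc and z_repl")
        hit *= (np.sign(z_disc) == np.sign(z_repl)).astype(float)
    lo, hi = neglog10p_range
    acc = _CurveAccumulator(np.linspace(lo, hi, n_bins + 1), track_second=False)
    with np.errstate(divide="ignore"):
        x = -np.log10(p_disc)
    acc.add(x, hit)
    return acc.curve()


def smooth_curve(curve: BinnedCurve, n_knots: int = 20, min_bins: int = 10) -> BinnedCurve:
    """Count-weighted cubic regression spline over nonempty bins.

    Interior knots sit at count-weighted quantiles of the bin midpoints
    (deduplicated, reduced as needed to satisfy the spline's
    interlacing conditions).  With fewer than ``min_bins`` nonempty bins
    the raw curve is returned unchanged with a warning.
    """
    import warnings

    from scipy.interpolate import LSQUnivariateSpline

    ok = curve.nonempty & np.isfinite(curve.value)
    if ok.sum() < min_bins:
        warnings.warn("too few nonempty bins to smooth; returning raw curve")
        return curve
    x = curve.midpoints[ok]
    y = curve.value[ok]
    w = np.sqrt(curve.count[ok].astype(float))
    cum = np.cumsum(curve.count[ok]) / curve.count[ok].sum()
    knots = None
    for k in range(min(n_knots, max(ok.sum() - 8, 0)), -1, -1):
        if k == 0:
            t = np.array([])
        else:
            q = (np.arange(k) + 1.0) / (k + 1.0)
            t = np.unique(np.interp(q, cum, x))
            t = t[(t > x[0]) & (t < x[-1])]
        try:
            spl = LSQUnivariateSpline(x, y, t, w=w, k=3)
            knots = t
            break
        except ValueError:
            continue
    if knots is None:  # pragma: no cover - k=0 always satisfiable for >=4 pts
        warnings.warn("spline fit failed; returning raw curve")
        return curve
    smoothed = np.full_like(curve.value, np.nan)
    smoothed[ok] = spl(x)
    return replace(curve, smoothed=smoothed)


@dataclass
class ResamplingResult:
    """Per-stratum pooled curves from a resampling run.

    Keys of the per-stratum dicts are stratum indices (1..K, or 0 for
    the unstratified curve when no strata were given).  ``n_disc`` and
    ``n_repl`` are the across-iteration average discovery/replication
    effective sample sizes.
    """

    moment_curves: dict
    rate_curves: dict
    n_disc: float
    n_repl: float
    iterations: int
    pairs: list = field(default_factory=list)


def run_resampling(
    panel: SubStudyPanel,
    scheme: PartitionScheme,
    stratum_index=None,
    n_bins: int = 1001,
    z_range=(-15.0, 15.0),
    neglog10p_range=(0.0, 12.0),
    alpha: float = 0.05,
    sign_consistent: bool = False,
    ld=None,
    prune_r2: float = 0.8,
    prune_each_iter: bool = False,
    keep_pairs: bool = False,
) -> ResamplingResult:
    """Stratified nonparametric replication curves over random partitions.

    For every iteration: draw a random discovery/replication partition
    of the sub-studies, meta-analyze both halves, optionally randomly
    LD-prune the SNP set (fresh seed per iteration), and accumulate the
    per-stratum binned mean/second-moment curves (over discovery z) and
    replication-rate curves (over discovery -log10 p).  Final curves
    pool all SNP-iteration pairs, which equals the count-weighted
    across-iteration average.  Per-iteration seeds derive
    deterministically from the scheme's master seed.
    """
    if scheme.J != panel.J:
        raise ValueError("scheme J does not match the panel")
    if stratum_index is None:
        stratum_index = np.zeros(panel.m, dtype=int)
        strata_ids = [0]
    else:
        stratum_index = np.asarray(stratum_index)
        if stratum_index.size != panel.m:
            raise ValueError("stratum index misaligned with panel")
        strata_ids = sorted(np.unique(stratum_index))
    if prune_each_iter and ld is None:
        raise ValueError("per-iteration pruning requires an LD panel")

    z_edges = np.linspace(z_range[0], z_range[1], n_bins + 1)
    p_edges = np.linspace(neglog10p_range[0], neglog10p_range[1], n_bins + 1)
    mom = {s: _CurveAccumulator(z_edges) for s in strata_ids}
    rate = {s: _CurveAccumulator(p_edges, track_second=False) for s in strata_ids}
    masks = {s: stratum_index == s for s in strata_ids}

    ss = as_seedseq(scheme.seed)
    child_seeds = ss.spawn(scheme.iterations)
    sum_nd = sum_nr = 0.0
    pairs = []
    for it in range(scheme.iterations):
        it_ss = child_seeds[it]
        s_part, s_prune = it_ss.spawn(2)
        disc, repl = partition_substudies(scheme.J, scheme.n_discovery, seed=s_part)
        zd, nd = meta_z(panel, disc)
        zr, nr = meta_z(panel, repl)
        sum_nd += nd
        sum_nr += nr
        if prune_each_iter:
            from .ld import random_prune

            kept = random_prune(panel.snps, ld, prune_r2, seed=s_prune)
            keep_mask = panel.snps["snp_id"].isin(set(kept["snp_id"])).to_numpy()
        else:
            keep_mask = np.ones(panel.m, dtype=bool)
        pd_disc = p_from_z(zd)
        pr = p_from_z(zr)
        for s in strata_ids:
            msk = masks[s] & keep_mask
            mom[s].add(zd[msk], zr[msk])
            hit = (pr[msk] < alpha).astype(float)
            if sign_consistent:
                hit *= (np.sign(zd[msk]) == np.sign(zr[msk])).astype(float)
            with np.errstate(divide="ignore"):
                rate[s].add(-np.log10(pd_disc[msk]), hit)
        if keep_pairs:
            pairs.append((zd, zr, keep_mask))
    return ResamplingResult(
        moment_curves={s: mom[s].curve() for s in strata_ids},
        rate_curves={s: rate[s].curve() for s in strata_ids},
        n_disc=sum_nd / scheme.iterations,
        n_repl=sum_nr / scheme.iterations,
        iterations=scheme.iterations,
        pairs=pairs,
    )
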