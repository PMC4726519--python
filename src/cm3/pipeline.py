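"""End-to-end orchestration: rank, evaluate, and report loci.

Ties the stages together: meta-analyze, build the enrichment strata,
run the resampling, fit the per-stratum mixtures, build the prediction
lookup, rank SNPs by predicted replication probability, compare the
resulting out-of-sample yield against nominal-p ranking, and clump the
confident SNPs into independent loci.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import as_seedseq
import pandas as pd

from . import enrichment as enr
from . import estimation as est
from . import ld as ldmod
from . import mixture as mix
from . import resampling as rs
from . import simulate as sim
from .sumstats import SubStudyPanel, p_from_z, write_table


def rank_snps(predictions: pd.DataFrame, by: str = "pred_repl_desc") -> pd.DataFrame:
    """Total ordering of SNPs for follow-up.

    ``pred_repl_desc`` sorts by predicted replication probability, best
    first, breaking ties by smaller p then snp_id; ``p_asc`` is the
    standard GWAS ranking with pred_repl then snp_id as tie-breakers.
    """
    if by == "pred_repl_desc":
        keys, asc = ["pred_repl", "p", "snp_id"], [False, True, True]
    elif by == "p_asc":
        keys, asc = ["p", "pred_repl", "snp_id"], [True, False, True]
    else:
        raise ValueError(f"unknown ranking {by!r}")
    missing = [k for k in keys if k not in predictions.columns]
    if missing:
        raise ValueError(f"ranking requires columns {missing}")
    return predictions.sort_values(keys, ascending=asc, kind="stable").reset_index(
        drop=True
    )


def cumulative_replication_curve(
    repl_p_ordered, alpha: float = 0.05, sign_ok_ordered=None
) -> np.ndarray:
    """Cumulative fraction of the top-k SNPs that replicate, for each k.

    ``repl_p_ordered`` must already be in ranking order; a SNP counts as
    replicated when its replication p < alpha (optionally also requiring
    ``sign_ok_ordered``, a boolean sign-consistency vector).
    """
    repl_p_ordered = np.asarray(repl_p_ordered, dtype=float)
    hit = (repl_p_ordered < alpha).astype(float)
    if sign_ok_ordered is not None:
        hit *= np.asarray(sign_ok_ordered, dtype=float)
    k = np.arange(1, hit.size + 1)
    return np.cumsum(hit) / k


def yield_at_rate(cum_curve, rate: float = 0.5) -> int:
    """Largest prefix size whose cumulative replication rate is >= rate."""
    cum_curve = np.asarray(cum_curve, dtype=float)
    ok = np.flatnonzero(cum_curve >= rate)
    return int(ok[-1] + 1) if ok.size else 0


def loci_report(
    predictions: pd.DataFrame,
    ld: ldmod.LdPanel,
    threshold: float = 0.8,
    r2_max: float = 0.1,
    dist_bp: int = 250_000,
    ablation_column: str | None = None,
) -> pd.DataFrame:
    """Independent loci with predicted replication probability >= threshold.

    Filters, removes the extended MHC, then LD-clumps (r^2 < 0.1, merge
    within 250 kbp) keeping the largest-pred_repl lead per locus.  The
    result follows the standard loci-table schema (Loci, LeadingSNP, A1,
    Chrnum, Pos, Pred_Repl, P); an optional ablation column (predictions
    recomputed without one covariate group) is carried through.
    """
    req = {"snp_id", "chrom", "pos", "a1", "p", "pred_repl"}
    missing = req - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions missing columns: {sorted(missing)}")
    sel = predictions.loc[predictions["pred_repl"] >= threshold]
    sel = ldmod.exclude_xmhc(sel)
    cols = ["Loci", "LeadingSNP", "A1", "Chrnum", "Pos", "Pred_Repl", "P"]
    if ablation_column:
        cols.append(ablation_column)
    if len(sel) == 0:
        return pd.DataFrame(columns=cols)
    leads = ldmod.clump_loci(
        sel, ld, criterion="pred_repl", r2_max=r2_max, dist_bp=dist_bp,
        ascending=False,
    )
    out = pd.DataFrame(
        {
            "Loci": leads["locus"],
            "LeadingSNP": leads["snp_id"],
            "A1": leads["a1"],
            "Chrnum": leads["chrom"],
            "Pos": leads["pos"],
            "Pred_Repl": leads["pred_repl"],
            "P": leads["p"],
        }
    )
    if ablation_column:
        out[ablation_column] = leads[ablation_column].to_numpy()
    return out


@dataclass
class Cm3Fit:
    """A fitted CM3 model: enrichment strata + per-stratum mixtures."""

    model: enr.EnrichmentModel
    strata: enr.EnrichmentStrata
    fits: dict
    targets: est.EmpiricalTargets
    fit_studies: np.ndarray
    n_fit_total: float


def fit_cm3(
    panel: SubStudyPanel,
    covariates: pd.DataFrame,
    study_subset=None,
    p_thresh: float = 1e-3,
    K: int | None = None,
    bin_mode: str = "equal_width",
    fractions=est.DEFAULT_FRACTIONS,
    iterations: int = 50,
    n_restarts: int = 8,
    lam: float = 1.0,
    seed=None,
    ld: ldmod.LdPanel | None = None,
    prune_each_iter: bool = False,
    n_bins: int = 1001,
    covariate_columns=None,
) -> Cm3Fit:
    """Fit the full covariate-modulated mixture model.

    Steps: meta-analyze the fitting studies, threshold the p-values and
    fit the enrichment logistic regression, stratify the scores into K
    bins, run the resampling over the discovery fractions within the
    fitting studies, and fit each stratum's mixture parameters.  Pass
    ``study_subset`` to restrict every fitting stage to those studies
    (out-of-sample mode); downstream evaluation then only needs the
    complementary studies.
    """
    if study_subset is None:
        study_subset = np.arange(panel.J)
    study_subset = np.asarray(study_subset, dtype=int)
    if study_subset.size < 2:
        raise ValueError("need at least 2 studies to fit")
    sub = SubStudyPanel(
        snps=panel.snps,
        z=panel.z[:, study_subset],
        n_eff=panel.n_eff[study_subset],
        labels=[panel.labels[j] for j in study_subset],
    )
    if K is None:
        K = 10 if panel.m >= 100_000 else 6
    z_meta, n_total = rs.meta_z(sub, np.arange(sub.J))
    p_meta = p_from_z(z_meta)
    cov_cols = list(covariate_columns) if covariate_columns is not None else [
        c for c in sim.COVARIATE_COLUMNS if c in covariates.columns
    ]
    Y = enr.threshold_outcome(p_meta, p_thresh)
    model = enr.fit_enrichment_model(
        Y, covariates[cov_cols], p_thresh=p_thresh,
        training_filters="meta-analysis of fitting studies",
    )
    scores = enr.enrichment_scores(model, covariates)
    strata = enr.stratify_scores(scores, K=K, mode=bin_mode)
    targets = est.empirical_target_set(
        sub,
        covariates["H"].to_numpy(),
        stratum_index=strata.bin_index,
        fractions=fractions,
        iterations=iterations,
        seed=as_seedseq(seed).spawn(1)[0],
        n_bins=n_bins,
        ld=ld,
        prune_each_iter=prune_each_iter,
    )
    fits = est.fit_all_strata(
        targets, n_restarts=n_restarts, lam=lam,
        seed=as_seedseq(seed).spawn(2)[1],
    )
    return Cm3Fit(
        model=model, strata=strata, fits=fits, targets=targets,
        fit_studies=study_subset, n_fit_total=n_total,
    )


def predictions_frame(
    fit: Cm3Fit,
    panel: SubStudyPanel,
    n: float,
    n_r: float,
    z=None,
    z_alpha: float = 1.959964,
    z_max: float = 15.0,
    z_step: float = 0.01,
    max_h_points: int = 256,
) -> pd.DataFrame:
    """Per-SNP predictions from a fitted model at a stated design.

    Builds the per-stratum lookup at discovery size ``n`` and
    replication size ``n_r`` and interpolates each SNP's z (default:
    the meta-analysis z over the fitting studies, rescaled to size n).
    """
    if z is None:
        sub_ids = fit.fit_studies
        z_full, n_full = rs.meta_z(
            SubStudyPanel(
                snps=panel.snps, z=panel.z[:, sub_ids],
                n_eff=panel.n_eff[sub_ids],
                labels=[panel.labels[j] for j in sub_ids],
            ),
            np.arange(sub_ids.size),
        )
        z = z_full * np.sqrt(n / n_full) if abs(n - n_full) > 1e-9 else z_full
    lookup = mix.build_lookup(
        {s: fr.params for s, fr in fit.fits.items()},
        fit.targets.H_by_stratum,
        n=n, n_r=n_r, z_alpha=z_alpha, z_max=z_max, z_step=z_step,
        max_h_points=max_h_points,
    )
    pred = mix.predict_snps(lookup, z, fit.strata.bin_index)
    out = panel.snps.copy()
    out["z"] = np.asarray(z, dtype=float)
    out["p"] = p_from_z(out["z"].to_numpy())
    for c in ("stratum", "fdr", "post_mean", "repl_mean", "repl_prob", "clamped"):
        out[c] = pred[c].to_numpy()
    out["pred_repl"] = out["repl_prob"]
    return out


@dataclass
class YieldComparison:
    """Average yield of pred-repl vs p ranking at a target rate."""

    rate: float
    yield_pred: float
    yield_p: float
    curves_pred: list = field(default_factory=list)
    curves_p: list = field(default_factory=list)


def evaluate_yield(
    panel: SubStudyPanel,
    fit: Cm3Fit,
    eval_iterations: int = 20,
    seed=None,
    alpha: float = 0.05,
    rate: float = 0.5,
    restrict_to_fit_studies: bool = False,
    z_alpha: float = 1.959964,
    max_h_points: int = 64,
) -> YieldComparison:
    """Out-of-sample yield comparison over random split halves.

    For each iteration the panel's studies are split in half; SNPs are
    ranked once by predicted replication probability (lookup evaluated
    at the iteration's discovery z) and once by the discovery p-value,
    and the cumulative empirical replication rate of each ordering is
    measured on the held-out half.  Reports the average number of SNPs
    whose cumulative replication rate stays at or above ``rate``.
    """
    eligible = (
        fit.fit_studies if restrict_to_fit_studies else np.arange(panel.J)
    )
    J = eligible.size
    ss = as_seedseq(seed)
    child = ss.spawn(eval_iterations)
    yields_pred, yields_p = [], []
    curves_pred, curves_p = [], []
    for it in range(eval_iterations):
        disc_rel, repl_rel = rs.partition_substudies(J, J // 2, seed=child[it])
        disc, repl = eligible[disc_rel], eligible[repl_rel]
        sub = lambda ids: SubStudyPanel(  # noqa: E731
            snps=panel.snps, z=panel.z[:, ids], n_eff=panel.n_eff[ids],
            labels=[panel.labels[j] for j in ids],
        )
        zd, nd = rs.meta_z(sub(disc), np.arange(disc.size))
        zr, nr = rs.meta_z(sub(repl), np.arange(repl.size))
        lookup = mix.build_lookup(
            {s: fr.params for s, fr in fit.fits.items()},
            fit.targets.H_by_stratum,
            n=nd, n_r=nr, z_alpha=z_alpha, max_h_points=max_h_points,
            z_step=0.05,
        )
        pred = mix.predict_snps(lookup, zd, fit.strata.bin_index)
        df = pd.DataFrame(
            {
                "snp_id": panel.snps["snp_id"],
                "p": p_from_z(zd),
                "pred_repl": pred["repl_prob"].to_numpy(),
                "repl_p": p_from_z(zr),
            }
        ).dropna(subset=["pred_repl"])
        for by, ys, cs in (
            ("pred_repl_desc", yields_pred, curves_pred),
            ("p_asc", yields_p, curves_p),
        ):
            ranked = rank_snps(df, by=by)
            curve = cumulative_replication_curve(ranked["repl_p"].to_numpy(), alpha)
            ys.append(yield_at_rate(curve, rate))
            cs.append(curve)
    return YieldComparison(
        rate=rate,
        yield_pred=float(np.mean(yields_pred)),
        yield_p=float(np.mean(yields_p)),
        curves_pred=curves_pred,
        curves_p=curves_p,
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute a full synthetic-data run and write all artifacts.

    Config keys (all optional except ``simulate``):

    - ``seed``: master seed for every stage.
    - ``simulate``: m, J, params {pi1, sigma0_sq, sigma1_sq, sigma2_sq},
      effect_map, noise_sd, n_range.
    - ``enrichment``: p_thresh, bins, bin_mode.
    - ``resampling``: fractions, iterations, n_bins.
    - ``fit``: restarts, lam.
    - ``lookup``: z_alpha, z_max, z_step.
    - ``report``: thresholds (list), rate, eval_iterations.
    - ``mode``: "in_sample" (fit on all studies) or "out_of_sample"
      (fit on a random half, evaluate on the rest).

    Returns a dict of in-memory artifacts; TSV artifacts are written
    under ``out_dir`` stamped with a config hash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    simc = config["simulate"]
    params = mix.MixtureParams(**simc["params"])
    ss = as_seedseq(seed)
    s_data, s_fit, s_eval = ss.spawn(3)
    data = sim.simulate_enriched_dataset(
        m=simc["m"], J=simc["J"], params=params,
        effect_map=simc.get("effect_map"), noise_sd=simc.get("noise_sd", 0.0),
        n_range=tuple(simc.get("n_range", (1_000, 4_000))), seed=s_data,
    )
    panel, cov = data.panel, data.covariates

    mode = config.get("mode", "in_sample")
    if mode == "out_of_sample":
        disc_studies, _ = rs.partition_substudies(panel.J, panel.J // 2, seed=s_fit)
        study_subset = disc_studies
    elif mode == "in_sample":
        study_subset = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    enrc = config.get("enrichment", {})
    resc = config.get("resampling", {})
    fitc = config.get("fit", {})
    fit = fit_cm3(
        panel, cov,
        study_subset=study_subset,
        p_thresh=enrc.get("p_thresh", 1e-3),
        K=enrc.get("bins"),
        bin_mode=enrc.get("bin_mode", "equal_width"),
        fractions=tuple(resc.get("fractions", est.DEFAULT_FRACTIONS)),
        iterations=resc.get("iterations", 50),
        n_bins=resc.get("n_bins", 1001),
        n_restarts=fitc.get("restarts", 8),
        lam=fitc.get("lam", 1.0),
        seed=s_fit,
    )

    lookc = config.get("lookup", {})
    n_total = panel.n_total if study_subset is None else float(
        panel.n_eff[study_subset].sum()
    )
    pred = predictions_frame(
        fit, panel, n=n_total, n_r=n_total,
        z_alpha=lookc.get("z_alpha", 1.959964),
        z_max=lookc.get("z_max", 15.0), z_step=lookc.get("z_step", 0.01),
    )
    repc = config.get("report", {})
    comparison = evaluate_yield(
        panel, fit,
        eval_iterations=repc.get("eval_iterations", 20),
        seed=s_eval, rate=repc.get("rate", 0.5),
    )

    stamp = _config_hash(config)
    report = est.fit_report(fit.fits)
    report.to_csv(out_dir / f"fits_{stamp}.tsv", sep="\t", index=False)
    write_table(
        pred.rename(columns={})[
            ["snp_id", "chrom", "pos", "z", "p", "stratum", "fdr",
             "post_mean", "repl_mean", "repl_prob", "pred_repl"]
        ],
        out_dir / f"predictions_{stamp}.tsv",
        kind="predictions",
    )
    summary = {
        "config_hash": stamp,
        "seed": seed,
        "mode": mode,
        "m": panel.m,
        "J": panel.J,
        "yield_pred_repl": comparison.yield_pred,
        "yield_p": comparison.yield_p,
        "rate": comparison.rate,
    }
    with open(out_dir / f"summary_{stamp}.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {
        "data": data,
        "fit": fit,
        "predictions": pred,
        "comparison": comparison,
        "summary": summary,
    }
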