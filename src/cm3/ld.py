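"""Linkage-disequilibrium utilities on a genotype reference panel.

r^2 between two SNPs is the squared Pearson correlation of their
genotype dosage vectors; pairs with an undefined correlation (a
monomorphic SNP) count as 0, and pairs farther apart than the window
(default 1 Mbp) are treated as unlinked.  On top of the pairwise query
this module provides the per-SNP LD-derived covariates — LD-weighted
annotation scores, total LD, heterozygosity — plus the extended-MHC
exclusion and the greedy pruning/clumping operators used throughout the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: extended MHC region, chr6, 1-based inclusive at both ends
XMHC_CHROM = "6"
XMHC_START = 25652429
XMHC_END = 33368333

#: the eight LD-weighted positional annotation categories
ANNOTATION_CATEGORIES = (
    "exon", "intron", "utr5", "utr3",
    "up1k", "up10k", "down1k", "down10k",
)


def _snap_unit(r2):
    """Clip r^2 into [0, 1], snapping float noise at the top to exactly 1.

    Perfectly duplicated dosage columns must give r^2 = 1 so that the
    inclusive score bound of 1.0 behaves as stated.
    """
    out = np.clip(r2, 0.0, 1.0)
    return np.where(out > 1.0 - 1e-12, 1.0, out) if np.ndim(out) else (
        1.0 if out > 1.0 - 1e-12 else float(out)
    )


def heterozygosity(maf):
    """H = 2k(1-k) for minor allele frequency k in [0, 0.5]."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("minor allele frequency must be in [0, 0.5]")
    return 2.0 * maf * (1.0 - maf)


@dataclass
class LdPanel:
    """Genotype reference panel with windowed pairwise-r^2 queries.

    ``genotypes`` is an (n_samples, m) dosage matrix; ``snps`` a frame
    with snp_id / chrom / pos (1-based) aligned to its columns.  SNPs
    must be sorted by (chrom, pos).  ``window_bp`` bounds the range of
    the LD queries: pairs farther apart, or on different chromosomes,
    have r^2 = 0.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be (n_samples, m)")
        if self.genotypes.shape[1] != len(self.snps):
            raise ValueError("genotype columns and snp rows differ")
        self.snps = self.snps.reset_index(drop=True)
        order_ok = (
            self.snps.sort_values(["chrom", "pos"], kind="stable").index
            == self.snps.index
        ).all()
        if not order_ok:
            raise ValueError("panel SNPs must be sorted by (chrom, pos)")
        g = self.genotypes
        mean = g.mean(axis=0)
        sd = g.std(axis=0)
        self._poly = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            self._std = np.where(self._poly, (g - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        freq = mean / 2.0
        self._maf = np.minimum(freq, 1.0 - freq)
        self._id_to_idx = {s: i for i, s in enumerate(self.snps["snp_id"])}

    @classmethod
    def from_vcf(cls, path, window_bp: int = 1_000_000) -> "LdPanel":
        """Load biallelic sites from a VCF into an in-memory panel."""
        from cyvcf2 import VCF

        rows, dosages = [], []
        for var in VCF(str(path)):
            if len(var.ALT) != 1:
                continue
            gt = np.asarray(var.gt_types, dtype=float)
            # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            dose = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
            dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
            rows.append(
                {
                    "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": str(var.CHROM).removeprefix("chr"),
                    "pos": var.POS,
                }
            )
            dosages.append(dose)
        snps = pd.DataFrame(rows)
        return cls(np.array(dosages).T, snps, window_bp=window_bp)

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return self._maf

    def index_of(self, snp_id: str) -> int:
        return self._id_to_idx[snp_id]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of panel SNPs within the bp window of SNP i (incl. i)."""
        chrom = self.snps["chrom"].iat[i]
        pos = self.snps["pos"].iat[i]
        sub = self.snps.index[
            (self.snps["chrom"] == chrom)
            & (self.snps["pos"] >= pos - self.window_bp)
            & (self.snps["pos"] <= pos + self.window_bp)
        ]
        return sub.to_numpy()

    def r2(self, i: int, j: int) -> float:
        """Squared dosage correlation; 0 if monomorphic or out of window."""
        if i == j:
            return 1.0 if self._poly[i] else 0.0
        if not (self._poly[i] and self._poly[j]):
            return 0.0
        if self.snps["chrom"].iat[i] != self.snps["chrom"].iat[j]:
            return 0.0
        if abs(int(self.snps["pos"].iat[i]) - int(self.snps["pos"].iat[j])) > self.window_bp:
            return 0.0
        r = float(self._std[:, i] @ self._std[:, j]) / self.genotypes.shape[0]
        return _snap_unit(r * r)

    def r2_profile(self, i: int, js: np.ndarray) -> np.ndarray:
        """Vectorized r^2 of SNP i against an index array js (same window rules)."""
        js = np.asarray(js, dtype=int)
        n = self.genotypes.shape[0]
        r = (self._std[:, js].T @ self._std[:, i]) / n
        out = _snap_unit(r * r)
        chrom = self.snps["chrom"].iat[i]
        pos = int(self.snps["pos"].iat[i])
        same_chrom = self.snps["chrom"].to_numpy()[js] == chrom
        close = np.abs(self.snps["pos"].to_numpy()[js] - pos) <= self.window_bp
        out = np.where(same_chrom & close & self._poly[js] & self._poly[i], out, 0.0)
        out[js == i] = 1.0 if self._poly[i] else 0.0
        return out


@dataclass
class CovariateRow:
    """Per-SNP enrichment predictors (one row of the covariate table)."""

    snp_id: str
    scores: dict
    tld: float
    H: float
    bip_z2: float


def annotation_scores(
    ld: LdPanel,
    category_positions: dict,
    tags: pd.DataFrame,
) -> pd.DataFrame:
    """LD-weighted annotation scores for tag SNPs.

    ``category_positions`` maps a category name to a set of (chrom, pos)
    tuples (1-based) of panel SNPs in that category.  The score of a tag
    for a category is the sum of r^2 between the tag and every panel SNP
    in the category within the window (the tag's own self-term counts if
    the tag itself sits in the category).  Membership uses the inclusive
    lower bound of 1.0; tags with all scores below 1 are labeled
    intergenic.  Tags absent from the panel get NaN scores.
    """
    cats = list(category_positions)
    cat_masks = {}
    panel_keys = list(zip(ld.snps["chrom"].astype(str), ld.snps["pos"].astype(int)))
    for cat in cats:
        wanted = {(str(c), int(p)) for c, p in category_positions[cat]}
        cat_masks[cat] = np.array([k in wanted for k in panel_keys])

    rows = []
    for snp_id in tags["snp_id"]:
        row = {"snp_id": snp_id}
        if snp_id not in ld._id_to_idx:
            for cat in cats:
                row[cat] = np.nan
            row["category"] = "missing"
            rows.append(row)
            continue
        i = ld.index_of(snp_id)
        js = ld.neighbors(i)
        r2s = ld.r2_profile(i, js)
        member = []
        for cat in cats:
            score = float(r2s[cat_masks[cat][js]].sum())
            row[cat] = score
            if score >= 1.0:
                member.append(cat)
        row["category"] = ",".join(member) if member else "intergenic"
        rows.append(row)
    return pd.DataFrame(rows)


def total_ld(ld: LdPanel, tags: pd.DataFrame, include_self: bool = True) -> pd.Series:
    """Total LD: sum of r^2 of each tag with all panel SNPs in window.

    The self-term (r^2 = 1) is included by default, so TLD >= 1 for any
    polymorphic tag present in the panel.
    """
    out = []
    for snp_id in tags["snp_id"]:
        if snp_id not in ld._id_to_idx:
            out.append(np.nan)
            continue
        i = ld.index_of(snp_id)
        js = ld.neighbors(i)
        r2s = ld.r2_profile(i, js)
        tot = float(r2s.sum())
        if not include_self:
            tot -= float(r2s[js == i].sum())
        out.append(tot)
    return pd.Series(out, index=tags.index, name="tld")


def exclude_xmhc(snps: pd.DataFrame) -> pd.DataFrame:
    """Drop SNPs in the extended MHC (chr6:25652429-33368333, inclusive)."""
    chrom = snps["chrom"].astype(str).str.replace("^chr", "", regex=True)
    in_region = (
        (chrom == XMHC_CHROM)
        & (snps["pos"] >= XMHC_START)
        & (snps["pos"] <= XMHC_END)
    )
    return snps.loc[~in_region].reset_index(drop=True)


def _greedy_prune(snps: pd.DataFrame, ld: LdPanel, r2_max: float, order: np.ndarray):
    """Greedy acceptance in the given visiting order; returns kept row labels."""
    idx_panel = np.array([ld.index_of(s) for s in snps["snp_id"]])
    kept_rows: list[int] = []
    kept_panel: list[int] = []
    for row in order:
        i = idx_panel[row]
        ok = True
        for j in kept_panel:
            if ld.r2(i, j) >= r2_max:
                ok = False
                break
        if ok:
            kept_rows.append(row)
            kept_panel.append(i)
    return sorted(kept_rows)


def selective_prune(
    snps: pd.DataFrame,
    ld: LdPanel,
    r2_max: float,
    criterion: str,
    ascending: bool = True,
) -> pd.DataFrame:
    """LD-prune keeping the best SNP of each correlated set.

    Greedy: visit SNPs best-criterion first (ascending=True keeps the
    smallest value, e.g. min p; False keeps the largest, e.g. max
    predicted replication probability); accept a SNP iff its r^2 with
    every already-accepted SNP is below ``r2_max``.  Ties break by
    (chrom, pos, snp_id) so the result is deterministic.
    """
    if criterion not in snps.columns:
        raise ValueError(f"criterion column {criterion!r} absent")
    snps = snps.reset_index(drop=True)
    key = snps[criterion] if ascending else -snps[criterion]
    order = (
        pd.DataFrame({"k": key, "chrom": snps["chrom"], "pos": snps["pos"],
                      "snp_id": snps["snp_id"]})
        .sort_values(["k", "chrom", "pos", "snp_id"], kind="stable")
        .index.to_numpy()
    )
    kept = _greedy_prune(snps, ld, r2_max, order)
    return snps.loc[kept].reset_index(drop=True)


def random_prune(snps: pd.DataFrame, ld: LdPanel, r2_max: float, seed) -> pd.DataFrame:
    """LD-prune visiting SNPs in seeded uniform-random order.

    The surviving set satisfies the same no-pair-above-threshold
    invariant as :func:`selective_prune`; which member of a correlated
    block survives varies with the seed.
    """
    snps = snps.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(snps))
    kept = _greedy_prune(snps, ld, r2_max, order)
    return snps.loc[kept].reset_index(drop=True)


def clump_loci(
    snps: pd.DataFrame,
    ld: LdPanel,
    criterion: str = "pred_repl",
    r2_max: float = 0.1,
    dist_bp: int = 250_000,
    ascending: bool = False,
) -> pd.DataFrame:
    """Collapse correlated/nearby SNPs into independent loci.

    First LD-prune at ``r2_max`` keeping the best-criterion SNP of each
    block (largest by default), then merge surviving SNPs on the same
    chromosome within ``dist_bp`` of each other into a single locus
    whose lead is the best-criterion member.  Returns one row per locus
    with a 1-based ``locus`` id, ordered by (chrom, pos) of the lead.
    """
    if len(snps) == 0:
        return snps.assign(locus=pd.Series(dtype=int))
    pruned = selective_prune(snps, ld, r2_max, criterion, ascending=ascending)
    pruned = pruned.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    locus_of = np.zeros(len(pruned), dtype=int)
    current = 0
    for i in range(len(pruned)):
        if i == 0 or (
            pruned["chrom"].iat[i] != pruned["chrom"].iat[i - 1]
            or pruned["pos"].iat[i] - pruned["pos"].iat[i - 1] > dist_bp
        ):
            current += 1
        locus_of[i] = current
    pruned["locus"] = locus_of
    best = (
        pruned.sort_values(criterion, ascending=ascending, kind="stable")
        .groupby("locus", as_index=False)
        .head(1)
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    best["locus"] = np.arange(1, len(best) + 1)
    return best


def read_bed_categories(paths: dict) -> dict:
    """Read category position sets from BED files (0-based half-open).

    ``paths`` maps category name -> BED path.  Every base covered by an
    interval contributes its 1-based position; intended for the small
    SNP-position BED files this package consumes, not genome-scale
    interval sets.
    """
    out = {}
    for cat, path in paths.items():
        bed = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
        )
        positions = set()
        for chrom, start, end in bed.itertuples(index=False):
            c = str(chrom).removeprefix("chr")
            for pos in range(int(start) + 1, int(end) + 1):
                positions.add((c, pos))
        out[cat] = positions
    return out
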