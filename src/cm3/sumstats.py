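"""Reading, validating and writing GWAS summary-statistic tables.

Conventions: z-scores are signed association statistics with two-sided
p = 2*Phi(-|z|); p-to-z uses the two-sided quantile with the effect sign
carried separately (a one-sided dialect is not supported).  Positions
are 1-based inclusive; chromosome labels are normalized without a "chr"
prefix.  For p below ~1e-300 the -log10 p branch keeps the transform
finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri_exp

_LN10 = np.log(10.0)
_P_UNDERFLOW = 1e-300

#: default column-name mapping for delimited sumstats files
DEFAULT_SCHEMA = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "p": "P",
    "n_eff": "N",
}


@dataclass(frozen=True)
class ReplicationDesign:
    """Discovery/replication effective sizes and significance threshold."""

    n: float
    n_r: float
    z_alpha: float = 1.959964

    def __post_init__(self) -> None:
        if self.n <= 0 or self.n_r <= 0 or self.z_alpha <= 0:
            raise ValueError("n, n_r and z_alpha must all be positive")


def p_from_z(z):
    """Two-sided tail probability of |z| under the standard normal.

    Floored at 1e-300 so the result always lies in the documented
    (0, 1] domain even where the true tail underflows double precision
    (|z| > ~37); carry -log10 p separately when that matters.
    """
    z = np.asarray(z, dtype=float)
    return np.maximum(2.0 * ndtr(-np.abs(z)), _P_UNDERFLOW)


def z_from_p(p, sign):
    """Signed z with two-sided tail p: z = sign * Q(1 - p/2).

    ``sign`` is +/-1 (elementwise allowed).  p must lie in (0, 1];
    p = 1 maps to z = 0.
    """
    p = np.asarray(p, dtype=float)
    sign = np.asarray(sign, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p must be in (0, 1]")
    if not np.all(np.isin(sign, (-1.0, 1.0))):
        raise ValueError("sign must be +1 or -1")
    # Q(1 - p/2) = -ndtri(p/2); log branch is exact and underflow-safe
    return sign * -ndtri_exp(np.log(p) - np.log(2.0))


def z_from_neglog10p(neglog10p, sign):
    """Signed z from -log10 p, for p far below float underflow."""
    neglog10p = np.asarray(neglog10p, dtype=float)
    sign = np.asarray(sign, dtype=float)
    if np.any(neglog10p < 0):
        raise ValueError("-log10 p must be nonnegative")
    return sign * -ndtri_exp(-neglog10p * _LN10 - np.log(2.0))


def effective_sample_size(n_cases, n_controls):
    """Balanced-equivalent effective sample size 4/(1/cases + 1/controls)."""
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    if np.any(n_cases <= 0) or np.any(n_controls <= 0):
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def normalize_chrom(chrom) -> pd.Series:
    """Strip a leading 'chr' prefix and return string labels."""
    s = pd.Series(chrom).astype(str)
    return s.str.replace("^chr", "", regex=True, case=False)


class SumstatsError(ValueError):
    pass


def read_sumstats(
    path,
    schema_map: dict | None = None,
    strict: bool = False,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into a validated frame.

    Required logical columns: snp_id, chrom, pos, a1, a2, n_eff and at
    least one of z / p.  A missing p column is back-filled from z; a
    missing z column requires a p column plus a ``sign`` column in the
    schema map (values +/-1 or a signed effect whose sign is used).
    Rows failing validation (p outside (0,1], pos < 1, n_eff <= 0,
    unparseable numerics, p/z inconsistency beyond 1e-10) are dropped
    with a report, or fatal under ``strict``.

    Returns a DataFrame with columns snp_id, chrom, pos, a1, a2, z, p,
    neglog10p, n_eff and an attached ``attrs["row_errors"]`` list of
    (line_number, reason) for dropped rows.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_map:
        schema.update(schema_map)
    df = pd.read_csv(path, sep=sep or r"\s+", engine="python")
    required = ["snp_id", "chrom", "pos", "a1", "a2", "n_eff"]
    for logical in required:
        if schema[logical] not in df.columns:
            raise SumstatsError(f"missing required column {schema[logical]!r}")
    has_z = schema.get("z") in df.columns
    has_p = schema.get("p") in df.columns
    if not has_z and not has_p:
        raise SumstatsError("need at least one of the z / p columns")

    out = pd.DataFrame(
        {
            "snp_id": df[schema["snp_id"]].astype(str),
            "chrom": normalize_chrom(df[schema["chrom"]]),
            "pos": pd.to_numeric(df[schema["pos"]], errors="coerce"),
            "a1": df[schema["a1"]].astype(str).str.upper(),
            "a2": df[schema["a2"]].astype(str).str.upper(),
            "n_eff": pd.to_numeric(df[schema["n_eff"]], errors="coerce"),
        }
    )
    out["z"] = (
        pd.to_numeric(df[schema["z"]], errors="coerce") if has_z else np.nan
    )
    out["p"] = (
        pd.to_numeric(df[schema["p"]], errors="coerce") if has_p else np.nan
    )

    errors: list[tuple[int, str]] = []

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in out.index[mask.fillna(False)]:
            errors.append((int(idx) + 2, reason))  # +2: header + 1-based

    bad = pd.Series(False, index=out.index)
    m = out["pos"].isna() | (out["pos"] < 1)
    flag(m & ~bad, "invalid position")
    bad |= m
    m = out["n_eff"].isna() | (out["n_eff"] <= 0)
    flag(m & ~bad, "invalid effective sample size")
    bad |= m
    if has_p:
        m = out["p"].notna() & ((out["p"] <= 0) | (out["p"] > 1))
        flag(m & ~bad, "p outside (0, 1]")
        bad |= m
    if has_z:
        m = out["z"].isna()
        flag(m & ~bad, "unparseable z")
        bad |= m
    if has_z and has_p:
        with np.errstate(invalid="ignore"):
            m = out["z"].notna() & out["p"].notna() & (
                np.abs(p_from_z(out["z"].to_numpy()) - out["p"].to_numpy()) > 1e-10
            )
        flag(m & ~bad, "p and z inconsistent")
        bad |= m

    if strict and bad.any():
        lines = ", ".join(f"line {ln}: {r}" for ln, r in errors[:10])
        raise SumstatsError(f"{int(bad.sum())} invalid rows ({lines})")
    out = out.loc[~bad].reset_index(drop=True)

    if not has_p:
        out["p"] = p_from_z(out["z"].to_numpy())
    if not has_z:
        sign_col = schema.get("sign")
        if sign_col is None or sign_col not in df.columns:
            raise SumstatsError(
                "z column absent: schema_map must name a 'sign' column"
            )
        signs = np.sign(pd.to_numeric(df[sign_col], errors="coerce"))
        signs = signs.loc[out.index].replace(0, 1.0).to_numpy()
        out["z"] = z_from_p(out["p"].to_numpy(), signs)
    out["pos"] = out["pos"].astype(np.int64)
    with np.errstate(divide="ignore"):
        out["neglog10p"] = -np.log10(np.maximum(out["p"], _P_UNDERFLOW))
    out.attrs["row_errors"] = errors
    return out


@dataclass
class SubStudyPanel:
    """Aligned per-SNP z-scores across J independent sub-studies.

    ``snps`` carries the shared SNP index (snp_id, chrom, pos, a1, a2);
    ``z`` is an (m, J) array (NaN = SNP missing in that study);
    ``n_eff`` the per-study effective sizes; ``labels`` the study names.
    """

    snps: pd.DataFrame
    z: np.ndarray
    n_eff: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.n_eff = np.asarray(self.n_eff, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be (m, J)")
        m, J = self.z.shape
        if J < 2:
            raise ValueError("a sub-study panel needs J >= 2 studies")
        if len(self.snps) != m:
            raise ValueError("snps and z row counts differ")
        if self.n_eff.shape != (J,):
            raise ValueError("n_eff must have one entry per study")
        if np.any(self.n_eff <= 0):
            raise ValueError("effective sample sizes must be positive")
        if not self.labels:
            self.labels = [f"study_{j + 1}" for j in range(J)]

    @property
    def m(self) -> int:
        return self.z.shape[0]

    @property
    def J(self) -> int:
        return self.z.shape[1]

    @property
    def n_total(self) -> float:
        return float(self.n_eff.sum())


_TABLE_KINDS = {
    "lookup": ["stratum", "z", "fdr", "post_mean", "repl_mean",
               "repl_second_moment", "repl_prob"],
    "loci": ["Loci", "LeadingSNP", "A1", "Chrnum", "Pos", "Pred_Repl", "P"],
    "curves": ["stratum", "midpoint", "count", "value", "smoothed"],
    "predictions": ["snp_id", "chrom", "pos", "z", "p", "stratum", "fdr",
                    "post_mean", "repl_mean", "repl_prob"],
}


def write_table(records: pd.DataFrame, path, kind: str) -> None:
    """Write a known artifact kind as TSV with a stable schema.

    Reals are serialized with 17 significant digits so a re-read
    reproduces them bit-exactly; strings and integers round-trip as-is.
    An empty record set is an error and produces no file.
    """
    if kind not in _TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    if records is None or len(records) == 0:
        raise ValueError("refusing to write an empty table")
    missing = [c for c in _TABLE_KINDS[kind] if c not in records.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns: {missing}")
    cols = _TABLE_KINDS[kind] + [
        c for c in records.columns if c not in _TABLE_KINDS[kind]
    ]
    records[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path, kind: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    if kind not in _TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _TABLE_KINDS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns: {missing}")
    return df
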