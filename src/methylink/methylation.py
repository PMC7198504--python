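"""CpG methylation counts and differential-methylation testing.

Methylation is observed as per-CpG, per-sample read counts: ``M`` methylated
and ``U`` unmethylated reads at coverage ``N = M + U``, giving a beta score
``M / N``.  Differential methylation across phenotype groups is tested per
CpG with a beta-binomial model under an arcsine variance-stabilizing link:
each sample's proportion is transformed as ``Y = arcsin(2p - 1)`` (with a
continuity correction ``p = (M + 0.5) / (N + 1)``), which has approximate
variance ``(1 + (N - 1) * phi) / N`` under beta-binomial sampling with
dispersion ``phi`` — free of the unknown proportion, which is what makes
the transform variance-stabilizing.  A group-means linear model is then fitted by
generalized least squares with those variances and group equality is tested
with a Wald chi-squared statistic (df = groups - 1), followed by
Benjamini-Hochberg FDR control; a CpG is a DMC at q < 0.05.

Bisulfite conversion efficiency is estimated from unmethylated
lambda-bacteriophage spike-in CpGs as the percentage of unmethylated reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .rnaseq import bh_fdr

LAMBDA_CONTIG = "lambda"

_COLUMNS = ["chrom", "position", "sample_id", "count_methylated", "count_unmethylated"]


@dataclass(frozen=True)
class CpGMethylationTable:
    """Long-format table of per-CpG, per-sample methylation counts.

    ``records`` has columns chrom, position (1-based), sample_id,
    count_methylated, count_unmethylated; (chrom, position, sample_id) is
    unique and coverage is at least 1 for every retained record.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if len(df):
            m = df["count_methylated"].to_numpy()
            u = df["count_unmethylated"].to_numpy()
            if (m < 0).any() or (u < 0).any():
                raise ValueError("methylation counts must be non-negative")
            if ((m + u) < 1).any():
                raise ValueError("zero-coverage records are not allowed")
            if df.duplicated(["chrom", "position", "sample_id"]).any():
                raise ValueError("(chrom, position, sample_id) must be unique")

    @property
    def coverage(self) -> pd.Series:
        return self.records["count_methylated"] + self.records["count_unmethylated"]

    @property
    def beta(self) -> pd.Series:
        return self.records["count_methylated"] / self.coverage

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def subset_contig(self, chrom: str, invert: bool = False) -> "CpGMethylationTable":
        mask = self.records["chrom"] == chrom
        if invert:
            mask = ~mask
        return CpGMethylationTable(self.records.loc[mask].reset_index(drop=True))


@dataclass(frozen=True)
class ConversionEfficiency:
    """Spike-in conversion efficiency summary (percent scale)."""

    percent_converted: float
    sd: float
    n_lambda_cpgs: int
    per_sample: pd.Series


def read_bismark_coverage(path, sample_id: str | None = None) -> CpGMethylationTable:
    """Read one sample's Bismark coverage file.

    Expected columns: chromosome, start, end, methylation percentage, count
    methylated, count unmethylated (tab separated, 1-based inclusive
    positions with start = end for CpGs).  Zero-coverage rows are dropped
    with a warning; a methylation percentage inconsistent with the counts by
    more than 0.5 triggers a warning (upstream rounding is tolerated).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem.replace(".cov", "")
    rows = []
    n_zero = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            try:
                chrom = parts[0]
                pos = int(parts[1])
                pct = float(parts[3])
                m = int(parts[4])
                u = int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if m + u == 0:
                n_zero += 1
                continue
            if abs(pct - 100.0 * m / (m + u)) > 0.5:
                warnings.warn(
                    f"{path}:{lineno}: methylation% {pct} inconsistent with "
                    f"counts {m}/{m + u}",
                    stacklevel=2,
                )
            rows.append((chrom, pos, sample_id, m, u))
    if n_zero:
        warnings.warn(f"{path}: dropped {n_zero} zero-coverage rows", stacklevel=2)
    if not rows:
        warnings.warn(f"{path}: empty coverage file", stacklevel=2)
        return CpGMethylationTable(pd.DataFrame(columns=_COLUMNS))
    return CpGMethylationTable(pd.DataFrame(rows, columns=_COLUMNS))


def read_coverage_dir(directory, pattern: str = "*.cov") -> CpGMethylationTable:
    """Read every coverage file in a directory (one per sample) into one table."""
    frames = [
        read_bismark_coverage(p).records for p in sorted(Path(directory).glob(pattern))
    ]
    if not frames:
        raise FileNotFoundError(f"no {pattern} files under {directory}")
    return CpGMethylationTable(pd.concat(frames, ignore_index=True))


def write_bismark_coverage(table: CpGMethylationTable, directory) -> list[Path]:
    """Write one Bismark coverage file per sample; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, sub in table.records.groupby("sample_id", sort=True):
        sub = sub.sort_values(["chrom", "position"])
        m = sub["count_methylated"].to_numpy()
        u = sub["count_unmethylated"].to_numpy()
        out = pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": sub["position"].to_numpy(),
                "end": sub["position"].to_numpy(),
                "pct": np.round(100.0 * m / (m + u), 6),
                "m": m,
                "u": u,
            }
        )
        p = directory / f"{sample}.cov"
        out.to_csv(p, sep="\t", header=False, index=False)
        paths.append(p)
    return paths


def conversion_efficiency(lambda_table: CpGMethylationTable) -> ConversionEfficiency:
    """Percent of unmethylated calls among spike-in CpGs, per sample and pooled.

    For fully unmethylated lambda DNA every methylated call is a conversion
    failure, so ``100 * sum(U) / (sum(M) + sum(U))`` estimates the conversion
    efficiency.
    """
    df = lambda_table.records
    if df.empty:
        raise ValueError("no spike-in CpG records")
    grouped = df.groupby("sample_id")
    m = grouped["count_methylated"].sum()
    u = grouped["count_unmethylated"].sum()
    per_sample = 100.0 * u / (m + u)
    per_sample.name = "percent_converted"
    return ConversionEfficiency(
        percent_converted=float(per_sample.mean()),
        sd=float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0,
        n_lambda_cpgs=int(df.groupby(["chrom", "position"]).ngroups),
        per_sample=per_sample,
    )


def arcsine_transform(M, N):
    """Variance-stabilizing transform ``arcsin(2p - 1)`` with continuity correction.

    ``p = (M + 0.5) / (N + 1)`` keeps the transform finite at the boundaries
    M = 0 and M = N; the result lies strictly inside (-pi/2, pi/2).
    """
    M = np.asarray(M, dtype=float)
    N = np.asarray(N, dtype=float)
    if (N < 1).any():
        raise ValueError("coverage must be >= 1")
    if (M > N).any() or (M < 0).any():
        raise ValueError("need 0 <= M <= N")
    p = (M + 0.5) / (N + 1.0)
    return np.arcsin(2.0 * p - 1.0)


def _pivot(table: CpGMethylationTable, sample_ids: list[str]):
    """CpG x sample matrices of M and N (NaN where a record is missing)."""
    df = table.records
    m = df.pivot_table(
        index=["chrom", "position"],
        columns="sample_id",
        values="count_methylated",
        aggfunc="first",
    ).reindex(columns=sample_ids)
    n = (
        df.assign(n=df["count_methylated"] + df["count_unmethylated"])
        .pivot_table(
            index=["chrom", "position"], columns="sample_id", values="n",
            aggfunc="first",
        )
        .reindex(columns=sample_ids)
    )
    return m, n


def _bb_dispersion_mom(
    p_obs: np.ndarray, n_cov: np.ndarray, group_idx: list[np.ndarray]
) -> np.ndarray:
    """Per-CpG method-of-moments beta-binomial dispersion, floored at zero.

    Pools squared deviations of sample proportions around coverage-weighted
    group means; under the beta-binomial, their scaled expectation is
    ``(n_used - n_groups) + phi * sum(N_i - 1)``.
    """
    n_cpgs = p_obs.shape[0]
    resid_sum = np.zeros(n_cpgs)
    used = np.zeros(n_cpgs)
    excess = np.zeros(n_cpgs)
    for idx in group_idx:
        n_g = n_cov[:, idx]
        p_g = p_obs[:, idx]
        with np.errstate(invalid="ignore"):
            tot = np.nansum(n_g, axis=1)
            phat = np.nansum(n_g * p_g, axis=1) / np.maximum(tot, 1.0)
        phat = np.clip(phat, 1e-6, 1 - 1e-6)
        r = n_g * (p_g - phat[:, None]) ** 2 / (phat * (1 - phat))[:, None]
        resid_sum += np.nansum(r, axis=1)
        obs = ~np.isnan(n_g)
        used += obs.sum(axis=1)
        excess += np.nansum(n_g - 1.0, axis=1)
    n_groups = len(group_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (resid_sum - (used - n_groups)) / np.maximum(excess, 1e-12)
    return np.clip(np.nan_to_num(phi), 0.0, 1.0)


def dm_wald_test(
    table: CpGMethylationTable,
    design: pd.Series,
    min_coverage: int = 1,
    min_samples_per_group: int = 2,
) -> pd.DataFrame:
    """Per-CpG beta-binomial Wald test across design groups.

    A CpG is retained when every group has at least ``min_samples_per_group``
    samples with coverage >= ``min_coverage``; unretained CpGs appear in the
    output with ``retained = False`` and a reason, and are excluded from the
    FDR computation.  Returns a table indexed by (chrom, position) with
    coverage-weighted per-group mean methylation, the omnibus Wald statistic,
    pairwise z statistics, p and BH q-values.
    """
    sample_ids = [s for s in design.index if s in set(table.records["sample_id"])]
    if not sample_ids:
        raise ValueError("no overlap between design samples and table samples")
    design = design.reindex(sample_ids)
    groups = list(pd.unique(design))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    m_mat, n_mat = _pivot(table, sample_ids)
    M = m_mat.to_numpy(dtype=float)
    N = n_mat.to_numpy(dtype=float)
    low = ~np.isnan(N) & (N < min_coverage)
    M[low] = np.nan
    N[low] = np.nan
    group_idx = [
        np.flatnonzero((design == g).to_numpy()) for g in groups
    ]

    covered_per_group = np.stack(
        [(~np.isnan(N[:, idx])).sum(axis=1) for idx in group_idx], axis=1
    )
    retained = (covered_per_group >= min_samples_per_group).all(axis=1)

    with np.errstate(invalid="ignore"):
        p_obs = M / N
    phi = _bb_dispersion_mom(p_obs, N, group_idx)
    # moderate the noisy per-CpG dispersions toward a lowess trend across
    # mean methylation; this variance reduction keeps the Wald calibrated
    with np.errstate(invalid="ignore"):
        overall = np.nansum(M, axis=1) / np.maximum(np.nansum(N, axis=1), 1.0)
    if phi.size >= 50:
        fit = sm_lowess(phi, overall, frac=0.4, return_sorted=True)
        trend = np.maximum(np.interp(overall, fit[:, 0], fit[:, 1]), 0.0)
        phi = 0.5 * phi + 0.5 * trend

    # arcsine-transformed responses and GLS variances
    Y = np.full_like(M, np.nan)
    ok = ~np.isnan(N)
    Y[ok] = np.arcsin(2.0 * (M[ok] + 0.5) / (N[ok] + 1.0) - 1.0)
    # delta method: Var(arcsin(2p-1)) = Var(p)/(p(1-p)) = (1+(N-1)phi)/N
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (1.0 + (N - 1.0) * phi[:, None]) / N
        w = 1.0 / var

    n_cpgs = M.shape[0]
    means = np.full((n_cpgs, len(groups)), np.nan)  # GLS group means of Y
    vargm = np.full((n_cpgs, len(groups)), np.nan)
    beta_means = np.full((n_cpgs, len(groups)), np.nan)  # weighted beta scores
    for k, idx in enumerate(group_idx):
        wk = w[:, idx]
        sw = np.nansum(wk, axis=1)
        means[:, k] = np.nansum(wk * Y[:, idx], axis=1) / sw
        vargm[:, k] = 1.0 / sw
        tot = np.nansum(N[:, idx], axis=1)
        beta_means[:, k] = np.nansum(M[:, idx], axis=1) / np.maximum(tot, 1.0)

    inv_v = 1.0 / vargm
    grand = np.nansum(means * inv_v, axis=1) / np.nansum(inv_v, axis=1)
    wald = np.nansum((means - grand[:, None]) ** 2 * inv_v, axis=1)
    df = len(groups) - 1
    p = stats.chi2.sf(wald, df)
    p = np.where(retained, p, np.nan)
    q = bh_fdr(p)

    out = pd.DataFrame(index=m_mat.index)
    for k, g in enumerate(groups):
        out[f"mean_meth_{g}"] = beta_means[:, k]
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            z = (means[:, b] - means[:, a]) / np.sqrt(vargm[:, a] + vargm[:, b])
            out[f"z_{groups[b]}_vs_{groups[a]}"] = z
    out["dispersion"] = phi
    out["wald"] = wald
    out["df"] = df
    out["p_value"] = p
    out["q_value"] = q
    out["n_samples_covered"] = (~np.isnan(N)).sum(axis=1)
    out["retained"] = retained
    out["reason"] = np.where(retained, "", "insufficient_group_coverage")
    return out


def dmc_positions(dm_result: pd.DataFrame, q_cutoff: float = 0.05) -> pd.DataFrame:
    """The DMC subset (q < cutoff) of a :func:`dm_wald_test` result."""
    return dm_result.loc[dm_result["q_value"] < q_cutoff]


def write_dm_results(dm_result: pd.DataFrame, path) -> None:
    dm_result.to_csv(path, sep="\t", index_label=["chrom", "position"])


def write_dmc_bed(dm_result: pd.DataFrame, path, q_cutoff: float = 0.05) -> None:
    """Export DMCs as BED (0-based half-open) for genome-browser use."""
    dmc = dmc_positions(dm_result, q_cutoff).reset_index()
    bed = pd.DataFrame(
        {
            "chrom": dmc["chrom"],
            "start": dmc["position"] - 1,
            "end": dmc["position"],
            "name": "dmc",
            "score": np.minimum(
                1000, (-10.0 * np.log10(np.maximum(dmc["q_value"], 1e-100))).astype(int)
            ),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
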