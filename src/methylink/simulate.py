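"""Synthetic paired expression + methylation cohorts with planted truth.

The generator emulates the study design the pipeline targets: three
phenotype groups (control, mild, classic; unbalanced 4/3/5 by default),
bulk RNA-seq counts and reduced-representation bisulfite CpG counts from
the same samples, a lambda-bacteriophage spike-in, cell-type mixtures, and
a phenotype criteria table.

Expression counts are negative-binomial around library-size-scaled
lognormal baselines; a configured fraction of genes are planted as
differentially expressed with a fixed log2 fold-change spread across
groups.  CpG methylation counts are beta-binomial with shifted-Poisson
coverage; a configured fraction of the planted DEGs are additionally
*methylation-regulated*: their promoter CpGs' true methylation decreases by
``meth_delta`` as group mean expression increases, so that across groups
promoter methylation rank order is exactly the reverse of expression rank
order.  All other genes and CpGs have group-invariant parameters.  Every
output is a deterministic function of the configuration seed.

Genes live on one synthetic chromosome with non-overlapping bodies at a
fixed 10 kb spacing so that promoter/association window logic is exactly
testable without a reference genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .methylation import LAMBDA_CONTIG, CpGMethylationTable, write_bismark_coverage
from .rnaseq import ExpressionCountMatrix, write_counts_tsv

GROUPS = ("control", "mild", "classic")
CHROM = "chrS1"

_GENE_SPACING = 10_000
_BODY_LENGTH = 6_000
_FIRST_BODY_START = 2_001  # keeps the first promoter clear of position 1


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; ``seed`` fixes every output."""

    n_genes: int = 2000
    n_cpgs_per_promoter: int = 3
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"control": 4, "mild": 3, "classic": 5}
    )
    frac_deg: float = 0.10
    frac_mr: float = 0.50  # fraction of DEGs that are methylation-regulated
    expr_log2fc: float = 2.0
    meth_delta: float = 0.30  # proportion-scale methylation span across groups
    nb_dispersion: tuple[float, float] = (0.05, 0.2)
    bb_dispersion: float = 0.02
    coverage_mean: float = 30.0
    libsize_range: tuple[float, float] = (8e5, 1.6e6)
    n_lambda_cpgs: int = 500
    lambda_meth_rate: float = 0.004
    dropout: float = 0.0  # per CpG-sample record deletion probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cpgs_per_promoter < 1:
            raise ValueError("gene and CpG counts must be positive")
        for frac, name in [
            (self.frac_deg, "frac_deg"),
            (self.frac_mr, "frac_mr"),
            (self.dropout, "dropout"),
            (self.lambda_meth_rate, "lambda_meth_rate"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if set(self.n_samples_per_group) != set(GROUPS):
            raise ValueError(f"n_samples_per_group must have keys {GROUPS}")
        for g, n in self.n_samples_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not 0.0 < self.meth_delta <= 1.0:
            raise ValueError("meth_delta must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    deg_ids: set[str]
    mr_ids: set[str]
    dmc_positions: set[tuple[str, int]]
    group_mean_expression: dict[str, dict[str, float]]  # gene -> group -> CPM
    group_mean_methylation: dict[tuple[str, int], dict[str, float]]
    true_proportions: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "deg_ids": sorted(self.deg_ids),
            "mr_ids": sorted(self.mr_ids),
            "dmc_positions": sorted([list(t) for t in self.dmc_positions]),
            "group_mean_expression": self.group_mean_expression,
            "group_mean_methylation": {
                f"{c}:{p}": v for (c, p), v in self.group_mean_methylation.items()
            },
        }
        if self.true_proportions is not None:
            payload["true_proportions"] = self.true_proportions.to_dict()
        Path(path).write_text(json.dumps(payload, indent=1))


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, groups = [], []
    for g in GROUPS:
        for i in range(config.n_samples_per_group[g]):
            ids.append(f"{g}_{i + 1}")
            groups.append(g)
    return ids, groups


def make_annotation(n_genes: int) -> pd.DataFrame:
    """Gene bodies on one chromosome, 10 kb spacing, alternating strand."""
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    body_start = _FIRST_BODY_START + _GENE_SPACING * np.arange(n_genes)
    body_end = body_start + _BODY_LENGTH - 1
    strand = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    tss = np.where(strand == "+", body_start, body_end)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": CHROM,
            "strand": strand,
            "tss": tss,
            "body_start": body_start,
            "body_end": body_end,
        }
    ).set_index("gene_id")


def _betabinomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, phi: float
) -> np.ndarray:
    """Beta-binomial draws with Var = n p (1-p) (1 + (n-1) phi)."""
    if phi <= 0:
        return rng.binomial(n.astype(int), p)
    conc = 1.0 / phi - 1.0  # alpha + beta
    a = np.clip(p * conc, 1e-8, None)
    b = np.clip((1.0 - p) * conc, 1e-8, None)
    pi = rng.beta(a, b)
    return rng.binomial(n.astype(int), pi)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[
    ExpressionCountMatrix, CpGMethylationTable, pd.DataFrame, pd.DataFrame, SyntheticTruth
]:
    """Generate one paired cohort.

    Returns ``(counts, methylation, annotation, sample_sheet, truth)``.
    """
    rng = np.random.default_rng([config.seed, 0])
    sample_ids, sample_groups = _sample_ids(config)
    n_samples = len(sample_ids)
    annotation = make_annotation(config.n_genes)
    gene_ids = annotation.index.to_numpy()

    # --- expression ---
    base = rng.lognormal(mean=np.log(60.0), sigma=1.2, size=config.n_genes)
    rel = base / base.sum()
    lib = rng.uniform(*config.libsize_range, size=n_samples)
    phi_g = rng.uniform(*config.nb_dispersion, size=config.n_genes)

    n_deg = int(round(config.frac_deg * config.n_genes))
    n_mr = int(round(config.frac_mr * n_deg))
    deg_idx = rng.choice(config.n_genes, size=n_deg, replace=False)
    mr_idx = deg_idx[:n_mr]

    # per-gene per-group log2 offsets; DEGs get (0, lfc/2, lfc) permuted
    offsets = np.zeros((config.n_genes, len(GROUPS)))
    levels = np.array([0.0, config.expr_log2fc / 2.0, config.expr_log2fc])
    for gi in deg_idx:
        offsets[gi] = levels[rng.permutation(3)]

    group_of = np.array([GROUPS.index(g) for g in sample_groups])
    mu = (
        lib[None, :]
        * rel[:, None]
        * 2.0 ** offsets[np.arange(config.n_genes)[:, None], group_of[None, :]]
    )
    lam = rng.gamma(shape=1.0 / phi_g[:, None], scale=phi_g[:, None] * mu)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    group_mean_expression = {
        str(gene_ids[gi]): {
            g: float(rel[gi] * 2.0 ** offsets[gi, k] * 1e6)
            for k, g in enumerate(GROUPS)
        }
        for gi in deg_idx
    }

    # --- methylation ---
    promoter_half = 1000
    cpg_rows = []
    true_meth: dict[tuple[str, int], dict[str, float]] = {}
    dmc_positions: set[tuple[str, int]] = set()
    mr_set = set(mr_idx.tolist())
    positions_per_gene = {}
    for gi in range(config.n_genes):
        tss = int(annotation["tss"].iloc[gi])
        lo, hi = max(1, tss - promoter_half), tss + promoter_half
        pos = rng.choice(
            np.arange(lo, hi + 1), size=config.n_cpgs_per_promoter, replace=False
        )
        positions_per_gene[gi] = np.sort(pos)

    n_cpgs_total = config.n_genes * config.n_cpgs_per_promoter
    all_pos = np.concatenate([positions_per_gene[gi] for gi in range(config.n_genes)])
    # true per-group methylation proportion for every CpG
    p_groups = np.empty((n_cpgs_total, len(GROUPS)))
    cursor = 0
    for gi in range(config.n_genes):
        k = config.n_cpgs_per_promoter
        if gi in mr_set:
            # highest methylation in the lowest-expression group
            expr_rank = np.argsort(np.argsort(offsets[gi]))  # 0 = lowest expression
            p_low = rng.uniform(config.meth_delta + 0.05, 0.95, size=k)
            for j in range(k):
                p_groups[cursor + j] = p_low[j] - config.meth_delta * (
                    expr_rank / (len(GROUPS) - 1)
                )
                dmc_positions.add((CHROM, int(positions_per_gene[gi][j])))
        else:
            p0 = rng.uniform(0.1, 0.9, size=k)
            p_groups[cursor : cursor + k] = p0[:, None]
        for j in range(k):
            true_meth[(CHROM, int(positions_per_gene[gi][j]))] = {
                g: float(p_groups[cursor + j, m]) for m, g in enumerate(GROUPS)
            }
        cursor += k

    cov = 1 + rng.poisson(config.coverage_mean - 1.0, size=(n_cpgs_total, n_samples))
    p_mat = p_groups[:, group_of]
    meth = np.empty_like(cov)
    for j in range(n_samples):
        meth[:, j] = _betabinomial(
            rng, cov[:, j], np.clip(p_mat[:, j], 1e-6, 1 - 1e-6), config.bb_dispersion
        )
    keep = np.ones((n_cpgs_total, n_samples), dtype=bool)
    if config.dropout > 0:
        keep = rng.random((n_cpgs_total, n_samples)) >= config.dropout

    for j, sid in enumerate(sample_ids):
        kj = keep[:, j]
        cpg_rows.append(
            pd.DataFrame(
                {
                    "chrom": CHROM,
                    "position": all_pos[kj],
                    "sample_id": sid,
                    "count_methylated": meth[kj, j],
                    "count_unmethylated": cov[kj, j] - meth[kj, j],
                }
            )
        )
    cpg_table = CpGMethylationTable(
        pd.concat(cpg_rows, ignore_index=True)
        .sort_values(["chrom", "position", "sample_id"])
        .reset_index(drop=True)
    )

    sample_sheet = pd.DataFrame({"sample_id": sample_ids, "group": sample_groups})
    truth = SyntheticTruth(
        deg_ids={str(g) for g in gene_ids[deg_idx]},
        mr_ids={str(g) for g in gene_ids[mr_idx]},
        dmc_positions=dmc_positions,
        group_mean_expression=group_mean_expression,
        group_mean_methylation=true_meth,
    )
    return ExpressionCountMatrix(counts_df), cpg_table, annotation, sample_sheet, truth


def simulate_lambda_spikein(config: SimulationConfig) -> CpGMethylationTable:
    """Spike-in CpGs on the reserved ``lambda`` contig.

    True methylation equals ``lambda_meth_rate`` (near zero for fully
    unmethylated phage DNA), so the measured percent of unmethylated calls
    estimates the bisulfite conversion efficiency.
    """
    if config.n_lambda_cpgs < 1:
        raise ValueError("n_lambda_cpgs must be >= 1")
    rng = np.random.default_rng([config.seed, 1])
    sample_ids, _ = _sample_ids(config)
    positions = 1 + 50 * np.arange(config.n_lambda_cpgs)
    rows = []
    for sid in sample_ids:
        cov = 1 + rng.poisson(config.coverage_mean - 1.0, size=config.n_lambda_cpgs)
        m = rng.binomial(cov, config.lambda_meth_rate)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": LAMBDA_CONTIG,
                    "position": positions,
                    "sample_id": sid,
                    "count_methylated": m,
                    "count_unmethylated": cov - m,
                }
            )
        )
    return CpGMethylationTable(pd.concat(rows, ignore_index=True))


def simulate_reference(
    n_genes: int = 300,
    cell_types: tuple[str, ...] = ("B", "T", "NK", "Mono"),
    markers_per_type: int = 25,
    fold: float = 32.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell-type mean expression with planted marker genes.

    Each cell type over-expresses its own block of ``markers_per_type``
    genes by ``fold`` relative to a shared lognormal baseline.
    """
    rng = np.random.default_rng([seed, 2])
    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)
    ref = np.tile(base[:, None], (1, len(cell_types)))
    for t in range(len(cell_types)):
        lo = t * markers_per_type
        hi = min(lo + markers_per_type, n_genes)
        ref[lo:hi, t] *= fold
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    return pd.DataFrame(ref, index=gene_ids, columns=list(cell_types))


def simulate_mixtures(
    reference: pd.DataFrame,
    proportions: pd.DataFrame,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk profiles as proportion-weighted sums of reference columns.

    ``proportions`` is samples x cell types with rows summing to one;
    ``noise`` is the sigma of mean-one multiplicative lognormal noise.
    Returns a genes x samples expression DataFrame.
    """
    if set(proportions.columns) != set(reference.columns):
        raise ValueError("proportion and reference cell types differ")
    props = proportions[reference.columns]
    sums = props.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("proportion rows must sum to 1")
    bulk = reference.to_numpy() @ props.to_numpy().T
    if noise > 0:
        rng = np.random.default_rng([seed, 3])
        bulk = bulk * rng.lognormal(
            mean=-0.5 * noise**2, sigma=noise, size=bulk.shape
        )
    return pd.DataFrame(bulk, index=reference.index, columns=props.index)


def simulate_phenotype_table(
    n_mild: int = 3, n_classic: int = 5, nk_rate: float = 0.15, seed: int = 0
) -> pd.DataFrame:
    """Yes/No/NK criteria rows consistent with the mild/classic score rule."""
    from .cohort import CRITERIA

    rng = np.random.default_rng([seed, 4])
    rows = []
    i = 0
    while len(rows) < n_mild + n_classic:
        want_mild = len(rows) < n_mild
        vals = []
        for _ in CRITERIA:
            if rng.random() < nk_rate:
                vals.append("NK")
            else:
                p_yes = 0.3 if want_mild else 0.8
                vals.append("Yes" if rng.random() < p_yes else "No")
        known = [v for v in vals if v != "NK"]
        if not known:
            continue
        frac = known.count("Yes") / len(known)
        if want_mild != (frac <= 0.5):
            continue
        i += 1
        rows.append(
            [f"SIM{i:03d}", *vals, float(rng.integers(8, 40)),
             "mild" if want_mild else "classic"]
        )
    return pd.DataFrame(
        rows, columns=["participant_id", *CRITERIA, "age_years", "phenotype"]
    )


def write_cohort(
    outdir,
    counts: ExpressionCountMatrix,
    cpgs: CpGMethylationTable,
    annotation: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> None:
    """Serialize a simulated cohort (counts TSV, coverage files, annotation,
    sample sheet, truth JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(counts, outdir / "counts.tsv")
    write_bismark_coverage(cpgs, outdir / "coverage")
    annotation.to_csv(outdir / "annotation.tsv", sep="\t")
    sample_sheet.to_csv(outdir / "samples.csv", index=False)
    if truth is not None:
        truth.to_json(outdir / "truth.json")


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a config from a plain mapping (e.g. parsed YAML/JSON)."""
    d = dict(d)
    for key in ("nb_dispersion", "libsize_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
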