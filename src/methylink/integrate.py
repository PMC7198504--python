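"""Joining differential methylation to differential expression.

A gene's *promoter* is the closed interval TSS ± 1 kb; its *association*
window extends the gene body by 2 kb on each side (both 1-based inclusive,
clipped at position 1).  Differentially methylated CpGs (DMCs) are mapped
to every gene whose window contains them.  A gene is called
*methylation-regulated* when it is (i) a DEG (expression q < 0.05),
(ii) carries at least one promoter DMC, and (iii) at least one such
promoter CpG passes the inverse-directionality difference filter: its mean
methylation in the lowest-expression group exceeds that in the
highest-expression group by at least the threshold (default 0.25 on the
proportion scale, i.e. 25 percentage points).  The filter direction is what
makes the call *inverse*: methylation must be higher where expression is
lower; a difference of any size in the same direction as expression fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUP_ORDER = ("control", "mild", "classic")


@dataclass(frozen=True)
class VennPartition:
    """Exact partition of the DEG and DMC-associated gene universes."""

    only_deg: set[str]
    only_dm: set[str]
    both: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "only_deg": len(self.only_deg),
            "only_dm": len(self.only_dm),
            "both": len(self.both),
        }


def gene_windows(
    annotation: pd.DataFrame,
    promoter_halfwidth: int = 1000,
    body_flank: int = 2000,
) -> pd.DataFrame:
    """Closed 1-based promoter and association intervals per gene.

    ``annotation`` needs columns chrom, strand, tss, body_start, body_end
    (gene_id index).  Intervals are clipped at position 1.
    """
    if (annotation["body_start"] > annotation["body_end"]).any():
        raise ValueError("body_start must not exceed body_end")
    out = annotation[["chrom", "strand", "tss", "body_start", "body_end"]].copy()
    out["promoter_start"] = np.maximum(1, out["tss"] - promoter_halfwidth)
    out["promoter_end"] = out["tss"] + promoter_halfwidth
    out["assoc_start"] = np.maximum(1, out["body_start"] - body_flank)
    out["assoc_end"] = out["body_end"] + body_flank
    return out


def associate_dmcs(
    positions: Iterable[tuple[str, int]],
    windows: pd.DataFrame,
    scope: str = "promoter",
) -> dict[str, list[tuple[str, int]]]:
    """Map each position to every gene whose window contains it (closed interval).

    ``scope`` is ``"promoter"`` or ``"association"``.  A position inside two
    overlapping windows is assigned to both genes.  Genes without any hit
    are omitted from the result.
    """
    col = {"promoter": ("promoter_start", "promoter_end"),
           "association": ("assoc_start", "assoc_end")}
    if scope not in col:
        raise ValueError(f"scope must be promoter or association, got {scope!r}")
    lo_col, hi_col = col[scope]
    by_chrom: dict[str, np.ndarray] = {}
    pos_list = list(positions)
    for chrom in {c for c, _ in pos_list}:
        by_chrom[chrom] = np.sort(
            np.array([p for c, p in pos_list if c == chrom], dtype=int)
        )
    out: dict[str, list[tuple[str, int]]] = {}
    for gene_id, row in windows.iterrows():
        arr = by_chrom.get(row["chrom"])
        if arr is None:
            continue
        lo = np.searchsorted(arr, row[lo_col], side="left")
        hi = np.searchsorted(arr, row[hi_col], side="right")
        if hi > lo:
            out[str(gene_id)] = [(row["chrom"], int(p)) for p in arr[lo:hi]]
    return out


def venn_partition(deg_ids: set[str], dm_gene_ids: set[str]) -> VennPartition:
    """Partition genes into DEG-only, DMC-associated-only, and both."""
    both = deg_ids & dm_gene_ids
    return VennPartition(deg_ids - both, dm_gene_ids - both, both)


def order_groups_by_expression(
    group_mean_cpm: Mapping[str, float],
    group_order: Sequence[str] = GROUP_ORDER,
) -> tuple[list[str], bool]:
    """Groups sorted ascending by mean CPM; ties broken by fixed group order.

    Returns ``(ordered_groups, tie_flag)``.
    """
    missing = [g for g in group_order if g not in group_mean_cpm]
    if missing:
        raise ValueError(f"missing group means for {missing}")
    vals = [group_mean_cpm[g] for g in group_order]
    tie = len(set(vals)) < len(vals)
    ordered = sorted(group_order, key=lambda g: (group_mean_cpm[g], group_order.index(g)))
    return ordered, tie


def methylation_difference_filter(
    cpg_group_means: pd.DataFrame,
    expression_order: Sequence[str],
    threshold: float = 0.25,
    strict: bool = False,
) -> tuple[bool, list]:
    """Inverse-directionality difference filter over one gene's promoter CpGs.

    ``cpg_group_means`` is CpGs x groups (proportion scale);
    ``expression_order`` lists groups ascending by expression.  A CpG passes
    when methylation in the lowest-expression group minus methylation in the
    highest-expression group is at least ``threshold``; in ``strict`` mode
    methylation must additionally be monotone non-increasing along the full
    expression ordering.  Returns ``(any_pass, passing_index_labels)``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    low, high = expression_order[0], expression_order[-1]
    delta = cpg_group_means[low] - cpg_group_means[high]
    passing = delta >= threshold
    if strict:
        ordered = cpg_group_means[list(expression_order)].to_numpy()
        monotone = (np.diff(ordered, axis=1) <= 0).all(axis=1)
        passing = passing & monotone
    labels = cpg_group_means.index[passing].tolist()
    return bool(passing.any()), labels


def identify_methylation_regulated_genes(
    de_result: pd.DataFrame,
    dm_result: pd.DataFrame,
    annotation: pd.DataFrame,
    threshold: float = 0.25,
    q_cutoff: float = 0.05,
    require_dmc: bool = True,
    strict: bool = False,
    group_order: Sequence[str] = GROUP_ORDER,
) -> pd.DataFrame:
    """Compose DEG calls, promoter DMCs and the difference filter.

    ``de_result`` comes from the ANOVA-like expression fit (needs q_value
    and per-group ``mean_cpm_<group>`` columns), ``dm_result`` from the
    methylation Wald test (indexed by (chrom, position) with q_value and
    ``mean_meth_<group>`` columns).  When ``require_dmc`` the CpG that
    passes the difference filter must itself be a DMC; otherwise any
    promoter CpG may pass while DMC presence is still required.

    Returns a per-gene audit table; the methylation-regulated set is the
    ``passed`` subset.
    """
    windows = gene_windows(annotation)
    degs = de_result.index[de_result["q_value"] < q_cutoff]
    dm_retained = dm_result.loc[dm_result["q_value"].notna()]
    dmc = dm_retained.loc[dm_retained["q_value"] < q_cutoff]
    dmc_by_gene = associate_dmcs(dmc.index.tolist(), windows.loc[windows.index.intersection(degs)], "promoter")

    meth_cols = {g: f"mean_meth_{g}" for g in group_order}
    rows = []
    for gene in degs:
        cpgs = dmc_by_gene.get(str(gene), [])
        if not cpgs:
            continue
        order, tie = order_groups_by_expression(
            {g: de_result.loc[gene, f"mean_cpm_{g}"] for g in group_order},
            group_order,
        )
        if require_dmc:
            candidates = dmc.loc[dmc.index.isin(cpgs)]
        else:
            w = windows.loc[gene]
            in_prom = dm_retained.index.map(
                lambda t: t[0] == w["chrom"]
                and w["promoter_start"] <= t[1] <= w["promoter_end"]
            )
            candidates = dm_retained.loc[np.asarray(in_prom, dtype=bool)]
        means = candidates[[meth_cols[g] for g in group_order]].copy()
        means.columns = list(group_order)
        passed, passing = methylation_difference_filter(
            means, order, threshold=threshold, strict=strict
        )
        best = float((means[order[0]] - means[order[-1]]).max()) if len(means) else np.nan
        rows.append(
            {
                "gene_id": gene,
                "de_q": float(de_result.loc[gene, "q_value"]),
                "n_promoter_dmcs": len(cpgs),
                "expression_order": "<".join(order),
                "expression_tie": tie,
                "best_delta": best,
                "n_passing_cpgs": len(passing),
                "passing_cpgs": passing,
                "passed": passed,
                "threshold": threshold,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "gene_id", "de_q", "n_promoter_dmcs", "expression_order",
                "expression_tie", "best_delta", "n_passing_cpgs",
                "passing_cpgs", "passed", "threshold",
            ]
        ).set_index("gene_id")
    return pd.DataFrame(rows).set_index("gene_id")


def methylation_regulated_ids(audit: pd.DataFrame) -> set[str]:
    """The gene ids that passed the full filter, from an audit table."""
    if audit.empty:
        return set()
    return set(audit.index[audit["passed"]].astype(str))
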