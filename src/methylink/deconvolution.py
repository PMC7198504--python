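"""Marker-gene deconvolution of bulk expression.

Cell-type proportions in bulk RNA-seq samples are estimated from a
cell-type reference: markers are chosen among highly variable genes by a
deterministic specificity score (log fold-change of the top-expressing
cell type over the runner-up), balanced across types, and per-sample
fractions are obtained by non-negative least squares of bulk CPM on the
marker signature, renormalized to sum to one.  Group differences in the
estimated fractions are assessed with a two-sided Mann-Whitney U test
(exact for small samples without ties, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls


@dataclass(frozen=True)
class SignatureMatrix:
    """Marker-gene reference expression (markers x cell types)."""

    values: pd.DataFrame
    n_hvg: int
    n_markers: int

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need at least two cell types")
        if (self.values.sum(axis=1) == 0).any():
            raise ValueError("signature contains an all-zero marker row")


@dataclass(frozen=True)
class ProportionEstimate:
    """Per-sample cell-type fractions and NNLS residual norms."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    residuals: pd.Series


def _log_normalize(reference: pd.DataFrame) -> pd.DataFrame:
    cpm = reference / reference.sum(axis=0) * 1e6
    return np.log1p(cpm)


def select_markers(
    reference: pd.DataFrame, n_hvg: int = 2000, n_markers: int = 600
) -> SignatureMatrix:
    """Pick cell-type marker genes from a per-type mean expression table.

    Highly variable genes are ranked by variance-to-mean ratio of the
    log-normalized reference; among them, each gene's specificity is the
    log fold-change of its top cell type over the second-highest, and
    ``n_markers`` genes are taken round-robin across top types so the
    signature stays balanced.  The signature keeps the reference's linear
    expression values on the selected rows.
    """
    logref = _log_normalize(reference)
    mean = logref.mean(axis=1)
    var = logref.var(axis=1, ddof=1)
    dispersion = var / np.maximum(mean, 1e-8)
    if n_hvg > len(reference):
        warnings.warn("fewer genes than n_hvg; using all", stacklevel=2)
        hvg = logref.index
    else:
        hvg = dispersion.nlargest(n_hvg).index
    sub = logref.loc[hvg]
    arr = sub.to_numpy()
    order = np.argsort(arr, axis=1)
    top_type = sub.columns[order[:, -1]]
    specificity = arr[np.arange(len(sub)), order[:, -1]] - arr[
        np.arange(len(sub)), order[:, -2]
    ]
    ranked = pd.DataFrame(
        {"type": top_type, "score": specificity}, index=sub.index
    ).sort_values("score", ascending=False)
    n_markers = min(n_markers, len(ranked))
    # round-robin over cell types by decreasing specificity
    chosen: list[str] = []
    queues = {t: list(grp.index) for t, grp in ranked.groupby("type", sort=False)}
    types = list(reference.columns)
    while len(chosen) < n_markers:
        progressed = False
        for t in types:
            q = queues.get(t)
            if q and len(chosen) < n_markers:
                chosen.append(q.pop(0))
                progressed = True
        if not progressed:
            break
    sig = reference.loc[chosen]
    sig = sig.loc[sig.sum(axis=1) > 0]
    return SignatureMatrix(values=sig, n_hvg=len(hvg), n_markers=len(sig))


def estimate_proportions(
    bulk: pd.DataFrame, signature: SignatureMatrix
) -> ProportionEstimate:
    """Non-negative least squares of bulk CPM on the marker signature.

    ``bulk`` is genes x samples (counts or expression).  At least half the
    signature markers must be present in the bulk matrix.  Fractions are
    normalized to sum to one per sample; the pre-normalization residual
    norm is reported.
    """
    markers = signature.values.index.intersection(bulk.index)
    if len(markers) < 0.5 * len(signature.values):
        raise ValueError(
            f"only {len(markers)}/{len(signature.values)} signature markers "
            "present in the bulk matrix"
        )
    colsums = bulk.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("bulk contains an all-zero sample")
    bulk_cpm = (bulk / colsums * 1e6).loc[markers]
    # the signature keeps its linear scale: a mixture of reference columns
    # then recovers the mixing weights themselves (up to the global CPM
    # factor, which the sum-to-one renormalization removes)
    A = signature.values.loc[markers].to_numpy()
    fracs = np.empty((bulk.shape[1], A.shape[1]))
    resid = np.empty(bulk.shape[1])
    for j in range(bulk.shape[1]):
        coef, r = nnls(A, bulk_cpm.iloc[:, j].to_numpy())
        total = coef.sum()
        fracs[j] = coef / total if total > 0 else np.full(A.shape[1], 1 / A.shape[1])
        resid[j] = r
    return ProportionEstimate(
        proportions=pd.DataFrame(
            fracs, index=bulk.columns, columns=signature.values.columns
        ),
        residuals=pd.Series(resid, index=bulk.columns, name="residual_norm"),
    )


def compare_group_proportions(
    estimates: ProportionEstimate | pd.DataFrame,
    design: pd.Series,
    cell_type: str,
    pair: tuple[str, str],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on one cell type's fractions between two groups.

    The exact null distribution is used for total n <= 12 without ties;
    otherwise the normal approximation with tie correction (no continuity
    correction, so full ties give p = 1).
    """
    props = (
        estimates.proportions if isinstance(estimates, ProportionEstimate) else estimates
    )
    design = design.reindex(props.index)
    a = props.loc[design == pair[0], cell_type].to_numpy()
    b = props.loc[design == pair[1], cell_type].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
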