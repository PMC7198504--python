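"""Unsupervised structure of significant feature sets.

Row z-scoring, sample-space PCA (centered SVD, deterministic sign
convention), k-means with elbow-based selection of k, and MA-table export
for pairwise expression contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray


@dataclass(frozen=True)
class ClusterAssignment:
    k: int
    labels: pd.Series  # per-feature cluster label in 1..k
    wcss: dict[int, float]  # within-cluster sum of squares over the k grid
    seed: int


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row z-score (ddof = 1); constant rows become zero and are flagged."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns to z-score rows")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[constant] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(constant, index=matrix.index, name="constant_row"),
    )


def pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA of samples over features via SVD of the feature-centered matrix.

    ``matrix`` is features x samples.  Each feature is centered across
    samples; component signs are fixed by making the largest-magnitude
    loading positive, so score tables are reproducible.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = matrix.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    total = (s**2).sum()
    varexp = s**2 / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=comp),
        variance_explained=varexp,
    )


def kmeans_elbow(
    matrix: pd.DataFrame,
    k_grid: range = range(1, 11),
    seed: int = 0,
    n_restarts: int = 10,
    k: int | None = None,
) -> ClusterAssignment:
    """K-means over rows with elbow-based choice of k.

    The full WCSS curve over ``k_grid`` is always computed and reported so
    the selection is auditable; the elbow is the k maximizing the second
    difference of log WCSS (interior grid points).  The log scale makes the
    rule scale-free: on the raw curve the large early drops dominate the
    curvature and the rule collapses to k = 2 even for well-separated
    clusters.  Pass ``k`` to override the automatic choice.
    """
    ks = sorted(k_grid)
    if max(ks) > matrix.shape[0]:
        raise ValueError("k exceeds the number of rows")
    X = matrix.to_numpy(dtype=float)
    wcss: dict[int, float] = {}
    fits = {}
    for kk in ks:
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
        km.fit(X)
        wcss[kk] = float(km.inertia_)
        fits[kk] = km
    if k is None:
        if len(ks) < 3:
            k = ks[-1]
        else:
            curve = np.log(np.maximum([wcss[kk] for kk in ks], 1e-12))
            second = curve[:-2] - 2 * curve[1:-1] + curve[2:]
            k = ks[1 + int(np.argmax(second))]
    elif k not in fits:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        wcss[k] = float(km.inertia_)
        fits[k] = km
    labels = pd.Series(fits[k].labels_ + 1, index=matrix.index, name="cluster")
    return ClusterAssignment(k=k, labels=labels, wcss=wcss, seed=seed)


def ma_data(de_result: pd.DataFrame, pair: tuple[str, str]) -> pd.DataFrame:
    """MA table for a pairwise contrast: A = mean log2 CPM, M = log2 FC.

    ``de_result`` needs ``mean_cpm_<group>`` columns for both groups plus
    q_value; the DEG flag is q < 0.05.
    """
    a_grp, b_grp = pair
    la = np.log2(de_result[f"mean_cpm_{a_grp}"] + 0.5)
    lb = np.log2(de_result[f"mean_cpm_{b_grp}"] + 0.5)
    col = f"log2fc_{b_grp}_vs_{a_grp}"
    if col in de_result.columns:
        m = de_result[col]
    else:
        m = -de_result[f"log2fc_{a_grp}_vs_{b_grp}"]
    return pd.DataFrame(
        {
            "A": 0.5 * (la + lb),
            "M": m,
            "q_value": de_result["q_value"],
            "deg": de_result["q_value"] < 0.05,
        },
        index=de_result.index,
    )
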