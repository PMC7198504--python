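"""Normalization, dispersion estimation and the NB GLM tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

import methylink as ml
from methylink.rnaseq import (
    ExpressionCountMatrix,
    _fit_group_means,
    _nb_loglik,
    estimate_dispersion,
)


def ecm(array, genes=None, samples=None):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return ExpressionCountMatrix(pd.DataFrame(array, index=genes, columns=samples))


# --- low-expression filter ---


def test_filter_removes_all_zero_genes_and_keeps_expressed():
    counts = ecm([[0, 0, 0], [2, 2, 2], [999_998, 999_998, 999_998]])
    assert counts.library_sizes.tolist() == [1_000_000] * 3
    kept = ml.filter_low_expression(counts, min_cpm=1.0, min_samples=3)
    assert "g0" not in kept.gene_ids
    assert "g1" in kept.gene_ids  # CPM exactly 2 in every sample


def test_filter_strictness_exact_million_library():
    counts = ecm([[1, 1, 1], [2, 2, 2], [999_997, 999_997, 999_997]])
    # library size is exactly 1e6 so gene 0 sits at CPM exactly 1.0
    assert counts.library_sizes.tolist() == [1_000_000] * 3
    kept = ml.filter_low_expression(counts)
    assert "g0" not in kept.gene_ids and "g1" in kept.gene_ids


def test_filter_empty_result_warns():
    counts = ecm([[1, 1, 1], [1, 1, 1]])
    with pytest.warns(UserWarning):
        out = ml.filter_low_expression(counts, min_cpm=1e9)
    assert out.counts.shape[0] == 0


# --- TMM ---


def test_tmm_identical_and_depth_scaled_columns():
    rng = np.random.default_rng(0)
    col = rng.poisson(100, size=200)
    same = ecm(np.column_stack([col, col]))
    np.testing.assert_allclose(ml.tmm_factors(same), [1.0, 1.0])
    doubled = ecm(np.column_stack([col, 2 * col]))
    np.testing.assert_allclose(ml.tmm_factors(doubled), [1.0, 1.0])


def test_tmm_single_upregulated_gene_shrinks_factor():
    base = np.full(10, 100)
    other = base.copy()
    other[0] = 100 * 100  # one gene 100-fold up in sample 2
    counts = ecm(np.column_stack([base, other]))
    f = ml.tmm_factors(counts, reference="s0")
    assert f["s1"] < 1.0


def test_tmm_matches_brute_force_trimmed_mean():
    """Independent re-derivation of the doubly trimmed weighted mean."""
    rng = np.random.default_rng(1)
    a = rng.poisson(rng.lognormal(4, 1, 150)).astype(float) + 1
    b = rng.poisson(rng.lognormal(4, 1, 150)).astype(float) + 1
    counts = ecm(np.column_stack([a, b]))
    f = ml.tmm_factors(counts, reference="s0")
    la, lb = a.sum(), b.sum()
    M = np.log2((b / lb) / (a / la))
    A = 0.5 * np.log2((b / lb) * (a / la))
    w = 1.0 / ((lb - b) / (lb * b) + (la - a) / (la * a))
    n = len(M)
    import scipy.stats as ss

    rm, ra = ss.rankdata(M), ss.rankdata(A)
    keep = (
        (rm >= np.floor(n * 0.3) + 1)
        & (rm <= n - np.floor(n * 0.3))
        & (ra >= np.floor(n * 0.05) + 1)
        & (ra <= n - np.floor(n * 0.05))
    )
    expected = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    # factors are rescaled to geometric mean one across both samples
    expected_pair = np.array([1.0, expected])
    expected_pair /= np.exp(np.mean(np.log(expected_pair)))
    np.testing.assert_allclose(f.to_numpy(), expected_pair, rtol=1e-10)


def test_tmm_column_scaling_leaves_cpm_unchanged():
    rng = np.random.default_rng(2)
    mat = rng.poisson(50, size=(100, 4))
    counts = ecm(mat)
    norm1 = ml.normalize(counts)
    scaled = mat.astype(float).copy()
    scaled[:, 2] *= 7  # depth change only
    norm2 = ml.normalize(ecm(scaled))
    # near-invariance: the trimmed ratio set is unchanged, but the
    # inverse-variance weights depend weakly on depth, so allow ~0.5%
    np.testing.assert_allclose(norm1.cpm, norm2.cpm, rtol=5e-3)


# --- CPM ---


def test_cpm_arithmetic_and_column_sums():
    counts = ecm([[5], [999_995]])
    assert ml.cpm(counts).iloc[0, 0] == pytest.approx(5.0)
    eff = pd.Series([2e6], index=["s0"])
    assert ml.cpm(counts, eff).iloc[0, 0] == pytest.approx(2.5)
    rng = np.random.default_rng(3)
    counts = ecm(rng.poisson(30, size=(50, 3)))
    np.testing.assert_allclose(ml.cpm(counts).sum(axis=0), 1e6)


# --- BH FDR ---


def test_bh_hand_example_and_degenerate_inputs():
    np.testing.assert_allclose(ml.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(ml.bh_fdr([0.42]), [0.42])
    np.testing.assert_allclose(ml.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_nan_propagation():
    q = ml.bh_fdr([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    # m = 2 without the NaN entry
    np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])


@given(
    p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
    seed=st.integers(0, 2**16),
)
@settings(max_examples=60, derandomize=True)
def test_bh_permutation_equivariant_and_dominates_p(p, seed):
    p = np.array(p)
    q = ml.bh_fdr(p)
    assert (q >= p - 1e-12).all() and (q <= 1.0).all()
    perm = np.random.default_rng(seed).permutation(len(p))
    np.testing.assert_allclose(ml.bh_fdr(p[perm]), q[perm])


# --- dispersion estimation ---


def test_dispersion_poisson_counts_go_to_zero():
    rng = np.random.default_rng(4)
    mat = rng.poisson(rng.lognormal(4, 1, 100)[:, None], size=(100, 200))
    counts = ecm(mat)
    design = pd.Series(["a"] * 100 + ["b"] * 100, index=counts.sample_ids)
    phi = estimate_dispersion(counts, design, shrink=1.0)
    assert np.median(phi) < 0.01


def test_dispersion_recovers_nb_truth_at_small_n():
    rng = np.random.default_rng(5)
    mu = rng.lognormal(4.5, 0.8, 400)[:, None] * np.ones((400, 12))
    lam = rng.gamma(1 / 0.1, 0.1 * mu)
    counts = ecm(rng.poisson(lam))
    design = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.sample_ids)
    phi = estimate_dispersion(counts, design)
    assert 0.05 <= np.median(phi) <= 0.2


def test_dispersion_constant_gene_is_zero():
    counts = ecm(np.vstack([np.full(8, 50), np.full(8, 120), [3, 9, 4, 8, 2, 7, 5, 6]]))
    design = pd.Series(["a"] * 8, index=counts.sample_ids)
    norm = ml.NormalizationResult(
        pd.Series(1.0, index=counts.sample_ids),
        pd.Series(1.0, index=counts.sample_ids) * counts.library_sizes.mean(),
        ml.cpm(counts),
    )
    phi = estimate_dispersion(counts, design, norm, shrink=1.0)
    assert phi.iloc[0] == 0.0 and phi.iloc[1] == 0.0


# --- GLM fits ---


def test_glm_null_gene_has_unit_pvalue(small_de, small_cohort):
    de = small_de["de"]
    truth = small_cohort["truth"]
    null_genes = de.index.difference(list(truth.deg_ids))
    # most null genes should have large p; the very flattest essentially 1
    assert de.loc[null_genes, "p_value"].median() > 0.2


def test_glm_matches_brute_force_likelihood_oracle():
    """NB group-means MLE agrees with scalar optimization within 1e-4."""
    rng = np.random.default_rng(6)
    y = rng.poisson([[40, 50, 45, 200, 210, 190], [30, 35, 28, 30, 33, 29]]).astype(
        float
    )
    offsets = np.array([1e6, 1.2e6, 0.9e6, 1.1e6, 1e6, 1.05e6]) / 1e6
    phi = np.array([0.08, 0.12])
    idx_a, idx_b = np.arange(3), np.arange(3, 6)
    ll_ours = 0.0
    mu = np.empty_like(y)
    for idx in (idx_a, idx_b):
        beta = _fit_group_means(y[:, idx], offsets[idx], phi)
        mu[:, idx] = offsets[idx][None, :] * np.exp(beta)[:, None]
    ll_ours = _nb_loglik(y, mu, phi).sum()

    def neg_ll_gene_group(g, idx):
        def f(beta):
            m = offsets[idx][None, :] * np.exp(np.array([beta]))[:, None]
            return -_nb_loglik(y[g : g + 1, idx], m, phi[g : g + 1])[0]

        return minimize_scalar(f, bounds=(-10, 10), method="bounded").fun

    ll_oracle = -sum(
        neg_ll_gene_group(g, idx) for g in range(2) for idx in (idx_a, idx_b)
    )
    assert ll_ours == pytest.approx(ll_oracle, abs=1e-4)


def test_pairwise_equals_anova_on_two_group_design():
    rng = np.random.default_rng(7)
    mat = rng.poisson(rng.lognormal(4, 1, 80)[:, None], size=(80, 8))
    counts = ecm(mat)
    design = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.sample_ids)
    anova = ml.fit_glm_anova_like(counts, design)
    pair = ml.fit_glm_pairwise(counts, design, pair=("a", "b"))
    np.testing.assert_allclose(pair["p_value"], anova["p_value"], rtol=1e-8)


def test_merged_test_is_relabeling_identity(small_cohort):
    counts = ml.filter_low_expression(small_cohort["counts"])
    design = small_cohort["design"]
    merged = ml.fit_glm_pairwise(
        counts, design, pair=("control", "AT"), merge={"AT": ["mild", "classic"]}
    )
    relabeled = design.replace({"mild": "AT", "classic": "AT"})
    direct = ml.fit_glm_pairwise(counts, relabeled, pair=("control", "AT"))
    np.testing.assert_allclose(merged["p_value"], direct["p_value"], rtol=1e-8)


def test_planted_deg_direction_and_power(small_cohort, small_de):
    de = small_de["de"]
    truth = small_cohort["truth"]
    planted = de.index.intersection(list(truth.deg_ids))
    recovered = planted[de.loc[planted, "q_value"] < 0.05]
    assert len(recovered) >= 0.8 * len(planted)
    # fitted group ordering matches the planted ordering for recovered DEGs
    agree = 0
    for g in recovered:
        fit_means = {
            grp: de.loc[g, f"mean_cpm_{grp}"] for grp in ("control", "mild", "classic")
        }
        true_means = truth.group_mean_expression[str(g)]
        if max(fit_means, key=fit_means.get) == max(true_means, key=true_means.get):
            agree += 1
    assert agree >= 0.95 * len(recovered)
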