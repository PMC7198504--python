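"""Beta scores, spike-in conversion efficiency and the DM Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methylink as ml
from methylink.methylation import (
    CpGMethylationTable,
    read_bismark_coverage,
    write_bismark_coverage,
)

from conftest import make_bb_table


def table_from_rows(rows):
    return CpGMethylationTable(
        pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "position",
                "sample_id",
                "count_methylated",
                "count_unmethylated",
            ],
        )
    )


# --- Bismark coverage I/O ---


def test_parse_simple_line(tmp_path):
    p = tmp_path / "s1.cov"
    p.write_text("chr1\t100\t100\t75.0\t3\t1\n")
    t = read_bismark_coverage(p)
    rec = t.records.iloc[0]
    assert (rec["count_methylated"], rec["count_unmethylated"]) == (3, 1)
    assert t.beta.iloc[0] == pytest.approx(0.75)
    assert t.records["sample_id"].iloc[0] == "s1"


def test_empty_file_warns(tmp_path):
    p = tmp_path / "empty.cov"
    p.write_text("")
    with pytest.warns(UserWarning):
        t = read_bismark_coverage(p)
    assert len(t.records) == 0


def test_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.cov"
    p.write_text("chr1\t100\t100\t75.0\t3\t1\nchr1\tnot_a_number\t5\t0\t1\t1\n")
    with pytest.raises(ValueError, match=":2"):
        read_bismark_coverage(p)


def test_inconsistent_percentage_warns(tmp_path):
    p = tmp_path / "odd.cov"
    p.write_text("chr1\t100\t100\t10.0\t3\t1\n")  # true 75%
    with pytest.warns(UserWarning, match="inconsistent"):
        read_bismark_coverage(p)


def test_zero_coverage_rows_dropped(tmp_path):
    p = tmp_path / "z.cov"
    p.write_text("chr1\t1\t1\t0.0\t0\t0\nchr1\t2\t2\t50.0\t1\t1\n")
    with pytest.warns(UserWarning, match="zero-coverage"):
        t = read_bismark_coverage(p)
    assert len(t.records) == 1


def test_roundtrip_write_read_identity(tmp_path, small_cohort):
    table = small_cohort["cpgs"]
    write_bismark_coverage(table, tmp_path)
    back = ml.methylation.read_coverage_dir(tmp_path)
    a = table.records.sort_values(["sample_id", "chrom", "position"]).reset_index(
        drop=True
    )
    b = back.records.sort_values(["sample_id", "chrom", "position"]).reset_index(
        drop=True
    )
    pd.testing.assert_frame_equal(a, b[a.columns], check_dtype=False)


# --- conversion efficiency ---


def test_fully_unmethylated_spikein_is_100_percent():
    t = table_from_rows([("lambda", i, "s1", 0, 10) for i in range(1, 6)])
    eff = ml.conversion_efficiency(t)
    assert eff.percent_converted == pytest.approx(100.0)


def test_conversion_efficiency_arithmetic():
    # 1 methylated among 250 total calls -> 99.6%
    rows = [("lambda", i, "s1", 0, 25) for i in range(1, 10)]
    rows.append(("lambda", 10, "s1", 1, 24))
    eff = ml.conversion_efficiency(table_from_rows(rows))
    assert eff.percent_converted == pytest.approx(99.6)


def test_simulated_spikein_recovers_conversion_rate():
    cfg = ml.SimulationConfig(n_lambda_cpgs=1000, lambda_meth_rate=0.004, seed=11)
    lam = ml.simulate_lambda_spikein(cfg)
    eff = ml.conversion_efficiency(lam)
    assert eff.percent_converted == pytest.approx(99.6, abs=0.1)
    assert len(lam.records.query("count_methylated > 0")) > 0


def test_zero_rate_spikein_has_no_methylated_calls():
    cfg = ml.SimulationConfig(n_lambda_cpgs=200, lambda_meth_rate=0.0, seed=3)
    lam = ml.simulate_lambda_spikein(cfg)
    assert (lam.records["count_methylated"] == 0).all()


def test_no_lambda_records_is_error():
    with pytest.raises(ValueError):
        ml.conversion_efficiency(
            CpGMethylationTable(
                pd.DataFrame(
                    columns=[
                        "chrom",
                        "position",
                        "sample_id",
                        "count_methylated",
                        "count_unmethylated",
                    ]
                )
            )
        )


# --- arcsine transform ---


def test_arcsine_midpoint_and_boundary_values():
    assert ml.arcsine_transform(5, 10) == pytest.approx(0.0)
    expected = np.arcsin(2 * (0.5 / 11) - 1)
    assert ml.arcsine_transform(0, 10) == pytest.approx(expected)
    assert expected == pytest.approx(-1.1411, abs=1e-4)


def test_arcsine_rejects_invalid_counts():
    with pytest.raises(ValueError):
        ml.arcsine_transform(11, 10)


@given(n=st.integers(1, 200))
@settings(max_examples=40, derandomize=True)
def test_arcsine_strictly_monotone_in_m(n):
    vals = [float(ml.arcsine_transform(m, n)) for m in range(n + 1)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert all(-np.pi / 2 < v < np.pi / 2 for v in vals)


def test_arcsine_variance_stabilization():
    """Var(arcsin(2p_hat - 1)) is approximately 1/N under binomial sampling."""
    rng = np.random.default_rng(12)
    for n in (10, 30, 100):
        for p in (0.3, 0.5, 0.7):
            m = rng.binomial(n, p, size=40_000)
            y = ml.arcsine_transform(m, np.full_like(m, n))
            assert np.var(y) == pytest.approx(1.0 / n, rel=0.2)


# --- DM Wald test ---


def test_flat_cpg_has_null_statistics():
    rows = []
    for j, g in enumerate(["a"] * 3 + ["b"] * 3):
        rows.append(("c1", 100, f"{g}{j}", 5, 5))
    design = pd.Series(
        ["a", "a", "a", "b", "b", "b"],
        index=[f"{g}{j}" for j, g in enumerate(["a"] * 3 + ["b"] * 3)],
    )
    res = ml.dm_wald_test(table_from_rows(rows), design)
    assert res["wald"].iloc[0] == pytest.approx(0.0, abs=1e-10)
    assert res["p_value"].iloc[0] == pytest.approx(1.0)


def test_insufficient_coverage_reported_not_tested():
    rows = [("c1", 1, "a1", 3, 3), ("c1", 1, "a2", 3, 3), ("c1", 1, "b1", 3, 3)]
    design = pd.Series(["a", "a", "b"], index=["a1", "a2", "b1"])
    res = ml.dm_wald_test(
        table_from_rows(rows), design, min_samples_per_group=2
    )
    assert not res["retained"].iloc[0]
    assert res["reason"].iloc[0] == "insufficient_group_coverage"
    assert np.isnan(res["p_value"].iloc[0])


def test_wald_grows_with_information():
    """Doubling all counts at fixed proportions increases the statistic."""
    design = pd.Series(
        ["a", "a", "a", "b", "b", "b"], index=["a1", "a2", "a3", "b1", "b2", "b3"]
    )

    def wald_at(scale):
        rows = []
        for s in ("a1", "a2", "a3"):
            rows.append(("c1", 1, s, 2 * scale, 8 * scale))
        for s in ("b1", "b2", "b3"):
            rows.append(("c1", 1, s, 6 * scale, 4 * scale))
        return ml.dm_wald_test(table_from_rows(rows), design)["wald"].iloc[0]

    w = [wald_at(s) for s in (1, 2, 4, 8)]
    assert all(b > a for a, b in zip(w, w[1:]))


def test_wald_agrees_with_betabinomial_lrt_oracle():
    """Two-group Wald z^2 tracks a brute-force beta-binomial LRT."""
    from scipy.special import betaln, gammaln

    def bb_loglik(m, n, p, phi):
        conc = 1 / phi - 1
        a, b = p * conc, (1 - p) * conc
        return np.sum(
            gammaln(n + 1)
            - gammaln(m + 1)
            - gammaln(n - m + 1)
            + betaln(m + a, n - m + b)
            - betaln(a, b)
        )

    p_grid = np.linspace(0.02, 0.98, 385)
    phi_grid = np.geomspace(1e-4, 0.3, 50)

    def lrt(m_a, n_a, m_b, n_b):
        # profile the dispersion under the full model, then compare
        # likelihoods at that fixed dispersion (as a GLM LRT does)
        best, phi_star = -np.inf, phi_grid[0]
        m_all, n_all = np.concatenate([m_a, m_b]), np.concatenate([n_a, n_b])
        for phi in phi_grid:
            full = max(bb_loglik(m_a, n_a, p, phi) for p in p_grid) + max(
                bb_loglik(m_b, n_b, p, phi) for p in p_grid
            )
            if full > best:
                best, phi_star = full, phi
        null = max(bb_loglik(m_all, n_all, p, phi_star) for p in p_grid)
        return 2 * (best - null)

    rng = np.random.default_rng(21)
    design = pd.Series(
        ["a", "a", "a", "b", "b", "b"], index=["a1", "a2", "a3", "b1", "b2", "b3"]
    )
    ratios = []
    for rep in range(5):
        n = rng.integers(40, 60, size=6)
        m = np.concatenate(
            [rng.binomial(n[:3], 0.30), rng.binomial(n[3:], 0.62)]
        )
        rows = [
            ("c1", 1, s, int(m[j]), int(n[j] - m[j]))
            for j, s in enumerate(design.index)
        ]
        res = ml.dm_wald_test(table_from_rows(rows), design)
        wald = res["wald"].iloc[0]
        z = res["z_b_vs_a"].iloc[0]
        assert np.sign(z) > 0  # direction matches the planted increase
        ratios.append(wald / lrt(m[:3], n[:3], m[3:], n[3:]))
    assert np.median(ratios) == pytest.approx(1.0, abs=0.15)


def test_null_type_one_error_calibrated():
    rng = np.random.default_rng(22)
    p_true = rng.uniform(0.1, 0.9, 3000)
    table, design = make_bb_table(
        rng,
        {"control": p_true, "mild": p_true, "classic": p_true},
        {"control": 4, "mild": 3, "classic": 5},
        n_cpgs=3000,
    )
    res = ml.dm_wald_test(table, design)
    frac = float((res["p_value"] < 0.05).mean())
    assert 0.03 <= frac <= 0.07


def test_planted_difference_power():
    rng = np.random.default_rng(23)
    n_null, n_alt = 2500, 500
    p_null = rng.uniform(0.1, 0.9, n_null)
    p_by_group = {
        "control": np.concatenate([p_null, np.full(n_alt, 0.35)]),
        "mild": np.concatenate([p_null, np.full(n_alt, 0.65)]),
        "classic": np.concatenate([p_null, np.full(n_alt, 0.65)]),
    }
    table, design = make_bb_table(
        rng, p_by_group, {"control": 4, "mild": 3, "classic": 5}, n_cpgs=n_null + n_alt
    )
    res = ml.dm_wald_test(table, design).reset_index()
    alt = res["position"] > n_null
    assert (res.loc[alt, "q_value"] < 0.05).mean() >= 0.8


def test_q_calls_subset_of_p_calls(small_dm):
    res = small_dm.dropna(subset=["q_value"])
    assert ((res["q_value"] >= res["p_value"]) | np.isclose(res["q_value"], res["p_value"])).all()
    assert set(res.index[res["q_value"] < 0.05]) <= set(res.index[res["p_value"] < 0.05])
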