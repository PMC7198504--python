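import numpy as np
import pandas as pd
import pytest

import methylink as ml


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared by unit tests (fast to generate)."""
    cfg = ml.SimulationConfig(
        n_genes=300,
        n_cpgs_per_promoter=2,
        frac_deg=0.2,
        frac_mr=0.5,
        seed=7,
    )
    counts, cpgs, annotation, sheet, truth = ml.simulate_cohort(cfg)
    design = sheet.set_index("sample_id")["group"]
    return {
        "config": cfg,
        "counts": counts,
        "cpgs": cpgs,
        "annotation": annotation,
        "sheet": sheet,
        "design": design,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_de(small_cohort):
    counts = ml.filter_low_expression(small_cohort["counts"])
    norm = ml.normalize(counts)
    de = ml.fit_glm_anova_like(counts, small_cohort["design"], norm)
    return {"counts": counts, "norm": norm, "de": de}


@pytest.fixture(scope="session")
def small_dm(small_cohort):
    return ml.dm_wald_test(small_cohort["cpgs"], small_cohort["design"])


def make_bb_table(
    rng: np.random.Generator,
    p_by_group: dict[str, float] | dict[str, np.ndarray],
    n_per_group: dict[str, int],
    n_cpgs: int,
    coverage_mean: float = 30.0,
    phi: float = 0.02,
    chrom: str = "c1",
) -> tuple[ml.CpGMethylationTable, pd.Series]:
    """Direct beta-binomial CpG table with given per-group true proportions."""
    rows = []
    sids, groups = [], []
    for g, n in n_per_group.items():
        for i in range(n):
            sids.append(f"{g}_{i + 1}")
            groups.append(g)
    conc = 1.0 / phi - 1.0 if phi > 0 else None
    for sid, g in zip(sids, groups):
        cov = 1 + rng.poisson(coverage_mean - 1, n_cpgs)
        p = np.broadcast_to(np.asarray(p_by_group[g], dtype=float), (n_cpgs,))
        if conc is not None:
            pi = rng.beta(np.clip(p * conc, 1e-8, None),
                          np.clip((1 - p) * conc, 1e-8, None))
        else:
            pi = p
        m = rng.binomial(cov, pi)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "position": 1 + np.arange(n_cpgs),
                    "sample_id": sid,
                    "count_methylated": m,
                    "count_unmethylated": cov - m,
                }
            )
        )
    table = ml.CpGMethylationTable(pd.concat(rows, ignore_index=True))
    return table, pd.Series(groups, index=sids)
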