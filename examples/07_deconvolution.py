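"""Estimate cell-type proportions in bulk mixtures from marker genes.

Markers are chosen by cell-type specificity among highly variable genes of
a reference profile; each bulk sample's CPM vector is then decomposed by
non-negative least squares into reference contributions, normalized to
fractions.  Groups are compared with a Mann-Whitney U test.
"""

import numpy as np
import pandas as pd

import methylink as ml

reference = ml.simulate_reference(n_genes=300, seed=0)
signature = ml.select_markers(reference, n_hvg=200, n_markers=100)
print(f"signature: {signature.n_markers} markers over {list(reference.columns)}")

rng = np.random.default_rng(1)
# controls richer in B cells than the affected group
props = pd.DataFrame(
    np.vstack(
        [
            rng.dirichlet([6, 4, 2, 2], size=4),  # control
            rng.dirichlet([2, 4, 2, 2], size=8),  # A-T (merged)
        ]
    ),
    index=[f"control_{i}" for i in range(4)] + [f"at_{i}" for i in range(8)],
    columns=reference.columns,
)
bulk = ml.simulate_mixtures(reference, props, noise=0.05, seed=1)

est = ml.estimate_proportions(bulk, signature)
mae = float((est.proportions - props).abs().mean().mean())
print(f"mean absolute recovery error at 5% noise: {mae:.4f}")

design = pd.Series(
    ["control"] * 4 + ["AT"] * 8, index=est.proportions.index
)
u, p = ml.compare_group_proportions(est.proportions, design, "B", ("control", "AT"))
print(f"\nB-cell fraction, control vs A-T: U = {u:.0f}, p = {p:.4f}")
print(
    "\nA small p with lower A-T fractions mirrors the reduced B-cell "
    "representation expected in lymphopenic participants."
)
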