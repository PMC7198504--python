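"""Score the example A-T cohort and compare group ages.

Each participant with ataxia-telangiectasia is scored on six standard
clinical criteria (Yes/No/NK); the fraction of known criteria met decides
mild (<= 0.5) versus classic (> 0.5) phenotype.  Ages are then compared
across control / mild / classic with a one-way ANOVA and a pooled-variance
pairwise test.
"""

import methylink as ml
from methylink.datasets import example_ages_by_group, example_cohort_records

for record in example_cohort_records():
    call = ml.call_phenotype(record)
    print(
        f"{record.participant_id}: % criteria = "
        f"{call.percent_criteria_rounded:.2f} -> {call.phenotype}"
    )

ages = example_ages_by_group()
F, p, df_b, df_w = ml.one_way_anova(ages)
print(f"\nage ANOVA: F({df_b},{df_w}) = {F:.3f}, p = {p:.3f}")
t, p_pair = ml.pooled_pairwise_comparison(ages, ("control", "classic"), family_size=1)
print(f"control vs classic (pooled variance): t = {t:.3f}, p = {p_pair:.3f}")
print(
    "\nA p just above 0.05 means the age differences between groups are "
    "not statistically significant, though age remains a potential confounder."
)
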