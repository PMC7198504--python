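"""Phenotype percent-criteria scoring and cohort-level statistics.

Participants with ataxia-telangiectasia (A-T) are classified as *mild* or
*classic* by the fraction of standard clinical criteria they meet (ataxia
before age 8, loss of walking before 15, oculomotor ataxia before 15,
ocular telangiectasia before 15, IgA deficiency, clinical
immunodeficiency).  Criteria may be recorded as ``Yes``, ``No`` or ``NK``
(not known); NK entries are excluded from the denominator, so the score is
``#Yes / (#Yes + #No)``.  A participant is *mild* when the score is at or
below one half and *classic* otherwise.

The module also provides the cohort-level age comparisons used to check
group comparability: a classical fixed-effects one-way ANOVA and a
pooled-variance pairwise t comparison with an optional Sidak family
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CRITERIA = (
    "ataxia<8y",
    "loss_of_walking<15y",
    "oculomotor_ataxia<15y",
    "ocular_telangiectasia<15y",
    "IgA_deficiency",
    "clinical_immunodeficiency",
)

_VALID_VALUES = frozenset({"Yes", "No", "NK"})


class UndefinedScoreError(ValueError):
    """Raised when every criterion is NK and no score can be formed."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """One participant's six criterion calls and age.

    ``criteria`` maps each name in :data:`CRITERIA` to ``"Yes"``, ``"No"``
    or ``"NK"``.
    """

    participant_id: str
    criteria: Mapping[str, str]
    age_years: float = float("nan")

    def __post_init__(self) -> None:
        if set(self.criteria) != set(CRITERIA):
            missing = set(CRITERIA) - set(self.criteria)
            extra = set(self.criteria) - set(CRITERIA)
            raise ValueError(
                f"record {self.participant_id!r}: expected exactly the six "
                f"standard criteria (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )
        bad = {k: v for k, v in self.criteria.items() if v not in _VALID_VALUES}
        if bad:
            raise ValueError(
                f"record {self.participant_id!r}: criterion values must be "
                f"Yes/No/NK, got {bad}"
            )
        if not np.isnan(self.age_years) and self.age_years <= 0:
            raise ValueError("age_years must be positive")


@dataclass(frozen=True)
class PhenotypeCall:
    """Score and classification for one participant."""

    participant_id: str
    percent_criteria: float  # unrounded fraction in [0, 1]
    phenotype: str  # "mild" or "classic"
    percent_criteria_rounded: float = field(default=float("nan"))


def compute_percent_criteria(record: PhenotypeRecord) -> float:
    """Fraction of known criteria met: ``#Yes / (#Yes + #No)``.

    NK values are excluded from the denominator.  Raises
    :class:`UndefinedScoreError` if all six criteria are NK.
    """
    values = [record.criteria[name] for name in CRITERIA]
    n_yes = values.count("Yes")
    n_no = values.count("No")
    if n_yes + n_no == 0:
        raise UndefinedScoreError(
            f"record {record.participant_id!r}: all criteria are NK"
        )
    return n_yes / (n_yes + n_no)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.675 -> 0.68), unlike banker's rounding."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def classify_phenotype(percent: float) -> str:
    """``mild`` iff the (unrounded) criteria fraction is <= 0.5, else ``classic``."""
    if not 0.0 <= percent <= 1.0:
        raise ValueError(f"percent_criteria must be in [0, 1], got {percent}")
    return "mild" if percent <= 0.5 else "classic"


def call_phenotype(record: PhenotypeRecord) -> PhenotypeCall:
    """Score a record and classify it in one step."""
    frac = compute_percent_criteria(record)
    return PhenotypeCall(
        participant_id=record.participant_id,
        percent_criteria=frac,
        phenotype=classify_phenotype(frac),
        percent_criteria_rounded=round_half_away(frac, 2),
    )


def one_way_anova(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[float, float, int, int]:
    """Classical fixed-effects one-way ANOVA.

    Returns ``(F, p, df_between, df_within)``.  When both the between- and
    within-group sums of squares are zero (all values identical) the test is
    degenerate and ``p = 1`` by convention.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(values_by_group, groups):
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    n = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0, df_between, df_within
        return float("inf"), 0.0, df_between, df_within
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p, df_between, df_within


def pooled_pairwise_comparison(
    values_by_group: Mapping[str, Sequence[float]],
    pair: tuple[str, str],
    family_size: int = 1,
) -> tuple[float, float]:
    """Two-sided pairwise t on the ANOVA pooled within-group variance.

    The t statistic uses the pooled within-group variance over *all* groups
    and its error degrees of freedom (the classical post hoc construction),
    then applies a Sidak family adjustment
    ``p_adj = 1 - (1 - p) ** family_size``.  ``family_size = 1`` is the
    unadjusted comparison.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    for g in pair:
        if g not in values_by_group:
            raise ValueError(f"group {g!r} not present")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    n = sum(g.size for g in groups.values())
    k = len(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_err = n - k
    s2 = ss_within / df_err
    a, b = groups[pair[0]], groups[pair[1]]
    if s2 == 0.0:
        t = 0.0 if a.mean() == b.mean() else float("inf")
    else:
        t = (a.mean() - b.mean()) / np.sqrt(s2 * (1 / a.size + 1 / b.size))
    p = float(2 * stats.t.sf(abs(t), df_err)) if np.isfinite(t) else 0.0
    p_adj = 1.0 - (1.0 - p) ** family_size
    return float(t), float(p_adj)


def two_group_score_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "t",
) -> tuple[float, float]:
    """Compare a score between two participant groups.

    ``method="t"`` is Welch's two-sample t; ``method="mannwhitney"`` is the
    two-sided Mann-Whitney U.  Both are exposed because the cohort contrast
    between phenotype classes does not prescribe one.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def read_cohort_table(path) -> list[PhenotypeRecord]:
    """Read a cohort CSV with columns participant_id, the six criteria, age_years.

    ``NK`` is the literal for not-known.  Rows whose criteria are all missing
    (e.g. unaffected controls marked with dashes) are skipped.
    """
    df = pd.read_csv(path, dtype=str)
    records = []
    for _, row in df.iterrows():
        crit = {name: str(row[name]).strip() for name in CRITERIA}
        if all(v not in _VALID_VALUES for v in crit.values()):
            continue
        records.append(
            PhenotypeRecord(
                participant_id=str(row["participant_id"]),
                criteria=crit,
                age_years=float(row.get("age_years", "nan")),
            )
        )
    return records


def write_calls(calls: Sequence[PhenotypeCall], path) -> None:
    """Write participant calls to CSV (id, rounded score, phenotype)."""
    pd.DataFrame(
        {
            "participant_id": [c.participant_id for c in calls],
            "percent_criteria": [c.percent_criteria_rounded for c in calls],
            "phenotype": [c.phenotype for c in calls],
        }
    ).to_csv(path, index=False)
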