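"""Small built-in example datasets.

``example_cohort`` is a twelve-participant clinical series — eight people
with ataxia-telangiectasia scored on the six standard diagnostic criteria
(Yes/No/NK, NK = not known) plus four unaffected young-adult controls —
used throughout the documentation and tests to exercise the phenotype
scoring and the cohort age statistics.
"""

from __future__ import annotations

import pandas as pd

from .cohort import CRITERIA, PhenotypeRecord

# participant_id, six criteria in CRITERIA order, age (years), group
_COHORT_ROWS = [
    ("AT002", "Yes", "Yes", "NK", "NK", "Yes", "No", 26, "classic"),
    ("AT005", "Yes", "Yes", "Yes", "Yes", "NK", "No", 29, "classic"),
    ("AT006", "Yes", "Yes", "Yes", "Yes", "No", "No", 12, "classic"),
    ("AT007", "Yes", "Yes", "Yes", "Yes", "Yes", "No", 14, "classic"),
    ("AT008", "Yes", "Yes", "Yes", "Yes", "Yes", "No", 12, "classic"),
    ("AT001", "Yes", "No", "NK", "NK", "No", "No", 33, "mild"),
    ("AT003", "Yes", "No", "Yes", "Yes", "No", "No", 29, "mild"),
    ("AT004", "Yes", "No", "NK", "Yes", "NK", "No", 31, "mild"),
    ("AT009", None, None, None, None, None, None, 21, "control"),
    ("AT010", None, None, None, None, None, None, 26, "control"),
    ("AT011", None, None, None, None, None, None, 26, "control"),
    ("AT012", None, None, None, None, None, None, 31, "control"),
]


def example_cohort() -> pd.DataFrame:
    """The example A-T cohort as a DataFrame.

    Columns: ``participant_id``, the six criteria (``None`` for controls,
    who are not scored), ``age_years`` and ``group``
    (control/mild/classic).
    """
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=["participant_id", *CRITERIA, "age_years", "group"],
    )


def example_cohort_records() -> list[PhenotypeRecord]:
    """The scoreable (A-T) participants as :class:`PhenotypeRecord` objects."""
    records = []
    for row in _COHORT_ROWS:
        if row[1] is None:
            continue
        records.append(
            PhenotypeRecord(
                participant_id=row[0],
                criteria=dict(zip(CRITERIA, row[1:7])),
                age_years=float(row[7]),
            )
        )
    return records


def example_ages_by_group() -> dict[str, list[float]]:
    """Participant ages keyed by group (control, mild, classic)."""
    out: dict[str, list[float]] = {"control": [], "mild": [], "classic": []}
    for row in _COHORT_ROWS:
        out[row[8]].append(float(row[7]))
    return out
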