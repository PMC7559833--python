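"""Embedded reference panels from a published questionnaire-validation study.

Two 11-expert panels (sports-medicine physicians and nurses) each rated the
30 items of a physical-activity-on-prescription questionnaire on a 1-5
Likert scale. The published rating tables print items as rows and experts
as columns, with the replacement ("exchanged") expert in the column of the
judge they substituted and the excluded judge's ratings in the last column;
the constants below transcribe them verbatim in that orientation, and the
loader transposes to the experts-as-rows convention used everywhere else.

The nurses table is known to disagree with the published per-item frequency
table at two cells (expert 3/item 26 and expert 8/item 27: the ratings print
as 2 and 1 where the frequencies imply 3 at both). Neither reading is
silently preferred: ``variant="verbatim"`` returns the rating table as
printed, ``variant="table6-reconciled"`` returns the frequency-consistent
correction.
"""

from __future__ import annotations

import numpy as np

from .data import ExpertProfile, LikertScale, RatingMatrix

__all__ = ["FIXTURE_NAMES", "FIXTURE_VARIANTS", "load_fixture", "original_pool", "replacement_experts"]

FIXTURE_NAMES = ("physicians", "nurses")
FIXTURE_VARIANTS = ("verbatim", "table6-reconciled")

# Items 1-30 as rows; expert columns in published order.
_PHYSICIAN_COLUMNS = ("1", "2", "11", "4", "5", "6", "7", "8", "9", "10", "3")
_PHYSICIAN_RATINGS = """\
5 5 5 4 4 5 5 5 5 5 5
5 5 4 2 4 5 5 5 5 4 5
5 4 3 4 3 5 5 5 5 3 3
5 5 4 5 3 4 5 5 5 5 4
4 5 5 5 3 5 5 5 5 5 5
5 5 3 4 4 5 5 4 5 5 4
4 5 5 4 4 3 5 5 5 5 5
4 5 5 4 4 5 5 5 5 5 3
3 4 3 3 4 5 5 4 5 5 4
3 4 3 3 4 5 5 5 5 5 4
4 3 3 4 4 4 5 4 5 5 4
4 3 4 3 4 5 5 5 5 4 1
3 4 5 5 4 5 5 5 5 5 3
4 3 5 5 4 5 5 4 5 4 4
3 3 5 5 4 5 5 5 5 4 1
3 3 5 5 4 5 5 5 5 5 3
3 4 4 5 4 5 5 5 5 5 4
3 4 3 5 4 5 5 4 5 5 3
3 4 5 5 4 5 5 5 5 5 5
3 4 5 4 4 5 5 5 5 5 3
4 3 3 4 4 5 5 5 5 4 4
3 3 4 4 4 5 5 5 5 4 3
3 4 3 4 4 5 5 5 5 4 3
4 4 3 4 3 5 5 5 5 5 2
4 4 3 4 3 5 5 5 5 5 3
3 4 3 4 3 5 5 5 5 5 3
4 4 5 5 4 5 5 3 5 5 1
3 4 4 4 4 5 5 4 5 5 1
3 5 4 4 4 5 5 5 3 4 2
4 4 4 5 4 5 5 5 5 4 4
"""

_NURSE_COLUMNS = ("1", "2", "3", "4", "5", "6", "11", "8", "9", "10", "7")
_NURSE_RATINGS = """\
5 4 5 4 4 5 4 5 5 5 2
5 4 3 3 4 5 4 4 4 5 1
5 5 3 5 4 5 4 5 3 5 5
4 5 4 4 4 5 4 5 5 5 4
5 4 5 5 5 5 4 4 4 5 1
5 4 3 4 4 5 3 5 5 5 4
5 4 4 5 4 5 4 3 5 5 4
5 4 5 5 5 5 3 4 5 5 3
5 4 4 5 5 5 3 5 5 5 5
5 4 4 5 4 5 4 4 3 5 5
5 4 5 4 5 5 4 5 5 5 4
4 4 4 5 5 5 3 5 3 4 2
4 5 5 5 5 5 3 5 5 5 4
5 5 4 5 5 5 4 5 5 5 2
5 5 4 5 5 5 3 5 4 4 2
5 5 5 5 5 5 3 5 4 5 4
5 5 5 4 5 5 4 5 5 5 5
5 5 5 5 5 5 4 5 5 5 5
2 5 5 5 5 5 4 5 5 5 5
5 5 5 5 5 5 4 5 5 5 5
4 5 4 5 5 5 4 5 5 5 5
5 5 5 5 5 5 5 5 5 5 5
5 5 5 5 5 5 4 5 5 5 5
2 4 4 4 5 5 3 5 4 5 5
5 5 4 5 5 5 4 5 5 5 5
2 5 2 4 5 5 3 5 4 5 5
3 5 2 4 5 5 4 1 5 5 3
5 5 3 4 5 5 4 2 5 5 4
4 4 5 5 5 5 4 5 5 5 5
5 5 5 5 5 5 4 5 5 5 5
"""

# (expert_id -> corrected rating) per item, applied on top of the verbatim
# nurses table to match the published frequency rows.
_NURSE_RECONCILIATIONS = {("3", "26"): 3, ("8", "27"): 3}

# Published panel metadata for the ten final experts (the excluded judge's
# profile was not published). Tuples: (id, age_range, sex, career_years).
_PHYSICIAN_PROFILES = (
    ("1", "51-55", "Female", 20, False),
    ("2", "51-55", "Female", 25, False),
    ("11", "56-60", "Male", 36, True),
    ("4", "56-60", "Male", 31, False),
    ("5", ">60", "Female", 36, False),
    ("6", "56-60", "Male", 30, False),
    ("7", ">60", "Male", 30, False),
    ("8", ">60", "Female", 25, False),
    ("9", ">60", "Male", 25, False),
    ("10", "51-55", "Female", 26, False),
)
_NURSE_PROFILES = (
    ("1", "56-60", "Female", 35, False),
    ("2", "46-50", "Male", 28, False),
    ("3", "41-45", "Female", 19, False),
    ("4", "36-40", "Female", 10, False),
    ("5", "41-45", "Male", 20, False),
    ("6", "41-45", "Female", 3, False),
    ("11", "36-40", "Female", 4, True),
    ("8", "46-50", "Female", 9, False),
    ("9", "36-40", "Male", 5, False),
    ("10", "51-55", "Female", 30, False),
)


def _parse_items_by_experts(text: str) -> np.ndarray:
    rows = [[int(x) for x in line.split()] for line in text.strip().splitlines()]
    return np.array(rows, dtype=np.int64)


def load_fixture(
    panel_name: str, variant: str = "verbatim"
) -> tuple[RatingMatrix, list[ExpertProfile]]:
    """Return one embedded 11-expert x 30-item panel with its expert profiles.

    Parameters
    ----------
    panel_name : {"physicians", "nurses"}
    variant : {"verbatim", "table6-reconciled"}
        ``"verbatim"`` transcribes the published rating table as printed.
        ``"table6-reconciled"`` additionally applies the two nurses-panel
        cell corrections implied by the published frequency table; for the
        physicians panel the variants are identical.

    Returns
    -------
    (RatingMatrix, list[ExpertProfile])
        The matrix has experts as rows in published column order; items are
        labelled ``"1"``..``"30"``. Profiles cover the ten published final
        experts, with the replacement judge flagged.
    """
    if panel_name not in FIXTURE_NAMES:
        raise KeyError(f"unknown panel {panel_name!r}; expected one of {FIXTURE_NAMES}")
    if variant not in FIXTURE_VARIANTS:
        raise KeyError(f"unknown variant {variant!r}; expected one of {FIXTURE_VARIANTS}")

    scale = LikertScale(1, 5)
    if panel_name == "physicians":
        columns, text, raw_profiles, role = (
            _PHYSICIAN_COLUMNS, _PHYSICIAN_RATINGS, _PHYSICIAN_PROFILES, "physician",
        )
    else:
        columns, text, raw_profiles, role = (
            _NURSE_COLUMNS, _NURSE_RATINGS, _NURSE_PROFILES, "nurse",
        )
    items_by_experts = _parse_items_by_experts(text)
    ratings = items_by_experts.T.copy()  # experts as rows
    item_ids = [str(j + 1) for j in range(items_by_experts.shape[0])]
    if panel_name == "nurses" and variant == "table6-reconciled":
        for (expert, item), value in _NURSE_RECONCILIATIONS.items():
            ratings[columns.index(expert), item_ids.index(item)] = value
    matrix = RatingMatrix(panel_name, scale, columns, item_ids, ratings)
    profiles = [
        ExpertProfile(
            expert_id=eid, role=role, age_range=age, sex=sex,
            career_years=years, replacement=repl,
        )
        for eid, age, sex, years, repl in raw_profiles
    ]
    return matrix, profiles


def replacement_experts(profiles) -> list[str]:
    """Expert ids flagged as replacements, in profile order."""
    return [p.expert_id for p in profiles if p.replacement]


def original_pool(matrix: RatingMatrix, profiles) -> list[str]:
    """Screening pool: matrix experts that are not replacements, matrix order."""
    repl = set(replacement_experts(profiles))
    return [e for e in matrix.expert_ids if e not in repl]
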