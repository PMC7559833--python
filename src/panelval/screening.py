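"""Discordant-judge screening by leave-one-out comparison.

Before computing validity coefficients, the panel is screened for judges
whose answers are far from the consensus: for each expert and item, the
expert's rating is compared with the mean rating of the *other* experts in
the screening pool (the leave-one-out mean). An answer is deviant when the
absolute difference reaches the deviance threshold (default: 3 scale
points), and an expert with deviant answers on at least ``m`` items
(default: 2) is excluded. Excluded judges are then substituted by
replacement experts when the final panel is assembled.

An alternative ``sd_multiple`` policy mode flags answers at least
``d`` leave-one-out sample SDs from the leave-one-out mean; it is provided
for sensitivity analyses but is not the default (see the package methods
note for why the absolute-points reading is the one that reproduces the
reference panels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import RatingMatrix

__all__ = [
    "DeviancePolicy",
    "AnswerFlag",
    "ScreeningResult",
    "loo_mean",
    "flag_deviant_answers",
    "screen_experts",
    "assemble_final_panel",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeviancePolicy:
    """Rule deciding which answers are deviant and which experts are excluded.

    Parameters
    ----------
    deviance_threshold : float
        Deviance distance ``d`` in rating points (``absolute_points`` mode)
        or in leave-one-out SD multiples (``sd_multiple`` mode). Default 3.
    min_flagged_items : int
        Minimum number of flagged items ``m`` that excludes an expert.
        Default 2 ("two or more questions").
    mode : {"absolute_points", "sd_multiple"}
    inclusive : bool
        If True (default), a difference of exactly ``d`` flags (the rule is
        a ">=" comparison).
    """

    deviance_threshold: float = 3.0
    min_flagged_items: int = 2
    mode: str = "absolute_points"
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.deviance_threshold <= 0:
            raise ValueError("deviance_threshold must be positive")
        if self.min_flagged_items < 1:
            raise ValueError("min_flagged_items must be >= 1")
        if self.mode not in ("absolute_points", "sd_multiple"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class AnswerFlag:
    """One deviant answer: who, where, and how far from the consensus."""

    expert_id: str
    item_id: str
    rating: int
    loo_mean: float
    abs_difference: float


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of screening a pool of experts."""

    policy: DeviancePolicy
    flags: tuple[AnswerFlag, ...]
    flag_count_per_expert: Mapping[str, int]
    excluded_experts: tuple[str, ...]
    retained_expert_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "policy": vars(self.policy) | {},
            "flags": [vars(f) | {} for f in self.flags],
            "flag_count_per_expert": dict(self.flag_count_per_expert),
            "excluded_experts": list(self.excluded_experts),
            "retained_expert_ids": list(self.retained_expert_ids),
        }


def _check_pool(matrix: RatingMatrix, pool: Sequence[str]) -> list[str]:
    pool = [str(e) for e in pool]
    unknown = [e for e in pool if e not in matrix.expert_ids]
    if unknown:
        raise ValueError(f"pool experts not in matrix: {unknown}")
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate experts in pool")
    if len(pool) < 2:
        raise ValueError("screening pool needs at least 2 experts")
    # matrix order, regardless of how the pool was passed
    return [e for e in matrix.expert_ids if e in set(pool)]


def loo_mean(matrix: RatingMatrix, expert: str, item: str, pool: Sequence[str]) -> float:
    """Mean rating of the pool at ``item`` with ``expert`` left out."""
    pool = _check_pool(matrix, pool)
    if str(expert) not in pool:
        raise ValueError(f"expert {expert!r} not in pool")
    others = [e for e in pool if e != str(expert)]
    return float(np.mean(matrix.item_ratings(item, others)))


def flag_deviant_answers(
    matrix: RatingMatrix, pool: Sequence[str], policy: DeviancePolicy | None = None
) -> list[AnswerFlag]:
    """All deviant answers within the pool, in matrix (expert, item) order."""
    policy = policy or DeviancePolicy()
    pool = _check_pool(matrix, pool)
    flags: list[AnswerFlag] = []
    for expert in pool:
        others = [e for e in pool if e != expert]
        for item in matrix.item_ids:
            rating = matrix.rating(expert, item)
            other_ratings = matrix.item_ratings(item, others)
            mu = float(np.mean(other_ratings))
            diff = abs(rating - mu)
            if policy.mode == "sd_multiple":
                sd = float(np.std(other_ratings, ddof=1)) if len(other_ratings) > 1 else 0.0
                cutoff = policy.deviance_threshold * sd
            else:
                cutoff = policy.deviance_threshold
            hit = diff >= cutoff if policy.inclusive else diff > cutoff
            if hit:
                flags.append(AnswerFlag(expert, item, rating, mu, diff))
                logger.info(
                    "deviant answer: expert %s item %s rating %d vs leave-one-out mean %.3f",
                    expert, item, rating, mu,
                )
    return flags


def screen_experts(
    matrix: RatingMatrix, pool: Sequence[str], policy: DeviancePolicy | None = None
) -> ScreeningResult:
    """Screen the pool: exclude every expert with >= ``m`` deviant answers."""
    policy = policy or DeviancePolicy()
    pool = _check_pool(matrix, pool)
    flags = flag_deviant_answers(matrix, pool, policy)
    counts = {e: 0 for e in pool}
    for f in flags:
        counts[f.expert_id] += 1
    excluded = tuple(e for e in pool if counts[e] >= policy.min_flagged_items)
    retained = tuple(e for e in pool if e not in excluded)
    for e in excluded:
        logger.info("excluding expert %s (%d deviant answers)", e, counts[e])
    return ScreeningResult(
        policy=policy,
        flags=tuple(flags),
        flag_count_per_expert=counts,
        excluded_experts=excluded,
        retained_expert_ids=retained,
    )


def assemble_final_panel(
    matrix: RatingMatrix,
    screening: ScreeningResult,
    replacements: Sequence[str] = (),
) -> RatingMatrix:
    """Final panel: retained experts plus replacement experts, in that order.

    Replacements must be experts present in the matrix but outside the
    screened pool (they were recruited after the fact to substitute the
    excluded judges).
    """
    replacements = [str(e) for e in replacements]
    pool = set(screening.retained_expert_ids) | set(screening.excluded_experts)
    overlap = [e for e in replacements if e in pool]
    if overlap:
        raise ValueError(f"replacement experts already in screened pool: {overlap}")
    final = list(screening.retained_expert_ids) + replacements
    if len(final) < 2:
        raise ValueError("final panel would have fewer than 2 experts")
    return matrix.subset(final)
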