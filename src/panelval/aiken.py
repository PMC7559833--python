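"""Aiken's V content-validity coefficient with score-method confidence intervals.

For ``n`` judges rating an item on an integer scale ``l..h`` with span
``k = h - l``, Aiken's V rescales the mean rating onto [0, 1]:

    S = sum_i (r_i - l),    V = S / (n * k) = (mean(r) - l) / k

V = 0 when every judge gives the lowest rating, V = 1 when every judge
gives the highest. Treating ``S`` as a score out of ``n*k`` effective
trials, a Wilson-type (score) confidence interval for V inverts the normal
score test:

    L, U = [2*n*k*V + z^2 -/+ z * sqrt(4*n*k*V*(1-V) + z^2)] / [2*(n*k + z^2)]

Both endpoints satisfy the defining equation (V - p)^2 = z^2 p (1-p)/(n k).
An item is declared valid when its (unrounded) V reaches the validity
threshold, conventionally 0.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import LikertScale, RatingMatrix

__all__ = [
    "AikenResult",
    "QuestionnaireSummary",
    "rating_frequencies",
    "aiken_v",
    "score_ci",
    "validate_item",
    "analyze_items",
    "summarize_questionnaire",
]

DEFAULT_THRESHOLD = 0.75
#: Conventional two-sided 95% normal quantile; kept at 1.96 rather than the
#: exact 1.95996... for parity with the standard desk implementations.
DEFAULT_Z = 1.96


def normal_quantile(confidence: float) -> float:
    """Two-sided normal quantile for a confidence level; 1.96 at 95%."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if confidence == 0.95:
        return DEFAULT_Z
    return float(stats.norm.ppf(0.5 + confidence / 2))


@dataclass(frozen=True)
class AikenResult:
    """Per-item validity analysis over the final panel."""

    item_id: str
    n: int
    freq: tuple[int, ...]
    mean_rating: float
    S: int
    V: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95
    z: float = DEFAULT_Z
    threshold: float = DEFAULT_THRESHOLD
    valid: bool = True


@dataclass(frozen=True)
class QuestionnaireSummary:
    """Distribution of the per-item V values and the overall verdict."""

    n_items: int
    mean_V: float
    sd_V: float
    min_V: float
    max_V: float
    all_valid: bool


def rating_frequencies(ratings: Sequence[int], scale: LikertScale) -> tuple[int, ...]:
    """Counts per scale category ``l..h``; sums to the number of ratings."""
    arr = np.asarray(ratings, dtype=np.int64).ravel()
    if arr.size and (arr.min() < scale.lowest or arr.max() > scale.highest):
        raise ValueError(
            f"rating outside scale [{scale.lowest}, {scale.highest}]"
        )
    counts = np.bincount(arr - scale.lowest, minlength=scale.categories) if arr.size \
        else np.zeros(scale.categories, dtype=np.int64)
    return tuple(int(c) for c in counts)


def aiken_v(ratings: Sequence[int], scale: LikertScale) -> tuple[int, float, float]:
    """Return ``(S, V, mean_rating)`` for one item.

    ``S`` is the integer rank sum over judges; ``V = S / (n*k)``.
    """
    arr = np.asarray(ratings, dtype=np.int64).ravel()
    if arr.size == 0:
        raise ValueError("aiken_v needs at least one rating")
    if arr.min() < scale.lowest or arr.max() > scale.highest:
        raise ValueError(f"rating outside scale [{scale.lowest}, {scale.highest}]")
    S = int((arr - scale.lowest).sum())
    V = S / (arr.size * scale.span)
    return S, V, float(arr.mean())


def score_ci(
    V: float,
    n: int,
    k: int,
    confidence: float = 0.95,
    z: float | None = None,
) -> tuple[float, float]:
    """Score-method confidence interval for Aiken's V.

    Inverts the normal score test for a proportion on ``n*k`` effective
    trials. ``z`` overrides the quantile (default 1.96 at 95%); the
    endpoints collapse exactly to 0 / 1 at V = 0 / V = 1.
    """
    if not 0 <= V <= 1:
        raise ValueError("V must lie in [0, 1]")
    nk = n * k
    if nk < 1:
        raise ValueError("n*k must be at least 1")
    if z is None:
        z = normal_quantile(confidence)
    z2 = z * z
    half = z * math.sqrt(4 * nk * V * (1 - V) + z2)
    low = (2 * nk * V + z2 - half) / (2 * (nk + z2))
    high = (2 * nk * V + z2 + half) / (2 * (nk + z2))
    # guard against 1-ulp excursions outside [0, 1]
    return max(0.0, min(1.0, low)), max(0.0, min(1.0, high))


def validate_item(V: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff the unrounded V reaches the validity threshold (inclusive)."""
    if not 0 <= V <= 1:
        raise ValueError("V must lie in [0, 1]")
    return V >= threshold


def analyze_items(
    matrix: RatingMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    confidence: float = 0.95,
    z: float | None = None,
) -> list[AikenResult]:
    """Per-item frequencies, mean, V, CI and validity over a final panel."""
    if z is None:
        z = normal_quantile(confidence)
    out = []
    for item in matrix.item_ids:
        ratings = matrix.item_ratings(item)
        S, V, mean = aiken_v(ratings, matrix.scale)
        low, high = score_ci(V, matrix.n_experts, matrix.scale.span, confidence, z)
        out.append(
            AikenResult(
                item_id=item,
                n=matrix.n_experts,
                freq=rating_frequencies(ratings, matrix.scale),
                mean_rating=mean,
                S=S,
                V=V,
                ci_low=low,
                ci_high=high,
                confidence=confidence,
                z=z,
                threshold=threshold,
                valid=validate_item(V, threshold),
            )
        )
    return out


def summarize_questionnaire(results: Sequence[AikenResult]) -> QuestionnaireSummary:
    """Mean, sample SD, min and max of the per-item (unrounded) V values."""
    if not results:
        raise ValueError("summarize_questionnaire needs at least one item result")
    v = np.array([r.V for r in results], dtype=float)
    return QuestionnaireSummary(
        n_items=len(results),
        mean_V=float(v.mean()),
        sd_V=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        min_V=float(v.min()),
        max_V=float(v.max()),
        all_valid=all(r.valid for r in results),
    )
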