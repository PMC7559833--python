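"""Model/results interface for expert-panel content validation.

:class:`ContentValidityModel` bundles a rating matrix with the procedure's
tunables (screening pool and policy, confidence level, validity threshold);
``fit()`` runs screening, assembles the final panel and computes the
per-item Aiken's V analysis, returning a :class:`ContentValidityResults`
that carries the estimates, their score intervals, the screening audit
trail and a ``summary()`` table in the layout of a published item-validity
table (per-category frequencies, mean, "V (L-U)").
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import fixtures as _fixtures
from .aiken import (
    DEFAULT_THRESHOLD,
    AikenResult,
    QuestionnaireSummary,
    analyze_items,
    normal_quantile,
    summarize_questionnaire,
)
from .data import (
    ExpertProfile,
    LikertScale,
    PanelDescriptives,
    RatingMatrix,
    panel_descriptives,
    read_ratings,
)
from .rounding import fmt
from .screening import (
    DeviancePolicy,
    ScreeningResult,
    assemble_final_panel,
    screen_experts,
)

__all__ = ["ContentValidityModel", "ContentValidityResults"]


class ContentValidityModel:
    """Content-validation analysis of one expert panel.

    Parameters
    ----------
    ratings : RatingMatrix
        Complete experts-by-items matrix (may include replacement experts).
    profiles : list of ExpertProfile, optional
        Panel metadata; used for career descriptives and, when ``pool`` /
        ``replacements`` are not given, to split originals from
        replacements.
    pool : sequence of str, optional
        Experts screened against each other. Defaults to the
        non-replacement experts when profiles are available, else to all
        experts.
    replacements : sequence of str, optional
        Experts appended to the final panel after exclusion. Defaults to
        the profile-flagged replacements (empty without profiles).
    policy : DeviancePolicy, optional
    screen : bool
        If False, skip screening: the final panel is ``pool`` plus
        ``replacements`` (for pre-cleaned panels).
    v_threshold, confidence, z
        Validity threshold on unrounded V, confidence level for the score
        interval, and an optional explicit normal quantile.
    """

    def __init__(
        self,
        ratings: RatingMatrix,
        profiles: Sequence[ExpertProfile] | None = None,
        pool: Sequence[str] | None = None,
        replacements: Sequence[str] | None = None,
        policy: DeviancePolicy | None = None,
        screen: bool = True,
        v_threshold: float = DEFAULT_THRESHOLD,
        confidence: float = 0.95,
        z: float | None = None,
    ) -> None:
        if not 0 < v_threshold <= 1:
            raise ValueError("v_threshold must lie in (0, 1]")
        self.ratings = ratings
        self.profiles = list(profiles) if profiles is not None else None
        if pool is None:
            pool = (
                _fixtures.original_pool(ratings, self.profiles)
                if self.profiles
                else list(ratings.expert_ids)
            )
        if replacements is None:
            replacements = (
                [e for e in _fixtures.replacement_experts(self.profiles)
                 if e in ratings.expert_ids]
                if self.profiles
                else []
            )
        self.pool = [str(e) for e in pool]
        self.replacements = [str(e) for e in replacements]
        self.policy = policy or DeviancePolicy()
        self.screen = bool(screen)
        self.v_threshold = float(v_threshold)
        self.confidence = float(confidence)
        self.z = normal_quantile(confidence) if z is None else float(z)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_fixture(cls, panel_name: str, variant: str = "verbatim", **kwargs):
        """Build the model for one of the embedded reference panels."""
        matrix, profiles = _fixtures.load_fixture(panel_name, variant)
        return cls(matrix, profiles=profiles, **kwargs)

    @classmethod
    def from_csv(cls, path, scale: LikertScale | None = None, **kwargs):
        """Build the model from a CSV/TSV rating table."""
        matrix = read_ratings(path, scale or LikertScale())
        return cls(matrix, **kwargs)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "ContentValidityResults":
        """Screen, assemble the final panel, and analyze every item."""
        if self.screen:
            screening = screen_experts(self.ratings, self.pool, self.policy)
            panel = assemble_final_panel(self.ratings, screening, self.replacements)
        else:
            screening = None
            final = self.pool + [e for e in self.replacements if e not in self.pool]
            panel = self.ratings.subset(final)
        items = analyze_items(panel, self.v_threshold, self.confidence, self.z)
        summary = summarize_questionnaire(items)
        descriptives = (
            panel_descriptives(self.profiles)
            if self.profiles and len(self.profiles) >= 2
            else None
        )
        return ContentValidityResults(self, screening, panel, items, summary, descriptives)


class ContentValidityResults:
    """Fitted content-validation results for one panel.

    Attributes
    ----------
    screening : ScreeningResult or None
        Audit trail of the discordance screen (None when skipped).
    panel : RatingMatrix
        The final panel the coefficients are computed on.
    item_results : list of AikenResult
    questionnaire : QuestionnaireSummary
    descriptives : PanelDescriptives or None
    """

    def __init__(
        self,
        model: ContentValidityModel,
        screening: ScreeningResult | None,
        panel: RatingMatrix,
        item_results: list[AikenResult],
        questionnaire: QuestionnaireSummary,
        descriptives: PanelDescriptives | None,
    ) -> None:
        self.model = model
        self.screening = screening
        self.panel = panel
        self.item_results = item_results
        self.questionnaire = questionnaire
        self.descriptives = descriptives

    @property
    def all_valid(self) -> bool:
        return self.questionnaire.all_valid

    @property
    def items(self) -> pd.DataFrame:
        """Per-item results as a DataFrame (full precision)."""
        scale = self.panel.scale
        rows = []
        for r in self.item_results:
            row = {"item": r.item_id}
            for cat, count in zip(range(scale.lowest, scale.highest + 1), r.freq):
                row[f"freq_{cat}"] = count
            row.update(
                n=r.n, mean=r.mean_rating, S=r.S, V=r.V,
                ci_low=r.ci_low, ci_high=r.ci_high, valid=r.valid,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self, rounding: str = "truncate") -> str:
        """Item-validity table: frequencies, mean, "V (L-U)" per item.

        ``rounding`` applies to the V/CI columns; the mean column always
        prints half-up at 2 decimals, matching report convention. Output is
        deterministic for identical results.
        """
        scale = self.panel.scale
        cats = list(range(scale.lowest, scale.highest + 1))
        header = ["Item"] + [str(c) for c in cats] + ["Mean", f"Aiken's V ({self.model.confidence:.0%} CI)"]
        lines = ["\t".join(header)]
        for r in self.item_results:
            cells = [r.item_id] + [str(c) for c in r.freq]
            cells.append(fmt(r.mean_rating, 2, "half-up"))
            cells.append(
                f"{fmt(r.V, 2, rounding)} "
                f"({fmt(r.ci_low, 2, rounding)}-{fmt(r.ci_high, 2, rounding)})"
            )
            lines.append("\t".join(cells))
        q = self.questionnaire
        lines.append(
            "\t".join(
                ["Total"] + [""] * (len(cats) + 1)
                + [f"{fmt(q.mean_V, 2, rounding)} (SD ± {fmt(q.sd_V, 2, rounding)})"]
            )
        )
        if self.descriptives is not None:
            d = self.descriptives
            lines.append(
                f"Panel: {d.n_experts} experts, "
                f"{fmt(d.mean_career_years, 1, 'half-up')} ± "
                f"{fmt(d.sd_career_years, 1, 'half-up')} y career experience"
            )
        return "\n".join(lines)

    def to_csv(self, path=None) -> str | None:
        """Per-item results as CSV (full precision); returns text if no path."""
        return self.items.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        q = self.questionnaire
        return (
            f"<ContentValidityResults {self.panel.panel_id!r}: "
            f"{q.n_items} items, mean V {q.mean_V:.4f}, "
            f"{'all valid' if q.all_valid else 'some invalid'}>"
        )
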