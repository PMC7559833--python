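"""End-to-end orchestration: configuration, validation runs, report rendering.

A :class:`RunConfig` declares everything a run depends on — input (file or
embedded fixture), scale bounds, screening pool and policy, confidence
level, validity threshold, display rounding. :func:`run_validation`
executes load -> screen -> assemble -> per-item V/CI -> summary and returns
a :class:`ValidationReport` that is self-contained and serializes to JSON
byte-identically for identical inputs. :func:`render_report` emits the
report as a tab-separated item-validity table, CSV, or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__ as _pkg_version
from .aiken import AikenResult, QuestionnaireSummary
from .data import LikertScale, PanelDescriptives, RatingLoadError
from .fixtures import FIXTURE_NAMES, FIXTURE_VARIANTS
from .model import ContentValidityModel, ContentValidityResults
from .rounding import ROUNDING_POLICIES, fmt
from .screening import AnswerFlag, DeviancePolicy, ScreeningResult

__all__ = ["RunConfig", "ValidationReport", "run_validation", "render_report"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one validation run."""

    fixture: str | None = None
    variant: str = "verbatim"
    ratings_path: str | None = None
    scale_low: int = 1
    scale_high: int = 5
    pool: tuple[str, ...] | None = None
    replacements: tuple[str, ...] | None = None
    screen: bool = True
    deviance_threshold: float = 3.0
    min_flagged_items: int = 2
    deviance_mode: str = "absolute_points"
    confidence: float = 0.95
    z: float | None = None
    v_threshold: float = 0.75
    rounding: str = "truncate"
    out_json: str | None = None
    out_csv: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.fixture is None) == (self.ratings_path is None):
            raise ValueError("exactly one of fixture / ratings_path must be set")
        if self.fixture is not None and self.fixture not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.fixture!r}")
        if self.variant not in FIXTURE_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0 < self.v_threshold <= 1:
            raise ValueError("v_threshold must lie in (0, 1]")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        if self.rounding not in ROUNDING_POLICIES:
            raise ValueError(f"unknown rounding policy {self.rounding!r}")
        if self.pool is not None:
            object.__setattr__(self, "pool", tuple(str(e) for e in self.pool))
        if self.replacements is not None:
            object.__setattr__(self, "replacements", tuple(str(e) for e in self.replacements))

    @property
    def scale(self) -> LikertScale:
        return LikertScale(self.scale_low, self.scale_high)

    @property
    def policy(self) -> DeviancePolicy:
        return DeviancePolicy(
            deviance_threshold=self.deviance_threshold,
            min_flagged_items=self.min_flagged_items,
            mode=self.deviance_mode,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("pool", "replacements"):
            if data.get(key) is not None:
                data[key] = tuple(str(e) for e in data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON config file (YAML is a JSON superset here)."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("pool", "replacements"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


@dataclass(frozen=True)
class ValidationReport:
    """Self-contained result of one validation run.

    Holds unrounded values only; rounding happens at render time, so
    downstream consumers never inherit display truncation.
    """

    config: dict
    descriptives: PanelDescriptives | None
    screening: ScreeningResult | None
    final_expert_ids: tuple[str, ...]
    item_results: tuple[AikenResult, ...]
    questionnaire: QuestionnaireSummary
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "descriptives": None if self.descriptives is None else vars(self.descriptives) | {},
            "screening": None if self.screening is None else self.screening.to_dict(),
            "final_expert_ids": list(self.final_expert_ids),
            "item_results": [
                {**(vars(r) | {}), "freq": list(r.freq)} for r in self.item_results
            ],
            "questionnaire": vars(self.questionnaire) | {},
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        desc = d["descriptives"]
        screening = d["screening"]
        return cls(
            config=d["config"],
            descriptives=None if desc is None else PanelDescriptives(**desc),
            screening=None
            if screening is None
            else ScreeningResult(
                policy=DeviancePolicy(**screening["policy"]),
                flags=tuple(AnswerFlag(**f) for f in screening["flags"]),
                flag_count_per_expert=dict(screening["flag_count_per_expert"]),
                excluded_experts=tuple(screening["excluded_experts"]),
                retained_expert_ids=tuple(screening["retained_expert_ids"]),
            ),
            final_expert_ids=tuple(d["final_expert_ids"]),
            item_results=tuple(
                AikenResult(**{**r, "freq": tuple(r["freq"])}) for r in d["item_results"]
            ),
            questionnaire=QuestionnaireSummary(**d["questionnaire"]),
            provenance=d["provenance"],
        )

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls.from_dict(json.loads(text))


def run_validation(config: RunConfig) -> ValidationReport:
    """Execute the full pipeline described by ``config``.

    Deterministic: identical config and input give an identical report.
    Screening always precedes the validity analysis; V is computed only on
    the final assembled panel.
    """
    kwargs: dict[str, Any] = dict(
        policy=config.policy,
        screen=config.screen,
        v_threshold=config.v_threshold,
        confidence=config.confidence,
        z=config.z,
    )
    if config.pool is not None:
        kwargs["pool"] = list(config.pool)
    if config.replacements is not None:
        kwargs["replacements"] = list(config.replacements)
    if config.fixture is not None:
        model = ContentValidityModel.from_fixture(config.fixture, config.variant, **kwargs)
    else:
        model = ContentValidityModel.from_csv(config.ratings_path, config.scale, **kwargs)
    results = model.fit()
    return ValidationReport(
        config=config.to_dict(),
        descriptives=results.descriptives,
        screening=results.screening,
        final_expert_ids=results.panel.expert_ids,
        item_results=tuple(results.item_results),
        questionnaire=results.questionnaire,
        provenance={"software": "panelval", "version": _pkg_version},
    )


def _report_scale(report: ValidationReport) -> LikertScale:
    return LikertScale(report.config["scale_low"], report.config["scale_high"])


def render_report(report: ValidationReport, format: str = "table") -> str:
    """Render a report as ``table`` (TSV item-validity table), ``csv`` or ``json``.

    Bit-identical output for identical reports.
    """
    if format == "json":
        return report.to_json()
    if format == "csv":
        scale = _report_scale(report)
        cats = list(range(scale.lowest, scale.highest + 1))
        header = (
            ["item"] + [f"freq_{c}" for c in cats]
            + ["n", "mean", "S", "V", "ci_low", "ci_high", "valid"]
        )
        lines = [",".join(header)]
        for r in report.item_results:
            lines.append(
                ",".join(
                    [r.item_id] + [str(c) for c in r.freq]
                    + [str(r.n), repr(r.mean_rating), str(r.S), repr(r.V),
                       repr(r.ci_low), repr(r.ci_high), str(r.valid)]
                )
            )
        return "\n".join(lines) + "\n"
    if format == "table":
        rounding = report.config.get("rounding", "truncate")
        scale = _report_scale(report)
        cats = list(range(scale.lowest, scale.highest + 1))
        conf = report.config.get("confidence", 0.95)
        header = ["Item"] + [str(c) for c in cats] + ["Mean", f"Aiken's V ({conf:.0%} CI)"]
        lines = ["\t".join(header)]
        for r in report.item_results:
            lines.append(
                "\t".join(
                    [r.item_id] + [str(c) for c in r.freq]
                    + [fmt(r.mean_rating, 2, "half-up"),
                       f"{fmt(r.V, 2, rounding)} ({fmt(r.ci_low, 2, rounding)}-{fmt(r.ci_high, 2, rounding)})"]
                )
            )
        q = report.questionnaire
        lines.append(
            "\t".join(
                ["Total"] + [""] * (len(cats) + 1)
                + [f"{fmt(q.mean_V, 2, rounding)} (SD ± {fmt(q.sd_V, 2, rounding)})"]
            )
        )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
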