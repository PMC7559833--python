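"""Rating-panel data model and tabular I/O.

A content-validation study collects integer relevance judgements from a
panel of expert raters: every expert scores every questionnaire item on a
bounded Likert scale (here typically 1-5, with 5 the highest relevance).
This module defines the containers for that data — :class:`LikertScale`,
:class:`ExpertProfile`, :class:`RatingMatrix` — plus CSV/TSV readers and
writers and panel-level descriptive statistics.

Files store experts as rows and items as columns (panels grow by expert),
with one header row of item labels and a leading column of expert labels.
Missing cells are a load error, never imputed: the validation procedure
assumes a complete panel.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LikertScale",
    "ExpertProfile",
    "PanelDescriptives",
    "RatingMatrix",
    "RatingLoadError",
    "read_ratings",
    "write_ratings",
    "panel_descriptives",
]

EXPERT_ROLES = frozenset({"physician", "nurse", "other"})


class RatingLoadError(ValueError):
    """Raised when a rating table cannot be read as a valid panel.

    The message names the offending row/column so a malformed file can be
    fixed rather than silently patched.
    """


@dataclass(frozen=True)
class LikertScale:
    """Bounded integer response scale.

    Parameters
    ----------
    lowest : int
        Lowest category ``l`` (worst judgement).
    highest : int
        Highest category ``h`` (best judgement); must exceed ``lowest``.

    The number of categories is ``c = h - l + 1`` and the span
    ``k = c - 1 = h - l`` is the number of scale steps, which is the
    per-judge maximum of the rescaled score entering Aiken's V.
    """

    lowest: int = 1
    highest: int = 5

    def __post_init__(self) -> None:
        if int(self.lowest) != self.lowest or int(self.highest) != self.highest:
            raise ValueError("scale bounds must be integers")
        if self.highest <= self.lowest:
            raise ValueError(
                f"scale needs highest > lowest, got [{self.lowest}, {self.highest}]"
            )

    @property
    def categories(self) -> int:
        """Number of response categories ``c``."""
        return self.highest - self.lowest + 1

    @property
    def span(self) -> int:
        """Scale span ``k = c - 1``."""
        return self.highest - self.lowest

    def contains(self, rating: int) -> bool:
        return self.lowest <= rating <= self.highest

    def clamp(self, value: float) -> int:
        return int(min(self.highest, max(self.lowest, value)))


@dataclass(frozen=True)
class ExpertProfile:
    """Metadata for one panel member.

    ``replacement`` marks an expert recruited to substitute a judge who was
    excluded by the discordance screen (the "expert exchanged" convention).
    """

    expert_id: str
    role: str = "other"
    age_range: str = ""
    sex: str = ""
    career_years: int = 0
    replacement: bool = False

    def __post_init__(self) -> None:
        if self.role not in EXPERT_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(EXPERT_ROLES)}")
        if self.career_years < 0:
            raise ValueError("career_years must be non-negative")


@dataclass(frozen=True)
class PanelDescriptives:
    """Mean and sample SD (n-1 denominator) of panel career experience."""

    n_experts: int
    mean_career_years: float
    sd_career_years: float


class RatingMatrix:
    """Complete experts-by-items integer rating matrix.

    Parameters
    ----------
    panel_id : str
        Label for the panel (e.g. ``"physicians"``).
    scale : LikertScale
        Bounds every rating must respect.
    expert_ids, item_ids : sequence of str
        Ordered, unique labels. Order is the file order and is preserved by
        every operation; it is never sorted.
    ratings : array-like of int, shape (n_experts, n_items)
    """

    def __init__(
        self,
        panel_id: str,
        scale: LikertScale,
        expert_ids: Sequence[str],
        item_ids: Sequence[str],
        ratings,
    ) -> None:
        self.panel_id = str(panel_id)
        self.scale = scale
        self.expert_ids = tuple(str(e) for e in expert_ids)
        self.item_ids = tuple(str(j) for j in item_ids)
        arr = np.asarray(ratings)
        if arr.ndim != 2:
            raise ValueError("ratings must be a 2-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("ratings must be integers")
            arr = arr.astype(np.int64)
        if arr.shape != (len(self.expert_ids), len(self.item_ids)):
            raise ValueError(
                f"ratings shape {arr.shape} does not match "
                f"{len(self.expert_ids)} experts x {len(self.item_ids)} items"
            )
        if len(set(self.expert_ids)) != len(self.expert_ids):
            raise ValueError("duplicate expert labels")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item labels")
        lo, hi = int(arr.min(initial=scale.lowest)), int(arr.max(initial=scale.highest))
        if lo < scale.lowest or hi > scale.highest:
            bad = np.argwhere((arr < scale.lowest) | (arr > scale.highest))[0]
            raise ValueError(
                f"rating {arr[tuple(bad)]} at expert {self.expert_ids[bad[0]]!r}, "
                f"item {self.item_ids[bad[1]]!r} outside scale "
                f"[{scale.lowest}, {scale.highest}]"
            )
        arr = arr.astype(np.int64)
        arr.setflags(write=False)
        self.ratings = arr

    # -- basic container protocol ------------------------------------------------
    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RatingMatrix({self.panel_id!r}, {self.n_experts} experts x "
            f"{self.n_items} items, scale {self.scale.lowest}-{self.scale.highest})"
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RatingMatrix)
            and self.panel_id == other.panel_id
            and self.scale == other.scale
            and self.expert_ids == other.expert_ids
            and self.item_ids == other.item_ids
            and np.array_equal(self.ratings, other.ratings)
        )

    def __hash__(self):  # pragma: no cover
        return hash((self.panel_id, self.scale, self.expert_ids, self.item_ids))

    # -- accessors ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Ratings as a DataFrame indexed by expert, one column per item."""
        return pd.DataFrame(
            np.array(self.ratings),
            index=pd.Index(self.expert_ids, name="expert"),
            columns=list(self.item_ids),
        )

    def rating(self, expert: str, item: str) -> int:
        return int(self.ratings[self._ei(expert), self._ii(item)])

    def item_ratings(self, item: str, experts: Iterable[str] | None = None) -> np.ndarray:
        """Ratings for one item, over all experts or the given subset (in matrix order)."""
        j = self._ii(item)
        if experts is None:
            return np.array(self.ratings[:, j])
        keep = self._expert_index_list(experts)
        return np.array(self.ratings[keep, j])

    def subset(self, experts: Sequence[str]) -> "RatingMatrix":
        """Submatrix over the given experts, in the given order."""
        keep = self._expert_index_list(experts, preserve_order=True)
        return RatingMatrix(
            self.panel_id, self.scale, [self.expert_ids[i] for i in keep],
            self.item_ids, self.ratings[keep, :],
        )

    def _ei(self, expert: str) -> int:
        try:
            return self.expert_ids.index(str(expert))
        except ValueError:
            raise KeyError(f"unknown expert {expert!r}") from None

    def _ii(self, item: str) -> int:
        try:
            return self.item_ids.index(str(item))
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None

    def _expert_index_list(self, experts: Iterable[str], preserve_order: bool = False):
        experts = [str(e) for e in experts]
        if len(set(experts)) != len(experts):
            raise ValueError("duplicate experts in selection")
        idx = [self._ei(e) for e in experts]
        return idx if preserve_order else sorted(idx)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def _infer_sep(source, text: str | None = None) -> str:
    name = getattr(source, "name", source)
    if isinstance(name, (str, Path)) and str(name).lower().endswith(".tsv"):
        return "\t"
    if text is not None and "\t" in text.splitlines()[0]:
        return "\t"
    return ","


def read_ratings(source, scale: LikertScale, panel_id: str | None = None) -> RatingMatrix:
    """Read an experts-by-items rating table from CSV/TSV.

    The first row holds item labels, the first column expert labels; every
    other cell must be an integer within ``scale``. Any violation — ragged
    rows, missing or non-integer cells, out-of-scale ratings, duplicate
    labels — raises :class:`RatingLoadError` naming the offending cell.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        text = Path(source).read_text(encoding="utf-8")
        name = str(source)
    sep = _infer_sep(source, text)

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise RatingLoadError(f"{name}: need a header row and at least one expert row")
    header = lines[0].split(sep)
    item_ids = [h.strip() for h in header[1:]]
    width = len(header)
    expert_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != width:
            raise RatingLoadError(
                f"{name}: line {lineno} has {len(cells)} fields, expected {width} (ragged row)"
            )
        expert = cells[0].strip()
        expert_ids.append(expert)
        row = []
        for item, cell in zip(item_ids, cells[1:]):
            cell = cell.strip()
            if cell == "":
                raise RatingLoadError(
                    f"{name}: missing rating at expert {expert!r}, item {item!r}"
                )
            try:
                value = float(cell)
            except ValueError:
                raise RatingLoadError(
                    f"{name}: non-numeric rating {cell!r} at expert {expert!r}, item {item!r}"
                ) from None
            if not value.is_integer():
                raise RatingLoadError(
                    f"{name}: non-integer rating {cell!r} at expert {expert!r}, item {item!r}"
                )
            value = int(value)
            if not scale.contains(value):
                raise RatingLoadError(
                    f"{name}: rating {value} at expert {expert!r}, item {item!r} "
                    f"outside scale [{scale.lowest}, {scale.highest}]"
                )
            row.append(value)
        rows.append(row)
    if len(set(expert_ids)) != len(expert_ids):
        raise RatingLoadError(f"{name}: duplicate expert labels")
    if len(set(item_ids)) != len(item_ids):
        raise RatingLoadError(f"{name}: duplicate item labels")
    try:
        return RatingMatrix(
            panel_id if panel_id is not None else Path(name).stem,
            scale, expert_ids, item_ids, np.array(rows, dtype=np.int64),
        )
    except ValueError as exc:  # pragma: no cover - defensive, re-tagged
        raise RatingLoadError(f"{name}: {exc}") from exc


def write_ratings(matrix: RatingMatrix, sink) -> None:
    """Write a rating matrix in the dialect :func:`read_ratings` accepts.

    Read-back equality holds: ``read_ratings(write_ratings(M)) == M`` up to
    the ``panel_id`` carried by the file name.
    """
    sep = _infer_sep(sink)
    df = matrix.to_frame()
    if hasattr(sink, "write"):
        df.to_csv(sink, sep=sep)
    else:
        df.to_csv(Path(sink), sep=sep)


def panel_descriptives(profiles: Sequence[ExpertProfile]) -> PanelDescriptives:
    """Mean and sample SD of the panel's career experience, in years.

    Uses the n-1 (sample) denominator, which is what the study-report
    convention "mean ± SD" refers to. Requires at least two profiles.
    """
    if len(profiles) < 2:
        raise ValueError("panel descriptives need at least 2 profiles")
    years = np.array([p.career_years for p in profiles], dtype=float)
    return PanelDescriptives(
        n_experts=len(profiles),
        mean_career_years=float(years.mean()),
        sd_career_years=float(years.std(ddof=1)),
    )


def profiles_to_json(profiles: Sequence[ExpertProfile]) -> str:
    """Serialize profiles to a JSON array (stable key order)."""
    return json.dumps([vars(p) | {} for p in profiles], indent=2)
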