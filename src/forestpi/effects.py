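"""Per-study effect sizes and study-table I/O.

Raw inputs are either 2x2 contingency tables (events / totals in two arms)
or pre-computed effect estimates with standard errors. All downstream
pooling and prediction happens on a linear scale; for ratio measures that
is the log scale, where the normal approximation of the random-effects
hierarchy is reasonable. Ratio measures are exponentiated only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

__all__ = [
    "TwoByTwoTable",
    "StudyRecord",
    "log_odds_ratio",
    "read_study_table",
    "write_study_table",
    "StudyDataError",
]

ScaleTag = Literal["log_ratio", "linear"]

COUNT_COLUMNS = ["label", "events_trt", "total_trt", "events_ctl", "total_ctl"]
EFFECT_COLUMNS = ["label", "effect", "se"]


class StudyDataError(ValueError):
    """Invalid study-level input (counts, effects or file contents)."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts for one two-arm trial with a binary outcome.

    ``events_*`` are outcome events, ``total_*`` the arm sizes; non-events
    are derived. Counts must be non-negative with events <= total and
    totals > 0.
    """

    events_trt: int
    total_trt: int
    events_ctl: int
    total_ctl: int
    label: str = ""

    def __post_init__(self) -> None:
        cells = (self.events_trt, self.total_trt, self.events_ctl, self.total_ctl)
        if any(c < 0 for c in cells):
            raise StudyDataError(f"negative count in study {self.label!r}: {cells}")
        if self.total_trt <= 0 or self.total_ctl <= 0:
            raise StudyDataError(f"empty arm in study {self.label!r}")
        if self.events_trt > self.total_trt or self.events_ctl > self.total_ctl:
            raise StudyDataError(
                f"events exceed total in study {self.label!r}: {cells}"
            )

    @property
    def nonevents_trt(self) -> int:
        return self.total_trt - self.events_trt

    @property
    def nonevents_ctl(self) -> int:
        return self.total_ctl - self.events_ctl


@dataclass(frozen=True)
class StudyRecord:
    """One study's effect estimate on the analysis scale.

    ``scale_tag`` records whether ``effect`` is a log-transformed ratio
    measure (plotted on a log axis after exponentiation) or an untransformed
    linear measure such as a mean difference.
    """

    label: str
    effect: float
    se: float
    scale_tag: ScaleTag = "linear"

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect):
            raise StudyDataError(f"non-finite effect in study {self.label!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise StudyDataError(
                f"standard error must be positive and finite in study "
                f"{self.label!r}, got {self.se!r}"
            )


def log_odds_ratio(
    table: TwoByTwoTable, zero_cell_policy: str = "haldane"
) -> StudyRecord:
    """Log odds ratio and its large-sample standard error from a 2x2 table.

    With cells a (events, treatment), b (non-events, treatment), c (events,
    control), d (non-events, control):

        effect = ln(a*d / (b*c)),   se = sqrt(1/a + 1/b + 1/c + 1/d)

    Zero cells make the estimate degenerate. Under the default
    ``"haldane"`` policy (Haldane–Anscombe) 0.5 is added to all four cells
    of any table containing a zero cell; tables without zeros are left
    untouched. Under ``"strict"`` a zero cell raises. A table with a
    double-zero row or column carries no information about the odds ratio
    and always raises, naming the study.
    """
    a = float(table.events_trt)
    b = float(table.nonevents_trt)
    c = float(table.events_ctl)
    d = float(table.nonevents_ctl)

    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise StudyDataError(
            f"study {table.label!r} has no events (or no non-events) in either "
            "arm; the odds ratio is undefined for this table"
        )

    if min(a, b, c, d) == 0:
        if zero_cell_policy == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        elif zero_cell_policy == "strict":
            raise StudyDataError(
                f"zero cell in study {table.label!r} with strict zero-cell policy"
            )
        else:
            raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")

    effect = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return StudyRecord(label=table.label, effect=effect, se=se, scale_tag="log_ratio")


def _detect_schema(columns: Sequence[str]) -> str:
    cols = set(columns)
    has_counts = set(COUNT_COLUMNS) <= cols
    has_effects = set(EFFECT_COLUMNS) <= cols
    if has_counts and has_effects:
        raise StudyDataError(
            "ambiguous study table: contains both count and effect/se columns"
        )
    if has_counts:
        return "counts"
    if has_effects:
        return "effects"
    raise StudyDataError(
        f"study table must have columns {COUNT_COLUMNS} or {EFFECT_COLUMNS}; "
        f"found {sorted(cols)}"
    )


def read_study_table(
    path: str | Path,
    format_hint: Optional[str] = None,
    zero_cell_policy: str = "haldane",
) -> list[StudyRecord]:
    """Read study records from a CSV file.

    Two schemas are accepted: 2x2 counts
    (``label,events_trt,total_trt,events_ctl,total_ctl``), converted per
    row via :func:`log_odds_ratio`, or pre-computed estimates
    (``label,effect,se``), passed through. An optional ``scale`` column
    (``log_ratio`` or ``linear``, default ``linear``) tags pre-computed
    effects so written tables round-trip. ``format_hint`` (``"counts"`` or
    ``"effects"``) overrides detection. Errors name the offending 1-based
    data row.
    """
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise StudyDataError(f"cannot read study table {path}: {exc}") from exc

    schema = format_hint or _detect_schema(frame.columns)
    if schema == "counts":
        required = COUNT_COLUMNS
    elif schema == "effects":
        required = EFFECT_COLUMNS
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise StudyDataError(f"study table {path} is missing columns {missing}")

    records: list[StudyRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        label = str(getattr(row, "label"))
        try:
            if schema == "counts":
                table = TwoByTwoTable(
                    events_trt=_as_count(getattr(row, "events_trt")),
                    total_trt=_as_count(getattr(row, "total_trt")),
                    events_ctl=_as_count(getattr(row, "events_ctl")),
                    total_ctl=_as_count(getattr(row, "total_ctl")),
                    label=label,
                )
                records.append(log_odds_ratio(table, zero_cell_policy))
            else:
                scale = str(getattr(row, "scale", "linear"))
                if scale not in ("log_ratio", "linear"):
                    raise StudyDataError(f"unknown scale tag {scale!r}")
                records.append(
                    StudyRecord(
                        label=label,
                        effect=float(getattr(row, "effect")),
                        se=float(getattr(row, "se")),
                        scale_tag=scale,  # type: ignore[arg-type]
                    )
                )
        except (StudyDataError, TypeError, ValueError) as exc:
            raise StudyDataError(f"row {i} of {path}: {exc}") from exc
    return records


def _as_count(value: object) -> int:
    x = float(value)  # type: ignore[arg-type]
    if not x.is_integer():
        raise StudyDataError(f"count {value!r} is not an integer")
    return int(x)


def write_study_table(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write records to CSV in the ``label,effect,se,scale`` schema."""
    rows = [
        {"label": r.label, "effect": r.effect, "se": r.se, "scale": r.scale_tag}
        for r in records
    ]
    pd.DataFrame(rows, columns=EFFECT_COLUMNS + ["scale"]).to_csv(path, index=False)
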