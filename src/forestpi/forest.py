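"""Forest plots with a dedicated prediction-interval row.

A conventional forest plot shows one row per study (a square sized by the
study's weight, with a CI line) and a summary diamond for the pooled
effect and its CI. For random-effects meta-analyses this module adds the
prediction interval in one of three styles:

* ``rectangle`` (default, recommended): a separate labelled row carrying a
  rectangle spanning the PI. The rectangle is what a column of
  infinitely large studies would look like — their CI lines shrink to
  nothing and the weight squares merge into a block whose horizontal
  extent is the dispersion of true effects.
* ``hollow_diamond``: an additional unfilled diamond spanning the PI
  (Higgins-style).
* ``extended_diamond``: the pooled-effect diamond with horizontal lines
  extended to the PI bounds (Riley-style).

The rectangle style keeps the PI glyph visually distinct from the CI
diamond; the other two reuse diamond/line symbolism already claimed by the
CI, which invites misreading, but are retained for comparison figures.

Plot content is described by a declarative, JSON-serializable
:class:`ForestSpec`; :func:`render` turns a spec into SVG or PNG via
matplotlib. Rendering is deterministic for a given spec and format, so
SVG output is suitable for golden-file testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
import matplotlib.pyplot as plt
from matplotlib.patches import Polygon, Rectangle
from matplotlib.ticker import ScalarFormatter
from scipy import stats as _stats

from .effects import StudyRecord
from .pooling import PoolResult, pool_random, tau2_dersimonian_laird
from .prediction import PredictionInterval, prediction_interval

__all__ = [
    "StudyRow",
    "SummaryRow",
    "AxisSpec",
    "ForestSpec",
    "build_forest_spec",
    "render",
    "rectangle_rationale_demo",
    "PI_STYLES",
]

PI_STYLES = ("rectangle", "hollow_diamond", "extended_diamond", "none")

POOLED_LABEL = "Total expectation (95% CI)"
PI_LABEL = "95% prediction interval"

# Fixed rendering metrics; golden files depend on them.
_FIG_WIDTH = 8.0
_ROW_HEIGHT_IN = 0.45
_DPI = 100
_MAX_SQUARE_PTS = 14.0
_DIAMOND_HALF_HEIGHT = 0.3
_RECT_HALF_HEIGHT = 0.3  # rectangle occupies 0.6 of a row height
_HASHSALT = "forestpi"


@dataclass(frozen=True)
class StudyRow:
    label: str
    effect: float
    ci_lower: float
    ci_upper: float
    weight: float


@dataclass(frozen=True)
class SummaryRow:
    """One summary glyph row.

    ``lower``/``upper`` give the full horizontal extent of the glyph. For
    the ``extended_diamond`` glyph that extent is the PI while
    ``ci_lower``/``ci_upper`` carry the diamond (CI) extent.
    """

    label: str
    glyph: str  # "diamond" | "rectangle" | "hollow_diamond" | "extended_diamond"
    center: float
    lower: float
    upper: float
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None


@dataclass(frozen=True)
class AxisSpec:
    scale: str  # "log" | "linear"
    reference_line: float
    tick_values: tuple[float, ...]
    label: str
    limits: tuple[float, float]


@dataclass(frozen=True)
class ForestSpec:
    """Declarative description of every row and glyph of a forest plot.

    All coordinates are in plotted units: ratio scale for log axes,
    analysis scale for linear axes.
    """

    study_rows: tuple[StudyRow, ...]
    summary_rows: tuple[SummaryRow, ...]
    axis: AxisSpec
    pi_style: str
    annotations: str = ""

    def __post_init__(self) -> None:
        if self.pi_style not in PI_STYLES:
            raise ValueError(f"unknown pi_style {self.pi_style!r}")
        for row in self.study_rows:
            if row.weight < 0:
                raise ValueError(f"negative weight in study row {row.label!r}")
            if not row.ci_lower <= row.effect <= row.ci_upper:
                raise ValueError(f"unordered interval in study row {row.label!r}")
        for row in self.summary_rows:
            if not row.lower <= row.center <= row.upper:
                raise ValueError(f"unordered interval in summary row {row.label!r}")

    def plotted_values(self) -> list[float]:
        vals: list[float] = [self.axis.reference_line, *self.axis.tick_values]
        for r in self.study_rows:
            vals += [r.effect, r.ci_lower, r.ci_upper]
        for r in self.summary_rows:
            vals += [r.center, r.lower, r.upper]
            if r.ci_lower is not None:
                vals += [r.ci_lower, r.ci_upper]
        return vals

    def to_dict(self) -> dict:
        return {
            "study_rows": [asdict(r) for r in self.study_rows],
            "summary_rows": [asdict(r) for r in self.summary_rows],
            "axis": asdict(self.axis),
            "pi_style": self.pi_style,
            "annotations": self.annotations,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ForestSpec":
        axis = d["axis"]
        return cls(
            study_rows=tuple(StudyRow(**r) for r in d["study_rows"]),
            summary_rows=tuple(SummaryRow(**r) for r in d["summary_rows"]),
            axis=AxisSpec(
                scale=axis["scale"],
                reference_line=axis["reference_line"],
                tick_values=tuple(axis["tick_values"]),
                label=axis["label"],
                limits=tuple(axis["limits"]),
            ),
            pi_style=d["pi_style"],
            annotations=d["annotations"],
        )

    @classmethod
    def from_json(cls, s: str) -> "ForestSpec":
        return cls.from_dict(json.loads(s))


def _nice_log_ticks(lo: float, hi: float) -> tuple[float, ...]:
    ticks = []
    for exp in range(-4, 5):
        for m in (1.0, 2.0, 5.0):
            t = m * 10.0**exp
            if lo <= t <= hi:
                ticks.append(round(t, 6))
    return tuple(ticks)


def _nice_linear_ticks(lo: float, hi: float) -> tuple[float, ...]:
    locator = matplotlib.ticker.MaxNLocator(nbins=6)
    return tuple(t for t in locator.tick_values(lo, hi) if lo <= t <= hi)


def _padded_limits(values: Sequence[float], log: bool) -> tuple[float, float]:
    lo, hi = min(values), max(values)
    if log:
        llo, lhi = math.log(lo), math.log(hi)
        pad = 0.08 * (lhi - llo or 1.0)
        return math.exp(llo - pad), math.exp(lhi + pad)
    pad = 0.08 * ((hi - lo) or 1.0)
    return lo - pad, hi + pad


def build_forest_spec(
    studies: Sequence[StudyRecord],
    pool: PoolResult,
    pi: Optional[PredictionInterval] = None,
    pi_style: str = "rectangle",
) -> ForestSpec:
    """Assemble a plot spec from analysis results.

    Study rows appear in input order with Wald CIs at the pooling level.
    One diamond summary row carries the pooled effect and its CI; the PI
    enters in the requested style (see module docstring). Ratio-scale
    (``log_ratio``) inputs are exponentiated and plotted on a log axis
    with the reference line at 1; linear inputs keep a linear axis with
    the reference at 0.
    """
    if pi_style not in PI_STYLES:
        raise ValueError(f"unknown pi_style {pi_style!r}")
    if pi_style != "none" and pi is None:
        raise ValueError(f"pi_style {pi_style!r} requires a prediction interval")
    if not studies:
        raise ValueError("no studies to plot")

    is_log = studies[0].scale_tag == "log_ratio"
    trans = math.exp if is_log else (lambda x: x)
    z = _stats.norm.ppf(0.5 + pool.level / 2.0)

    weights = pool.weights if pool.weights else tuple([1.0 / len(studies)] * len(studies))
    study_rows = tuple(
        StudyRow(
            label=s.label,
            effect=trans(s.effect),
            ci_lower=trans(s.effect - z * s.se),
            ci_upper=trans(s.effect + z * s.se),
            weight=w,
        )
        for s, w in zip(studies, weights)
    )

    ci_lo, ci_hi = trans(pool.ci[0]), trans(pool.ci[1])
    pooled = trans(pool.pooled)
    pct = f"{pool.level:.0%}"
    diamond = SummaryRow(
        label=f"Total expectation ({pct} CI)",
        glyph="diamond",
        center=pooled,
        lower=ci_lo,
        upper=ci_hi,
    )

    summary_rows: list[SummaryRow]
    if pi_style == "none":
        summary_rows = [diamond]
    else:
        assert pi is not None
        pi_lo, pi_hi = trans(pi.lower), trans(pi.upper)
        pi_label = f"{pi.level:.0%} prediction interval"
        if pi_style == "rectangle":
            summary_rows = [
                diamond,
                SummaryRow(pi_label, "rectangle", trans(pi.center), pi_lo, pi_hi),
            ]
        elif pi_style == "hollow_diamond":
            summary_rows = [
                diamond,
                SummaryRow(pi_label, "hollow_diamond", trans(pi.center), pi_lo, pi_hi),
            ]
        else:  # extended_diamond
            summary_rows = [
                SummaryRow(
                    label=f"Total expectation ({pct} CI) + {pi_label}",
                    glyph="extended_diamond",
                    center=pooled,
                    lower=pi_lo,
                    upper=pi_hi,
                    ci_lower=ci_lo,
                    ci_upper=ci_hi,
                )
            ]

    ref = 1.0 if is_log else 0.0
    values = [ref]
    for r in study_rows:
        values += [r.ci_lower, r.ci_upper]
    for r in summary_rows:
        values += [r.lower, r.upper]
    limits = _padded_limits(values, is_log)
    ticks = (
        _nice_log_ticks(*limits) if is_log else _nice_linear_ticks(*limits)
    )
    axis = AxisSpec(
        scale="log" if is_log else "linear",
        reference_line=ref,
        tick_values=ticks,
        label="Odds ratio" if is_log else "Effect",
        limits=limits,
    )

    tau = math.sqrt(pool.tau2)
    annotations = (
        f"Heterogeneity: τ̂ = {tau:.2f}, "
        f"I² = {pool.i2:.0%}, "
        f"Q = {pool.q_stat:.2f} (df = {pool.q_df})"
    )
    return ForestSpec(
        study_rows=study_rows,
        summary_rows=tuple(summary_rows),
        axis=axis,
        pi_style=pi_style,
        annotations=annotations,
    )


def rectangle_rationale_demo(
    studies: Sequence[StudyRecord],
    inflation: float,
    level: float = 0.95,
) -> ForestSpec:
    """Pedagogical spec showing why the PI rectangle depicts dispersion.

    Divides every study's SE by ``inflation`` — emulating ever-larger
    studies — while holding the between-study variance at the value
    estimated from the original data. As inflation grows the study CIs
    shrink toward points; the pooled SE falls to its random-effects floor
    tau_hat/sqrt(k), so the PI stabilizes at
    ``center -/+ t * tau_hat * sqrt(1 + 1/k)`` — essentially the
    between-study dispersion that the merged squares of infinitely large
    studies would trace out.
    """
    if inflation < 1:
        raise ValueError(f"inflation must be >= 1, got {inflation}")
    tau2 = tau2_dersimonian_laird(studies)
    shrunk = [
        StudyRecord(s.label, s.effect, s.se / inflation, s.scale_tag)
        for s in studies
    ]
    pool = pool_random(shrunk, level=level, tau2_override=tau2)
    pi = prediction_interval(
        pool.pooled,
        pool.se_pooled,
        tau2,
        k=len(shrunk),
        level=level,
        scale_tag=shrunk[0].scale_tag,
    )
    return build_forest_spec(shrunk, pool, pi, pi_style="rectangle")


# ---------------------------------------------------------------------------
# Rendering


def _data_square(ax, x: float, y: float, side_pts: float, gid: str):
    """Square marker of a given side in points, as a display-space polygon.

    Drawn after the axes limits are frozen so the data<->display transform
    is final; this keeps the square visually square on a log axis.
    """
    cx, cy = ax.transData.transform((x, y))
    h = side_pts * _DPI / 72.0 / 2.0
    corners_disp = [
        (cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)
    ]
    corners = ax.transData.inverted().transform(corners_disp)
    patch = Polygon(corners, closed=True, facecolor="0.2", edgecolor="none")
    patch.set_gid(gid)
    ax.add_patch(patch)


def _diamond(ax, row: SummaryRow, y: float, gid: str, hollow: bool = False):
    lo = row.ci_lower if row.glyph == "extended_diamond" else row.lower
    hi = row.ci_upper if row.glyph == "extended_diamond" else row.upper
    verts = [
        (lo, y),
        (row.center, y + _DIAMOND_HALF_HEIGHT),
        (hi, y),
        (row.center, y - _DIAMOND_HALF_HEIGHT),
    ]
    patch = Polygon(
        verts,
        closed=True,
        facecolor="none" if hollow else "0.2",
        edgecolor="0.2",
        linewidth=1.2,
    )
    patch.set_gid(gid)
    ax.add_patch(patch)


def render(spec: ForestSpec, path: str | Path, format: Optional[str] = None) -> Path:
    """Render a forest spec to SVG or PNG.

    The format is taken from the filename suffix unless given explicitly.
    Output is deterministic for identical spec and format. Raises before
    touching the filesystem if the spec cannot be plotted (e.g. a
    non-positive value on a log axis).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported format {fmt!r} (svg or png)")
    if spec.axis.scale == "log" and min(spec.plotted_values()) <= 0:
        raise ValueError("log axis requires all plotted values to be positive")
    if spec.axis.scale not in ("log", "linear"):
        raise ValueError(f"unknown axis scale {spec.axis.scale!r}")

    n_study = len(spec.study_rows)
    rows = list(spec.study_rows) + [None] + list(spec.summary_rows)
    n_rows = len(rows) + (1 if spec.annotations else 0)
    fig_h = _ROW_HEIGHT_IN * n_rows + 1.2

    with matplotlib.rc_context(
        {
            "svg.hashsalt": _HASHSALT,
            "font.family": "DejaVu Sans",
            "font.size": 9.0,
        }
    ):
        fig, ax = plt.subplots(
            figsize=(_FIG_WIDTH, fig_h), dpi=_DPI, layout=None
        )
        try:
            fig.subplots_adjust(left=0.34, right=0.97, top=0.97, bottom=1.0 / fig_h)
            if spec.axis.scale == "log":
                ax.set_xscale("log")
            ax.set_xlim(*spec.axis.limits)
            y_top = len(rows)
            ax.set_ylim(-0.5 - (1 if spec.annotations else 0), y_top + 0.5)
            ax.patch.set_gid("plot-area")

            ax.axvline(
                spec.axis.reference_line, color="0.6", linewidth=0.8, zorder=0
            )

            max_w = max((r.weight for r in spec.study_rows), default=1.0) or 1.0
            labels: list[tuple[float, str]] = []
            y = y_top
            for i, row in enumerate(rows):
                y -= 1
                if row is None:
                    continue
                if isinstance(row, StudyRow):
                    line, = ax.plot(
                        [row.ci_lower, row.ci_upper], [y, y],
                        color="0.2", linewidth=1.0, zorder=2,
                    )
                    line.set_gid(f"study-ci-{i}")
                    side = _MAX_SQUARE_PTS * math.sqrt(row.weight / max_w)
                    _data_square(ax, row.effect, y, side, f"study-square-{i}")
                    labels.append((y, row.label))
                else:
                    _draw_summary(ax, row, y)
                    labels.append((y, row.label))
            if spec.annotations:
                txt = ax.text(
                    0.0, -0.5 - (1 if spec.annotations else 0) + 0.5,
                    spec.annotations,
                    transform=ax.get_yaxis_transform(),
                    ha="left", va="center", fontsize=8,
                )
                txt.set_gid("heterogeneity-note")

            ax.set_yticks([p for p, _ in labels])
            ax.set_yticklabels([l for _, l in labels])
            ax.tick_params(axis="y", length=0)
            ax.set_xticks(list(spec.axis.tick_values))
            ax.xaxis.set_major_formatter(ScalarFormatter())
            ax.xaxis.set_minor_locator(matplotlib.ticker.NullLocator())
            ax.set_xlabel(spec.axis.label)
            for side_name in ("top", "right", "left"):
                ax.spines[side_name].set_visible(False)

            metadata = {"Date": None} if fmt == "svg" else None
            fig.savefig(path, format=fmt, metadata=metadata)
        finally:
            plt.close(fig)
    return path


def _draw_summary(ax, row: SummaryRow, y: float) -> None:
    if row.glyph == "diamond":
        _diamond(ax, row, y, gid="summary-diamond")
    elif row.glyph == "hollow_diamond":
        _diamond(ax, row, y, gid="pi-hollow-diamond", hollow=True)
    elif row.glyph == "rectangle":
        patch = Rectangle(
            (row.lower, y - _RECT_HALF_HEIGHT),
            row.upper - row.lower,
            2 * _RECT_HALF_HEIGHT,
            facecolor="0.55",
            edgecolor="0.2",
            linewidth=1.0,
        )
        patch.set_gid("pi-rectangle")
        ax.add_patch(patch)
    elif row.glyph == "extended_diamond":
        _diamond(ax, row, y, gid="summary-diamond")
        assert row.ci_lower is not None and row.ci_upper is not None
        left, = ax.plot(
            [row.lower, row.ci_lower], [y, y], color="0.2", linewidth=1.2
        )
        right, = ax.plot(
            [row.ci_upper, row.upper], [y, y], color="0.2", linewidth=1.2
        )
        left.set_gid("pi-extension-left")
        right.set_gid("pi-extension-right")
    else:
        raise ValueError(f"unknown summary glyph {row.glyph!r}")
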