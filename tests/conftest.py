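import math
import re

import pytest

from forestpi import StudyRecord, pool_random, prediction_interval


# Published summary of the eight-trial amantadine influenza-prevention
# meta-analysis: pooled OR with 95% CI, DerSimonian-Laird tau-hat, k.
AMANTADINE = {"or": 0.34, "ci": (0.22, 0.53), "tau": 0.4, "k": 8}


@pytest.fixture
def toy_pair():
    """Two equally precise studies at 0 and 1 with closed-form statistics.

    Hand computation: w = 4 each, FE pooled = 0.5 with se = sqrt(1/8);
    Q = 2 on 1 df; DL tau2 = (2-1)/(8 - 32/8) = 0.25; I2 = 0.5; RE weights
    1/(0.25+0.25) = 2 each, pooled 0.5 with se 0.5.
    """
    return [
        StudyRecord("a", 0.0, 0.5),
        StudyRecord("b", 1.0, 0.5),
    ]


@pytest.fixture
def trio():
    """Three-study fixture used for cross-checks against metafor (R)."""
    return [
        StudyRecord("a", -0.9, 0.30),
        StudyRecord("b", -0.2, 0.45),
        StudyRecord("c", -1.4, 0.25),
    ]


@pytest.fixture
def ratio_studies():
    """Four log-odds-ratio studies for plot construction."""
    vals = [(-1.2, 0.3), (-0.8, 0.5), (-1.5, 0.4), (0.1, 0.6)]
    return [
        StudyRecord(f"Trial {i + 1}", e, se, "log_ratio")
        for i, (e, se) in enumerate(vals)
    ]


@pytest.fixture
def ratio_analysis(ratio_studies):
    pool = pool_random(ratio_studies)
    pi = prediction_interval(
        pool.pooled, pool.se_pooled, pool.tau2, len(ratio_studies),
        scale_tag="log_ratio",
    )
    return ratio_studies, pool, pi


_PATH_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def svg_group_xy(svg_text: str, gid: str):
    """Return (xs, ys) of the first path inside the group with this gid."""
    m = re.search(rf'<g id="{re.escape(gid)}">\s*<path d="([^"]+)"', svg_text)
    if m is None:
        raise AssertionError(f"no path group with id {gid!r} in SVG")
    nums = [float(x) for x in _PATH_RE.findall(m.group(1))]
    return nums[0::2], nums[1::2]


def svg_x_extent(svg_text: str, gid: str):
    xs, _ = svg_group_xy(svg_text, gid)
    return min(xs), max(xs)


def data_to_frac(value: float, limits, log: bool) -> float:
    """Fraction of the axes width at which a data value sits."""
    lo, hi = limits
    if log:
        return (math.log(value) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return (value - lo) / (hi - lo)
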