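"""t-based prediction interval for the true effect of a new study.

Under the random-effects hierarchy

    theta_i ~ N(theta, tau^2),   theta_hat ~ N(theta, SE(theta_hat)^2),

the interval expected to contain the true effect of a single new study
with probability 1 - alpha is

    theta_hat -/+ t_{1-alpha/2; k-2} * sqrt(tau2_hat + SE(theta_hat)^2).

The t quantile (rather than z) on k - 2 degrees of freedom accounts for
the extra uncertainty from estimating tau. The interval quantifies the
dispersion of true effects, not the precision of theta_hat, and carries
no notion of statistical significance — significance statements belong to
the confidence interval of the pooled effect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "PredictionInterval",
    "prediction_interval",
    "se_from_ci",
    "pi_from_summary",
]


@dataclass(frozen=True)
class PredictionInterval:
    """A symmetric prediction interval on the analysis scale.

    ``df = k - 2`` is the t degrees of freedom; ``tau2`` and ``se_pooled``
    are the variance components that were combined. When
    ``scale_tag == "log_ratio"`` the bounds exponentiate to the ratio
    scale (see :attr:`ratio_bounds`).
    """

    lower: float
    upper: float
    level: float
    df: int
    tau2: float
    se_pooled: float
    center: float
    scale_tag: str = "linear"

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def ratio_bounds(self) -> tuple[float, float]:
        """Bounds exponentiated to the ratio scale (log_ratio inputs only)."""
        if self.scale_tag != "log_ratio":
            raise ValueError("ratio_bounds only applies to log_ratio intervals")
        return math.exp(self.lower), math.exp(self.upper)

    def to_dict(self) -> dict:
        d = {
            "pi_lower": self.lower,
            "pi_upper": self.upper,
            "level": self.level,
            "df": self.df,
            "tau2": self.tau2,
            "se_pooled": self.se_pooled,
            "center": self.center,
            "scale": self.scale_tag,
        }
        if self.scale_tag == "log_ratio":
            lo, hi = self.ratio_bounds
            d["pi_lower_ratio"] = lo
            d["pi_upper_ratio"] = hi
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def prediction_interval(
    pooled: float,
    se_pooled: float,
    tau2: float,
    k: int,
    level: float = 0.95,
    scale_tag: str = "linear",
) -> PredictionInterval:
    """Prediction interval for the true effect of a new study.

    Bounds are ``pooled -/+ t_{1-alpha/2; k-2} * sqrt(tau2 + se_pooled^2)``.
    Requires k >= 3 so that the t distribution has at least one degree of
    freedom; smaller meta-analyses do not support this interval.
    """
    if k < 3:
        raise ValueError(
            f"prediction interval needs k >= 3 studies (df = k - 2 >= 1); got k={k}"
        )
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2}")
    if se_pooled <= 0:
        raise ValueError(f"se_pooled must be > 0, got {se_pooled}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    df = k - 2
    t = float(stats.t.ppf(0.5 + level / 2.0, df))
    half = t * math.sqrt(tau2 + se_pooled**2)
    return PredictionInterval(
        lower=pooled - half,
        upper=pooled + half,
        level=level,
        df=df,
        tau2=tau2,
        se_pooled=se_pooled,
        center=pooled,
        scale_tag=scale_tag,
    )


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Back-derive a standard error from a symmetric Wald CI.

    ``se = (upper - lower) / (2 * z_{1-alpha/2})``. Inputs must already be
    on the analysis (e.g. log) scale.
    """
    if upper <= lower:
        raise ValueError(f"need upper > lower, got ({lower}, {upper})")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return (upper - lower) / (2.0 * z)


def pi_from_summary(
    pooled_ratio: float,
    ci_ratio: tuple[float, float],
    tau: float,
    k: int,
    level: float = 0.95,
) -> PredictionInterval:
    """Prediction interval from a published ratio-scale summary.

    Takes the pooled ratio estimate (e.g. odds ratio) with its CI as
    printed, plus the reported between-study standard deviation ``tau``
    (not tau^2) and study count ``k``. Everything is log-transformed, the
    pooled SE is back-derived from the CI width, and
    :func:`prediction_interval` is applied. The returned interval is on
    the log scale (``scale_tag="log_ratio"``); use
    :attr:`PredictionInterval.ratio_bounds` for presentation.
    """
    lo, hi = ci_ratio
    if pooled_ratio <= 0 or lo <= 0 or hi <= 0:
        raise ValueError(
            f"ratio-scale inputs must be positive, got {pooled_ratio}, {ci_ratio}"
        )
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    se = se_from_ci(math.log(lo), math.log(hi), level)
    return prediction_interval(
        pooled=math.log(pooled_ratio),
        se_pooled=se,
        tau2=tau**2,
        k=k,
        level=level,
        scale_tag="log_ratio",
    )
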