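"""Inverse-variance pooling and heterogeneity statistics.

Implements fixed-effect and random-effects (DerSimonian–Laird) pooling on
the analysis scale, together with Cochran's Q, the DL moment estimator of
the between-study variance tau^2, and Higgins' I^2.

The fixed-effect model assumes one common true effect underlying all k
studies; the random-effects model draws each study's true effect from
N(theta, tau^2) and estimates theta, the mean of that distribution. With
tau^2 = 0 the two coincide.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import StudyRecord

__all__ = [
    "PoolResult",
    "pool_fixed",
    "pool_random",
    "cochran_q",
    "tau2_dersimonian_laird",
    "i_squared",
]


@dataclass(frozen=True)
class PoolResult:
    """Pooled estimate with heterogeneity statistics.

    ``pooled`` and its Wald CI are on the analysis (possibly log) scale.
    ``weights`` are the normalized inverse-variance weights actually used
    (random-effects weights include tau^2), summing to 1.
    """

    model: str  # "fixed" | "random"
    k: int
    pooled: float
    se_pooled: float
    ci: tuple[float, float]
    level: float
    q_stat: float
    q_df: int
    tau2: float
    i2: float
    weights: tuple[float, ...] = field(default=())
    scale_tag: str = "linear"

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "k": self.k,
            "pooled": self.pooled,
            "se": self.se_pooled,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "level": self.level,
            "q": self.q_stat,
            "q_df": self.q_df,
            "tau2": self.tau2,
            "i2": self.i2,
            "weights": list(self.weights),
            "scale": self.scale_tag,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _validate(studies: Sequence[StudyRecord], min_k: int) -> None:
    if len(studies) < min_k:
        raise ValueError(
            f"need at least {min_k} studies, got {len(studies)}"
        )
    scales = {s.scale_tag for s in studies}
    if len(scales) > 1:
        raise ValueError(f"studies mix analysis scales: {sorted(scales)}")


def _inverse_variance(
    y: np.ndarray, v: np.ndarray, level: float
) -> tuple[float, float, tuple[float, float], np.ndarray]:
    w = 1.0 / v
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    ci = (pooled - z * se, pooled + z * se)
    return pooled, se, ci, w / np.sum(w)


def pool_fixed(studies: Sequence[StudyRecord], level: float = 0.95) -> PoolResult:
    """Fixed-effect inverse-variance pooling.

    Weights are 1/se_i^2; the CI uses the normal quantile. Q/I^2 are
    attached when k >= 2 (they need at least two studies) and reported as
    zero for a single study.
    """
    _validate(studies, 1)
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    y = np.array([s.effect for s in studies])
    v = np.array([s.se**2 for s in studies])
    pooled, se, ci, w = _inverse_variance(y, v, level)
    if len(studies) >= 2:
        q, q_df = cochran_q(studies)
        i2 = i_squared(q, q_df)
    else:
        q, q_df, i2 = 0.0, 0, 0.0
    return PoolResult(
        model="fixed",
        k=len(studies),
        pooled=pooled,
        se_pooled=se,
        ci=ci,
        level=level,
        q_stat=q,
        q_df=q_df,
        tau2=0.0,
        i2=i2,
        weights=tuple(float(x) for x in w),
        scale_tag=studies[0].scale_tag,
    )


def cochran_q(studies: Sequence[StudyRecord]) -> tuple[float, int]:
    """Cochran's Q: weighted squared deviations from the fixed-effect mean.

    Q = sum w_i (y_i - y_FE)^2 with w_i = 1/se_i^2, on k-1 degrees of
    freedom. Requires k >= 2.
    """
    _validate(studies, 2)
    y = np.array([s.effect for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    y_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fe) ** 2))
    return q, len(studies) - 1


def tau2_dersimonian_laird(studies: Sequence[StudyRecord]) -> float:
    """DerSimonian–Laird moment estimator of the between-study variance.

    tau2_hat = max(0, (Q - (k-1)) / (S1 - S2/S1)) with S1 = sum(w_i),
    S2 = sum(w_i^2) and fixed-effect weights w_i = 1/se_i^2. The estimator
    is truncated at zero.
    """
    _validate(studies, 2)
    q, q_df = cochran_q(studies)
    w = np.array([1.0 / s.se**2 for s in studies])
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    denom = s1 - s2 / s1
    if denom <= 0:
        return 0.0
    return max(0.0, (q - q_df) / denom)


def i_squared(q_stat: float, q_df: int) -> float:
    """I^2: share of total variability in study effects due to heterogeneity.

    Computed as max(0, (Q - df)/Q); 0 when Q = 0.
    """
    if q_df < 1:
        raise ValueError(f"q_df must be >= 1, got {q_df}")
    if q_stat < 0:
        raise ValueError(f"Q must be >= 0, got {q_stat}")
    if q_stat == 0.0:
        return 0.0
    return max(0.0, (q_stat - q_df) / q_stat)


def pool_random(
    studies: Sequence[StudyRecord],
    level: float = 0.95,
    tau2_override: Optional[float] = None,
) -> PoolResult:
    """Random-effects pooling with DerSimonian–Laird tau^2.

    Weights are 1/(se_i^2 + tau2_hat); tau2_hat comes from
    :func:`tau2_dersimonian_laird` unless ``tau2_override`` supplies a
    fixed non-negative value (useful for reproducing published analyses).
    With tau2_hat = 0 the result equals :func:`pool_fixed` on the same
    input, up to the model tag.
    """
    if tau2_override is not None and tau2_override < 0:
        raise ValueError(f"tau2_override must be >= 0, got {tau2_override}")
    _validate(studies, 1 if tau2_override is not None else 2)
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")

    tau2 = tau2_dersimonian_laird(studies) if tau2_override is None else float(tau2_override)
    y = np.array([s.effect for s in studies])
    v = np.array([s.se**2 for s in studies]) + tau2
    pooled, se, ci, w = _inverse_variance(y, v, level)
    if len(studies) >= 2:
        q, q_df = cochran_q(studies)
        i2 = i_squared(q, q_df)
    else:
        q, q_df, i2 = 0.0, 0, 0.0
    return PoolResult(
        model="random",
        k=len(studies),
        pooled=pooled,
        se_pooled=se,
        ci=ci,
        level=level,
        q_stat=q,
        q_df=q_df,
        tau2=tau2,
        i2=i2,
        weights=tuple(float(x) for x in w),
        scale_tag=studies[0].scale_tag,
    )
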