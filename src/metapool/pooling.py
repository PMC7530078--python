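"""Conventional (frequentist) meta-analysis on the log scale.

Fixed-effect pooling weights each study by its inverse within-study
variance, ``w_i = 1/v_i``. The random-effects model adds the
DerSimonian-Laird moment estimate of the between-study variance ``tau^2``
to every study variance before re-weighting, ``w*_i = 1/(v_i + tau^2)``.
Heterogeneity is summarized by Cochran's Q (computed with fixed-effect
weights in both models) and I^2 = max(0, (Q - (k-1))/Q).

Confidence intervals use normal quantiles on the log scale; no
Knapp-Hartung small-sample adjustment is applied (the plain
DerSimonian-Laird model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import EmptyEvidenceError, InsufficientStudiesError
from .records import EffectEstimate


@dataclass(frozen=True)
class PooledResult:
    """Pooled log-effect with heterogeneity statistics and study weights."""

    model: str  # "fixed" | "random_dl"
    k: int
    mu_hat: float
    var_mu: float
    ci_level: float
    ci_lower_log: float
    ci_upper_log: float
    Q: float
    tau2: float
    i2: float
    weights: tuple[float, ...]  # normalized, sum to 1, in study order
    study_ids: tuple[str, ...]

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_mu))

    @property
    def rr(self) -> float:
        """Pooled estimate back-transformed to the relative-risk scale."""
        return float(np.exp(self.mu_hat))

    @property
    def rr_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_lower_log)), float(np.exp(self.ci_upper_log))

    def __str__(self) -> str:
        lo, hi = self.rr_ci
        return (
            f"{self.model} pooling of k={self.k}: RR {self.rr:.2f} "
            f"({100 * self.ci_level:.0f}% CI {lo:.2f}, {hi:.2f}); "
            f"Q={self.Q:.2f}, tau^2={self.tau2:.4f}, I^2={100 * self.i2:.1f}%"
        )


def _arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise EmptyEvidenceError("cannot pool an empty set of studies")
    y = np.asarray([e.y for e in effects], dtype=float)
    v = np.asarray([e.v for e in effects], dtype=float)
    return y, v


def _fe_mu(y: np.ndarray, v: np.ndarray) -> tuple[float, float, np.ndarray]:
    w = 1.0 / v
    sw = w.sum()
    return float((w * y).sum() / sw), float(1.0 / sw), w


def cochran_q(effects: Sequence[EffectEstimate]) -> float:
    """Cochran's heterogeneity statistic Q = sum w_i (y_i - mu_FE)^2, w_i = 1/v_i."""
    y, v = _arrays(effects)
    mu, _, w = _fe_mu(y, v)
    return float((w * (y - mu) ** 2).sum())


def i_squared(Q: float, k: int) -> float:
    """Higgins' I^2, the fraction of total variability beyond chance.

    I^2 = max(0, (Q - (k-1))/Q), defined as 0 when Q = 0.
    """
    if k < 2:
        raise InsufficientStudiesError(f"I^2 needs at least 2 studies, got k={k}")
    if Q <= 0.0:
        return 0.0
    return max(0.0, (Q - (k - 1)) / Q)


def dl_tau2(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance.

    tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1)) with S1 = sum w_i,
    S2 = sum w_i^2 and w_i = 1/v_i; truncated at zero.
    """
    if len(effects) < 2:
        raise InsufficientStudiesError(
            f"tau^2 is not identifiable with k={len(effects)} study"
        )
    y, v = _arrays(effects)
    w = 1.0 / v
    s1 = w.sum()
    s2 = (w**2).sum()
    Q = cochran_q(effects)
    k = len(effects)
    return float(max(0.0, (Q - (k - 1)) / (s1 - s2 / s1)))


def _assemble(
    model: str,
    effects: Sequence[EffectEstimate],
    w_star: np.ndarray,
    y: np.ndarray,
    ci_level: float,
    Q: float,
    tau2: float,
) -> PooledResult:
    sw = w_star.sum()
    mu = float((w_star * y).sum() / sw)
    var_mu = float(1.0 / sw)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(var_mu)
    k = len(effects)
    i2 = i_squared(Q, k) if k >= 2 else 0.0
    return PooledResult(
        model=model,
        k=k,
        mu_hat=mu,
        var_mu=var_mu,
        ci_level=ci_level,
        ci_lower_log=float(mu - half),
        ci_upper_log=float(mu + half),
        Q=Q,
        tau2=tau2,
        i2=i2,
        weights=tuple((w_star / sw).tolist()),
        study_ids=tuple(e.study_id for e in effects),
    )


def fixed_effect_pool(
    effects: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PooledResult:
    """Inverse-variance fixed-effect pooling (common-effect model)."""
    y, v = _arrays(effects)
    w = 1.0 / v
    Q = cochran_q(effects)
    return _assemble("fixed", effects, w, y, ci_level, Q, tau2=0.0)


def random_effects_pool(
    effects: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling; needs at least 2 studies."""
    if len(effects) < 2:
        raise InsufficientStudiesError(
            f"random-effects pooling needs at least 2 studies, got k={len(effects)}"
        )
    y, v = _arrays(effects)
    tau2 = dl_tau2(effects)
    w_star = 1.0 / (v + tau2)
    Q = cochran_q(effects)
    return _assemble("random_dl", effects, w_star, y, ci_level, Q, tau2=tau2)
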