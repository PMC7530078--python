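"""Prior distributions for Bayesian pooling.

Two priors are involved: a normal prior on the pooled log relative risk,
elicited from stated 95% RR limits, and a prior on the between-study
standard deviation ``tau``. The default tau prior is the Jeffreys prior —
the square root of the Fisher information for tau in the marginal model
``y_i ~ N(mu, v_i + tau^2)`` — with half-normal and uniform alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .records import Z_975


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior on the pooled log-RR: mean ``m0``, variance ``s0_sq``."""

    m0: float
    s0_sq: float
    description: str = ""

    def __post_init__(self) -> None:
        if not (self.s0_sq > 0 and math.isfinite(self.s0_sq)):
            raise ValueError(f"prior variance must be positive, got {self.s0_sq}")

    @property
    def rr_center(self) -> float:
        """Prior center back-transformed to the relative-risk scale."""
        return math.exp(self.m0)


def elicit_normal_prior(
    rr_lower: float, rr_upper: float, coverage: float = 0.95
) -> NormalPrior:
    """Convert stated central RR limits into a normal prior on the log-RR.

    If the central ``coverage`` mass of relative risks is believed to lie
    between ``rr_lower`` and ``rr_upper``, the implied normal prior has

        m0    = (ln rr_lower + ln rr_upper) / 2
        s0^2  = ((ln rr_upper - ln rr_lower) / (2 z))^2

    with ``z`` the standard-normal ``(1 + coverage)/2`` quantile. Limits
    (0.25, 4) give the vague null-centered N(0, 0.5); limits (1, 2) give
    the informative N(0.347, 0.031) centered at RR 1.41.
    """
    if not (0 < rr_lower < rr_upper):
        raise ValueError(
            f"need 0 < rr_lower < rr_upper, got ({rr_lower}, {rr_upper})"
        )
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must lie in (0, 1), got {coverage}")
    z = float(stats.norm.ppf(0.5 + coverage / 2.0))
    lo, hi = math.log(rr_lower), math.log(rr_upper)
    m0 = (lo + hi) / 2.0
    s0_sq = ((hi - lo) / (2.0 * z)) ** 2
    return NormalPrior(
        m0=m0,
        s0_sq=s0_sq,
        description=f"central {coverage:.0%} of RR in ({rr_lower:g}, {rr_upper:g})",
    )


def vague_prior() -> NormalPrior:
    """Null-centered N(0, 0.5): 95% of relative risks between 0.25 and 4."""
    return elicit_normal_prior(0.25, 4.0)


def informative_prior() -> NormalPrior:
    """N(0.347, 0.031): 95% of relative risks between 1 and 2 (center RR 1.41)."""
    return elicit_normal_prior(1.0, 2.0)


def jeffreys_density(tau, variances: Sequence[float]):
    """Unnormalized Jeffreys prior density for tau (vectorized over ``tau``).

    Square root of the tau-block Fisher information in the marginal model
    y_i ~ N(mu, v_i + tau^2):

        p(tau) ∝ sqrt( sum_i tau^2 / (v_i + tau^2)^2 )

    Vanishes at tau = 0 and decays like sqrt(k)/tau; improper on both ends,
    hence the numerical propriety guard in the posterior routine.
    """
    tau_arr = np.asarray(tau, dtype=float)
    v = np.asarray(variances, dtype=float)[:, None]
    t = np.atleast_1d(tau_arr)[None, :]
    dens = np.sqrt((t**2 / (v + t**2) ** 2).sum(axis=0))
    return float(dens[0]) if np.isscalar(tau) or tau_arr.ndim == 0 else dens


@dataclass(frozen=True)
class HeterogeneityPrior:
    """Prior on the between-study SD tau and the grid it is evaluated on.

    ``form`` is one of ``jeffreys``, ``half_normal`` (with ``scale``),
    ``uniform`` (with ``scale`` as the upper bound) or ``fixed`` (tau pinned
    at ``scale``; ``uniform`` with upper bound 0 degenerates to the same
    point mass at 0). ``tau_max`` is the grid truncation point; ``None``
    selects it adaptively from a pilot scan of the tau posterior.
    """

    form: str = "jeffreys"
    scale: float | None = None
    tau_max: float | None = None
    grid_size: int = 2001

    def __post_init__(self) -> None:
        if self.form not in ("jeffreys", "half_normal", "uniform", "fixed"):
            raise ValueError(f"unknown heterogeneity prior form {self.form!r}")
        if self.form in ("half_normal", "uniform", "fixed") and self.scale is None:
            raise ValueError(f"{self.form} prior needs a scale parameter")
        if self.form in ("half_normal",) and not self.scale > 0:
            raise ValueError("half_normal scale must be positive")
        if self.form in ("uniform", "fixed") and self.scale < 0:
            raise ValueError("tau cannot be negative")
        if self.tau_max is not None and not self.tau_max > 0:
            raise ValueError(f"tau_max must be positive, got {self.tau_max}")
        if self.grid_size < 100:
            raise ValueError(f"grid_size must be >= 100, got {self.grid_size}")

    @classmethod
    def jeffreys(cls, tau_max: float | None = None, grid_size: int = 2001):
        return cls(form="jeffreys", tau_max=tau_max, grid_size=grid_size)

    @classmethod
    def half_normal(cls, scale: float, tau_max: float | None = None, grid_size: int = 2001):
        return cls(form="half_normal", scale=scale, tau_max=tau_max, grid_size=grid_size)

    @classmethod
    def uniform(cls, upper: float, grid_size: int = 2001):
        if upper == 0:
            return cls(form="fixed", scale=0.0)
        return cls(form="uniform", scale=upper, tau_max=upper, grid_size=grid_size)

    @classmethod
    def fixed(cls, tau: float):
        return cls(form="fixed", scale=float(tau))

    @property
    def is_point_mass(self) -> bool:
        return self.form == "fixed"

    def log_density(self, tau_grid: np.ndarray, variances: Sequence[float]) -> np.ndarray:
        """Unnormalized log prior density on the grid (-inf where zero)."""
        tau_grid = np.asarray(tau_grid, dtype=float)
        with np.errstate(divide="ignore"):
            if self.form == "jeffreys":
                return np.log(jeffreys_density(tau_grid, variances))
            if self.form == "half_normal":
                return -0.5 * (tau_grid / self.scale) ** 2
            if self.form == "uniform":
                out = np.zeros_like(tau_grid)
                out[tau_grid > self.scale] = -np.inf
                return out
        raise ValueError("point-mass prior has no grid density")
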