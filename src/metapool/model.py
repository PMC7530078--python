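"""Model/Results interface over the pooling engines.

:class:`MetaAnalysis` is constructed from an evidence base (or CSV, or
DataFrame); ``fit()`` runs a frequentist pooling model and ``fit_bayes()``
the Bayesian grid posterior. Both return results objects carrying the
estimates, their uncertainty, heterogeneity diagnostics, a ``summary()``
table, and ``plot_forest()``.

Example
-------
>>> from metapool import MetaAnalysis
>>> from metapool.datasets import load_synthetic_cyp2d6
>>> ma = MetaAnalysis(load_synthetic_cyp2d6())
>>> res = ma.fit(method="random_dl")
>>> print(res.summary())          # doctest: +SKIP
>>> bres = ma.fit_bayes(prior=(1, 2))
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from . import bayes as _bayes
from . import pooling as _pooling
from .priors import HeterogeneityPrior, NormalPrior, elicit_normal_prior, vague_prior
from .records import (
    Z_975,
    EvidenceBase,
    FilterSpec,
    StudyRecord,
    apply_filter,
    load_evidence_base,
)


class MetaAnalysis:
    """A meta-analytic model over a study-level evidence base.

    Parameters
    ----------
    evidence
        The :class:`~metapool.records.EvidenceBase` to pool.
    z
        Normal quantile used to invert published 95% CIs into within-study
        variances (default: the exact 97.5% point).
    """

    def __init__(self, evidence: EvidenceBase, z: float = Z_975):
        self.evidence = evidence
        self.z = z
        self.effects = evidence.effects(z=z)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_csv(cls, source: str | os.PathLike, z: float = Z_975) -> "MetaAnalysis":
        """Build the model from a CSV path or CSV text in the canonical dialect."""
        return cls(load_evidence_base(source), z=z)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, z: float = Z_975) -> "MetaAnalysis":
        """Build the model from a DataFrame with the canonical columns."""
        records = tuple(
            StudyRecord(**{k: row[k] for k in df.columns}) for _, row in df.iterrows()
        )
        return cls(EvidenceBase(records=records, provenance="from DataFrame"), z=z)

    # ------------------------------------------------------------------ #
    @property
    def k(self) -> int:
        return len(self.evidence)

    def filter(self, spec: FilterSpec | None = None, **criteria) -> "MetaAnalysis":
        """A new model on the filtered subset (criteria as FilterSpec fields)."""
        if spec is None:
            spec = FilterSpec(**criteria)
        elif criteria:
            raise TypeError("pass either a FilterSpec or keyword criteria, not both")
        return MetaAnalysis(apply_filter(self.evidence, spec), z=self.z)

    def fit(self, method: str = "random_dl", ci_level: float = 0.95) -> "FrequentistResults":
        """Frequentist pooling: ``method`` is ``"fixed"`` or ``"random_dl"``."""
        if method == "fixed":
            pooled = _pooling.fixed_effect_pool(self.effects, ci_level=ci_level)
        elif method == "random_dl":
            pooled = _pooling.random_effects_pool(self.effects, ci_level=ci_level)
        else:
            raise ValueError(f"unknown method {method!r}; use 'fixed' or 'random_dl'")
        return FrequentistResults(self, pooled)

    def fit_bayes(
        self,
        prior: NormalPrior | tuple[float, float] | None = None,
        het: HeterogeneityPrior | None = None,
        ci_level: float = 0.95,
    ) -> "BayesianResults":
        """Bayesian pooling; ``prior`` is a NormalPrior or (rr_lower, rr_upper).

        Default prior: vague N(0, 0.5); default tau prior: Jeffreys on an
        adaptively truncated grid.
        """
        if prior is None:
            prior = vague_prior()
        elif isinstance(prior, tuple):
            prior = elicit_normal_prior(*prior)
        post = _bayes.posterior(self.effects, prior, het=het, ci_level=ci_level)
        return BayesianResults(self, post, prior)


class _ResultsBase:
    def __init__(self, model: MetaAnalysis):
        self.model = model

    def _study_table(self) -> pd.DataFrame:
        rows = []
        for rec, eff in zip(self.model.evidence, self.model.effects):
            rows.append(
                {
                    "study_id": rec.study_id,
                    "author": rec.author,
                    "year": rec.year,
                    "rr": rec.rr,
                    "ci_lower": rec.ci_lower,
                    "ci_upper": rec.ci_upper,
                    "y": eff.y,
                    "v": eff.v,
                }
            )
        return pd.DataFrame(rows)

    def plot_forest(self, path: str | os.PathLike | None = None) -> str:
        """Render a forest plot of the studies and this summary; returns SVG text."""
        from .forest import render_forest

        return render_forest(self.model.evidence, self._raw, path)


class FrequentistResults(_ResultsBase):
    """Results of inverse-variance (fixed) or DerSimonian-Laird (random) pooling."""

    def __init__(self, model: MetaAnalysis, pooled: _pooling.PooledResult):
        super().__init__(model)
        self._raw = pooled

    @property
    def pooled(self) -> _pooling.PooledResult:
        return self._raw

    mu_hat = property(lambda self: self._raw.mu_hat)
    var_mu = property(lambda self: self._raw.var_mu)
    se = property(lambda self: self._raw.se)
    rr = property(lambda self: self._raw.rr)
    rr_ci = property(lambda self: self._raw.rr_ci)
    Q = property(lambda self: self._raw.Q)
    tau2 = property(lambda self: self._raw.tau2)
    i2 = property(lambda self: self._raw.i2)
    k = property(lambda self: self._raw.k)

    def summary(self) -> str:
        r = self._raw
        lo, hi = r.rr_ci
        name = {"fixed": "Fixed-effect (inverse variance)",
                "random_dl": "Random-effects (DerSimonian-Laird)"}[r.model]
        lines = [
            "Meta-analysis results",
            "=" * 64,
            f"Model:              {name}",
            f"Studies pooled (k): {r.k}",
            f"Summary RR:         {r.rr:.2f}  ({100 * r.ci_level:.0f}% CI {lo:.2f}, {hi:.2f})",
            f"log-RR (SE):        {r.mu_hat:.4f} ({r.se:.4f})",
            f"Cochran's Q:        {r.Q:.3f}  (df = {r.k - 1})",
            f"tau^2 (DL):         {r.tau2:.4f}",
            f"I^2:                {100 * r.i2:.1f}%",
            "-" * 64,
            f"{'study':<10}{'RR':>8}{'95% CI':>18}{'weight':>10}",
        ]
        for rec, w in zip(self.model.evidence, r.weights):
            lines.append(
                f"{rec.study_id:<10}{rec.rr:>8.2f}"
                f"{f'({rec.ci_lower:.2f}, {rec.ci_upper:.2f})':>18}{100 * w:>9.1f}%"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


class BayesianResults(_ResultsBase):
    """Results of the Bayesian normal-normal model (tau-grid marginal posterior)."""

    def __init__(self, model: MetaAnalysis, post: _bayes.PosteriorSummary, prior: NormalPrior):
        super().__init__(model)
        self._raw = post
        self.prior = prior

    @property
    def posterior(self) -> _bayes.PosteriorSummary:
        return self._raw

    mu_median = property(lambda self: self._raw.mu_median)
    mu_mean = property(lambda self: self._raw.mu_mean)
    rr_median = property(lambda self: self._raw.rr_median)
    rr_mean = property(lambda self: self._raw.rr_mean)
    rr_cri = property(lambda self: self._raw.rr_cri)
    tau_mean = property(lambda self: self._raw.tau_mean)
    k = property(lambda self: self._raw.k)

    def summary(self) -> str:
        p = self._raw
        lo, hi = p.rr_cri
        lines = [
            "Bayesian meta-analysis results",
            "=" * 64,
            "Model:              normal-normal hierarchical (grid marginal)",
            f"Studies pooled (k): {p.k}",
            f"Prior on log-RR:    N({self.prior.m0:.3f}, {self.prior.s0_sq:.3f})"
            + (f"  [{self.prior.description}]" if self.prior.description else ""),
            f"tau prior:          {p.het_form}",
            f"Summary RR:         {p.rr_median:.2f}  "
            f"({100 * p.ci_level:.0f}% CrI {lo:.2f}, {hi:.2f})  [posterior median]",
            f"Posterior mean RR:  {p.rr_mean:.2f}",
            f"Posterior mean tau: {p.tau_mean:.3f}",
            "=" * 64,
        ]
        return "\n".join(lines)
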