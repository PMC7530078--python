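"""Scenario runner: sensitivity grids over study-selection criteria.

A *scenario* pairs a study filter with a list of analyses (conventional
fixed/random-effects, or Bayesian with an elicited prior). Running a list
of scenarios against an evidence base produces a machine-readable report —
a grid of pooled summaries, one cell per (scenario x analysis) — carrying
full filter provenance and an input checksum so every number is auditable.

The shipped default configuration covers the canonical selection criteria
for the CYP2D6/tamoxifen literature (all studies; Caucasian/*4; Asian/*10;
RR<=2; tumour DNA; non-neoplastic DNA) plus two manually trimmed subsets
(Asian/*10 restricted to RR<=2, and RR<=2 restricted to *4-genotyping
studies), each analysed conventionally and with vague and informative
priors.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import bayes as _bayes
from . import pooling as _pooling
from ._version import __version__
from .exceptions import ConfigError, EmptyEvidenceError
from .priors import HeterogeneityPrior, elicit_normal_prior
from .records import EvidenceBase, FilterSpec, apply_filter


@dataclass(frozen=True)
class AnalysisSpec:
    """One analysis cell: a model, and (for Bayesian models) a prior."""

    model: str  # "fixed" | "random_dl" | "bayes"
    prior_limits: tuple[float, float] | None = None
    het: HeterogeneityPrior | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random_dl", "bayes"):
            raise ConfigError(f"unknown analysis model {self.model!r}")
        if self.model == "bayes" and self.prior_limits is None:
            raise ConfigError("a bayes analysis must carry (rr_lower, rr_upper) prior limits")
        if self.model != "bayes" and self.prior_limits is not None:
            raise ConfigError("frequentist analyses carry no prior")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.model == "fixed":
            return "conventional (fixed-effect)"
        if self.model == "random_dl":
            return "conventional (random-effects)"
        lo, hi = self.prior_limits
        return f"bayesian (95% RR in {lo:g}-{hi:g})"


@dataclass(frozen=True)
class ScenarioSpec:
    """A named study-selection criterion with its list of analyses."""

    name: str
    filter: FilterSpec = field(default_factory=FilterSpec)
    analyses: tuple[AnalysisSpec, ...] = ()

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ConfigError(f"scenario {self.name!r} lists no analyses")
        object.__setattr__(self, "analyses", tuple(self.analyses))


@dataclass(frozen=True)
class ScenarioReport:
    """The (scenario x analysis) grid with provenance and input checksum."""

    rows: tuple[dict, ...]
    skipped: tuple[dict, ...]
    input_checksum: str
    engine_version: str
    base_provenance: str

    def to_dict(self) -> dict:
        return {
            "engine": {"name": "metapool", "version": self.engine_version},
            "input": {
                "sha256": self.input_checksum,
                "provenance": self.base_provenance,
            },
            "results": list(self.rows),
            "skipped": list(self.skipped),
        }

    def to_json(self, path: str | os.PathLike | None = None) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is None:
            return text
        Path(path).write_text(text, encoding="utf-8")
        return None

    def to_text(self) -> str:
        """Human-readable grid, RR at 2 decimals."""
        lines = [f"{'Selection criterion':<28}{'Analysis':<34}{'Summary RR (95% interval)'}"]
        last = None
        for row in self.rows:
            crit = row["scenario"] if row["scenario"] != last else ""
            last = row["scenario"]
            lines.append(
                f"{crit:<28}{row['analysis']:<34}"
                f"{row['rr']:.2f} ({row['rr_lower']:.2f}, {row['rr_upper']:.2f})"
            )
        for s in self.skipped:
            lines.append(f"{s['scenario']:<28}{s['reason']}")
        return "\n".join(lines)


def evidence_checksum(base: EvidenceBase) -> str:
    return hashlib.sha256(base.to_csv().encode("utf-8")).hexdigest()


def _run_cell(analysis: AnalysisSpec, effects, ci_level: float) -> dict:
    if analysis.model == "fixed":
        res = _pooling.fixed_effect_pool(effects, ci_level=ci_level)
    elif analysis.model == "random_dl":
        res = _pooling.random_effects_pool(effects, ci_level=ci_level)
    else:
        prior = elicit_normal_prior(*analysis.prior_limits)
        post = _bayes.posterior(effects, prior, het=analysis.het, ci_level=ci_level)
        return {
            "model": "bayes",
            "k": post.k,
            "mu_log": post.mu_median,
            "ci_lower_log": post.cri_lower_log,
            "ci_upper_log": post.cri_upper_log,
            "rr": math.exp(post.mu_median),
            "rr_lower": math.exp(post.cri_lower_log),
            "rr_upper": math.exp(post.cri_upper_log),
            "mu_mean_log": post.mu_mean,
            "rr_mean": math.exp(post.mu_mean),
            "tau_posterior_mean": post.tau_mean,
            "prior": {"m0": prior.m0, "s0_sq": prior.s0_sq},
            "tau_prior": post.het_form,
        }
    return {
        "model": res.model,
        "k": res.k,
        "mu_log": res.mu_hat,
        "ci_lower_log": res.ci_lower_log,
        "ci_upper_log": res.ci_upper_log,
        "rr": math.exp(res.mu_hat),
        "rr_lower": math.exp(res.ci_lower_log),
        "rr_upper": math.exp(res.ci_upper_log),
        "Q": res.Q,
        "tau2": res.tau2,
        "i2": res.i2,
    }


def run_scenarios(
    base: EvidenceBase, specs: Sequence[ScenarioSpec], ci_level: float = 0.95
) -> ScenarioReport:
    """Apply each scenario's filter, run each analysis, assemble the grid.

    Scenarios whose filtered subset has fewer than 2 studies are flagged and
    skipped with a reason; a run in which *every* scenario is empty is an
    error.
    """
    if len(base) == 0:
        raise EmptyEvidenceError("scenario run requires a non-empty evidence base")
    rows: list[dict] = []
    skipped: list[dict] = []
    for spec in specs:
        subset = apply_filter(base, spec.filter)
        if len(subset) < 2:
            skipped.append(
                {
                    "scenario": spec.name,
                    "filter": spec.filter.describe(),
                    "reason": f"skipped: k={len(subset)}",
                }
            )
            continue
        effects = subset.effects()
        for analysis in spec.analyses:
            cell = _run_cell(analysis, effects, ci_level)
            cell.update(
                scenario=spec.name,
                analysis=analysis.name,
                filter=spec.filter.describe(),
                study_ids=list(subset.study_ids),
                ci_level=ci_level,
            )
            rows.append(cell)
    if not rows:
        raise EmptyEvidenceError("every scenario was empty after filtering")
    return ScenarioReport(
        rows=tuple(rows),
        skipped=tuple(skipped),
        input_checksum=evidence_checksum(base),
        engine_version=__version__,
        base_provenance=base.provenance,
    )


# ---------------------------------------------------------------------------
# scenario configuration files


def _analysis_from_dict(d: dict) -> AnalysisSpec:
    het = None
    if "tau_prior" in d:
        tp = d["tau_prior"]
        het = HeterogeneityPrior(
            form=tp.get("form", "jeffreys"),
            scale=tp.get("scale"),
            tau_max=tp.get("tau_max"),
            grid_size=tp.get("grid_size", 2001),
        )
    prior = d.get("prior")
    return AnalysisSpec(
        model=d["model"],
        prior_limits=tuple(prior) if prior is not None else None,
        het=het,
        label=d.get("label"),
    )


def load_scenarios(source: str | os.PathLike) -> list[ScenarioSpec]:
    """Load scenario specs from a YAML (or JSON) configuration file."""
    text = Path(source).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ConfigError(f"{source}: expected a top-level 'scenarios' list")
    specs = []
    for entry in doc["scenarios"]:
        try:
            filt = FilterSpec(**(entry.get("filter") or {}))
            analyses = tuple(_analysis_from_dict(a) for a in entry["analyses"])
            specs.append(ScenarioSpec(name=entry["name"], filter=filt, analyses=analyses))
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"{source}: bad scenario entry {entry!r}: {exc}") from exc
    return specs


def default_scenarios() -> list[ScenarioSpec]:
    """The shipped selection-criteria grid (six subsets + two manual trims)."""
    from .datasets import scenario_config_path

    return load_scenarios(scenario_config_path())
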