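"""Study-level evidence base: data model, CSV I/O, log-scale conversion, filters.

A meta-analytic *evidence base* is an ordered collection of published
studies, each contributing a relative estimate of effect (hazard, odds or
risk ratio — pooled uniformly on the log scale) with its 95% confidence
interval, plus the attributes a reviewer filters on: study population,
DNA source used for genotyping, the set of CYP2D6 alleles assayed, and
the outcome definition.

The CSV dialect is RFC-4180 with a header row and columns::

    study_id, author, year, pmid, country, population, dna_source,
    alleles, outcome, rr, ci_lower, ci_upper

``alleles`` is a semicolon-delimited list of allele tokens (e.g. ``*4;*10``).
Column matching is case-insensitive; values round-trip exactly (floats are
written in shortest-round-trip form).
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .exceptions import (
    DegenerateIntervalError,
    RecordValidationError,
    SchemaError,
)

#: Standard-normal 97.5% point used for all 95% interval arithmetic.
#: 1.96 reproduces every published rounding equally; the exact quantile is
#: kept for internal consistency.
Z_975 = 1.959964

POPULATIONS = ("asian", "caucasian", "mixed", "other")
DNA_SOURCES = ("tumour", "non_neoplastic", "mixed", "unknown")
OUTCOMES = ("recurrence", "bc_mortality", "composite")

#: Published point estimates may round outside their own interval; accept up
#: to this relative excursion before rejecting the row.
_CI_ROUNDING_TOL = 0.01

CSV_COLUMNS = (
    "study_id",
    "author",
    "year",
    "pmid",
    "country",
    "population",
    "dna_source",
    "alleles",
    "outcome",
    "rr",
    "ci_lower",
    "ci_upper",
)

_DNA_ALIASES = {"tumor": "tumour", "germline": "non_neoplastic"}


class StudyRecord(BaseModel):
    """One published study and its summary relative estimate of effect.

    ``rr`` is any relative measure (HR/OR/RR); all are pooled on a common
    log scale without distinction.
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    author: str
    year: int
    pmid: str = ""
    country: str = ""
    population: str
    dna_source: str
    alleles: frozenset[str]
    outcome: str
    rr: float
    ci_lower: float
    ci_upper: float

    @field_validator("study_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        v = v.strip()
        if not v:
            raise ValueError("study_id must be a non-empty token")
        return v

    @field_validator("population", mode="before")
    @classmethod
    def _norm_population(cls, v: str) -> str:
        v = str(v).strip().lower()
        if v not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}, got {v!r}")
        return v

    @field_validator("dna_source", mode="before")
    @classmethod
    def _norm_dna(cls, v: str) -> str:
        v = str(v).strip().lower()
        v = _DNA_ALIASES.get(v, v)
        if v not in DNA_SOURCES:
            raise ValueError(f"dna_source must be one of {DNA_SOURCES}, got {v!r}")
        return v

    @field_validator("outcome", mode="before")
    @classmethod
    def _norm_outcome(cls, v: str) -> str:
        v = str(v).strip().lower()
        if v not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {v!r}")
        return v

    @field_validator("alleles", mode="before")
    @classmethod
    def _parse_alleles(cls, v) -> frozenset[str]:
        if isinstance(v, str):
            v = [tok.strip() for tok in v.split(";")]
        toks = frozenset(t for t in (str(t).strip() for t in v) if t)
        if not toks:
            raise ValueError("alleles must be a non-empty set of allele tokens")
        return toks

    @model_validator(mode="after")
    def _check_effect(self) -> "StudyRecord":
        for name in ("rr", "ci_lower", "ci_upper"):
            val = getattr(self, name)
            if not (val > 0 and math.isfinite(val)):
                raise ValueError(f"{name} must be a positive finite real, got {val}")
        if self.ci_lower > self.ci_upper:
            raise ValueError(
                f"ci_lower ({self.ci_lower}) exceeds ci_upper ({self.ci_upper})"
            )
        if self.rr < self.ci_lower * (1 - _CI_ROUNDING_TOL) or self.rr > self.ci_upper * (
            1 + _CI_ROUNDING_TOL
        ):
            raise ValueError(
                f"rr {self.rr} falls outside [{self.ci_lower}, {self.ci_upper}] "
                "by more than the 1% rounding tolerance"
            )
        return self

    @property
    def alleles_str(self) -> str:
        """Alleles re-serialized as a sorted, semicolon-delimited list."""
        return ";".join(sorted(self.alleles))


@dataclass(frozen=True)
class EffectEstimate:
    """Log-scale effect ``y = ln(rr)`` and within-study variance ``v``."""

    study_id: str
    y: float
    v: float

    def __post_init__(self) -> None:
        if not (self.v > 0 and math.isfinite(self.v)):
            raise RecordValidationError(
                f"within-study variance must be positive, got {self.v}",
                study_id=self.study_id,
            )


def to_effect(record: StudyRecord, z: float = Z_975) -> EffectEstimate:
    """Invert a published 95% CI into a log-scale effect and variance.

    ``y = ln(rr)`` and ``v = ((ln ci_upper - ln ci_lower) / (2 z))^2``, the
    standard symmetric-on-log-scale inversion. ``y`` is taken from the point
    estimate (not the interval midpoint) so forest plots match published
    numbers even for asymmetric published intervals.
    """
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    if record.ci_upper == record.ci_lower:
        raise DegenerateIntervalError(
            f"study {record.study_id}: CI ({record.ci_lower}, {record.ci_upper}) "
            "has zero width; within-study variance is not representable"
        )
    y = math.log(record.rr)
    v = ((math.log(record.ci_upper) - math.log(record.ci_lower)) / (2.0 * z)) ** 2
    return EffectEstimate(study_id=record.study_id, y=y, v=v)


class FilterSpec(BaseModel):
    """Declarative, conjunctive selection of studies.

    All set criteria must hold for a record to be retained. ``rr_max`` is an
    inclusive ceiling on the point estimate; ``required_allele`` asks for
    membership in the record's allele set; ``exclude_ids`` is applied last.
    """

    model_config = ConfigDict(frozen=True)

    population: str | None = None
    dna_source: str | None = None
    required_allele: str | None = None
    rr_max: float | None = None
    include_ids: frozenset[str] | None = None
    exclude_ids: frozenset[str] | None = None

    @field_validator("population")
    @classmethod
    def _pop(cls, v):
        if v is not None and v not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}, got {v!r}")
        return v

    @field_validator("dna_source")
    @classmethod
    def _dna(cls, v):
        if v is not None:
            v = _DNA_ALIASES.get(v, v)
            if v not in DNA_SOURCES:
                raise ValueError(f"dna_source must be one of {DNA_SOURCES}, got {v!r}")
        return v

    @field_validator("rr_max")
    @classmethod
    def _rr_max(cls, v):
        if v is not None and not v > 0:
            raise ValueError(f"rr_max must be positive, got {v}")
        return v

    @field_validator("include_ids", "exclude_ids", mode="before")
    @classmethod
    def _as_frozenset(cls, v):
        return None if v is None else frozenset(v)

    @model_validator(mode="after")
    def _disjoint(self) -> "FilterSpec":
        if self.include_ids and self.exclude_ids and self.include_ids & self.exclude_ids:
            raise ValueError("include_ids and exclude_ids must be disjoint")
        return self

    def is_empty(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in (
                "population",
                "dna_source",
                "required_allele",
                "rr_max",
                "include_ids",
                "exclude_ids",
            )
        )

    def describe(self) -> str:
        """Human-readable provenance fragment, e.g. ``population=asian & allele *10``."""
        parts = []
        if self.population:
            parts.append(f"population={self.population}")
        if self.dna_source:
            parts.append(f"dna_source={self.dna_source}")
        if self.required_allele:
            parts.append(f"allele {self.required_allele}")
        if self.rr_max is not None:
            parts.append(f"RR<={self.rr_max:g}")
        if self.include_ids:
            parts.append(f"include {{{', '.join(sorted(self.include_ids))}}}")
        if self.exclude_ids:
            parts.append(f"exclude {{{', '.join(sorted(self.exclude_ids))}}}")
        return " & ".join(parts) if parts else "no filter"

    def matches(self, record: StudyRecord) -> bool:
        if self.population is not None and record.population != self.population:
            return False
        if self.dna_source is not None and record.dna_source != self.dna_source:
            return False
        if self.required_allele is not None and self.required_allele not in record.alleles:
            return False
        if self.rr_max is not None and record.rr > self.rr_max:
            return False
        if self.include_ids is not None and record.study_id not in self.include_ids:
            return False
        # exclusion applied last by convention
        if self.exclude_ids is not None and record.study_id in self.exclude_ids:
            return False
        return True


@dataclass(frozen=True)
class EvidenceBase:
    """Ordered, duplicate-free collection of :class:`StudyRecord`.

    ``provenance`` accumulates a human-readable description of the filters
    that produced this subset; filtering preserves record order.
    """

    records: tuple[StudyRecord, ...]
    provenance: str = "full evidence base"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for r in self.records:
            if r.study_id in seen:
                raise RecordValidationError(
                    f"duplicate study_id {r.study_id!r}", study_id=r.study_id
                )
            seen.add(r.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> StudyRecord:
        return self.records[i]

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(r.study_id for r in self.records)

    def effects(self, z: float = Z_975) -> list[EffectEstimate]:
        """Log-scale effect estimates for every record, in order."""
        return [to_effect(r, z=z) for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = r.model_dump()
            d["alleles"] = r.alleles_str
            rows.append(d)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def to_csv(self, path: str | os.PathLike | None = None) -> str | None:
        """Serialize to the canonical CSV dialect; returns the text if no path."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for r in self.records:
            writer.writerow(
                [
                    r.study_id,
                    r.author,
                    r.year,
                    r.pmid,
                    r.country,
                    r.population,
                    r.dna_source,
                    r.alleles_str,
                    r.outcome,
                    repr(r.rr),
                    repr(r.ci_lower),
                    repr(r.ci_upper),
                ]
            )
        text = buf.getvalue()
        if path is None:
            return text
        Path(path).write_text(text, encoding="utf-8")
        return None


def _coerce_row(row: dict[str, str], line_no: int) -> StudyRecord:
    sid = (row.get("study_id") or "").strip() or f"<row {line_no}>"
    try:
        return StudyRecord(
            study_id=row["study_id"],
            author=row.get("author", "").strip(),
            year=int(row["year"]),
            pmid=(row.get("pmid") or "").strip(),
            country=(row.get("country") or "").strip(),
            population=row["population"],
            dna_source=row["dna_source"],
            alleles=row["alleles"],
            outcome=row["outcome"],
            rr=float(row["rr"]),
            ci_lower=float(row["ci_lower"]),
            ci_upper=float(row["ci_upper"]),
        )
    except (ValueError, TypeError) as exc:
        raise RecordValidationError(
            f"row {line_no} (study_id={sid}): {exc}", study_id=sid
        ) from exc


def load_evidence_base(source: str | os.PathLike | io.TextIOBase) -> EvidenceBase:
    """Load an evidence base from a CSV path, CSV text, or open text stream.

    A string containing a newline is treated as CSV text; anything else is a
    path. Header matching is case-insensitive. Raises :class:`SchemaError`
    naming the first missing column, and :class:`RecordValidationError` with
    the offending ``study_id`` for row-level domain violations.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
        origin = "<stream>"
    elif isinstance(source, str) and "\n" in source:
        text = source
        origin = "<inline CSV>"
    else:
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        origin = str(path)

    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError(f"{origin}: empty CSV") from None
    colmap = {name.strip().lower(): i for i, name in enumerate(header)}
    for col in CSV_COLUMNS:
        if col not in colmap:
            raise SchemaError(f"{origin}: missing required column {col!r}", column=col)

    records: list[StudyRecord] = []
    for line_no, raw in enumerate(reader, start=2):
        if not raw or all(not cell.strip() for cell in raw):
            continue
        row = {
            name: (raw[idx] if idx < len(raw) else "")
            for name, idx in colmap.items()
        }
        records.append(_coerce_row(row, line_no))
    return EvidenceBase(records=tuple(records), provenance=f"loaded from {origin}")


def apply_filter(base: EvidenceBase, spec: FilterSpec) -> EvidenceBase:
    """Return the subset of ``base`` satisfying every set criterion of ``spec``.

    Conjunctive, order-preserving and idempotent; an empty result is returned
    as an empty EvidenceBase (the pooling layer rejects it, not this one).
    """
    kept = tuple(r for r in base.records if spec.matches(r))
    prov = base.provenance
    if not spec.is_empty():
        prov = f"{prov} | filter: {spec.describe()} -> k={len(kept)}"
    return EvidenceBase(records=kept, provenance=prov)
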