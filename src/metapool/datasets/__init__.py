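"""Bundled text datasets: a synthetic 36-study evidence base and the default
scenario configuration.

The evidence base is *synthetic* (see
:func:`metapool.simulate.make_example_evidence_base`, which regenerates it
deterministically); it emulates the schema and subgroup structure of the
published CYP2D6/tamoxifen literature with known true effects.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..records import EvidenceBase, load_evidence_base

SYNTHETIC_CSV = "synthetic_cyp2d6_36studies.csv"
SCENARIO_YAML = "default_scenarios.yaml"


def _data_path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def synthetic_cyp2d6_path() -> Path:
    """Path to the bundled synthetic 36-study CSV."""
    return _data_path(SYNTHETIC_CSV)


def scenario_config_path() -> Path:
    """Path to the shipped scenario configuration (YAML)."""
    return _data_path(SCENARIO_YAML)


def load_synthetic_cyp2d6() -> EvidenceBase:
    """The bundled synthetic 36-study evidence base."""
    return load_evidence_base(synthetic_cyp2d6_path())
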