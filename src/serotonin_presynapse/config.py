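"""Run configuration: YAML/JSON loading and section builders.

A config file may carry four sections::

    cohort:      # cells, allele_freqs, group_freqs, seed, simulate_ages
    kinetics:    # any KineticParameters field
    variants:    # per-variant allele-multiplier overrides
    statistics:  # yates, posthoc, bh_adjust, moment_convention

All sections are optional; omitted values fall back to package defaults.
YAML is a superset of JSON, so both formats parse with the same loader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .cohort import CohortCell, CohortDesign, DEFAULT_ALLELE_FREQS, default_study_design
from .kinetics import KineticParameters
from .variants import VariantSpec, default_variant_specs, specs_with_overrides

__all__ = [
    "load_config",
    "design_from_config",
    "params_from_config",
    "specs_from_config",
    "dump_config",
]


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return data


def dump_config(config: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def design_from_config(
    config: Mapping[str, Any], seed: int | None = None
) -> CohortDesign:
    """Build a CohortDesign from the ``cohort`` section (defaults otherwise)."""
    section = dict(config.get("cohort") or {})
    base = default_study_design()
    cells = base.cells
    if "cells" in section:
        cells = tuple(
            CohortCell(
                diagnosis=c["diagnosis"],
                sa_status=c["sa_status"],
                n=int(c["n"]),
                n_female=int(c["n_female"]),
            )
            for c in section["cells"]
        )
    allele_freqs = section.get("allele_freqs") or DEFAULT_ALLELE_FREQS
    group_freqs = section.get("group_freqs") or {}
    return CohortDesign(
        cells=cells,
        allele_freqs=allele_freqs,
        group_freqs=group_freqs,
        seed=int(seed if seed is not None else section.get("seed", 0)),
        simulate_ages=bool(section.get("simulate_ages", False)),
    )


def params_from_config(config: Mapping[str, Any]) -> KineticParameters:
    section = dict(config.get("kinetics") or {})
    return KineticParameters(**section)


def specs_from_config(config: Mapping[str, Any]) -> list[VariantSpec]:
    overrides = config.get("variants") or {}
    return specs_with_overrides(overrides, default_variant_specs())
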