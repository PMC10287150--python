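"""YAML/JSON configuration loading for the CLI.

A config file may carry any of the sections ``dialect``, ``catalogue``,
``eligibility``, ``analysis`` and ``simulation``; absent sections fall back
to package defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ConfigurationError
from .pipeline import AnalysisConfig
from .records import (
    DEFAULT_POPULATIONS_CATALOGUE,
    EligibilityRules,
    TableDialect,
)
from .simulate import CohortConfig, MaturityModel, TranslocationModel

__all__ = ["load_config", "AppConfig"]


class AppConfig:
    """Resolved configuration bundle."""

    def __init__(
        self,
        dialect: TableDialect,
        catalogue: tuple[str, ...],
        eligibility: EligibilityRules,
        analysis: AnalysisConfig,
        simulation: CohortConfig,
    ) -> None:
        self.dialect = dialect
        self.catalogue = catalogue
        self.eligibility = eligibility
        self.analysis = analysis
        self.simulation = simulation


def _build(cls, raw: dict, name: str):
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad {name} section: {exc}") from exc


def load_config(path: Optional[str | Path]) -> AppConfig:
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a mapping")

    catalogue = tuple(raw.get("catalogue", DEFAULT_POPULATIONS_CATALOGUE))

    dialect_raw = dict(raw.get("dialect", {}))
    dialect = _build(TableDialect, dialect_raw, "dialect")

    eligibility = _build(
        EligibilityRules, dict(raw.get("eligibility", {})), "eligibility"
    )

    analysis_raw = dict(raw.get("analysis", {}))
    analysis_raw.setdefault("populations_catalogue", catalogue)
    if "populations_catalogue" in analysis_raw:
        analysis_raw["populations_catalogue"] = tuple(
            analysis_raw["populations_catalogue"]
        )
    if analysis_raw.get("status_group_order") is not None:
        analysis_raw["status_group_order"] = tuple(
            analysis_raw["status_group_order"]
        )
    analysis = _build(AnalysisConfig, analysis_raw, "analysis")

    sim_raw = dict(raw.get("simulation", {}))
    if "maturity_model" in sim_raw:
        mm = dict(sim_raw["maturity_model"])
        for key in ("values", "weights"):
            if key in mm:
                mm[key] = tuple(mm[key])
        sim_raw["maturity_model"] = _build(MaturityModel, mm, "maturity_model")
    if "translocation_model" in sim_raw:
        tm = dict(sim_raw["translocation_model"])
        if "baseline" in tm:
            tm["baseline"] = tuple(tm["baseline"])
        sim_raw["translocation_model"] = _build(
            TranslocationModel, tm, "translocation_model"
        )
    if "question_tables" in sim_raw:
        # YAML cannot key on null cleanly; accept "NA" string keys for NA
        tables = {}
        for q, table in sim_raw["question_tables"].items():
            tables[q] = {
                (None if k in (None, "NA") else int(k)): float(v)
                for k, v in table.items()
            }
        sim_raw["question_tables"] = tables
    if "populations_weights" in sim_raw:
        sim_raw["populations_weights"] = {
            (None if k in (None, "NA") else k): float(v)
            for k, v in sim_raw["populations_weights"].items()
        }
    for key in ("taxon_weights", "region_weights", "status_weights",
                "populations_catalogue"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    sim_raw.setdefault("populations_catalogue", catalogue)
    simulation = _build(CohortConfig, sim_raw, "simulation")

    return AppConfig(dialect, catalogue, eligibility, analysis, simulation)
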