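"""Synthetic species cohorts with the statistical structure of the survey.

The generator samples each species' nine question codes from configurable
per-question categorical tables (with NA mass where the survey key allows
it), then samples translocation status from a logistic model whose
implemented-probability shifts monotonically with the species' realised
suitability index.  An association coefficient of 0 makes translocation
status independent of the index.  A fixed seed plus config reproduces the
cohort bit-for-bit.

A 12-record deterministic fixture cohort (with hand-computed index values
spanning -2..5 and priority numbers straddling every category boundary)
ships as package data for use in tests and examples.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .records import (
    DEFAULT_DIALECT,
    DEFAULT_POPULATIONS_CATALOGUE,
    NA_CAPABLE,
    QUESTION_FIELDS,
    GeneticRescueMention,
    ListingStatus,
    MarkerType,
    QuestionResponses,
    SpeciesRecord,
    TaxonomicGroup,
    TranslocationStatus,
    read_species_table,
)
from .scoring import compute_gr_index

__all__ = [
    "MaturityModel",
    "TranslocationModel",
    "CohortConfig",
    "generate_cohort",
    "empirical_check",
    "make_fixture_cohort",
    "load_fixture_expected",
]

_PROB_TOL = 1e-12


def _check_probs(name: str, probs: Sequence[float]) -> None:
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"{name}: negative probability")
    if abs(sum(probs) - 1.0) > _PROB_TOL:
        raise ConfigurationError(
            f"{name}: probabilities sum to {sum(probs)!r}, not 1"
        )


@dataclass(frozen=True)
class MaturityModel:
    """Discrete distribution over age-at-maturity values (years), with
    optional NA mass; values must straddle the 4-yr life-history cutoff."""

    values: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 8.0, 12.0)
    weights: tuple[float, ...] = (0.20, 0.20, 0.15, 0.20, 0.10, 0.05)
    na_mass: float = 0.10

    def validate(self) -> None:
        if len(self.values) != len(self.weights):
            raise ConfigurationError("maturity values/weights length mismatch")
        _check_probs("maturity_model", list(self.weights) + [self.na_mass])


@dataclass(frozen=True)
class TranslocationModel:
    """Baseline status probabilities plus an association coefficient.

    With coefficient b and a species of index g, the implemented
    probability is expit(logit(p_impl) + b*g); the remaining mass is split
    between considered and not_mentioned in their baseline proportions.
    b = 0 gives exact independence from the index.
    """

    baseline: tuple[float, float, float] = (0.44, 0.20, 0.36)
    association: float = 0.0

    def validate(self) -> None:
        _check_probs("translocation baseline", self.baseline)
        if not (0.0 < self.baseline[0] < 1.0):
            raise ConfigurationError(
                "baseline implemented-probability must be in (0, 1)"
            )

    def probs(self, gr_index: int) -> tuple[float, float, float]:
        p0 = self.baseline[0]
        logit = math.log(p0 / (1.0 - p0)) + self.association * gr_index
        p_impl = 1.0 / (1.0 + math.exp(-logit))
        rest = self.baseline[1] + self.baseline[2]
        p_cons = (1.0 - p_impl) * self.baseline[1] / rest
        p_not = (1.0 - p_impl) * self.baseline[2] / rest
        return (p_impl, p_cons, p_not)


# Default per-question code tables (None = NA).  Calibrated so the synthetic
# candidate fraction lands near two-thirds; a default, not a claim.
_DEFAULT_QUESTION_TABLES: dict[str, dict[Optional[int], float]] = {
    "q1_inbreeding": {0: 0.05, 1: 0.20, 2: 0.10, None: 0.65},
    "q2_low_variation": {0: 0.10, 1: 0.55, None: 0.35},
    "q3_small_pops": {0: 0.05, 1: 0.80, None: 0.15},
    "q4_genetic_survey": {0: 0.10, 1: 0.90},
    "q5_ploidy": {0: 0.95, -1: 0.05},
    "q6_adaptive_diff": {0: 0.15, -1: 0.05, None: 0.80},
    "q7_ecoregions": {0: 0.85, -1: 0.15},
    "q8_disease": {0: 0.10, -1: 0.25, None: 0.65},
    "q9_behavior": {-1: 0.15, None: 0.85},
}

_TAXA = tuple(TaxonomicGroup)
_REGIONS = tuple(range(1, 9))
_STATUSES = (ListingStatus.ENDANGERED, ListingStatus.THREATENED)
_TRANSLOC = (
    TranslocationStatus.IMPLEMENTED,
    TranslocationStatus.CONSIDERED,
    TranslocationStatus.NOT_MENTIONED,
)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic cohort."""

    n_species: int = 222
    taxon_weights: tuple[float, ...] = (
        25 / 222, 40 / 222, 95 / 222, 38 / 222, 24 / 222,
    )  # Amphibians, Birds, Fishes, Mammals, Reptiles
    region_weights: tuple[float, ...] = (
        20 / 222, 25 / 222, 30 / 222, 71 / 222, 25 / 222, 30 / 222,
        5 / 222, 16 / 222,
    )
    status_weights: tuple[float, float] = (0.70, 0.30)
    question_tables: Mapping[str, Mapping[Optional[int], float]] = dc_field(
        default_factory=lambda: {
            q: dict(t) for q, t in _DEFAULT_QUESTION_TABLES.items()
        }
    )
    translocation_model: TranslocationModel = TranslocationModel()
    populations_weights: Mapping[Optional[str], float] = dc_field(
        default_factory=lambda: {
            "1 to 5": 0.35, "6 to 20": 0.25, "21 to 80": 0.15,
            "81 to 300": 0.08, ">300": 0.07, None: 0.10,
        }
    )
    populations_catalogue: tuple[str, ...] = DEFAULT_POPULATIONS_CATALOGUE
    maturity_model: MaturityModel = MaturityModel()
    priority_na_mass: float = 0.10
    n_evaluators: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigurationError("n_species must be positive")
        _check_probs("taxon_weights", self.taxon_weights)
        if len(self.taxon_weights) != len(_TAXA):
            raise ConfigurationError("need 5 taxon weights")
        _check_probs("region_weights", self.region_weights)
        if len(self.region_weights) != len(_REGIONS):
            raise ConfigurationError("need 8 region weights")
        _check_probs("status_weights", self.status_weights)
        for q in QUESTION_FIELDS:
            if q not in self.question_tables:
                raise ConfigurationError(f"question_tables missing {q}")
            table = self.question_tables[q]
            _check_probs(q, list(table.values()))
            from .records import _QUESTION_CODES  # allowed-code source of truth

            for code, p in table.items():
                if code is None:
                    if q not in NA_CAPABLE and p > 0.0:
                        raise ConfigurationError(
                            f"{q}: NA mass must be zero (no NA state)"
                        )
                elif code not in _QUESTION_CODES[q]:
                    raise ConfigurationError(f"{q}: code {code} not allowed")
        self.translocation_model.validate()
        _check_probs("populations_weights", list(self.populations_weights.values()))
        for cat in self.populations_weights:
            if cat is not None and cat not in self.populations_catalogue:
                raise ConfigurationError(
                    f"populations_weights references unknown category {cat!r}"
                )
        self.maturity_model.validate()
        if not (0.0 <= self.priority_na_mass <= 1.0):
            raise ConfigurationError("priority_na_mass must be in [0, 1]")
        if self.n_evaluators < 1:
            raise ConfigurationError("n_evaluators must be positive")


def _choice(rng: np.random.Generator, options: Sequence, probs: Sequence[float]):
    idx = rng.choice(len(options), p=np.asarray(probs, dtype=float))
    return options[int(idx)]


def generate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> list[SpeciesRecord]:
    """Draw ``config.n_species`` records; identical config + seed gives a
    bit-identical cohort.  ``seed`` overrides ``config.seed`` if given."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[SpeciesRecord] = []

    for i in range(config.n_species):
        codes: dict[str, Optional[int]] = {}
        for q in QUESTION_FIELDS:
            table = config.question_tables[q]
            keys = list(table.keys())
            codes[q] = _choice(rng, keys, [table[k] for k in keys])
        responses = QuestionResponses(**codes)
        gr = compute_gr_index(responses)

        transloc = _choice(
            rng, _TRANSLOC, config.translocation_model.probs(gr)
        )
        pop_keys = list(config.populations_weights.keys())
        populations = _choice(
            rng, pop_keys, [config.populations_weights[k] for k in pop_keys]
        )
        mm = config.maturity_model
        maturity = _choice(
            rng,
            list(mm.values) + [None],
            list(mm.weights) + [mm.na_mass],
        )
        lifespan = (
            None if maturity is None
            else round(float(maturity) * float(rng.uniform(2.0, 5.0)), 1)
        )
        priority = (
            None if rng.random() < config.priority_na_mass
            else int(rng.integers(1, 19))
        )
        markers = frozenset(
            m for m, p in (
                (MarkerType.MTDNA_NUCLEAR, 0.77),
                (MarkerType.MICROSATELLITE, 0.74),
                (MarkerType.SNP, 0.23),
            ) if rng.random() < p
        )
        records.append(
            SpeciesRecord(
                species_id=f"SYN-{i + 1:04d}",
                scientific_name=f"Genus species{i + 1}",
                common_name=f"synthetic species {i + 1}",
                lead_region=_choice(rng, _REGIONS, config.region_weights),
                listing_status=_choice(rng, _STATUSES, config.status_weights),
                taxonomic_group=_choice(rng, _TAXA, config.taxon_weights),
                populations_remaining=populations,
                age_at_maturity_years=(
                    None if maturity is None else float(maturity)
                ),
                lifespan_years=lifespan,
                recovery_priority_number=priority,
                translocation_status=transloc,
                genetic_rescue_mentioned=GeneticRescueMention.ABSENT,
                marker_types=markers,
                evaluator_id=f"EV{int(rng.integers(1, config.n_evaluators + 1))}",
                responses=responses,
                island_species=False,
                marine_species=False,
                likely_extinct=False,
                in_us_range=True,
            )
        )
    return records


def empirical_check(
    cohort: Sequence[SpeciesRecord],
    config: CohortConfig,
    n_se: float = 4.0,
) -> dict:
    """Compare empirical per-question code frequencies against the config.

    Each code's observed frequency must lie within ``n_se`` binomial
    standard errors of its configured probability.  Returns a report dict
    with per-code entries and an overall ``ok`` flag.
    """
    n = len(cohort)
    report: dict = {"n": n, "questions": {}, "ok": True}
    for q in QUESTION_FIELDS:
        table = config.question_tables[q]
        entries = {}
        for code, p in table.items():
            observed = sum(
                1 for r in cohort if getattr(r.responses, q) == code
            )
            freq = observed / n
            se = math.sqrt(p * (1.0 - p) / n)
            ok = abs(freq - p) <= n_se * se + 1e-12
            entries["NA" if code is None else str(code)] = {
                "expected": p,
                "observed": freq,
                "se": se,
                "ok": ok,
            }
            report["ok"] = report["ok"] and ok
        report["questions"][q] = entries
    return report


def make_fixture_cohort() -> list[SpeciesRecord]:
    """The packaged 12-record deterministic fixture cohort."""
    source = resources.files("grindex.data").joinpath("fixture_cohort.csv")
    with source.open("r", encoding="utf-8", newline="") as fh:
        report = read_species_table(fh, DEFAULT_DIALECT)
    if not report.ok:
        raise ConfigurationError(f"fixture cohort invalid: {report.issues}")
    return report.records


def load_fixture_expected() -> dict[str, dict[str, int]]:
    """Hand-computed index values and missing counts for the fixture."""
    source = resources.files("grindex.data").joinpath("fixture_expected.csv")
    expected: dict[str, dict[str, int]] = {}
    with source.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            expected[row["species_id"]] = {
                "gr_index": int(row["gr_index"]),
                "n_missing": int(row["n_missing"]),
            }
    return expected
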