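"""Species survey records: domain types, CSV I/O, eligibility filters, recodings.

The survey table holds one row per listed species with taxonomy, listing
metadata, a populations-remaining range category, life-history numbers, and
the nine coded survey responses.  Missing values are carried as a distinct
state (``None`` internally, a configurable token -- default ``"NA"`` -- on
disk) and are never conflated with an explicit code of 0.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from .errors import ConfigurationError, ValidationError

__all__ = [
    "ListingStatus",
    "TaxonomicGroup",
    "TranslocationStatus",
    "GeneticRescueMention",
    "MarkerType",
    "PriorityCategory",
    "LifeHistory",
    "QuestionResponses",
    "SpeciesRecord",
    "EligibilityRules",
    "TableDialect",
    "LoadIssue",
    "LoadReport",
    "DEFAULT_POPULATIONS_CATALOGUE",
    "read_species_table",
    "write_species_table",
    "apply_eligibility_filters",
    "priority_category",
    "life_history_class",
    "populations_ordinal",
]


class ListingStatus(str, enum.Enum):
    ENDANGERED = "Endangered"
    THREATENED = "Threatened"


class TaxonomicGroup(str, enum.Enum):
    AMPHIBIANS = "Amphibians"
    BIRDS = "Birds"
    FISHES = "Fishes"
    MAMMALS = "Mammals"
    REPTILES = "Reptiles"


class TranslocationStatus(str, enum.Enum):
    IMPLEMENTED = "implemented"
    CONSIDERED = "considered"
    NOT_MENTIONED = "not_mentioned"


class GeneticRescueMention(str, enum.Enum):
    MENTIONED = "mentioned"
    CONSIDERED_CONCEPT = "considered_concept"
    ABSENT = "absent"


class MarkerType(str, enum.Enum):
    MTDNA_NUCLEAR = "mtdna_nuclear"
    MICROSATELLITE = "microsatellite"
    SNP = "snp"


class PriorityCategory(str, enum.Enum):
    """Broad recovery-priority category; ``rank`` orders High < Moderate < Low."""

    HIGH = "High"
    MODERATE = "Moderate"
    LOW = "Low"

    @property
    def rank(self) -> int:
        return ("High", "Moderate", "Low").index(self.value)


class LifeHistory(str, enum.Enum):
    FAST = "fast"
    SLOW = "slow"


#: Default ordered catalogue of populations-remaining range categories.
#: Strictly increasing in range midpoint; configurable because the range
#: labelling is a data-source dialect.
DEFAULT_POPULATIONS_CATALOGUE: tuple[str, ...] = (
    "1 to 5",
    "6 to 20",
    "21 to 80",
    "81 to 300",
    ">300",
)

# Allowed integer codes per survey question.  ``None`` (missing) is allowed
# only for the six questions listed in NA_CAPABLE.
_QUESTION_CODES: dict[str, frozenset[int]] = {
    "q1_inbreeding": frozenset({0, 1, 2}),
    "q2_low_variation": frozenset({0, 1}),
    "q3_small_pops": frozenset({0, 1}),
    "q4_genetic_survey": frozenset({0, 1}),
    "q5_ploidy": frozenset({0, -1}),
    "q6_adaptive_diff": frozenset({0, -1}),
    "q7_ecoregions": frozenset({0, -1}),
    "q8_disease": frozenset({0, -1}),
    "q9_behavior": frozenset({-1}),
}

NA_CAPABLE: tuple[str, ...] = (
    "q1_inbreeding",
    "q2_low_variation",
    "q3_small_pops",
    "q6_adaptive_diff",
    "q8_disease",
    "q9_behavior",
)

QUESTION_FIELDS: tuple[str, ...] = tuple(_QUESTION_CODES)


@dataclass(frozen=True)
class QuestionResponses:
    """The nine coded survey responses for one species.

    Codes follow the survey key: positive codes flag small-population
    concerns (inbreeding signs = 2, concerns = 1, genetic survey done = 1,
    ...), negative codes flag risk factors (ploidy variation, adaptive
    differentiation, distinct ecoregions, disease, behaviour = -1), and 0
    records an explicit statement of no concern.  ``None`` means the topic
    was not mentioned; only q1, q2, q3, q6, q8 and q9 admit it.
    """

    q1_inbreeding: Optional[int] = None
    q2_low_variation: Optional[int] = None
    q3_small_pops: Optional[int] = None
    q4_genetic_survey: int = 0
    q5_ploidy: int = 0
    q6_adaptive_diff: Optional[int] = None
    q7_ecoregions: int = 0
    q8_disease: Optional[int] = None
    q9_behavior: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, allowed in _QUESTION_CODES.items():
            code = getattr(self, name)
            if code is None:
                if name not in NA_CAPABLE:
                    raise ValidationError(
                        f"{name}: missing (NA) is not an allowed state"
                    )
                continue
            if code not in allowed:
                raise ValidationError(
                    f"{name}: code {code!r} not in allowed set {sorted(allowed)}"
                )

    def as_tuple(self) -> tuple[Optional[int], ...]:
        """Codes in q1..q9 order."""
        return tuple(getattr(self, name) for name in QUESTION_FIELDS)


@dataclass
class SpeciesRecord:
    """One surveyed species/subspecies with metadata and coded responses."""

    species_id: str
    scientific_name: str = ""
    common_name: str = ""
    lead_region: Optional[int] = None
    listing_status: Optional[ListingStatus] = None
    taxonomic_group: Optional[TaxonomicGroup] = None
    populations_remaining: Optional[str] = None
    age_at_maturity_years: Optional[float] = None
    lifespan_years: Optional[float] = None
    recovery_priority_number: Optional[int] = None
    translocation_status: Optional[TranslocationStatus] = None
    genetic_rescue_mentioned: Optional[GeneticRescueMention] = None
    marker_types: frozenset[MarkerType] = frozenset()
    evaluator_id: Optional[str] = None
    responses: QuestionResponses = field(default_factory=QuestionResponses)
    island_species: Optional[bool] = None
    marine_species: Optional[bool] = None
    likely_extinct: Optional[bool] = None
    in_us_range: Optional[bool] = None

    def validate(
        self,
        catalogue: Sequence[str] = DEFAULT_POPULATIONS_CATALOGUE,
    ) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be non-empty")
        if self.lead_region is not None and self.lead_region not in range(1, 9):
            raise ValidationError(
                f"lead_region {self.lead_region!r} not in 1..8"
            )
        if self.recovery_priority_number is not None and (
            self.recovery_priority_number not in range(1, 19)
        ):
            raise ValidationError(
                f"recovery_priority_number {self.recovery_priority_number!r} "
                "not in 1..18"
            )
        for name in ("age_at_maturity_years", "lifespan_years"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be non-negative")
        if (
            self.populations_remaining is not None
            and self.populations_remaining not in catalogue
        ):
            raise ValidationError(
                f"populations_remaining {self.populations_remaining!r} not in "
                f"catalogue {list(catalogue)}"
            )
        self.responses.validate()


@dataclass(frozen=True)
class EligibilityRules:
    """Which records enter the analysis.

    Defaults reproduce the study's filtering choices: all exclusions on and
    any populations-remaining category (the lowest default category already
    spans two or more populations).  ``min_populations_rank`` is a rank into
    the ordered catalogue; records in a category below that rank are
    excluded as effectively single-population.
    """

    min_populations_rank: int = 0
    exclude_islands: bool = True
    exclude_marine: bool = True
    exclude_extinct: bool = True
    require_us_range: bool = True


# ---------------------------------------------------------------------------
# CSV dialect and I/O
# ---------------------------------------------------------------------------

_FIELD_ORDER: tuple[str, ...] = (
    "species_id",
    "scientific_name",
    "common_name",
    "lead_region",
    "listing_status",
    "taxonomic_group",
    "populations_remaining",
    "age_at_maturity_years",
    "lifespan_years",
    "recovery_priority_number",
    "translocation_status",
    "genetic_rescue_mentioned",
    "marker_types",
    "evaluator_id",
    "q1",
    "q2",
    "q3",
    "q4",
    "q5",
    "q6",
    "q7",
    "q8",
    "q9",
    "island_species",
    "marine_species",
    "likely_extinct",
    "in_us_range",
)

_Q_SHORT_TO_FIELD = dict(zip(
    ("q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8", "q9"), QUESTION_FIELDS
))


@dataclass(frozen=True)
class TableDialect:
    """Field-name mapping and token conventions for the delimited table.

    ``columns`` maps logical field names (see ``TableDialect.field_names()``)
    to header names in the file; every logical field must be mapped and no
    extra headers are tolerated, so schema drift surfaces as a configuration
    error instead of silent misalignment.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {name: name for name in _FIELD_ORDER}
    )
    na_token: str = "NA"
    list_sep: str = ";"
    delimiter: str = ","

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return _FIELD_ORDER

    def header(self) -> list[str]:
        return [self.columns[name] for name in _FIELD_ORDER]

    def validate(self) -> None:
        missing = [n for n in _FIELD_ORDER if n not in self.columns]
        if missing:
            raise ConfigurationError(f"dialect missing field mappings: {missing}")


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class LoadIssue:
    row: int  # 1-based data-row number (header not counted)
    column: str
    message: str


@dataclass
class LoadReport:
    records: list[SpeciesRecord]
    issues: list[LoadIssue]

    @property
    def ok(self) -> bool:
        return not self.issues


def _parse_optional(token: str, na: str):
    return None if token == na or token == "" else token


def _parse_bool(token: str) -> bool:
    low = token.strip().lower()
    if low in ("true", "yes", "1"):
        return True
    if low in ("false", "no", "0"):
        return False
    raise ValidationError(f"cannot parse boolean from {token!r}")


def _parse_enum(enum_cls, token: str):
    try:
        return enum_cls(token)
    except ValueError:
        allowed = [e.value for e in enum_cls]
        raise ValidationError(f"{token!r} not one of {allowed}") from None


def _parse_row(
    raw: Mapping[str, str], dialect: TableDialect, catalogue: Sequence[str]
) -> SpeciesRecord:
    na = dialect.na_token

    def get(name: str) -> str:
        return raw[dialect.columns[name]].strip()

    def opt(name: str) -> Optional[str]:
        return _parse_optional(get(name), na)

    codes: dict[str, Optional[int]] = {}
    for short, fname in _Q_SHORT_TO_FIELD.items():
        token = get(short)
        if token == na or token == "":
            if fname not in NA_CAPABLE:
                raise ValidationError(
                    f"{short}: missing (NA) is not an allowed state"
                )
            codes[fname] = None
        else:
            try:
                codes[fname] = int(token)
            except ValueError:
                raise ValidationError(
                    f"{short}: cannot parse code from {token!r}"
                ) from None
    responses = QuestionResponses(**codes)

    markers_token = opt("marker_types")
    markers: frozenset[MarkerType] = frozenset()
    if markers_token:
        try:
            markers = frozenset(
                _parse_enum(MarkerType, t.strip())
                for t in markers_token.split(dialect.list_sep)
                if t.strip()
            )
        except ValidationError as exc:
            raise ValidationError(f"marker_types: {exc}") from None

    def opt_num(name: str, kind):
        token = opt(name)
        if token is None:
            return None
        try:
            return kind(token)
        except ValueError:
            raise ValidationError(
                f"{name}: cannot parse {kind.__name__} from {token!r}"
            ) from None

    def opt_enum(name: str, enum_cls):
        token = opt(name)
        if token is None:
            return None
        try:
            return _parse_enum(enum_cls, token)
        except ValidationError as exc:
            raise ValidationError(f"{name}: {exc}") from None

    def opt_bool(name: str) -> Optional[bool]:
        token = opt(name)
        if token is None:
            return None
        try:
            return _parse_bool(token)
        except ValidationError as exc:
            raise ValidationError(f"{name}: {exc}") from None

    record = SpeciesRecord(
        species_id=get("species_id"),
        scientific_name=get("scientific_name"),
        common_name=get("common_name"),
        lead_region=opt_num("lead_region", int),
        listing_status=opt_enum("listing_status", ListingStatus),
        taxonomic_group=opt_enum("taxonomic_group", TaxonomicGroup),
        populations_remaining=opt("populations_remaining"),
        age_at_maturity_years=opt_num("age_at_maturity_years", float),
        lifespan_years=opt_num("lifespan_years", float),
        recovery_priority_number=opt_num("recovery_priority_number", int),
        translocation_status=opt_enum("translocation_status", TranslocationStatus),
        genetic_rescue_mentioned=opt_enum(
            "genetic_rescue_mentioned", GeneticRescueMention
        ),
        marker_types=markers,
        evaluator_id=opt("evaluator_id"),
        responses=responses,
        island_species=opt_bool("island_species"),
        marine_species=opt_bool("marine_species"),
        likely_extinct=opt_bool("likely_extinct"),
        in_us_range=opt_bool("in_us_range"),
    )
    record.validate(catalogue)
    return record


Source = Union[str, Path, IO[str]]


def read_species_table(
    source: Source,
    dialect: TableDialect = DEFAULT_DIALECT,
    catalogue: Sequence[str] = DEFAULT_POPULATIONS_CATALOGUE,
    strict: bool = False,
) -> LoadReport:
    """Read a delimited species table into validated records.

    Header problems (a mapped column absent, or an unmapped extra column)
    raise :class:`ConfigurationError`.  Row-level problems (unparseable or
    out-of-set codes) skip the row and are collected as :class:`LoadIssue`
    entries naming the data row and column; with ``strict=True`` the first
    such issue raises instead.
    """
    dialect.validate()
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_species_table(fh, dialect, catalogue, strict)

    reader = csv.DictReader(source, delimiter=dialect.delimiter)
    if reader.fieldnames is None:
        raise ConfigurationError("input has no header row")
    expected = set(dialect.header())
    got = set(reader.fieldnames)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ConfigurationError(
            f"header mismatch: missing columns {missing}, unknown columns {extra}"
        )

    records: list[SpeciesRecord] = []
    issues: list[LoadIssue] = []
    for i, raw in enumerate(reader, start=1):
        try:
            records.append(_parse_row(raw, dialect, catalogue))
        except ValidationError as exc:
            message = str(exc)
            column = message.split(":", 1)[0] if ":" in message else "?"
            issue = LoadIssue(row=i, column=column, message=message)
            if strict:
                raise ValidationError(f"row {i}: {message}") from exc
            issues.append(issue)
    return LoadReport(records=records, issues=issues)


def _format_value(value, dialect: TableDialect) -> str:
    if value is None:
        return dialect.na_token
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, frozenset):
        return dialect.list_sep.join(sorted(m.value for m in value))
    return str(value)


def write_species_table(
    records: Iterable[SpeciesRecord],
    sink: Union[str, Path, IO[str]],
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write records as delimited text; ``read_species_table`` round-trips it."""
    dialect.validate()
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            write_species_table(records, fh, dialect)
        return

    writer = csv.writer(sink, delimiter=dialect.delimiter)
    writer.writerow(dialect.header())
    for record in records:
        row = []
        for name in _FIELD_ORDER:
            if name in _Q_SHORT_TO_FIELD:
                value = getattr(record.responses, _Q_SHORT_TO_FIELD[name])
            else:
                value = getattr(record, name)
            row.append(_format_value(value, dialect))
        writer.writerow(row)


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

def apply_eligibility_filters(
    records: Sequence[SpeciesRecord],
    rules: EligibilityRules = EligibilityRules(),
    catalogue: Sequence[str] = DEFAULT_POPULATIONS_CATALOGUE,
) -> tuple[list[SpeciesRecord], list[tuple[str, str]]]:
    """Split records into kept and excluded per the eligibility rules.

    Rules are checked in the study's order -- too-few-populations/extinct,
    island, marine, US range -- and each excluded record is logged once with
    the first rule it violated.  Records whose relevant flag is missing are
    kept but logged as ``"unassessable: <rule>"`` so the caller can audit
    them; this keeps filtering idempotent.
    """
    kept: list[SpeciesRecord] = []
    log: list[tuple[str, str]] = []
    rank = {cat: i for i, cat in enumerate(catalogue)}

    for record in records:
        reason = None
        unassessable: list[str] = []

        if rules.min_populations_rank > 0:
            if record.populations_remaining is None:
                unassessable.append("populations")
            elif rank[record.populations_remaining] < rules.min_populations_rank:
                reason = "too_few_populations"
        if reason is None and rules.exclude_extinct:
            if record.likely_extinct is None:
                unassessable.append("extinct")
            elif record.likely_extinct:
                reason = "likely_extinct"
        if reason is None and rules.exclude_islands:
            if record.island_species is None:
                unassessable.append("island")
            elif record.island_species:
                reason = "island_species"
        if reason is None and rules.exclude_marine:
            if record.marine_species is None:
                unassessable.append("marine")
            elif record.marine_species:
                reason = "marine_species"
        if reason is None and rules.require_us_range:
            if record.in_us_range is None:
                unassessable.append("us_range")
            elif not record.in_us_range:
                reason = "outside_us_range"

        if reason is not None:
            log.append((record.species_id, reason))
        else:
            kept.append(record)
            for rule in unassessable:
                log.append((record.species_id, f"unassessable: {rule}"))
    return kept, log


# ---------------------------------------------------------------------------
# Categorical recodings
# ---------------------------------------------------------------------------

def priority_category(recovery_priority_number: int) -> PriorityCategory:
    """Map a recovery priority number (1 highest .. 18 lowest) to its
    broad category: 1-6 High, 7-12 Moderate, 13-18 Low."""
    if recovery_priority_number not in range(1, 19):
        raise ValidationError(
            f"recovery priority number {recovery_priority_number!r} not in 1..18"
        )
    if recovery_priority_number <= 6:
        return PriorityCategory.HIGH
    if recovery_priority_number <= 12:
        return PriorityCategory.MODERATE
    return PriorityCategory.LOW


def life_history_class(
    age_at_maturity_years: Optional[float],
) -> Optional[LifeHistory]:
    """Dichotomize age at maturity: < 4 yr fast, >= 4 yr slow, missing -> None."""
    if age_at_maturity_years is None:
        return None
    if age_at_maturity_years < 0:
        raise ValidationError("age_at_maturity_years must be non-negative")
    return LifeHistory.FAST if age_at_maturity_years < 4 else LifeHistory.SLOW


def populations_ordinal(
    category: str,
    catalogue: Sequence[str] = DEFAULT_POPULATIONS_CATALOGUE,
) -> int:
    """0-based rank of a populations-remaining category in the catalogue."""
    try:
        return list(catalogue).index(category)
    except ValueError:
        raise ValidationError(
            f"unknown populations category {category!r}; "
            f"catalogue is {list(catalogue)}"
        ) from None
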