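"""Genetic-rescue suitability scoring.

The suitability index of a species is the integer sum of its nine coded
survey responses with missing answers contributing zero.  Scores therefore
live in [-5, +5]: the four concern questions contribute at most
2+1+1+1 = +5 and the five risk questions at most -5.  A species is a
candidate when its index reaches the (configurable) threshold, default 2.
All arithmetic is exact integer arithmetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import (
    NA_CAPABLE,
    QUESTION_FIELDS,
    QuestionResponses,
    SpeciesRecord,
)

__all__ = [
    "GR_INDEX_MIN",
    "GR_INDEX_MAX",
    "DEFAULT_CANDIDATE_THRESHOLD",
    "GRResult",
    "GRDistribution",
    "compute_gr_index",
    "count_missing",
    "classify_candidate",
    "score_cohort",
]

GR_INDEX_MIN = -5
GR_INDEX_MAX = 5
DEFAULT_CANDIDATE_THRESHOLD = 2


def compute_gr_index(responses: QuestionResponses) -> int:
    """Sum the nine question codes, counting missing (None) as zero."""
    return sum(
        code
        for code in (getattr(responses, name) for name in QUESTION_FIELDS)
        if code is not None
    )


def count_missing(responses: QuestionResponses) -> int:
    """Number of the six NA-capable questions recorded as missing (0..6)."""
    return sum(1 for name in NA_CAPABLE if getattr(responses, name) is None)


def classify_candidate(
    gr_index: int, threshold: int = DEFAULT_CANDIDATE_THRESHOLD
) -> bool:
    """True iff the index reaches the candidacy threshold."""
    return gr_index >= threshold


@dataclass(frozen=True)
class GRResult:
    species_id: str
    gr_index: int
    n_missing: int
    candidate: bool


@dataclass
class GRDistribution:
    """Counts of species per index value, overall and per grouping variable.

    ``by_group`` maps a stratifier name ("taxonomic_group", "lead_region",
    "translocation_status") to ``{level: {gr_index: count}}``.  Observed and
    theoretical index ranges are reported separately: the theoretical bound
    is a property of the scoring rules, the observed range of the cohort.
    """

    n: int
    counts: dict[int, int]
    by_group: dict[str, dict[str, dict[int, int]]]
    candidate_fraction: Optional[float]
    observed_min: Optional[int]
    observed_max: Optional[int]
    theoretical_min: int = GR_INDEX_MIN
    theoretical_max: int = GR_INDEX_MAX

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
            "by_group": {
                dim: {
                    level: {str(k): v for k, v in sorted(cnt.items())}
                    for level, cnt in sorted(levels.items())
                }
                for dim, levels in self.by_group.items()
            },
            "candidate_fraction": self.candidate_fraction,
            "observed_min": self.observed_min,
            "observed_max": self.observed_max,
            "theoretical_min": self.theoretical_min,
            "theoretical_max": self.theoretical_max,
        }


_STRATIFIERS = ("taxonomic_group", "lead_region", "translocation_status")


def _level_label(value) -> Optional[str]:
    if value is None:
        return None
    return value.value if hasattr(value, "value") else str(value)


def score_cohort(
    records: Sequence[SpeciesRecord],
    threshold: int = DEFAULT_CANDIDATE_THRESHOLD,
) -> tuple[list[GRResult], GRDistribution]:
    """Score every record and tabulate the index distribution.

    Returns one :class:`GRResult` per record plus a :class:`GRDistribution`
    stratified by taxonomic group, lead region and translocation status
    (records missing a stratifier are omitted from that stratification
    only, never from the overall counts).
    """
    results: list[GRResult] = []
    counts: Counter[int] = Counter()
    by_group: dict[str, dict[str, Counter]] = {d: {} for d in _STRATIFIERS}

    for record in records:
        gr = compute_gr_index(record.responses)
        result = GRResult(
            species_id=record.species_id,
            gr_index=gr,
            n_missing=count_missing(record.responses),
            candidate=classify_candidate(gr, threshold),
        )
        results.append(result)
        counts[gr] += 1
        for dim in _STRATIFIERS:
            label = _level_label(getattr(record, dim))
            if label is not None:
                by_group[dim].setdefault(label, Counter())[gr] += 1

    n = len(results)
    distribution = GRDistribution(
        n=n,
        counts=dict(counts),
        by_group={
            dim: {lvl: dict(c) for lvl, c in levels.items()}
            for dim, levels in by_group.items()
        },
        candidate_fraction=(
            sum(r.candidate for r in results) / n if n else None
        ),
        observed_min=min((r.gr_index for r in results), default=None),
        observed_max=max((r.gr_index for r in results), default=None),
    )
    return results, distribution
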