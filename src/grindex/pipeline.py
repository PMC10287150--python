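"""Full-cohort analysis: score, classify, and run the whole test battery.

Each test drops records that are missing its variable(s) (complete-case per
analysis) and reports its effective and dropped counts so the accounting
always satisfies effective + dropped = cohort size.  A grouping variable
with fewer than two non-empty levels marks the test skipped with a reason
instead of failing the pipeline.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .errors import DegenerateDataError, ValidationError
from .records import (
    DEFAULT_POPULATIONS_CATALOGUE,
    LifeHistory,
    SpeciesRecord,
    populations_ordinal,
    priority_category,
)
from .scoring import (
    DEFAULT_CANDIDATE_THRESHOLD,
    GRDistribution,
    score_cohort,
)
from . import stats

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "render_report"]

log = logging.getLogger("grindex")


@dataclass(frozen=True)
class AnalysisConfig:
    candidate_threshold: int = DEFAULT_CANDIDATE_THRESHOLD
    life_history_cutoff_years: float = 4.0
    posthoc_alpha: float = 0.05
    fisher_method: str = "auto"
    fisher_n_reps: int = 100_000
    seed: Optional[int] = None
    populations_catalogue: tuple[str, ...] = DEFAULT_POPULATIONS_CATALOGUE
    # signed two-group statistics are oriented by sorted label order unless
    # overridden here
    status_group_order: Optional[tuple[str, str]] = None


@dataclass
class TestEntry:
    """One named analysis: a result or an explicit skip, plus accounting."""

    name: str
    result: Optional[dict] = None
    pairwise: Optional[list[dict]] = None
    skipped: Optional[str] = None
    n_effective: int = 0
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "result": self.result,
            "pairwise": self.pairwise,
            "skipped": self.skipped,
            "n_effective": self.n_effective,
            "n_dropped": self.n_dropped,
        }


TEST_NAMES = (
    "evaluator_kw",
    "taxon_kw",
    "region_kw",
    "populations_kw",
    "populations_tau",
    "translocation_kw",
    "translocation_dunn",
    "status_mw",
    "lifehistory_mw",
    "taxon_translocation_fisher",
    "missing_tau",
    "priority_tau",
    "popsremaining_by_translocation_kw",
    "popsremaining_by_translocation_dunn",
)


@dataclass
class AnalysisReport:
    n_records: int
    gr_distribution: GRDistribution
    candidate_fraction: Optional[float]
    candidate_count: int
    observed_gr_min: Optional[int]
    observed_gr_max: Optional[int]
    tests: dict[str, TestEntry] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "gr_distribution": self.gr_distribution.to_dict(),
            "candidate_fraction": self.candidate_fraction,
            "candidate_count": self.candidate_count,
            "observed_gr_min": self.observed_gr_min,
            "observed_gr_max": self.observed_gr_max,
            "tests": {name: entry.to_dict() for name, entry in self.tests.items()},
        }


def _label(value) -> Optional[str]:
    if value is None:
        return None
    return value.value if hasattr(value, "value") else str(value)


def _grouped(
    pairs: Sequence[tuple[Optional[str], float]],
) -> tuple[list[str], list[list[float]], int]:
    """Split (level, value) pairs into per-level samples, dropping missing
    levels; returns (sorted labels, samples, n_dropped)."""
    groups: dict[str, list[float]] = {}
    dropped = 0
    for level, value in pairs:
        if level is None:
            dropped += 1
        else:
            groups.setdefault(level, []).append(value)
    labels = sorted(groups)
    return labels, [groups[g] for g in labels], dropped


def _run(entry_name: str, n_total: int, fn: Callable[[], TestEntry]) -> TestEntry:
    start = time.perf_counter()
    try:
        entry = fn()
    except (ValidationError, DegenerateDataError) as exc:
        entry = TestEntry(name=entry_name, skipped=str(exc), n_dropped=n_total)
    log.info(
        "%s: %s (n_eff=%d) [%.1f ms]",
        entry_name,
        "skipped: " + entry.skipped if entry.skipped else "ok",
        entry.n_effective,
        1e3 * (time.perf_counter() - start),
    )
    return entry


def _kw_entry(
    name: str,
    pairs: Sequence[tuple[Optional[str], float]],
    n_total: int,
) -> TestEntry:
    labels, samples, dropped = _grouped(pairs)
    if len(labels) < 2:
        return TestEntry(
            name=name,
            skipped="fewer than 2 non-empty levels",
            n_effective=sum(len(s) for s in samples),
            n_dropped=n_total - sum(len(s) for s in samples),
        )
    result = stats.kruskal_wallis(samples, labels)
    return TestEntry(
        name=name,
        result=result.to_dict(),
        n_effective=sum(len(s) for s in samples),
        n_dropped=dropped,
    )


def _dunn_entry(
    name: str,
    pairs: Sequence[tuple[Optional[str], float]],
    n_total: int,
    parent: TestEntry,
    alpha: float,
) -> TestEntry:
    if parent.skipped is not None:
        return TestEntry(
            name=name,
            skipped=f"parent test skipped ({parent.skipped})",
            n_dropped=n_total,
        )
    if parent.result["p_value"] >= alpha:
        return TestEntry(
            name=name,
            skipped=(
                f"parent Kruskal-Wallis not significant "
                f"(p={parent.result['p_value']:.4g} >= {alpha})"
            ),
            n_effective=parent.n_effective,
            n_dropped=parent.n_dropped,
        )
    labels, samples, dropped = _grouped(pairs)
    comparisons = stats.dunn_posthoc(samples, labels)
    return TestEntry(
        name=name,
        pairwise=[c.to_dict() for c in comparisons],
        n_effective=sum(len(s) for s in samples),
        n_dropped=dropped,
    )


def _tau_entry(
    name: str,
    pairs: Sequence[tuple[Optional[float], Optional[float]]],
    n_total: int,
) -> TestEntry:
    complete = [(a, b) for a, b in pairs if a is not None and b is not None]
    dropped = n_total - len(complete)
    if len(complete) < 2:
        return TestEntry(
            name=name,
            skipped="fewer than 2 complete pairs",
            n_effective=len(complete),
            n_dropped=dropped,
        )
    result = stats.kendall_tau_b(
        [a for a, _ in complete], [b for _, b in complete]
    )
    return TestEntry(
        name=name,
        result=result.to_dict(),
        n_effective=len(complete),
        n_dropped=dropped,
    )


def _mw_entry(
    name: str,
    pairs: Sequence[tuple[Optional[str], float]],
    n_total: int,
    group_order: Optional[tuple[str, str]] = None,
) -> TestEntry:
    labels, samples, dropped = _grouped(pairs)
    if len(labels) != 2:
        return TestEntry(
            name=name,
            skipped=f"need exactly 2 non-empty levels, got {len(labels)}",
            n_effective=sum(len(s) for s in samples),
            n_dropped=n_total - sum(len(s) for s in samples),
        )
    if group_order is not None:
        if sorted(group_order) != labels:
            return TestEntry(
                name=name,
                skipped=f"configured group order {group_order} does not match "
                f"observed levels {labels}",
                n_dropped=n_total,
            )
        ordered = list(group_order)
        samples = [samples[labels.index(g)] for g in ordered]
        labels = ordered
    result = stats.mann_whitney(
        samples[0], samples[1], group_labels=(labels[0], labels[1])
    )
    return TestEntry(
        name=name,
        result=result.to_dict(),
        n_effective=sum(len(s) for s in samples),
        n_dropped=dropped,
    )


def run_full_analysis(
    records: Sequence[SpeciesRecord],
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Score the cohort and run every named test, complete-case per test."""
    results, distribution = score_cohort(records, config.candidate_threshold)
    gr_by_id = {r.species_id: r for r in results}
    n = len(records)

    def gr(record: SpeciesRecord) -> float:
        return float(gr_by_id[record.species_id].gr_index)

    def pops_rank(record: SpeciesRecord) -> Optional[float]:
        if record.populations_remaining is None:
            return None
        return float(
            populations_ordinal(
                record.populations_remaining, config.populations_catalogue
            )
        )

    report = AnalysisReport(
        n_records=n,
        gr_distribution=distribution,
        candidate_fraction=distribution.candidate_fraction,
        candidate_count=sum(r.candidate for r in results),
        observed_gr_min=distribution.observed_min,
        observed_gr_max=distribution.observed_max,
    )
    tests = report.tests

    tests["evaluator_kw"] = _run("evaluator_kw", n, lambda: _kw_entry(
        "evaluator_kw", [(r.evaluator_id, gr(r)) for r in records], n
    ))
    tests["taxon_kw"] = _run("taxon_kw", n, lambda: _kw_entry(
        "taxon_kw", [(_label(r.taxonomic_group), gr(r)) for r in records], n
    ))
    tests["region_kw"] = _run("region_kw", n, lambda: _kw_entry(
        "region_kw", [(_label(r.lead_region), gr(r)) for r in records], n
    ))
    tests["populations_kw"] = _run("populations_kw", n, lambda: _kw_entry(
        "populations_kw",
        [(r.populations_remaining, gr(r)) for r in records], n,
    ))
    tests["populations_tau"] = _run("populations_tau", n, lambda: _tau_entry(
        "populations_tau", [(gr(r), pops_rank(r)) for r in records], n
    ))

    transloc_gr = [(_label(r.translocation_status), gr(r)) for r in records]
    tests["translocation_kw"] = _run("translocation_kw", n, lambda: _kw_entry(
        "translocation_kw", transloc_gr, n
    ))
    tests["translocation_dunn"] = _run("translocation_dunn", n, lambda: _dunn_entry(
        "translocation_dunn", transloc_gr, n,
        tests["translocation_kw"], config.posthoc_alpha,
    ))

    tests["status_mw"] = _run("status_mw", n, lambda: _mw_entry(
        "status_mw",
        [(_label(r.listing_status), gr(r)) for r in records], n,
        config.status_group_order,
    ))
    def lh(record: SpeciesRecord) -> Optional[str]:
        age = record.age_at_maturity_years
        if age is None:
            return None
        if age < config.life_history_cutoff_years:
            return LifeHistory.FAST.value
        return LifeHistory.SLOW.value

    tests["lifehistory_mw"] = _run("lifehistory_mw", n, lambda: _mw_entry(
        "lifehistory_mw", [(lh(r), gr(r)) for r in records], n,
    ))

    def fisher_entry() -> TestEntry:
        levels_t = sorted(
            {_label(r.translocation_status) for r in records} - {None}
        )
        levels_g = sorted(
            {_label(r.taxonomic_group) for r in records} - {None}
        )
        complete = [
            r for r in records
            if r.translocation_status is not None
            and r.taxonomic_group is not None
        ]
        if len(levels_t) < 2 or len(levels_g) < 2:
            return TestEntry(
                name="taxon_translocation_fisher",
                skipped="fewer than 2 non-empty levels in a margin",
                n_effective=len(complete),
                n_dropped=n - len(complete),
            )
        table = [
            [
                sum(
                    1 for r in complete
                    if _label(r.translocation_status) == t
                    and _label(r.taxonomic_group) == g
                )
                for g in levels_g
            ]
            for t in levels_t
        ]
        result = stats.fisher_exact_rxc(
            table,
            method=config.fisher_method,
            n_reps=config.fisher_n_reps,
            seed=config.seed,
        )
        result.group_labels = tuple(levels_t)
        result.extra["row_levels"] = levels_t
        result.extra["col_levels"] = levels_g
        result.extra["table"] = table
        return TestEntry(
            name="taxon_translocation_fisher",
            result=result.to_dict(),
            n_effective=len(complete),
            n_dropped=n - len(complete),
        )

    tests["taxon_translocation_fisher"] = _run(
        "taxon_translocation_fisher", n, fisher_entry
    )

    tests["missing_tau"] = _run("missing_tau", n, lambda: _tau_entry(
        "missing_tau",
        [
            (gr(r), float(gr_by_id[r.species_id].n_missing))
            for r in records
        ],
        n,
    ))
    tests["priority_tau"] = _run("priority_tau", n, lambda: _tau_entry(
        "priority_tau",
        [
            (
                gr(r),
                None if r.recovery_priority_number is None
                else float(priority_category(r.recovery_priority_number).rank),
            )
            for r in records
        ],
        n,
    ))

    transloc_pops = [
        (_label(r.translocation_status), pops_rank(r))
        for r in records
    ]
    transloc_pops_complete = [
        (t, v) for t, v in transloc_pops if v is not None
    ]
    tests["popsremaining_by_translocation_kw"] = _run(
        "popsremaining_by_translocation_kw", n, lambda: _kw_entry(
            "popsremaining_by_translocation_kw", transloc_pops_complete, n
        )
    )
    # the kw helper counts only missing *group* labels as dropped; fold in
    # records dropped for a missing populations category as well
    kw_entry = tests["popsremaining_by_translocation_kw"]
    kw_entry.n_dropped = n - kw_entry.n_effective
    tests["popsremaining_by_translocation_dunn"] = _run(
        "popsremaining_by_translocation_dunn", n, lambda: _dunn_entry(
            "popsremaining_by_translocation_dunn", transloc_pops_complete, n,
            kw_entry, config.posthoc_alpha,
        )
    )
    dunn_entry2 = tests["popsremaining_by_translocation_dunn"]
    if dunn_entry2.skipped is None:
        dunn_entry2.n_dropped = n - dunn_entry2.n_effective

    for name in TEST_NAMES:
        assert name in tests, f"missing test entry {name}"
    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_report(
    report: AnalysisReport,
    fmt: str,
    out: Path,
) -> list[Path]:
    """Write the report as ``json`` (single loss-less file), ``csv-bundle``
    (distribution tables + test summary), or ``markdown``."""
    out = Path(out)
    if fmt == "json":
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return [out]

    if fmt == "csv-bundle":
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        dist = report.gr_distribution
        for dim, stem in (
            ("taxonomic_group", "gr_by_taxon"),
            ("lead_region", "gr_by_region"),
            ("translocation_status", "gr_by_translocation"),
        ):
            path = out / f"{stem}.csv"
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow([dim, "gr_index", "count"])
                for level, counts in sorted(dist.by_group[dim].items()):
                    for value, count in sorted(counts.items()):
                        writer.writerow([level, value, count])
            written.append(path)
        path = out / "tests.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["test", "statistic_name", "statistic", "df", "p_value",
                 "method", "n_effective", "n_dropped", "skipped"]
            )
            for name, entry in report.tests.items():
                r = entry.result or {}
                writer.writerow([
                    name,
                    r.get("statistic_name", ""),
                    r.get("statistic", ""),
                    r.get("df", ""),
                    r.get("p_value", ""),
                    r.get("method", ""),
                    entry.n_effective,
                    entry.n_dropped,
                    entry.skipped or "",
                ])
        written.append(path)
        return written

    if fmt == "markdown":
        out.parent.mkdir(parents=True, exist_ok=True)
        lines = [
            "# Cohort analysis report",
            "",
            f"- records: {report.n_records}",
            f"- candidate fraction: {report.candidate_fraction}",
            f"- candidate count: {report.candidate_count}",
            f"- observed index range: "
            f"{report.observed_gr_min}..{report.observed_gr_max} "
            f"(theoretical {report.gr_distribution.theoretical_min}.."
            f"{report.gr_distribution.theoretical_max})",
            "",
        ]
        for name, entry in report.tests.items():
            lines.append(f"## {name}")
            lines.append("")
            if entry.skipped:
                lines.append(f"Skipped: {entry.skipped}")
            elif entry.result is not None:
                r = entry.result
                lines.append(
                    f"{r['statistic_name']} = {r['statistic']:.6g}, "
                    f"p = {r['p_value']:.4g} ({r['method']})"
                )
            if entry.pairwise:
                for c in entry.pairwise:
                    lines.append(
                        f"- {c['group_a']} vs {c['group_b']}: "
                        f"z = {c['z']:.4g}, adjusted p = {c['p_adjusted']:.4g}"
                    )
            lines.append(
                f"(effective n = {entry.n_effective}, "
                f"dropped = {entry.n_dropped})"
            )
            lines.append("")
        out.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return [out]

    raise ValidationError(f"unknown report format {fmt!r}")
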