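"""Cohort construction: joining FAERS tables into reports, matching target
drugs, tagging SMQ events and producing descriptive summaries.

A *case* here is a deduplicated report in which a dictionary drug appears with
the primary-suspect (PS) role and at least one reaction PT falls inside the
SMQ of interest.  Reports with a PS dictionary drug but no SMQ PT still count
toward the drug's report total — they are the non-case part of the drug's
denominator in descriptive tables and contingency margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_faers import (
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PtSocMap,
    ReacRecord,
    SmqDefinition,
    TherRecord,
)

logger = logging.getLogger(__name__)

# FAERS occupation codes as printed in descriptive tables
REPORTER_LABELS = {
    "CN": "Consumer",
    "HP": "Health Professional",
    "LW": "Lawyer",
    "MD": "Medical doctor",
    "OT": "Other",
    "PH": "Pharmacists",
}

COUNTRY_LABELS = {
    "US": "United States",
    "GB": "United Kingdom",
    "CA": "Canada",
    "AU": "Australia",
    "JP": "Japan",
}

AGE_STRATA = ("<18", "18-64.9", "65-85", ">85", "Missing")


def age_stratum(age_years: float | None) -> str:
    """Stratum edges [0,18), [18,65), [65,85], (85,inf); boundary 85 → 65-85."""
    if age_years is None or not np.isfinite(age_years):
        return "Missing"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64.9"
    if age_years <= 85:
        return "65-85"
    return ">85"


@dataclass
class SafetyReport:
    """One deduplicated spontaneous report: DEMO joined with its child rows."""

    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    therapies: list[TherRecord] = field(default_factory=list)
    outcomes: list[OutcRecord] = field(default_factory=list)

    @property
    def primaryid(self) -> str:
        return self.demo.primaryid

    @property
    def pts(self) -> set[str]:
        return {r.pt for r in self.reactions}

    @property
    def outcome_codes(self) -> set[str]:
        return {o.outcome_code for o in self.outcomes}


@dataclass(frozen=True)
class CaseFlag:
    """One (report, matched dictionary drug) pair with its SMQ hits."""

    primaryid: str
    drug: str
    matched_pts: frozenset[str]

    @property
    def is_case(self) -> bool:
        return bool(self.matched_pts)


@dataclass
class Tables:
    demo: Sequence[DemoRecord]
    drug: Sequence[DrugRecord]
    reac: Sequence[ReacRecord]
    ther: Sequence[TherRecord] = ()
    outc: Sequence[OutcRecord] = ()


def assemble_reports(tables: Tables, kept: set[str]) -> tuple[list[SafetyReport], list[tuple[str, str]]]:
    """Join child tables onto kept DEMO records.

    Returns the reports plus a log of orphan child rows — rows whose
    primaryid has no kept DEMO record (deduplicated-away versions or data
    errors); orphans are excluded, never silently merged.
    """
    reports: dict[str, SafetyReport] = {}
    orphans: list[tuple[str, str]] = []
    for demo in tables.demo:
        if demo.primaryid in kept:
            reports[demo.primaryid] = SafetyReport(demo=demo)
    for kind, rows, attach in (
        ("DRUG", tables.drug, lambda r, x: r.drugs.append(x)),
        ("REAC", tables.reac, lambda r, x: r.reactions.append(x)),
        ("THER", tables.ther, lambda r, x: r.therapies.append(x)),
        ("OUTC", tables.outc, lambda r, x: r.outcomes.append(x)),
    ):
        for row in rows:
            rep = reports.get(row.primaryid)
            if rep is None:
                orphans.append((kind, row.primaryid))
            else:
                attach(rep, row)
    if orphans:
        logger.info("%d orphan child rows excluded during assembly", len(orphans))
    return list(reports.values()), orphans


def match_drug(drugname: str, drug_dict: Mapping[str, str]) -> str | None:
    """Normalized substring match: 'ALENDRONATE SODIUM' matches 'ALENDRONATE'."""
    for pattern, label in drug_dict.items():
        if pattern in drugname:
            return label
    return None


def flag_cases(
    reports: Iterable[SafetyReport],
    drug_dict: Mapping[str, str],
    smq: SmqDefinition,
) -> list[CaseFlag]:
    """One CaseFlag per (report, matched dictionary drug with PS role).

    A report naming two target drugs as PS contributes to both cohorts (and is
    logged); drugs in non-PS roles never match.
    """
    if not drug_dict:
        raise ValueError("drug dictionary is empty")
    flags: list[CaseFlag] = []
    multi = 0
    for report in reports:
        matched: dict[str, None] = {}
        for drug in report.drugs:
            if drug.role_code != "PS":
                continue
            label = match_drug(drug.drugname, drug_dict)
            if label is not None:
                matched[label] = None
        if len(matched) > 1:
            multi += 1
        if matched:
            hits = frozenset(report.pts & smq.pts)
            for label in matched:
                flags.append(CaseFlag(primaryid=report.primaryid, drug=label, matched_pts=hits))
    if multi:
        logger.info("%d reports matched more than one dictionary drug as PS", multi)
    return flags


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def describe_cohort(
    case_reports: Mapping[str, list[SafetyReport]],
) -> dict:
    """Per-drug and total characteristics table.

    ``case_reports`` maps drug label → its case reports.  Percentages are over
    the drug's case total with missing categories included in the denominator;
    the age mean ± sample SD uses non-missing ages only.
    """
    drugs = list(case_reports)
    columns = drugs + ["Total"]
    pooled: list[SafetyReport] = [r for reps in case_reports.values() for r in reps]
    groups = {**{d: case_reports[d] for d in drugs}, "Total": pooled}

    out: dict = {"n": {}, "sex": {}, "age": {}, "age_mean_sd": {}, "reporter": {}, "country": {}}
    for col in columns:
        reps = groups[col]
        n = len(reps)
        out["n"][col] = n

        sex_counts = {"Female": 0, "Male": 0, "Missing": 0}
        for r in reps:
            key = {"F": "Female", "M": "Male"}.get(r.demo.sex or "", "Missing")
            sex_counts[key] += 1
        out["sex"][col] = {k: (v, _pct(v, n)) for k, v in sex_counts.items()}

        age_counts = {s: 0 for s in AGE_STRATA}
        ages = []
        for r in reps:
            age_counts[age_stratum(r.demo.age_years)] += 1
            if r.demo.age_years is not None:
                ages.append(r.demo.age_years)
        out["age"][col] = {k: (v, _pct(v, n)) for k, v in age_counts.items()}
        if ages:
            arr = np.asarray(ages, dtype=float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            out["age_mean_sd"][col] = (round(float(arr.mean()), 1), round(sd, 1))
        else:
            out["age_mean_sd"][col] = (float("nan"), float("nan"))

        rep_counts = {label: 0 for label in REPORTER_LABELS.values()}
        rep_counts["Missing"] = 0
        for r in reps:
            code = (r.demo.reporter_code or "").upper()
            if not code:
                rep_counts["Missing"] += 1
            else:
                rep_counts[REPORTER_LABELS.get(code, "Other")] += 1
        out["reporter"][col] = {k: (v, _pct(v, n)) for k, v in rep_counts.items()}

        ctry_counts = {label: 0 for label in COUNTRY_LABELS.values()}
        ctry_counts["Other"] = 0
        for r in reps:
            code = (r.demo.country or "").upper()
            ctry_counts[COUNTRY_LABELS.get(code, "Other")] += 1
        out["country"][col] = {k: (v, _pct(v, n)) for k, v in ctry_counts.items()}
    return out


def descriptive_rows(table: dict) -> list[dict]:
    """Flatten describe_cohort output to rows for CSV export."""
    rows = []
    columns = list(table["n"])
    rows.append({"block": "N", "category": "N", **{c: table["n"][c] for c in columns}})
    for block in ("sex", "age", "reporter", "country"):
        for category in next(iter(table[block].values())):
            rows.append(
                {
                    "block": block,
                    "category": category,
                    **{c: f"{table[block][c][category][0]} ({table[block][c][category][1]}%)" for c in columns},
                }
            )
    rows.append(
        {
            "block": "age",
            "category": "Mean +/- SD",
            **{c: f"{table['age_mean_sd'][c][0]} +/- {table['age_mean_sd'][c][1]}" for c in columns},
        }
    )
    return rows


def yearly_counts(case_reports: Iterable[SafetyReport], year_field: str = "fda_dt") -> dict[int, int]:
    """Histogram of reports by calendar year of the chosen date field.

    Reports whose date is missing are excluded (any precision supplies a year).
    """
    counts: dict[int, int] = {}
    for report in case_reports:
        date = getattr(report.demo, year_field)
        if date is None:
            continue
        counts[date.year] = counts.get(date.year, 0) + 1
    return dict(sorted(counts.items()))
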