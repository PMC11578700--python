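"""Hospitalization and mortality outcome rates per drug, with pairwise
Pearson chi-square contrasts.

A case contributes once to each outcome kind it reports (a report with both
HO and DE rows counts in both numerators); the denominator is the drug's case
count.  Pairwise contrasts are 2x2 Pearson chi-square tests without Yates
correction by default, with an optional Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import SafetyReport

HOSPITALIZATION = "HO"
DEATH = "DE"


@dataclass
class DrugOutcome:
    drug: str
    n_cases: int
    n_hospitalized: int
    n_died: int

    @property
    def hosp_rate(self) -> float:
        return self.n_hospitalized / self.n_cases if self.n_cases else float("nan")

    @property
    def death_rate(self) -> float:
        return self.n_died / self.n_cases if self.n_cases else float("nan")


@dataclass
class PairwiseTest:
    outcome: str
    drug1: str
    drug2: str
    chi2: float
    df: int
    p: float
    p_adjusted: float
    significant: bool
    unreliable: bool  # an expected cell < 1


@dataclass
class OutcomeSummary:
    per_drug: dict[str, DrugOutcome] = field(default_factory=dict)
    tests: list[PairwiseTest] = field(default_factory=list)


def outcome_rates(case_reports: Mapping[str, Sequence[SafetyReport]]) -> OutcomeSummary:
    summary = OutcomeSummary()
    for drug, reports in case_reports.items():
        codes = [r.outcome_codes for r in reports]
        summary.per_drug[drug] = DrugOutcome(
            drug=drug,
            n_cases=len(reports),
            n_hospitalized=sum(HOSPITALIZATION in c for c in codes),
            n_died=sum(DEATH in c for c in codes),
        )
    return summary


def _chi2_2x2(k1: int, n1: int, k2: int, n2: int, yates: bool) -> tuple[float, float, bool]:
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    unreliable = bool((expected < 1).any())
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return (0.0, 1.0, True)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return (float(chi2), float(p), unreliable)


def pairwise_chi2(
    summary: OutcomeSummary,
    correction: str = "none",
    alpha: float = 0.05,
    yates: bool = False,
) -> list[PairwiseTest]:
    """All drug-pair contrasts for both outcomes; df = 1 per test.

    ``correction`` is "none" (raw p-values, the default) or "bonferroni".
    Tests with an expected cell below 1 are flagged unreliable, not dropped.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    drugs = list(summary.per_drug)
    pairs = [(d1, d2) for i, d1 in enumerate(drugs) for d2 in drugs[i + 1 :]]
    n_tests = 2 * len(pairs)
    tests: list[PairwiseTest] = []
    for outcome, attr in ((HOSPITALIZATION, "n_hospitalized"), (DEATH, "n_died")):
        for d1, d2 in pairs:
            o1, o2 = summary.per_drug[d1], summary.per_drug[d2]
            if o1.n_cases == 0 or o2.n_cases == 0:
                raise ValueError(f"drug {d1 if o1.n_cases == 0 else d2!r} has no cases")
            chi2, p, unreliable = _chi2_2x2(getattr(o1, attr), o1.n_cases, getattr(o2, attr), o2.n_cases, yates)
            p_adj = min(1.0, p * n_tests) if correction == "bonferroni" else p
            tests.append(
                PairwiseTest(
                    outcome=outcome, drug1=d1, drug2=d2,
                    chi2=chi2, df=1, p=p, p_adjusted=p_adj,
                    significant=bool(p_adj < alpha), unreliable=unreliable,
                )
            )
    summary.tests = tests
    return tests


def summary_rows(summary: OutcomeSummary) -> list[dict]:
    return [
        {
            "drug": o.drug,
            "n_cases": o.n_cases,
            "n_hospitalized": o.n_hospitalized,
            "hosp_rate_pct": round(100 * o.hosp_rate, 1),
            "n_died": o.n_died,
            "death_rate_pct": round(100 * o.death_rate, 1),
        }
        for o in summary.per_drug.values()
    ]
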