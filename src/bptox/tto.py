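"""Time-to-onset analysis: onset intervals, Kaplan-Meier curves, log-rank.

The time-to-onset (TTO) of an adverse event in a spontaneous report is the
number of days from the start of therapy with the suspect drug (earliest
THER start date of the matched drug's rows; any THER row of the report when
sequence linkage is absent) to the event onset date.  Only reports where both
dates carry day precision and the interval is nonnegative are usable; every
exclusion is logged with its reason.

Because every FAERS report contains the event, all TTO records are treated as
events — there is no censoring — so the Kaplan-Meier survival curve is the
empirical survivor function and the cumulative incidence its complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort import CaseFlag, SafetyReport

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTORecord:
    primaryid: str
    drug: str
    tto_days: int


@dataclass
class KMCurve:
    times: np.ndarray        # ordered distinct event times
    survival: np.ndarray     # S(t) at those times
    median: float
    n: int

    @property
    def cumulative_incidence(self) -> np.ndarray:
        return 1.0 - self.survival


def extract_tto(
    case_reports: Mapping[str, Sequence[SafetyReport]],
    flags: Iterable[CaseFlag] | None = None,
) -> tuple[list[TTORecord], list[tuple[str, str, str]]]:
    """Per-drug onset intervals plus an exclusion log of (drug, pid, reason).

    The therapy start is the earliest day-precision start date among THER rows
    whose drug_seq points at a PS row matching the drug (all THER rows when no
    sequence matches).  Same-day onset (0 days) is retained.
    """
    records: list[TTORecord] = []
    excluded: list[tuple[str, str, str]] = []
    for drug, reports in case_reports.items():
        kept = 0
        for rep in reports:
            event = rep.demo.event_dt
            if event is None or event.precision != "day":
                excluded.append((drug, rep.primaryid, "partial date" if event else "missing event date"))
                continue
            # therapy rows for the matched drug's sequences, else any therapy row
            ps_seqs = {d.drug_seq for d in rep.drugs if d.role_code == "PS"}
            ther = [t for t in rep.therapies if t.drug_seq in ps_seqs] or list(rep.therapies)
            starts = [t.start_dt for t in ther if t.start_dt is not None and t.start_dt.precision == "day"]
            if not starts:
                has_partial = any(t.start_dt is not None for t in ther)
                excluded.append((drug, rep.primaryid, "partial date" if has_partial else "missing start date"))
                continue
            start = min(starts, key=lambda d: d.raw)
            days = event.to_ordinal() - start.to_ordinal()
            if days < 0:
                excluded.append((drug, rep.primaryid, "negative interval"))
                continue
            records.append(TTORecord(primaryid=rep.primaryid, drug=drug, tto_days=days))
            kept += 1
        logger.info("TTO %s: %d usable of %d case reports", drug, kept, len(reports))
    return records, excluded


def km_curve(ttos: Sequence[int] | Sequence[TTORecord]) -> KMCurve:
    """Product-limit curve over uncensored onset times.

    With no censoring the survival step function equals the empirical
    distribution; the median is the smallest time at which cumulative
    incidence reaches 0.5.
    """
    days = np.asarray([t.tto_days if isinstance(t, TTORecord) else t for t in ttos], dtype=float)
    if days.size == 0:
        raise ValueError("no usable time-to-onset records")
    kmf = KaplanMeierFitter()
    kmf.fit(days, event_observed=np.ones_like(days))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 anchor row unless events occur there
    if 0.0 in days:
        keep = np.ones_like(times, dtype=bool)
    return KMCurve(times=times[keep], survival=surv[keep], median=float(kmf.median_survival_time_), n=int(days.size))


def logrank(groups: Mapping[str, Sequence[int] | Sequence[TTORecord]]) -> tuple[float, int, float]:
    """k-sample log-rank test across drugs; returns (statistic, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations, labels = [], []
    for name, ttos in groups.items():
        days = [t.tto_days if isinstance(t, TTORecord) else t for t in ttos]
        if not days:
            raise ValueError(f"group {name!r} is empty")
        durations.extend(days)
        labels.extend([name] * len(days))
    result = multivariate_logrank_test(
        pd.Series(durations, dtype=float),
        pd.Series(labels),
        event_observed=pd.Series(np.ones(len(durations))),
    )
    return (float(result.test_statistic), len(groups) - 1, float(result.p_value))


def km_rows(curve: KMCurve, drug: str) -> list[dict]:
    """Flatten a KM curve for CSV export (time, survival, cumulative incidence)."""
    return [
        {
            "drug": drug,
            "time_days": float(t),
            "survival": float(s),
            "cumulative_incidence": float(1.0 - s),
        }
        for t, s in zip(curve.times, curve.survival)
    ]
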