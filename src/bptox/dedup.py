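"""FDA deduplication rule for FAERS spontaneous reports.

FAERS contains multiple versions of the same case (follow-up reports share a
CASEID).  The FDA-recommended rule keeps, within each CASEID, the version with
the highest FDA receipt date (FDA_DT); among versions tied on FDA_DT, the one
with the highest PRIMARYID.

Missing FDA_DT sorts lowest, so a dated version always beats an undated one.
Comparison uses the zero-padded YYYYMMDD string so partial dates (``201705``)
compare consistently with full ones.  PRIMARYID ties are broken numerically
when the ids are numeric, lexicographically otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .io_faers import DemoRecord

logger = logging.getLogger(__name__)


@dataclass
class DedupResult:
    kept: set[str]
    # (dropped primaryid, reason, primaryid of the surviving version)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)
    missing_caseid: list[str] = field(default_factory=list)


def _pid_key(pid: str):
    return (0, int(pid)) if pid.isdigit() else (1, pid)


def _sort_key(rec: DemoRecord):
    fda = rec.fda_dt.sort_key if rec.fda_dt is not None else ""
    return (fda, _pid_key(rec.primaryid))


def deduplicate(demo: Sequence[DemoRecord]) -> DedupResult:
    """Keep one report version per CASEID by max (FDA_DT, PRIMARYID).

    Deterministic regardless of input order.  Records without a caseid are
    kept as singletons and logged.
    """
    by_case: dict[str, list[DemoRecord]] = {}
    result = DedupResult(kept=set())
    for rec in demo:
        if not rec.caseid:
            result.kept.add(rec.primaryid)
            result.missing_caseid.append(rec.primaryid)
            continue
        by_case.setdefault(rec.caseid, []).append(rec)
    if result.missing_caseid:
        logger.info("%d records without caseid kept as singletons", len(result.missing_caseid))
    for caseid, versions in by_case.items():
        winner = max(versions, key=_sort_key)
        result.kept.add(winner.primaryid)
        for rec in versions:
            if rec.primaryid != winner.primaryid:
                reason = (
                    "older fda_dt"
                    if (rec.fda_dt.sort_key if rec.fda_dt else "") != (winner.fda_dt.sort_key if winner.fda_dt else "")
                    else "lower primaryid"
                )
                result.dropped.append((rec.primaryid, reason, winner.primaryid))
    return result
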