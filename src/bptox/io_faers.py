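"""Readers and writers for FAERS-quarterly-style ASCII tables.

FAERS distributes its spontaneous-report database as quarterly ``$``-delimited
text tables.  This module reads the five tables the pipeline uses — DEMO
(demographics and administrative fields), DRUG (reported products and their
role codes), REAC (MedDRA preferred terms), THER (therapy dates) and OUTC
(outcome codes) — into typed records, plus the two small dictionary files the
analysis needs: an SMQ definition (a named set of preferred terms describing a
medical condition of interest) and a PT→SOC map (preferred term to system
organ class).

Dates in FAERS are YYYYMMDD strings that are frequently partial (``2017``,
``201705``) or absent.  They are parsed into :class:`PartialDate` values that
keep an explicit precision level; nothing is silently coerced, and downstream
stages decide what precision they require.

Free-text fields (drug names, preferred terms) are upper-cased and
whitespace-collapsed on ingestion so that matching is insensitive to the
case/spacing noise typical of spontaneous reports.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

DELIMITER = "$"

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "HO", "LT", "DS", "CA", "RI", "OT"})
AGE_UNITS_TO_YEARS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "DEC": 10.0,
}

_WS = re.compile(r"\s+")


def normalize_term(text: str) -> str:
    """Upper-case and collapse internal whitespace; '' stays ''."""
    return _WS.sub(" ", text.strip()).upper()


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class PartialDate:
    """A possibly-partial FAERS date.

    ``precision`` is one of ``"day"``, ``"month"``, ``"year"``.  ``raw`` is the
    zero-padded digit string actually present (8, 6 or 4 digits), which also
    serves as the sort key: lexicographic order on the padded string is
    chronological order, with a shorter (less precise) date comparing as the
    earliest moment it could denote.
    """

    raw: str
    precision: str = field(compare=False)

    @property
    def year(self) -> int:
        return int(self.raw[:4])

    @property
    def sort_key(self) -> str:
        # pad to 8 with '00' so "201705" < "20170501" <= any day in that month
        return self.raw.ljust(8, "0")

    def to_ordinal(self) -> int:
        """Day number (proleptic Gregorian); day precision only."""
        if self.precision != "day":
            raise ValueError(f"date {self.raw!r} has {self.precision} precision")
        import datetime

        return datetime.date(int(self.raw[:4]), int(self.raw[4:6]), int(self.raw[6:8])).toordinal()


def parse_date(value: str | None) -> PartialDate | None:
    """Parse a FAERS YYYYMMDD field; returns None when missing or unparseable.

    4 digits → year precision, 6 → month, 8 → day.  Calendar-invalid strings
    (month 13, day 32 …) are treated as missing rather than guessed at.
    """
    if value is None:
        return None
    digits = value.strip()
    if not digits or not digits.isdigit():
        return None
    if len(digits) == 4:
        return PartialDate(digits, "year")
    if len(digits) == 6:
        month = int(digits[4:6])
        if not 1 <= month <= 12:
            return None
        return PartialDate(digits, "month")
    if len(digits) == 8:
        import datetime

        try:
            datetime.date(int(digits[:4]), int(digits[4:6]), int(digits[6:8]))
        except ValueError:
            return None
        return PartialDate(digits, "day")
    return None


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: PartialDate | None
    event_dt: PartialDate | None
    sex: str | None            # "F" / "M" / None
    age_years: float | None    # normalised to years at read time
    reporter_code: str | None  # raw occupation code, e.g. "CN", "MD"
    country: str | None


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drug_seq: str
    drugname: str
    role_code: str
    route: str | None = None


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    drug_seq: str
    start_dt: PartialDate | None


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    outcome_code: str


@dataclass
class ReadResult:
    """Records plus an audit trail: every input line is accounted for."""

    records: list
    rejects: list[tuple[int, str]]  # (1-based data line number, reason)

    @property
    def n_lines(self) -> int:
        return len(self.records) + len(self.rejects)


@dataclass(frozen=True)
class SmqDefinition:
    """A Standardized MedDRA Query: a named, deduplicated set of PTs."""

    smq_name: str
    pts: frozenset[str]


@dataclass(frozen=True)
class PtSocMap:
    """Preferred term → system organ class lookup."""

    mapping: Mapping[str, str]

    def soc_of(self, pt: str) -> str | None:
        return self.mapping.get(pt)


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

# column aliases accepted per table kind (case-insensitive, real FAERS headers)
_COLUMNS = {
    "DEMO": {
        "primaryid": ("primaryid", "isr"),
        "caseid": ("caseid", "case"),
        "fda_dt": ("fda_dt", "fdadt"),
        "event_dt": ("event_dt",),
        "sex": ("sex", "gndr_cod"),
        "age": ("age",),
        "age_cod": ("age_cod",),
        "occp_cod": ("occp_cod",),
        "country": ("occr_country", "reporter_country", "country"),
    },
    "DRUG": {
        "primaryid": ("primaryid", "isr"),
        "drug_seq": ("drug_seq",),
        "drugname": ("drugname",),
        "role_cod": ("role_cod", "role_code"),
        "route": ("route",),
    },
    "REAC": {"primaryid": ("primaryid", "isr"), "pt": ("pt",)},
    "THER": {
        "primaryid": ("primaryid", "isr"),
        "drug_seq": ("dsg_drug_seq", "drug_seq"),
        "start_dt": ("start_dt",),
    },
    "OUTC": {"primaryid": ("primaryid", "isr"), "outc_cod": ("outc_cod", "outc_code")},
}

_MANDATORY = {
    "DEMO": ("primaryid", "caseid"),
    "DRUG": ("primaryid", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
    "THER": ("primaryid", "drug_seq"),
    "OUTC": ("primaryid", "outc_cod"),
}


def _resolve_header(header: Sequence[str], table_kind: str) -> dict[str, int]:
    lower = [h.strip().lower() for h in header]
    index: dict[str, int] = {}
    for canonical, aliases in _COLUMNS[table_kind].items():
        for alias in aliases:
            if alias in lower:
                index[canonical] = lower.index(alias)
                break
    missing = [c for c in _MANDATORY[table_kind] if c not in index]
    if missing:
        raise ValueError(f"{table_kind} header missing mandatory column(s): {missing}")
    return index


def _get(fields: Sequence[str], index: dict[str, int], name: str) -> str | None:
    i = index.get(name)
    if i is None or i >= len(fields):
        return None
    value = fields[i].strip()
    return value or None


def read_faers_table(path: str | Path, table_kind: str) -> ReadResult:
    """Read one ``$``-delimited FAERS table into typed records.

    Every data line becomes either a record or a reject with a reason;
    ``len(records) + len(rejects)`` always equals the number of data lines.
    An unknown ``table_kind`` or a missing mandatory column is a hard error.
    """
    table_kind = table_kind.upper()
    if table_kind not in _COLUMNS:
        raise ValueError(f"unknown table_kind {table_kind!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, no header")
        index = _resolve_header(header_line.rstrip("\r\n").split(DELIMITER), table_kind)
        records: list = []
        rejects: list[tuple[int, str]] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(DELIMITER)
            rec, reason = _parse_row(fields, index, table_kind)
            if rec is not None:
                records.append(rec)
            else:
                rejects.append((lineno, reason))
                logger.debug("%s line %d rejected: %s", path.name, lineno, reason)
    return ReadResult(records=records, rejects=rejects)


def _parse_row(fields, index, table_kind):
    pid = _get(fields, index, "primaryid")
    if pid is None:
        return None, "missing primaryid"
    if table_kind == "DEMO":
        caseid = _get(fields, index, "caseid")
        if caseid is None:
            return None, "missing caseid"
        age_years = None
        age_raw = _get(fields, index, "age")
        if age_raw is not None:
            unit = (_get(fields, index, "age_cod") or "YR").upper()
            factor = AGE_UNITS_TO_YEARS.get(unit)
            try:
                value = float(age_raw)
            except ValueError:
                value = None
            if value is not None and factor is not None:
                age_years = value * factor
        sex = _get(fields, index, "sex")
        if sex is not None:
            sex = sex.upper()
            if sex not in ("F", "M"):
                sex = None
        return (
            DemoRecord(
                primaryid=pid,
                caseid=caseid,
                fda_dt=parse_date(_get(fields, index, "fda_dt")),
                event_dt=parse_date(_get(fields, index, "event_dt")),
                sex=sex,
                age_years=age_years,
                reporter_code=_get(fields, index, "occp_cod"),
                country=_get(fields, index, "country"),
            ),
            None,
        )
    if table_kind == "DRUG":
        role = (_get(fields, index, "role_cod") or "").upper()
        if role not in ROLE_CODES:
            return None, "invalid role_code"
        name = _get(fields, index, "drugname")
        if name is None:
            return None, "missing drugname"
        return (
            DrugRecord(
                primaryid=pid,
                drug_seq=_get(fields, index, "drug_seq") or "1",
                drugname=normalize_term(name),
                role_code=role,
                route=_get(fields, index, "route"),
            ),
            None,
        )
    if table_kind == "REAC":
        pt = _get(fields, index, "pt")
        if pt is None:
            return None, "missing pt"
        return ReacRecord(primaryid=pid, pt=normalize_term(pt)), None
    if table_kind == "THER":
        seq = _get(fields, index, "drug_seq")
        if seq is None:
            return None, "missing drug_seq"
        return TherRecord(primaryid=pid, drug_seq=seq, start_dt=parse_date(_get(fields, index, "start_dt"))), None
    # OUTC
    code = (_get(fields, index, "outc_cod") or "").upper()
    if code not in OUTCOME_CODES:
        return None, "invalid outcome_code"
    return OutcRecord(primaryid=pid, outcome_code=code), None


# ---------------------------------------------------------------------------
# Dictionary files
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "$" if "$" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=delim)
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise ValueError(f"{path}: empty file")
    return rows[0], rows[1:]


def read_smq(path: str | Path) -> SmqDefinition:
    """Read an SMQ definition file (columns: smq_name, pt).

    Terms are case-normalised and deduplicated.
    """
    header, rows = _read_delimited(path)
    names = {normalize_term(r[0]) for r in rows}
    if len(names) != 1:
        raise ValueError(f"{path}: expected one SMQ, found {sorted(names)}")
    pts = frozenset(normalize_term(r[1]) for r in rows if len(r) > 1 and r[1].strip())
    if not pts:
        raise ValueError(f"{path}: SMQ with no preferred terms")
    return SmqDefinition(smq_name=names.pop(), pts=pts)


def read_pt_soc_map(path: str | Path) -> PtSocMap:
    """Read a two-column PT→SOC file; a PT mapped to two SOCs is a hard error."""
    header, rows = _read_delimited(path)
    mapping: dict[str, str] = {}
    for row in rows:
        if len(row) < 2:
            continue
        pt, soc = normalize_term(row[0]), normalize_term(row[1])
        if pt in mapping and mapping[pt] != soc:
            raise ValueError(f"PT {pt!r} mapped to both {mapping[pt]!r} and {soc!r}")
        mapping[pt] = soc
    return PtSocMap(mapping=mapping)


def read_drug_dictionary(path: str | Path) -> dict[str, str]:
    """Read a drug dictionary CSV (pattern, canonical label) → {pattern: label}."""
    header, rows = _read_delimited(path)
    return {normalize_term(r[0]): normalize_term(r[1] if len(r) > 1 else r[0]) for r in rows}


# ---------------------------------------------------------------------------
# Report-table writer
# ---------------------------------------------------------------------------

def write_report_table(rows: Iterable[Mapping], path: str | Path, format: str = "csv") -> Path:
    """Write result rows (mappings) to CSV or JSON; round-trips losslessly.

    An empty row sequence yields a header-only CSV / empty JSON list.
    """
    path = Path(path)
    rows = [dict(r) for r in rows]
    if format == "json":
        path.write_text(json.dumps(rows, indent=1, default=str) + "\n", encoding="utf-8")
        return path
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    buf = io.StringIO()
    fieldnames = list(rows[0].keys()) if rows else []
    writer = csv.DictWriter(buf, fieldnames=fieldnames)
    writer.writeheader()
    writer.writerows(rows)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_report_table(path: str | Path, format: str = "csv") -> list[dict]:
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text(encoding="utf-8"))
    with path.open("r", encoding="utf-8", newline="") as fh:
        return [dict(r) for r in csv.DictReader(fh)]
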