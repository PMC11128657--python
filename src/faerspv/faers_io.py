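"""Reading, assembly and deduplication of FAERS-style quarterly ASCII tables.

The public FAERS quarterly extracts ship one "$"-delimited ASCII table per
entity: DEMO (one row per report version, demographics), DRUG (one row per
reported medicine, with a role code), REAC (one row per MedDRA Preferred
Term), THER (therapy episodes with start dates) and OUTC (outcome codes).
Rows are keyed by ``primaryid``; revisions of the same safety report share a
``caseid`` and carry increasing ``caseversion`` numbers.

This module parses those tables, assembles the multi-table rows into one
:class:`ReportCase` per report version, and deduplicates to one record per
case by keeping the highest ``caseversion`` (ties broken by the largest
``primaryid``), which is the FDA-documented convention for building a
current snapshot of the database.
"""

from __future__ import annotations

import calendar
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("faerspv")

DELIMITER = "$"

#: table name -> columns that must be present in the header
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid",),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "ther": ("primaryid",),
    "outc": ("primaryid",),
}

TABLE_NAMES = ("demo", "drug", "reac", "ther", "outc")

#: age_cod unit -> factor converting to years
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8760.0,
}

VALID_SEXES = {"M", "F", "UNK"}


class FaersIOError(ValueError):
    """Raised for unrecoverable problems in input tables (missing columns)."""


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

_DIGITS = re.compile(r"^\d+$")


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date field, possibly incomplete.

    FAERS dates are plain digit strings: YYYYMMDD when complete, YYYYMM or
    YYYY when the reporter only knew part of the date. ``completeness``
    classifies the raw text; only ``full`` dates take part in time-to-onset
    arithmetic.
    """

    raw: str
    year: int | None = None
    month: int | None = None
    day: int | None = None
    completeness: str = "invalid"  # full | year_month | year_only | invalid

    @property
    def is_full(self) -> bool:
        return self.completeness == "full"

    def to_ordinal(self) -> int:
        """Proleptic ordinal day; only defined for full dates."""
        if not self.is_full:
            raise ValueError(f"not a complete date: {self.raw!r}")
        import datetime

        return datetime.date(self.year, self.month, self.day).toordinal()


def parse_date(raw: object) -> PartialDate:
    """Classify a raw FAERS date string into a :class:`PartialDate`.

    Never raises: anything that is not a valid YYYYMMDD / YYYYMM / YYYY
    digit string comes back with ``completeness="invalid"``.
    """
    text = "" if raw is None else str(raw).strip()
    if not _DIGITS.match(text):
        return PartialDate(raw=text)
    if len(text) == 8:
        y, m, d = int(text[:4]), int(text[4:6]), int(text[6:8])
        if 1 <= m <= 12 and 1 <= d <= calendar.monthrange(y, m)[1] and y >= 1:
            return PartialDate(text, y, m, d, "full")
        return PartialDate(raw=text)
    if len(text) == 6:
        y, m = int(text[:4]), int(text[4:6])
        if 1 <= m <= 12:
            return PartialDate(text, y, m, None, "year_month")
        return PartialDate(raw=text)
    if len(text) == 4:
        return PartialDate(text, int(text), None, None, "year_only")
    return PartialDate(raw=text)


# ---------------------------------------------------------------------------
# Raw quarter
# ---------------------------------------------------------------------------


@dataclass
class RawQuarter:
    """Parsed rows of one quarterly extract, one list of dicts per table.

    Field maps are keyed by lower-cased column names; unknown columns are
    preserved verbatim. ``warnings`` counts malformed (skipped) rows per
    table.
    """

    demo_rows: list[dict] = field(default_factory=list)
    drug_rows: list[dict] = field(default_factory=list)
    reac_rows: list[dict] = field(default_factory=list)
    ther_rows: list[dict] = field(default_factory=list)
    outc_rows: list[dict] = field(default_factory=list)
    warnings: dict[str, int] = field(default_factory=dict)

    def rows(self, table: str) -> list[dict]:
        return getattr(self, f"{table}_rows")


def _read_table(path: Path, table: str) -> tuple[list[dict], int]:
    bad = {"n": 0}

    def _on_bad(line):  # wrong field count -> skip, count
        bad["n"] += 1
        return None

    df = pd.read_csv(
        path,
        sep=DELIMITER,
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_on_bad,
        encoding="utf-8",
        encoding_errors="replace",
    )
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in MANDATORY_COLUMNS[table]:
        if col not in df.columns:
            raise FaersIOError(f"{path}: mandatory column {col!r} missing from {table.upper()} table")
    rows = df.to_dict(orient="records")
    # a row without its primaryid is unusable
    kept = [r for r in rows if str(r.get("primaryid", "")).strip()]
    bad["n"] += len(rows) - len(kept)
    return kept, bad["n"]


def read_quarter(paths: Mapping[str, str | Path]) -> RawQuarter:
    """Read one quarterly extract from per-table file locations.

    ``paths`` maps the table role (demo/drug/reac/ther/outc) to a file; the
    role comes from configuration, never from filename sniffing. Missing
    mandatory columns raise :class:`FaersIOError`; malformed rows are
    skipped and counted in ``warnings``.
    """
    quarter = RawQuarter()
    for table in TABLE_NAMES:
        if table not in paths:
            if table in ("demo", "drug", "reac"):
                raise FaersIOError(f"no path configured for mandatory table {table.upper()}")
            continue
        path = Path(paths[table])
        if not path.exists():
            raise FaersIOError(f"{table.upper()} file not found: {path}")
        rows, nbad = _read_table(path, table)
        setattr(quarter, f"{table}_rows", rows)
        quarter.warnings[table] = nbad
        logger.info("read %s: %d rows (%d skipped)", path, len(rows), nbad)
    return quarter


# ---------------------------------------------------------------------------
# Report cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugEntry:
    name: str
    role: str  # PS | SS | C | I
    therapy_start: PartialDate


@dataclass
class ReportCase:
    """One assembled (and after deduplication, unique) safety report."""

    primaryid: str
    caseid: str
    caseversion: int
    age_years: float | None
    sex: str | None
    country: str | None
    reporter: str | None
    outcomes: frozenset[str]
    drugs: list[DrugEntry]
    reactions: list[str]
    event_date: PartialDate
    report_year: int | None


@dataclass
class DedupResult:
    """Outcome of assembly + deduplication, with conservation accounting."""

    cases: list[ReportCase]
    input_reports: int          # distinct primaryids across all quarters
    duplicates_removed: int     # older caseversions discarded
    dropped_no_reactions: int   # report versions with no REAC rows
    conflicting_demo: int       # primaryids with >1 differing DEMO row

    @property
    def removed(self) -> int:
        return self.duplicates_removed + self.dropped_no_reactions


def _parse_age(row: Mapping) -> float | None:
    raw = str(row.get("age", "")).strip()
    if not raw:
        return None
    try:
        value = float(raw)
    except ValueError:
        return None
    unit = str(row.get("age_cod", "YR")).strip().upper() or "YR"
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        return None
    years = value * factor
    if not (0.0 <= years <= 130.0):
        return None
    return years


def _parse_version(row: Mapping) -> int:
    raw = str(row.get("caseversion", "")).strip()
    try:
        v = int(float(raw))
    except ValueError:
        return 1
    return v if v >= 1 else 1


def _pid_sort_key(pid: str):
    # numeric primaryids compare numerically; fall back to text
    try:
        return (0, int(pid), pid)
    except ValueError:
        return (1, 0, pid)


def _report_year(row: Mapping, event: PartialDate) -> int | None:
    for col in ("rept_dt", "fda_dt", "init_fda_dt"):
        d = parse_date(row.get(col, ""))
        if d.year is not None:
            return d.year
    return event.year


def _clean(value: object) -> str | None:
    text = str(value).strip() if value is not None else ""
    return text or None


def assemble_cases(quarters: Sequence[RawQuarter]) -> tuple[list[ReportCase], int, int, int]:
    """Join DEMO/DRUG/REAC/THER/OUTC rows into one ReportCase per primaryid.

    Returns (cases, n_primaryids, n_dropped_no_reactions, n_conflicting_demo).
    Therapy start dates attach to drug rows via drug_seq/dsg_drug_seq when
    present, positionally otherwise.
    """
    demo_by_pid: dict[str, dict] = {}
    conflicts = 0
    for q in quarters:
        for row in q.demo_rows:
            pid = str(row["primaryid"]).strip()
            if pid in demo_by_pid:
                if row != demo_by_pid[pid]:
                    conflicts += 1
                    logger.warning("conflicting DEMO rows for primaryid %s; keeping first", pid)
                continue
            demo_by_pid[pid] = row

    drugs_by_pid: dict[str, list[dict]] = {}
    reacs_by_pid: dict[str, list[str]] = {}
    thers_by_pid: dict[str, list[dict]] = {}
    outcs_by_pid: dict[str, set[str]] = {}
    orphans = 0
    for q in quarters:
        for row in q.drug_rows:
            pid = str(row["primaryid"]).strip()
            if pid not in demo_by_pid:
                orphans += 1
                continue
            drugs_by_pid.setdefault(pid, []).append(row)
        for row in q.reac_rows:
            pid = str(row["primaryid"]).strip()
            if pid not in demo_by_pid:
                orphans += 1
                continue
            pt = str(row.get("pt", "")).strip()
            if pt:
                reacs_by_pid.setdefault(pid, []).append(pt)
        for row in q.ther_rows:
            pid = str(row["primaryid"]).strip()
            if pid in demo_by_pid:
                thers_by_pid.setdefault(pid, []).append(row)
        for row in q.outc_rows:
            pid = str(row["primaryid"]).strip()
            code = str(row.get("outc_cod", "")).strip().upper()
            if pid in demo_by_pid and code:
                outcs_by_pid.setdefault(pid, set()).add(code)
    if orphans:
        logger.warning("%d DRUG/REAC rows reference a primaryid absent from DEMO", orphans)

    cases: list[ReportCase] = []
    dropped = 0
    for pid, demo in demo_by_pid.items():
        reactions = reacs_by_pid.get(pid, [])
        if not reactions:
            dropped += 1
            continue
        ther_rows = thers_by_pid.get(pid, [])
        start_by_seq = {
            str(t.get("dsg_drug_seq", "")).strip(): parse_date(t.get("start_dt", ""))
            for t in ther_rows
        }
        entries: list[DrugEntry] = []
        for i, drow in enumerate(drugs_by_pid.get(pid, [])):
            seq = str(drow.get("drug_seq", "")).strip()
            if seq and seq in start_by_seq:
                start = start_by_seq[seq]
            elif i < len(ther_rows) and not seq:
                start = parse_date(ther_rows[i].get("start_dt", ""))
            else:
                start = PartialDate(raw="")
            name = _clean(drow.get("drugname")) or _clean(drow.get("prod_ai")) or ""
            entries.append(
                DrugEntry(
                    name=name,
                    role=str(drow.get("role_cod", "")).strip().upper(),
                    therapy_start=start,
                )
            )
        event = parse_date(demo.get("event_dt", ""))
        sex = str(demo.get("sex", "")).strip().upper()
        cases.append(
            ReportCase(
                primaryid=pid,
                caseid=str(demo.get("caseid", pid)).strip() or pid,
                caseversion=_parse_version(demo),
                age_years=_parse_age(demo),
                sex=sex if sex in VALID_SEXES else None,
                country=_clean(str(demo.get("occr_country", "")).strip().upper()),
                reporter=_clean(str(demo.get("occp_cod", "")).strip().upper()),
                outcomes=frozenset(outcs_by_pid.get(pid, set())),
                drugs=entries,
                reactions=reactions,
                event_date=event,
                report_year=_report_year(demo, event),
            )
        )
    return cases, len(demo_by_pid), dropped, conflicts


def deduplicate(quarters: Sequence[RawQuarter] | Iterable[RawQuarter]) -> DedupResult:
    """Collapse multi-quarter report versions to one ReportCase per caseid.

    All quarters are concatenated before deduplication so a case revised in
    a later quarter collapses onto its latest version. The retained version
    is the highest ``caseversion``; ties break toward the largest
    ``primaryid``.
    """
    quarters = list(quarters)
    if not quarters:
        raise ValueError("deduplicate requires at least one quarter")
    cases, n_input, dropped, conflicts = assemble_cases(quarters)
    best: dict[str, ReportCase] = {}
    for case in cases:
        cur = best.get(case.caseid)
        if cur is None:
            best[case.caseid] = case
        else:
            key = (case.caseversion, _pid_sort_key(case.primaryid))
            cur_key = (cur.caseversion, _pid_sort_key(cur.primaryid))
            if key > cur_key:
                best[case.caseid] = case
    retained = sorted(best.values(), key=lambda c: _pid_sort_key(c.primaryid))
    removed_dups = len(cases) - len(retained)
    logger.info(
        "deduplicate: %d report versions -> %d cases (%d duplicates removed, %d without reactions)",
        n_input, len(retained), removed_dups, dropped,
    )
    return DedupResult(
        cases=retained,
        input_reports=n_input,
        duplicates_removed=removed_dups,
        dropped_no_reactions=dropped,
        conflicting_demo=conflicts,
    )
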