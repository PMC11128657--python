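"""Target-drug case extraction and the descriptive demographics table.

Spontaneous-report databases record free-text drug names, so a target
medicine must be found through a synonym dictionary (innovator and generic
brand names) with normalization of salts and formulation suffixes. Reports
where the target carries the "primary suspect" (PS) role code form the
analysis cohort; the cohort is then summarized in an available-case
demographics table (age bands, sex, severe outcomes, reporter occupation,
top reporting countries, reporting year).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .faers_io import ReportCase

# tokens stripped during name normalization (salt/hydrate suffixes)
_SALT_TOKENS = {
    "HYDROCHLORIDE", "HCL", "SODIUM", "SULFATE", "SULPHATE", "PHOSPHATE",
    "ACETATE", "MESYLATE", "MALEATE", "TARTRATE", "CITRATE", "BESYLATE",
    "MONOHYDRATE", "DIHYDRATE", "ANHYDROUS",
}

_WS = re.compile(r"\s+")

#: FAERS occupation code -> Table-1 style reporter label
REPORTER_LABELS = {
    "MD": "Physicians",
    "PH": "Pharmacists",
    "CN": "Consumers",
    "HP": "Healthcare professionals",
    "OT": "Other health professionals",
    "RN": "Other health professionals",
    "LW": "Consumers",
}

#: outcome code -> severe-outcome level, in decreasing severity priority
OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Other severe outcomes",
    "RI": "Other severe outcomes",
    "OT": "Other severe outcomes",
}

AGE_BANDS = ("<18", "18-64", ">=65")


def percentage(count: float, denominator: float) -> float:
    """``100 * count / denominator`` rounded half-up to 2 decimals."""
    if denominator == 0:
        return float("nan")
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def normalize_name(raw: str) -> str:
    """Upper-case, trim, collapse whitespace, strip salt/hydrate tokens."""
    text = _WS.sub(" ", str(raw).upper().strip())
    tokens = [t for t in text.split(" ") if t not in _SALT_TOKENS]
    return " ".join(tokens)


def edit_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity: ``1 - dist / max(len)``."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return 1.0 - prev[-1] / max(len(a), len(b))


@dataclass(frozen=True)
class DrugDictionary:
    """Synonym dictionary for one target medicine.

    ``match_mode`` is "exact", "substring" (a synonym contained anywhere in
    the normalized drug name — the default, reproducing brand-name search
    with dose/formulation suffixes) or "fuzzy" (substring, or normalized
    edit similarity of at least ``fuzzy_threshold`` for the whole name or
    any of its tokens).
    """

    canonical_name: str
    synonyms: tuple[str, ...]
    match_mode: str = "substring"
    fuzzy_threshold: float = 0.9

    def __post_init__(self):
        if not self.synonyms:
            raise ValueError("synonyms must be non-empty")
        if self.match_mode not in ("exact", "substring", "fuzzy"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.match_mode == "fuzzy" and not (0.0 < self.fuzzy_threshold <= 1.0):
            raise ValueError("fuzzy threshold must lie in (0, 1]")
        object.__setattr__(
            self, "_normalized", tuple(normalize_name(s) for s in self.synonyms)
        )

    @classmethod
    def from_mapping(cls, data: dict) -> "DrugDictionary":
        mode = data.get("match_mode", "substring")
        return cls(
            canonical_name=data["canonical_name"],
            synonyms=tuple(data["synonyms"]),
            match_mode=mode,
            fuzzy_threshold=float(data.get("fuzzy_threshold", 0.9)),
        )


def match_target(drugname: str, dictionary: DrugDictionary) -> bool:
    """True iff the normalized drug name matches a synonym under the mode."""
    name = normalize_name(drugname)
    if not name:
        return False
    for syn in dictionary._normalized:
        if dictionary.match_mode == "exact":
            if name == syn:
                return True
        elif syn in name:
            return True
        if dictionary.match_mode == "fuzzy":
            candidates = [name] + name.split(" ")
            if any(edit_similarity(c, syn) >= dictionary.fuzzy_threshold for c in candidates):
                return True
    return False


@dataclass
class CaseSet:
    """Reports in which the target drug appears with the required role."""

    cases: list[ReportCase]
    target: DrugDictionary
    role_filter: str | None = "PS"

    def __len__(self) -> int:
        return len(self.cases)

    def primaryids(self) -> set[str]:
        return {c.primaryid for c in self.cases}


def case_matches(case: ReportCase, dictionary: DrugDictionary, role: str | None) -> bool:
    for entry in case.drugs:
        if role is not None and entry.role != role:
            continue
        if match_target(entry.name, dictionary):
            return True
    return False


def extract_cases(
    reports: Sequence[ReportCase],
    dictionary: DrugDictionary,
    role: str | None = "PS",
) -> CaseSet:
    """Select deduplicated reports with >=1 target-drug row in ``role``.

    ``role=None`` accepts any role code. A report counts once no matter how
    many of its drug rows match.
    """
    selected = [c for c in reports if case_matches(c, dictionary, role)]
    return CaseSet(cases=selected, target=dictionary, role_filter=role)


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------


@dataclass
class DescriptiveTable:
    """Available-case demographics summary (rows as a DataFrame).

    Columns: category, level, count, available_n, pct (of the category's
    available cases) and pct_total (of all reports). The per-category
    header rows carry the availability share in ``pct_total``.
    """

    rows: pd.DataFrame
    n_reports: int
    age_median: float | None
    age_mean: float | None

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _age_band(age: float) -> str:
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64"
    return ">=65"


def _severe_level(outcomes: Iterable[str]) -> str | None:
    codes = set(outcomes)
    for code in OUTCOME_PRIORITY:
        if code in codes:
            return OUTCOME_LABELS[code]
    return None


def describe_cohort(caseset: CaseSet, top_k_countries: int = 5) -> DescriptiveTable:
    """Build the available-case demographics table for a cohort.

    Missing values are excluded from each category's ``available_n``; each
    level's ``pct`` uses that available count as denominator, except the
    country category where the denominator is the sum over the reported
    top-k countries (so the shares of the listed countries total 100%).
    ``pct_total`` relates every count to the full cohort size.
    """
    cases = caseset.cases
    if not cases:
        raise ValueError("describe_cohort requires a non-empty cohort")
    n = len(cases)
    out: list[dict] = []

    def add_category(category: str, counts: dict[str, int], order: Sequence[str] | None = None,
                     denominator: int | None = None):
        available = sum(counts.values())
        denom = available if denominator is None else denominator
        out.append(
            dict(category=category, level="(available)", count=available,
                 available_n=available, pct=float("nan"),
                 pct_total=percentage(available, n))
        )
        levels = list(order) if order is not None else sorted(counts, key=counts.get, reverse=True)
        for level in levels:
            if level not in counts:
                continue
            out.append(
                dict(category=category, level=level, count=counts[level],
                     available_n=denom, pct=percentage(counts[level], denom),
                     pct_total=percentage(counts[level], n))
            )

    ages = [c.age_years for c in cases if c.age_years is not None]
    age_counts: dict[str, int] = {}
    for a in ages:
        age_counts[_age_band(a)] = age_counts.get(_age_band(a), 0) + 1
    add_category("Age (years old)", age_counts, order=AGE_BANDS)

    sex_counts: dict[str, int] = {}
    for c in cases:
        if c.sex in ("M", "F"):
            label = "Male" if c.sex == "M" else "Female"
            sex_counts[label] = sex_counts.get(label, 0) + 1
    add_category("Gender", sex_counts, order=("Male", "Female"))

    severe_counts: dict[str, int] = {}
    for c in cases:
        level = _severe_level(c.outcomes)
        if level is not None:
            severe_counts[level] = severe_counts.get(level, 0) + 1
    add_category(
        "Severe outcome", severe_counts,
        order=("Death", "Life-threatening", "Hospitalization", "Disability",
               "Other severe outcomes"),
    )

    reporter_counts: dict[str, int] = {}
    for c in cases:
        label = REPORTER_LABELS.get(c.reporter or "")
        if label is not None:
            reporter_counts[label] = reporter_counts.get(label, 0) + 1
    add_category("Reporters", reporter_counts)

    country_counts: dict[str, int] = {}
    for c in cases:
        if c.country:
            country_counts[c.country] = country_counts.get(c.country, 0) + 1
    top = sorted(country_counts, key=lambda k: (-country_counts[k], k))[:top_k_countries]
    top_counts = {k: country_counts[k] for k in top}
    add_category(
        f"Reported countries (top {top_k_countries})", top_counts,
        denominator=sum(top_counts.values()),
    )

    year_counts: dict[str, int] = {}
    for c in cases:
        if c.report_year is not None:
            key = str(c.report_year)
            year_counts[key] = year_counts.get(key, 0) + 1
    add_category("Reporting year", year_counts, order=sorted(year_counts))

    return DescriptiveTable(
        rows=pd.DataFrame(out),
        n_reports=n,
        age_median=float(np.median(ages)) if ages else None,
        age_mean=float(np.mean(ages)) if ages else None,
    )
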