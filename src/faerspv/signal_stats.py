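"""Case/non-case disproportionality statistics and the combined signal rule.

For every event term (MedDRA PT, or SOC after roll-up) the target-drug
cohort is crossed with the full deduplicated reporting background to give
the 2x2 table

    =============  =======  ============
                   event    other events
    target drug    a        b
    other drugs    c        d
    =============  =======  ============

with the unique report as counting unit. Four measures of disproportionate
reporting are computed:

* ROR  = (a*d)/(b*c), 95% CI exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d));
* PRR  = [a/(a+b)] / [c/(c+d)], with the Yates-corrected Pearson chi-square
  on the same table;
* IC   = log2((a+0.5)/(E+0.5)) with E = (a+b)(a+c)/N, the shrunken
  Bayesian information component, plus its credible lower bound;
* EBGM / EB05 from the empirical-Bayes gamma-Poisson shrinker
  (:mod:`faerspv.gps_ebgm`).

A pair is flagged as a signal of disproportionate reporting when all of
PRR >= 2, chi-square >= 4, a >= 3, IC lower bound > 0 and EBGM > 2 hold —
the conjunction criterion used in the pharmacovigilance literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .drug_cohort import CaseSet
from .meddra_map import HierarchyTable, case_socs

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """(a, b, c, d) report counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected_cells(self) -> tuple[float, float, float, float, bool]:
        """Cells with the Haldane–Anscombe +0.5 applied when any is zero."""
        cells = (self.a, self.b, self.c, self.d)
        if min(cells) == 0:
            return tuple(x + 0.5 for x in cells) + (True,)
        return tuple(float(x) for x in cells) + (False,)


@dataclass(frozen=True)
class SignalThresholds:
    """The combined disproportionality criterion's cut-offs."""

    prr_min: float = 2.0
    chi2_min: float = 4.0
    n_min: int = 3
    ic_lower_min: float = 0.0
    ebgm_min: float = 2.0


@dataclass
class SignalResult:
    """All four statistics and per-criterion flags for one event term."""

    term: str
    soc: str
    a: int
    ror: float
    ror_lower: float
    ror_upper: float
    ror_corrected: bool
    prr: float
    chi2: float
    ic: float
    ic_lower: float
    ebgm: float = float("nan")
    eb05: float = float("nan")
    flags: dict = field(default_factory=dict)
    is_signal: bool = False


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def build_tables(
    caseset: CaseSet,
    background_reports: Sequence,
    level: str = "PT",
    hierarchy: HierarchyTable | None = None,
) -> list[tuple[str, ContingencyTable]]:
    """One 2x2 table per event term with at least one target-cohort report.

    ``background_reports`` is the full deduplicated corpus and must contain
    the cohort. At ``level="SOC"`` the terms are primary SOCs and a report
    counts once per SOC it touches (``hierarchy`` required).
    """
    level = level.upper()
    if level not in ("PT", "SOC"):
        raise ValueError("level must be 'PT' or 'SOC'")
    if level == "SOC" and hierarchy is None:
        raise ValueError("SOC-level tables require a hierarchy")
    target_ids = caseset.primaryids()
    background_ids = {r.primaryid for r in background_reports}
    if not target_ids <= background_ids:
        raise ValueError("case set is not a subset of the background corpus")

    n_total = len(background_ids)
    n_target = len(target_ids)

    def terms_of(report) -> set[str]:
        if level == "PT":
            return set(report.reactions)
        return case_socs(report.reactions, hierarchy)

    target_counts: dict[str, int] = {}
    all_counts: dict[str, int] = {}
    for report in background_reports:
        in_target = report.primaryid in target_ids
        for term in terms_of(report):
            all_counts[term] = all_counts.get(term, 0) + 1
            if in_target:
                target_counts[term] = target_counts.get(term, 0) + 1

    out: list[tuple[str, ContingencyTable]] = []
    for term in sorted(target_counts):
        a = target_counts[term]
        c = all_counts[term] - a
        out.append((term, ContingencyTable(a=a, b=n_target - a, c=c,
                                           d=n_total - n_target - c)))
    return out


# ---------------------------------------------------------------------------
# Frequentist statistics
# ---------------------------------------------------------------------------


def ror_ci(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with log-normal 95% CI.

    Any zero cell triggers the Haldane–Anscombe 0.5 correction on all four
    cells; the returned flag records whether it was applied.
    """
    a, b, c, d, corrected = table.corrected_cells()
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return (ror, math.exp(log_ror - Z95 * se), math.exp(log_ror + Z95 * se), corrected)


def prr_chi2(table: ContingencyTable, yates: bool = True) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-square.

    The chi-square uses Yates' continuity correction by default (the
    convention behind the PRR >= 2 / chi2 >= 4 / n >= 3 rule); pass
    ``yates=False`` for the uncorrected statistic.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("PRR undefined: an all-zero table row")
    a, b, c, d, _ = table.corrected_cells()
    prr = (a / (a + b)) / (c / (c + d))
    chi2, _, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=yates
    )
    return prr, float(chi2)


# ---------------------------------------------------------------------------
# Bayesian information component (BCPNN)
# ---------------------------------------------------------------------------


def bcpnn_ic(
    table: ContingencyTable,
    method: str = "approx",
    quantile: float = 0.025,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Information component and its credible lower bound.

    IC = log2((a+0.5)/(E+0.5)); the implied posterior for the relative
    reporting rate is Gamma(a+0.5, rate E+0.5). The lower bound comes from

    * ``method="approx"``: the closed form
      IC - 3.3*(a+0.5)^(-1/2) - 2*(a+0.5)^(-3/2) (approximates the 2.5%
      posterior percentile);
    * ``method="gamma"``: the exact Gamma posterior ``quantile``;
    * ``method="mc"``: a Monte-Carlo percentile from ``n_mc`` posterior
      draws (mostly useful as an independent cross-check).
    """
    if table.n <= 0:
        raise ValueError("empty table")
    a = table.a
    e = table.expected
    ic = math.log2((a + 0.5) / (e + 0.5))
    if method == "approx":
        lower = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    elif method == "gamma":
        lower = math.log2(stats.gamma.ppf(quantile, a + 0.5, scale=1.0 / (e + 0.5)))
    elif method == "mc":
        rng = rng if rng is not None else np.random.default_rng(0)
        draws = rng.gamma(shape=a + 0.5, scale=1.0 / (e + 0.5), size=n_mc)
        lower = float(np.log2(np.quantile(draws, quantile)))
    else:
        raise ValueError(f"unknown IC method {method!r}")
    return ic, lower


# ---------------------------------------------------------------------------
# Combined criterion and ranking
# ---------------------------------------------------------------------------


def compute_signal(
    term: str,
    table: ContingencyTable,
    soc: str = "",
    ebgm: float = float("nan"),
    eb05: float = float("nan"),
    ic_method: str = "approx",
) -> SignalResult:
    """Assemble ROR/PRR/chi2/IC (and optionally EBGM) into a SignalResult."""
    ror, lo, hi, corrected = ror_ci(table)
    prr, chi2 = prr_chi2(table)
    ic, ic_lower = bcpnn_ic(table, method=ic_method)
    return SignalResult(
        term=term, soc=soc, a=table.a,
        ror=ror, ror_lower=lo, ror_upper=hi, ror_corrected=corrected,
        prr=prr, chi2=chi2, ic=ic, ic_lower=ic_lower, ebgm=ebgm, eb05=eb05,
    )


def evaluate_signal(result: SignalResult, thresholds: SignalThresholds | None = None) -> SignalResult:
    """Apply the combined criterion; "at least" cut-offs are >=, the IC and
    EBGM bounds are strict >."""
    t = thresholds or SignalThresholds()
    flags = {
        "prr": result.prr >= t.prr_min,
        "chi2": result.chi2 >= t.chi2_min,
        "n": result.a >= t.n_min,
        "ic": result.ic_lower > t.ic_lower_min,
        "ebgm": result.ebgm > t.ebgm_min,
    }
    out = replace(result)
    out.flags = flags
    out.is_signal = all(flags.values())
    return out


def rank_top(signals: Iterable[SignalResult], k: int) -> dict[str, list[SignalResult]]:
    """Two descending rankings, by report count and by ROR CI lower bound.

    Ties within a ranking break on the other ranking's statistic (stable
    sort); each list is truncated to ``k``.
    """
    sig = list(signals)
    by_count = sorted(sig, key=lambda s: (-s.a, -s.ror_lower, s.term))[:k]
    by_ror_lower = sorted(sig, key=lambda s: (-s.ror_lower, -s.a, s.term))[:k]
    return {"by_count": by_count, "by_ror_lower": by_ror_lower}


def signals_to_frame(signals: Iterable[SignalResult]) -> pd.DataFrame:
    """Flatten SignalResults into the output CSV schema."""
    rows = []
    for s in signals:
        rows.append(
            dict(term=s.term, soc=s.soc, a=s.a, ror=s.ror, ror_l=s.ror_lower,
                 ror_u=s.ror_upper, ror_corrected=s.ror_corrected, prr=s.prr,
                 chi2=s.chi2, ic=s.ic, ic_lower=s.ic_lower, ebgm=s.ebgm,
                 eb05=s.eb05,
                 flag_prr=s.flags.get("prr"), flag_chi2=s.flags.get("chi2"),
                 flag_n=s.flags.get("n"), flag_ic=s.flags.get("ic"),
                 flag_ebgm=s.flags.get("ebgm"), is_signal=s.is_signal)
        )
    return pd.DataFrame(rows)
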