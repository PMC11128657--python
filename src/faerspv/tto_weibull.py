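"""Time-to-onset (TTO) extraction, summaries and Weibull hazard-shape tests.

TTO is the number of days from the first administration of the suspect
drug to the onset of the adverse event. Only reports whose therapy start
and event dates are complete (YYYYMMDD) contribute; events dated before
the therapy start are treated as data-entry errors and excluded. Every
exclusion is flagged with its reason rather than silently dropped.

The onset distribution is summarized (median/IQR, 30-day bins, empirical
CDF) and fitted with a two-parameter Weibull (scale alpha in days, shape
beta). The shape parameter carries the hazard message: beta < 1 means a
decreasing hazard ("early failure" — the risk is front-loaded after
treatment start), beta = 1 a constant hazard, beta > 1 an increasing one.
The classification is made conservatively from the 95% CI of beta, not the
point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .drug_cohort import CaseSet, DrugDictionary, match_target, percentage
from .faers_io import ReportCase
from .meddra_map import HierarchyTable, case_socs

Z95 = 1.959963984540054

EXCLUSION_REASONS = ("incomplete_start", "incomplete_event", "negative_tto", "none")


@dataclass(frozen=True)
class TTORecord:
    primaryid: str
    soc: str
    onset_days: int | None
    included: bool
    exclusion_reason: str  # one of EXCLUSION_REASONS

    def __post_init__(self):
        if self.included != (self.exclusion_reason == "none"):
            raise ValueError("included must mirror exclusion_reason == 'none'")


def compute_tto(case: ReportCase, dictionary: DrugDictionary | None = None) -> TTORecord:
    """Onset days for one report: event date minus earliest complete
    therapy start among target-drug rows (all drug rows if ``dictionary``
    is None)."""
    rows = case.drugs
    if dictionary is not None:
        rows = [e for e in rows if match_target(e.name, dictionary)]
    starts = [e.therapy_start for e in rows if e.therapy_start.is_full]
    if not starts:
        return TTORecord(case.primaryid, "", None, False, "incomplete_start")
    if not case.event_date.is_full:
        return TTORecord(case.primaryid, "", None, False, "incomplete_event")
    start = min(starts, key=lambda d: d.to_ordinal())
    onset = case.event_date.to_ordinal() - start.to_ordinal()
    if onset < 0:
        return TTORecord(case.primaryid, "", None, False, "negative_tto")
    return TTORecord(case.primaryid, "", onset, True, "none")


def records_by_soc(
    caseset: CaseSet, hierarchy: HierarchyTable, use_target_rows: bool = True
) -> list[TTORecord]:
    """Per-(report, SOC) TTO records: a report contributes its onset once to
    every SOC its reactions map to; excluded reports appear once with an
    empty SOC."""
    out: list[TTORecord] = []
    dictionary = caseset.target if use_target_rows else None
    for case in caseset.cases:
        base = compute_tto(case, dictionary)
        if not base.included:
            out.append(base)
            continue
        for soc in sorted(case_socs(case.reactions, hierarchy)):
            out.append(TTORecord(case.primaryid, soc, base.onset_days, True, "none"))
    return out


def records_to_frame(records: Sequence[TTORecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(primaryid=r.primaryid, soc=r.soc, onset_days=r.onset_days,
              included=r.included, exclusion_reason=r.exclusion_reason)
         for r in records]
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_tto(records: Sequence[TTORecord]) -> dict:
    """Median/IQR, 30-day monthly bins and the empirical CDF.

    Bin 1 covers days 0-30 inclusive; bins 2..11 the following 30-day
    intervals; bin 12 runs to day 365 so that the final ">1 year" bin is
    exactly "more than one year after the start of therapy". Quartiles use
    linear interpolation (numpy default, type 7).
    """
    days = np.asarray([r.onset_days for r in records if r.included], dtype=float)
    if days.size == 0:
        raise ValueError("summarize_tto needs at least one included record")
    n = int(days.size)
    q1, med, q3 = np.percentile(days, [25, 50, 75])

    edges = [0.0] + [30.0 * m for m in range(1, 12)] + [365.0]
    labels = [f"month_{m}" for m in range(1, 13)]
    bins: dict[str, dict] = {}
    for m, label in enumerate(labels, start=1):
        lo = edges[m - 1]
        hi = edges[m]
        if m == 1:
            count = int(np.sum(days <= hi))
        else:
            count = int(np.sum((days > lo) & (days <= hi)))
        bins[label] = dict(count=count, pct=percentage(count, n))
    over = int(np.sum(days > 365.0))
    bins["over_1_year"] = dict(count=over, pct=percentage(over, n))

    xs = np.sort(days)
    ecdf = dict(days=xs.tolist(),
                cumulative=(np.arange(1, n + 1) / n).tolist())
    return dict(
        n=n, median=float(med), q1=float(q1), q3=float(q3),
        min=float(xs[0]), max=float(xs[-1]), bins=bins, ecdf=ecdf,
        n_excluded=sum(1 for r in records if not r.included),
    )


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class WeibullFit:
    alpha: float                      # scale, days
    beta: float                       # shape
    ci95_beta: tuple[float, float]
    loglik: float
    n: int
    hazard_class: str = ""


class WeibullFitError(RuntimeError):
    pass


def _profile_mle(t: np.ndarray) -> tuple[float, float]:
    """Exact two-parameter Weibull MLE via the profiled shape equation.

    The scale MLE given beta is alpha = (mean(t^beta))^(1/beta); plugging
    it back reduces the problem to one monotone equation in beta, solved
    by bracketed root finding. Log-domain weights keep t^beta stable.
    """
    log_t = np.log(t)
    mean_log = float(np.mean(log_t))
    shift = float(np.max(log_t))

    def score(beta: float) -> float:
        w = np.exp(beta * (log_t - shift))
        return float(np.sum(w * log_t) / np.sum(w) - 1.0 / beta - mean_log)

    lo, hi = 1e-3, 4.0
    while score(hi) < 0.0 and hi < 1e4:
        hi *= 2.0
    if score(lo) > 0.0 or score(hi) < 0.0:
        raise WeibullFitError("shape score equation has no bracketed root")
    from scipy import optimize

    beta = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=8.9e-16)
    w = np.exp(beta * (log_t - shift))
    alpha = math.exp(shift + math.log(float(np.mean(w))) / beta)
    return alpha, beta


def _weibull_loglik(t: np.ndarray, alpha: float, beta: float) -> float:
    z = t / alpha
    return float(
        t.size * (math.log(beta) - beta * math.log(alpha))
        + (beta - 1.0) * np.sum(np.log(t))
        - np.sum(z ** beta)
    )


def weibull_mle(
    data: Sequence[TTORecord] | Sequence[float] | np.ndarray,
    shift: float = 0.5,
    three_parameter: bool = False,
) -> WeibullFit:
    """Two-parameter Weibull MLE on onset times.

    Day-resolution onsets include exact zeros, which a continuous Weibull
    density cannot carry when beta < 1; ``shift`` (default half a day, the
    interval midpoint for day counts) is added to every time before
    fitting. Pass ``shift=0`` for already-continuous data. The beta CI is
    the observed-information (inverse-Hessian) normal approximation.
    ``three_parameter`` frees the location parameter instead of fixing it
    at zero; it is never selected automatically.
    """
    if not isinstance(data, np.ndarray) and len(data) and isinstance(data[0], TTORecord):
        t = np.asarray([r.onset_days for r in data if r.included], dtype=float)
    else:
        t = np.asarray(data, dtype=float)
    t = t + shift
    if t.size < 10:
        raise WeibullFitError(f"need >= 10 included onset times, got {t.size}")
    if np.any(t <= 0):
        raise WeibullFitError("non-positive onset times after shift")

    if three_parameter:
        beta, loc, alpha = stats.weibull_min.fit(t)
        t = t - loc
        if np.any(t <= 0):
            raise WeibullFitError("three-parameter fit produced non-positive residual times")
        alpha, beta = _profile_mle(t)  # re-solve precisely on shifted times
    else:
        alpha, beta = _profile_mle(t)
    if not (np.isfinite(alpha) and np.isfinite(beta) and alpha > 0 and beta > 0):
        raise WeibullFitError(f"fit did not converge: alpha={alpha}, beta={beta}")

    loglik = _weibull_loglik(t, alpha, beta)

    # observed information via central finite differences on (alpha, beta)
    h_a = max(alpha * 1e-5, 1e-8)
    h_b = max(beta * 1e-5, 1e-8)

    def ll(pa: float, pb: float) -> float:
        return _weibull_loglik(t, pa, pb)

    daa = (ll(alpha + h_a, beta) - 2 * loglik + ll(alpha - h_a, beta)) / h_a**2
    dbb = (ll(alpha, beta + h_b) - 2 * loglik + ll(alpha, beta - h_b)) / h_b**2
    dab = (
        ll(alpha + h_a, beta + h_b) - ll(alpha + h_a, beta - h_b)
        - ll(alpha - h_a, beta + h_b) + ll(alpha - h_a, beta - h_b)
    ) / (4 * h_a * h_b)
    info = -np.array([[daa, dab], [dab, dbb]])
    try:
        cov = np.linalg.inv(info)
        se_beta = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError as exc:
        raise WeibullFitError("singular observed information") from exc
    if not np.isfinite(se_beta) or se_beta == 0.0:
        raise WeibullFitError("degenerate beta standard error")

    return WeibullFit(
        alpha=float(alpha), beta=float(beta),
        ci95_beta=(beta - Z95 * se_beta, beta + Z95 * se_beta),
        loglik=loglik, n=int(t.size),
    )


def classify_hazard(fit: WeibullFit) -> str:
    """CI-based hazard-shape call: the whole 95% CI of beta must clear 1."""
    lo, hi = fit.ci95_beta
    if hi < 1.0:
        return "early_failure"
    if lo > 1.0:
        return "late_failure"
    return "constant"


def fit_by_soc(
    records: Sequence[TTORecord], min_n: int = 10, shift: float = 0.5
) -> pd.DataFrame:
    """Per-SOC summary + Weibull fit table (n, median, IQR, min/max, alpha,
    beta, beta CI, hazard class). SOCs with fewer than ``min_n`` included
    records are skipped."""
    by_soc: dict[str, list[TTORecord]] = {}
    for r in records:
        if r.included and r.soc:
            by_soc.setdefault(r.soc, []).append(r)
    rows = []
    for soc in sorted(by_soc):
        recs = by_soc[soc]
        if len(recs) < min_n:
            continue
        days = np.asarray([r.onset_days for r in recs], dtype=float)
        q1, med, q3 = np.percentile(days, [25, 50, 75])
        fit = weibull_mle(recs, shift=shift)
        fit.hazard_class = classify_hazard(fit)
        rows.append(
            dict(soc=soc, n=len(recs), median=float(med), q1=float(q1),
                 q3=float(q3), min=float(days.min()), max=float(days.max()),
                 alpha=fit.alpha, beta=fit.beta, beta_l=fit.ci95_beta[0],
                 beta_u=fit.ci95_beta[1], loglik=fit.loglik,
                 hazard_class=fit.hazard_class)
        )
    return pd.DataFrame(rows)
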