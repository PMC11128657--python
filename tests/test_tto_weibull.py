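import numpy as np
import pytest
from scipy import stats

from faerspv import (classify_hazard, compute_tto, records_by_soc,
                     summarize_tto, weibull_mle)
from faerspv.faers_io import DrugEntry, PartialDate, parse_date
from faerspv.tto_weibull import (TTORecord, WeibullFit, WeibullFitError,
                                 _weibull_loglik, fit_by_soc)

from test_drug_cohort import make_case


def case_with_dates(start, event, pid="1", role="PS", name="BENDAMUSTINE"):
    case = make_case(pid, drugs=(), event=event)
    case.drugs = [DrugEntry(name, role, parse_date(start))]
    case.event_date = parse_date(event)
    return case


# ---------------------------------------------------------------------------
# compute_tto
# ---------------------------------------------------------------------------


def test_tto_simple_difference():
    rec = compute_tto(case_with_dates("20230101", "20230114"))
    assert rec.included and rec.onset_days == 13


def test_tto_same_day_is_zero():
    rec = compute_tto(case_with_dates("20230101", "20230101"))
    assert rec.included and rec.onset_days == 0


def test_tto_partial_start_excluded():
    rec = compute_tto(case_with_dates("202301", "20230114"))
    assert not rec.included and rec.exclusion_reason == "incomplete_start"


def test_tto_partial_event_excluded():
    rec = compute_tto(case_with_dates("20230101", "202302"))
    assert not rec.included and rec.exclusion_reason == "incomplete_event"


def test_tto_event_before_start_excluded():
    rec = compute_tto(case_with_dates("20230601", "20230101"))
    assert not rec.included and rec.exclusion_reason == "negative_tto"


def test_tto_earliest_complete_start_wins():
    case = make_case("1", drugs=(), event="20230301")
    case.event_date = parse_date("20230301")
    case.drugs = [
        DrugEntry("BENDAMUSTINE", "PS", parse_date("202212")),    # incomplete
        DrugEntry("BENDAMUSTINE", "PS", parse_date("20230201")),
        DrugEntry("BENDAMUSTINE", "SS", parse_date("20230101")),
    ]
    rec = compute_tto(case)
    assert rec.onset_days == (parse_date("20230301").to_ordinal()
                              - parse_date("20230101").to_ordinal())


def test_tto_record_consistency_enforced():
    with pytest.raises(ValueError):
        TTORecord("1", "", 5, included=True, exclusion_reason="negative_tto")


def test_exclusion_partition(small_caseset, hierarchy):
    records = records_by_soc(small_caseset, hierarchy)
    included = [r for r in records if r.included]
    excluded = [r for r in records if not r.included]
    assert all(r.exclusion_reason == "none" for r in included)
    assert all(r.exclusion_reason in ("incomplete_start", "incomplete_event",
                                      "negative_tto") for r in excluded)
    # every cohort report shows up at least once, included or flagged
    assert {r.primaryid for r in records} == small_caseset.primaryids()


# ---------------------------------------------------------------------------
# summarize_tto
# ---------------------------------------------------------------------------


def _recs(days):
    return [TTORecord(str(i), "S", d, True, "none") for i, d in enumerate(days)]


def test_summary_three_point_quartiles():
    s = summarize_tto(_recs([0, 13, 59]))
    assert s["median"] == 13 and s["q1"] == pytest.approx(6.5) and s["q3"] == pytest.approx(36)


def test_summary_all_equal_iqr_zero():
    s = summarize_tto(_recs([7] * 20))
    assert s["q3"] - s["q1"] == 0


def test_summary_bins_and_shares():
    days = [10] * 6 + [45] * 3 + [400] * 1
    s = summarize_tto(_recs(days))
    assert s["bins"]["month_1"]["count"] == 6
    assert s["bins"]["month_2"]["count"] == 3
    assert s["bins"]["over_1_year"]["count"] == 1
    assert s["bins"]["month_1"]["pct"] == 60.00
    total = sum(b["count"] for b in s["bins"].values())
    assert total == len(days)


def test_summary_day30_boundary_in_first_month():
    s = summarize_tto(_recs([30, 31]))
    assert s["bins"]["month_1"]["count"] == 1
    assert s["bins"]["month_2"]["count"] == 1


def test_summary_requires_included_records():
    with pytest.raises(ValueError):
        summarize_tto([TTORecord("1", "", None, False, "incomplete_start")])


def test_summary_ecdf_monotone(small_caseset, hierarchy):
    records = [r for r in records_by_soc(small_caseset, hierarchy) if r.included]
    s = summarize_tto(records)
    cum = s["ecdf"]["cumulative"]
    assert cum == sorted(cum) and cum[-1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Weibull MLE
# ---------------------------------------------------------------------------


def test_weibull_recovers_exponential():
    rng = np.random.default_rng(5)
    fit = weibull_mle(rng.exponential(5.0, 2000), shift=0.0)
    assert 0.95 <= fit.beta <= 1.05
    assert fit.ci95_beta[0] <= 1.0 <= fit.ci95_beta[1]


def test_weibull_matches_grid_search():
    """On a 50-point sample, no (alpha, beta) grid point beats the MLE's
    log-likelihood, and the grid argmax sits next to the MLE."""
    rng = np.random.default_rng(8)
    t = stats.weibull_min.rvs(0.8, scale=20.0, size=50, random_state=rng)
    fit = weibull_mle(t, shift=0.0)
    alphas = np.linspace(fit.alpha * 0.5, fit.alpha * 1.5, 60)
    betas = np.linspace(fit.beta * 0.5, fit.beta * 1.5, 60)
    grid = np.array([[_weibull_loglik(t, a, b) for b in betas] for a in alphas])
    assert fit.loglik >= grid.max() - 1e-6
    ia, ib = np.unravel_index(grid.argmax(), grid.shape)
    assert alphas[ia] == pytest.approx(fit.alpha, rel=0.05)
    assert betas[ib] == pytest.approx(fit.beta, rel=0.05)


def test_weibull_scale_equivariance():
    rng = np.random.default_rng(9)
    t = stats.weibull_min.rvs(1.1, scale=12.0, size=400, random_state=rng)
    f1 = weibull_mle(t, shift=0.0)
    f2 = weibull_mle(t * 3.0, shift=0.0)
    assert f2.alpha / f1.alpha == pytest.approx(3.0, abs=1e-6)
    assert f2.beta == pytest.approx(f1.beta, abs=1e-6)


@pytest.mark.parametrize("beta_true", [0.6, 0.8, 1.0, 1.3])
def test_weibull_parameter_recovery(beta_true):
    """Mean shape estimate over 200 simulated datasets (n = 300) lands
    within 0.03 of the truth."""
    rng = np.random.default_rng(int(beta_true * 100))
    estimates = []
    for _ in range(200):
        t = stats.weibull_min.rvs(beta_true, scale=15.0, size=300,
                                  random_state=rng)
        estimates.append(weibull_mle(t, shift=0.0).beta)
    assert np.mean(estimates) == pytest.approx(beta_true, abs=0.03)


def test_weibull_fitted_median_within_bootstrap_band():
    rng = np.random.default_rng(10)
    t = stats.weibull_min.rvs(0.9, scale=25.0, size=500, random_state=rng)
    fit = weibull_mle(t, shift=0.0)
    fitted_median = fit.alpha * np.log(2.0) ** (1.0 / fit.beta)
    boots = [np.median(rng.choice(t, size=t.size, replace=True))
             for _ in range(500)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    assert lo <= fitted_median <= hi


def test_weibull_shift_handles_zero_days():
    days = np.array([0, 0, 1, 2, 3, 5, 8, 13, 21, 34, 55, 89])
    fit = weibull_mle(days, shift=0.5)
    assert fit.beta > 0 and np.isfinite(fit.loglik)


def test_weibull_small_sample_rejected():
    with pytest.raises(WeibullFitError):
        weibull_mle(np.arange(5.0), shift=0.5)


def test_weibull_against_lifelines():
    """Independent cross-check of the MLE against lifelines' WeibullFitter."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(12)
    t = stats.weibull_min.rvs(0.85, scale=30.0, size=800, random_state=rng)
    fit = weibull_mle(t, shift=0.0)
    wf = lifelines.WeibullFitter().fit(t)
    assert fit.alpha == pytest.approx(wf.lambda_, rel=1e-3)
    assert fit.beta == pytest.approx(wf.rho_, rel=1e-3)


# ---------------------------------------------------------------------------
# hazard classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "beta, ci, expected",
    [
        (0.74, (0.68, 0.80), "early_failure"),
        (1.0, (0.9, 1.1), "constant"),
        (1.4, (1.2, 1.6), "late_failure"),
        (0.95, (0.85, 1.02), "constant"),  # CI touches 1 -> no call
    ],
)
def test_classify_hazard(beta, ci, expected):
    fit = WeibullFit(alpha=10.0, beta=beta, ci95_beta=ci, loglik=0.0, n=100)
    assert classify_hazard(fit) == expected


def test_fit_by_soc_table(small_caseset, hierarchy):
    records = records_by_soc(small_caseset, hierarchy)
    table = fit_by_soc(records, min_n=10)
    assert not table.empty
    assert (table.beta_l <= table.beta).all() and (table.beta <= table.beta_u).all()
    assert set(table.hazard_class) <= {"early_failure", "constant", "late_failure"}
    by_soc_counts = {}
    for r in records:
        if r.included and r.soc:
            by_soc_counts[r.soc] = by_soc_counts.get(r.soc, 0) + 1
    for row in table.itertuples():
        assert row.n == by_soc_counts[row.soc] >= 10
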