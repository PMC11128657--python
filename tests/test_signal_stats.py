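import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv import (ContingencyTable, SignalThresholds, bcpnn_ic,
                     build_tables, compute_signal, evaluate_signal, prr_chi2,
                     rank_top, ror_ci)
from faerspv.drug_cohort import CaseSet
from faerspv.signal_stats import SignalResult

from test_drug_cohort import make_case


# ---------------------------------------------------------------------------
# build_tables
# ---------------------------------------------------------------------------


def _corpus_with_pt_x(target_dictionary):
    """100 reports: 10 target (4 with PT X), 6 non-target reports with X."""
    reports = []
    for i in range(10):
        pts = ("PT X", "Other") if i < 4 else ("Other",)
        reports.append(make_case(f"t{i}", drugs=(("BENDAMUSTINE", "PS"),),
                                 reactions=pts))
    for i in range(90):
        pts = ("PT X",) if i < 6 else ("Background",)
        reports.append(make_case(f"b{i}", drugs=(("DRUG_001", "PS"),),
                                 reactions=pts))
    caseset = CaseSet(reports[:10], target_dictionary)
    return caseset, reports


def test_build_tables_direct_count(target_dictionary):
    caseset, reports = _corpus_with_pt_x(target_dictionary)
    tables = dict(build_tables(caseset, reports, level="PT"))
    assert tables["PT X"] == ContingencyTable(4, 6, 6, 84)


def test_build_tables_excludes_a_zero(target_dictionary):
    caseset, reports = _corpus_with_pt_x(target_dictionary)
    tables = dict(build_tables(caseset, reports, level="PT"))
    assert "Background" not in tables  # occurs only outside the cohort


def test_build_tables_requires_subset(target_dictionary):
    caseset, reports = _corpus_with_pt_x(target_dictionary)
    with pytest.raises(ValueError):
        build_tables(caseset, reports[10:], level="PT")


def test_build_tables_margins_on_synthetic(small_caseset, small_dedup):
    """Every (a+b) equals the cohort size, every N the corpus size, and the
    a-cells equal an exhaustive recount."""
    tables = build_tables(small_caseset, small_dedup.cases, level="PT")
    n_target = len(small_caseset)
    n_corpus = len(small_dedup.cases)
    recount: dict[str, int] = {}
    for case in small_caseset.cases:
        for pt in set(case.reactions):
            recount[pt] = recount.get(pt, 0) + 1
    assert len(tables) == len(recount)
    for term, t in tables:
        assert t.a + t.b == n_target
        assert t.n == n_corpus
        assert t.a == recount[term]


def test_build_tables_a_counts_match_manifest(small_caseset, small_dedup, small_corpus):
    tables = dict(build_tables(small_caseset, small_dedup.cases, level="PT"))
    for pt, a in small_corpus["manifest"].pt_a_counts.items():
        assert tables[pt].a == a


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------


def test_ror_symmetric_table():
    ror, lo, hi, corrected = ror_ci(ContingencyTable(10, 10, 10, 10))
    assert ror == 1.0 and lo < 1.0 < hi and not corrected


def test_ror_against_bruteforce():
    a, b, c, d = 10, 90, 100, 9800
    ror, lo, hi, _ = ror_ci(ContingencyTable(a, b, c, d))
    assert ror == pytest.approx(a * d / (b * c))
    assert round(ror, 2) == 10.89
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert lo == pytest.approx(math.exp(math.log(ror) - 1.959964 * se), rel=1e-6)
    assert hi == pytest.approx(math.exp(math.log(ror) + 1.959964 * se), rel=1e-6)


def test_ror_haldane_correction():
    ror, lo, hi, corrected = ror_ci(ContingencyTable(3, 0, 5, 100))
    assert corrected and np.isfinite([ror, lo, hi]).all()
    assert ror == pytest.approx((3.5 * 100.5) / (0.5 * 5.5))


# ---------------------------------------------------------------------------
# PRR / chi-square
# ---------------------------------------------------------------------------


def test_prr_proportional_table():
    prr, chi2 = prr_chi2(ContingencyTable(10, 90, 100, 900))
    assert prr == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-9)


def test_prr_arithmetic():
    prr, _ = prr_chi2(ContingencyTable(10, 90, 100, 9800))
    assert prr == pytest.approx((10 / 100) / (100 / 9900))
    assert round(prr, 2) == 9.90


def _yates_chi2_bruteforce(a, b, c, d):
    n = a + b + c + d
    observed = np.array([[a, b], [c, d]], dtype=float)
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    expected = np.outer(rows, cols) / n
    return float(np.sum((np.abs(observed - expected) - 0.5) ** 2 / expected))


def test_chi2_against_bruteforce_yates():
    _, chi2 = prr_chi2(ContingencyTable(20, 80, 30, 870))
    assert chi2 == pytest.approx(_yates_chi2_bruteforce(20, 80, 30, 870), rel=1e-9)


def test_chi2_invariant_to_transpose():
    t = ContingencyTable(20, 80, 30, 870)
    tt = ContingencyTable(20, 30, 80, 870)
    assert prr_chi2(t)[1] == pytest.approx(prr_chi2(tt)[1], rel=1e-12)


def test_prr_undefined_on_empty_row():
    with pytest.raises(ValueError):
        prr_chi2(ContingencyTable(0, 0, 5, 5))


@settings(max_examples=200, derandomize=True)
@given(st.integers(1, 30), st.integers(900, 1100), st.integers(1, 50),
       st.integers(5000, 7000))
def test_prr_close_to_ror_for_rare_events(a, b, c, d):
    """With event rates <= 1% in both arms, PRR and ROR agree within 1%."""
    t = ContingencyTable(a, b, c, d)
    if t.a / (t.a + t.b) > 0.01 or t.c / (t.c + t.d) > 0.01:
        return
    prr, _ = prr_chi2(t)
    ror = ror_ci(t)[0]
    assert abs(prr - ror) / ror < 0.01


# ---------------------------------------------------------------------------
# information component
# ---------------------------------------------------------------------------


def test_ic_zero_when_observed_equals_expected():
    t = ContingencyTable(10, 90, 90, 810)  # E = 100*100/1000 = 10 = a
    ic, _ = bcpnn_ic(t)
    assert ic == pytest.approx(0.0, abs=1e-12)


def test_ic_arithmetic():
    t = ContingencyTable(100, 0, 0, 900)  # E = 100*100/1000 = 10
    ic, _ = bcpnn_ic(t)
    assert ic == pytest.approx(math.log2(100.5 / 10.5))
    assert round(ic, 3) == 3.259


def test_ic_lower_below_ic_and_methods_agree_in_sign():
    for table in (ContingencyTable(3, 7, 2, 88), ContingencyTable(50, 50, 50, 850)):
        for method in ("approx", "gamma", "mc"):
            ic, lower = bcpnn_ic(table, method=method)
            assert lower <= ic


def test_ic_gamma_quantile_matches_monte_carlo():
    rng = np.random.default_rng(123)
    t = ContingencyTable(3, 7, 40, 950)
    _, mc = bcpnn_ic(t, method="mc", n_mc=1_000_000, rng=rng)
    _, exact = bcpnn_ic(t, method="gamma")
    assert mc == pytest.approx(exact, abs=0.01)


# ---------------------------------------------------------------------------
# combined criterion and ranking
# ---------------------------------------------------------------------------


def _result(**kw):
    base = dict(term="X", soc="", a=10, ror=3, ror_lower=2, ror_upper=4,
                ror_corrected=False, prr=3, chi2=10, ic=1, ic_lower=0.5,
                ebgm=3, eb05=2)
    base.update(kw)
    return SignalResult(**base)


def test_small_count_blocks_signal():
    res = evaluate_signal(_result(a=2, prr=50, chi2=100))
    assert not res.is_signal and not res.flags["n"]


def test_boundary_semantics():
    at_boundary = evaluate_signal(
        _result(a=3, prr=2.0, chi2=4.0, ic_lower=1e-9, ebgm=2.0 + 1e-9))
    assert at_boundary.is_signal
    ic_at_zero = evaluate_signal(_result(a=3, prr=2.0, chi2=4.0, ic_lower=0.0))
    assert not ic_at_zero.is_signal  # IC bound is strictly > 0
    ebgm_at_two = evaluate_signal(_result(ebgm=2.0))
    assert not ebgm_at_two.is_signal  # EBGM bound is strictly > 2


def test_monotonicity_in_a():
    """With b, c, d fixed and the pair rare against the background (the
    case/non-case regime), ROR, PRR and IC all rise with a."""
    prev = None
    for a in (1, 3, 10, 30, 100):
        t = ContingencyTable(a, 500, 400, 90000)
        stats_now = (ror_ci(t)[0], prr_chi2(t)[0], bcpnn_ic(t)[0])
        if prev is not None:
            assert all(x >= p for x, p in zip(stats_now, prev))
        prev = stats_now


def test_rank_top_orders_and_truncates():
    sigs = [_result(term=t, a=a, ror_lower=r)
            for t, a, r in (("A", 5, 1.0), ("B", 9, 0.5), ("C", 2, 9.0))]
    ranks = rank_top(sigs, 2)
    assert [s.term for s in ranks["by_count"]] == ["B", "A"]
    assert [s.term for s in ranks["by_ror_lower"]] == ["C", "A"]
    assert [s.term for s in rank_top(sigs, 10)["by_count"]] == ["B", "A", "C"]


def test_rank_ties_break_on_other_statistic():
    sigs = [_result(term="low", a=5, ror_lower=1.0),
            _result(term="high", a=5, ror_lower=3.0)]
    assert [s.term for s in rank_top(sigs, 2)["by_count"]] == ["high", "low"]


def test_null_corpus_conjunction(small_dedup, target_dictionary, hierarchy):
    """On pairs with a >= 3 in a near-null corpus, the combined criterion
    passes less often than the most permissive single criterion and
    tightening thresholds never flags more pairs."""
    from faerspv import extract_cases

    caseset = extract_cases(small_dedup.cases, target_dictionary, "PS")
    tables = [t for _, t in build_tables(caseset, small_dedup.cases, level="PT")
              if t.a >= 3]
    assert tables
    base = SignalThresholds()
    strict = SignalThresholds(prr_min=4, chi2_min=8, n_min=6, ebgm_min=4)
    results = [evaluate_signal(compute_signal("x", t, ebgm=1.0), base) for t in tables]
    combined = sum(r.is_signal for r in results) / len(results)
    per_flag = {k: sum(r.flags[k] for r in results) / len(results)
                for k in ("prr", "chi2", "n", "ic")}
    assert combined < max(per_flag.values())  # the n>=3 flag passes for all
    stricter = [evaluate_signal(compute_signal("x", t, ebgm=1.0), strict) for t in tables]
    assert sum(r.is_signal for r in stricter) <= sum(r.is_signal for r in results)
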