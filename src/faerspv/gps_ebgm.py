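"""Empirical-Bayes gamma-Poisson shrinkage (the MGPS estimator).

Each drug-event pair's observed report count ``a`` is modelled as
Poisson(lambda * E), where E is the count expected under independence of
the drug and event margins and lambda is the pair's true relative
reporting rate. Across all pairs lambda follows a two-component gamma
mixture prior

    lambda ~ w * Gamma(alpha1, beta1) + (1 - w) * Gamma(alpha2, beta2)

(shape/rate parameterization). Marginally ``a`` is then a mixture of
negative binomials, whose likelihood is maximized over the five prior
parameters. The posterior of lambda given (a, E) is again a gamma mixture;
EBGM = 2^{E[log2 lambda | a, E]} is its geometric mean and EB05 its 5th
percentile, the shrunken analogues of the raw ratio a/E.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .signal_stats import ContingencyTable


@dataclass(frozen=True)
class PairExpected:
    """Observed count and independence-expected count for one pair."""

    a: int
    e: float

    def __post_init__(self):
        if self.a > 0 and self.e <= 0:
            raise ValueError("E must be positive when a > 0")


@dataclass
class GPSPrior:
    """Fitted two-component gamma mixture prior (shape/rate, weight w)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    converged: bool = False
    loglik: float = float("nan")

    def as_dict(self) -> dict:
        return dict(alpha1=self.alpha1, beta1=self.beta1, alpha2=self.alpha2,
                    beta2=self.beta2, w=self.w, converged=self.converged,
                    loglik=self.loglik)


class GPSFitError(RuntimeError):
    """Optimization failed on all starts; carries the best-so-far prior."""

    def __init__(self, message: str, best: GPSPrior):
        super().__init__(message)
        self.best = best


def expected_counts(tables: Sequence[tuple[str, ContingencyTable]] | Sequence[ContingencyTable]) -> list[PairExpected]:
    """E = (a+b)(a+c)/N for each table (accepts (term, table) pairs too)."""
    out = []
    for item in tables:
        table = item[1] if isinstance(item, tuple) else item
        out.append(PairExpected(a=table.a, e=table.expected))
    return out


def all_pair_counts(reports, include_zero: bool = True) -> list[PairExpected]:
    """(a, E) for every drug-name x PT pair across a deduplicated corpus.

    This is the database-wide pair grid the prior is fitted on. Margins are
    unique-report counts; with ``include_zero`` the full cross product is
    returned (pairs never reported together enter with a = 0), which is the
    untruncated MGPS likelihood.
    """
    n_total = len(reports)
    drug_margin: dict[str, int] = {}
    pt_margin: dict[str, int] = {}
    joint: dict[tuple[str, str], int] = {}
    for rep in reports:
        dnames = sorted({e.name for e in rep.drugs if e.name})
        pts = sorted(set(rep.reactions))
        for dn in dnames:
            drug_margin[dn] = drug_margin.get(dn, 0) + 1
        for pt in pts:
            pt_margin[pt] = pt_margin.get(pt, 0) + 1
        for dn in dnames:
            for pt in pts:
                joint[(dn, pt)] = joint.get((dn, pt), 0) + 1
    pairs: list[PairExpected] = []
    if include_zero:
        for dn, n_d in drug_margin.items():
            for pt, n_p in pt_margin.items():
                pairs.append(PairExpected(a=joint.get((dn, pt), 0),
                                          e=n_d * n_p / n_total))
    else:
        for (dn, pt), a in joint.items():
            pairs.append(PairExpected(a=a, e=drug_margin[dn] * pt_margin[pt] / n_total))
    return pairs


# ---------------------------------------------------------------------------
# Prior fitting
# ---------------------------------------------------------------------------

# fixed multi-start values (alpha1, beta1, alpha2, beta2, w); the first is
# the classic DuMouchel starting point
_STARTS = (
    (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0),
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.5, 3.0, 1.0, 0.2),
    (2.0, 2.0, 0.5, 0.1, 0.5),
    (1.0, 0.5, 5.0, 5.0, 0.1),
)

_LOGIT_CLIP = 30.0


def _unpack(theta: np.ndarray) -> tuple[float, float, float, float, float]:
    a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -20.0, 20.0))
    w = special.expit(np.clip(theta[4], -_LOGIT_CLIP, _LOGIT_CLIP))
    return a1, b1, a2, b2, w


def _mixture_logpmf(a: np.ndarray, e: np.ndarray, params) -> np.ndarray:
    a1, b1, a2, b2, w = params
    # marginal of a | E is NB(size=alpha, p=beta/(beta+E)) per component
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    return np.logaddexp(np.log(w) + lp1, np.log1p(-w) + lp2)


def _negloglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray, truncated: bool) -> float:
    params = _unpack(theta)
    ll = _mixture_logpmf(a, e, params)
    if truncated:
        p0 = np.exp(_mixture_logpmf(np.zeros_like(a), e, params))
        ll = ll - np.log1p(-np.clip(p0, 0.0, 1.0 - 1e-12))
    total = float(np.sum(ll))
    if not np.isfinite(total):
        return 1e30
    return -total


def fit_prior(pairs: Sequence[PairExpected], truncated: bool = False) -> GPSPrior:
    """Maximize the marginal negative-binomial-mixture likelihood.

    Deterministic multi-start quasi-Newton optimization on log/logit-
    transformed parameters; with ``truncated`` the likelihood conditions on
    a >= 1 (the zero-truncated MGPS variant). The returned components are
    ordered so component 1 has the smaller prior mean. Raises
    :class:`GPSFitError` (carrying the best parameters found) if no start
    converges.
    """
    if len(pairs) < 2:
        raise ValueError("fit_prior needs at least two pairs")
    a = np.asarray([p.a for p in pairs], dtype=float)
    e = np.asarray([p.e for p in pairs], dtype=float)
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    if truncated:
        keep = a >= 1
        a, e = a[keep], e[keep]
    if np.all(a == a[0]) and np.all(e == e[0]):
        raise GPSFitError(
            "degenerate input: all pairs identical, mixture not identifiable",
            GPSPrior(1.0, 1.0, 1.0, 1.0, 0.5, converged=False),
        )

    # two further deterministic, data-adaptive starts: seed the signal
    # component at the empirical heavy tail of (a+0.5)/E, which keeps the
    # optimizer out of the degenerate point-mass-at-1 local mode on corpora
    # holding only a handful of truly associated pairs
    tail = max(float(np.quantile((a + 0.5) / e, 0.99)), 2.0)
    starts = _STARTS + (
        (1.0, 1.0, 1.0, 1.0 / tail, 0.95),
        (1.0, 1.0, 2.0, 2.0 / tail, 0.9),
    )

    best = None
    best_ok = False
    for start in starts:
        theta0 = np.array([math.log(start[0]), math.log(start[1]),
                           math.log(start[2]), math.log(start[3]),
                           special.logit(start[4])])
        res = optimize.minimize(
            _negloglik, theta0, args=(a, e, truncated), method="L-BFGS-B",
            options=dict(maxiter=500, ftol=1e-10, gtol=1e-8),
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
            best_ok = bool(res.success)
        elif res.fun < best.fun + 1e-9 and res.success and not best_ok:
            best = res
            best_ok = True

    # derivative-free polish; also rescues quasi-Newton line-search aborts
    polish = optimize.minimize(
        _negloglik, best.x, args=(a, e, truncated), method="Nelder-Mead",
        options=dict(maxiter=4000, fatol=1e-9, xatol=1e-8),
    )
    if polish.fun <= best.fun + 1e-9:
        best_ok = best_ok or bool(polish.success)
    if polish.fun < best.fun:
        best = polish

    a1, b1, a2, b2, w = _unpack(best.x)
    if a1 / b1 > a2 / b2:  # order components by prior mean
        a1, b1, a2, b2, w = a2, b2, a1, b1, 1.0 - w
    prior = GPSPrior(a1, b1, a2, b2, w, converged=best_ok, loglik=-float(best.fun))
    if not best_ok:
        raise GPSFitError("gamma-mixture fit failed to converge on all starts", prior)
    return prior


# ---------------------------------------------------------------------------
# Posterior quantities
# ---------------------------------------------------------------------------


def _posterior_mixture(a: float, e: float, prior: GPSPrior):
    """Posterior component weights and gamma (shape, rate) parameters."""
    lp1 = math.log(prior.w) + stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lp2 = math.log1p(-prior.w) + stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    m = max(lp1, lp2)
    q1 = math.exp(lp1 - m) / (math.exp(lp1 - m) + math.exp(lp2 - m))
    return (
        (q1, prior.alpha1 + a, prior.beta1 + e),
        (1.0 - q1, prior.alpha2 + a, prior.beta2 + e),
    )


def posterior_ebgm(
    a: float, e: float, prior: GPSPrior, quantile: float = 0.05
) -> tuple[float, float]:
    """EBGM and the posterior ``quantile`` (default the 5th percentile, EB05).

    EBGM is the geometric mean exp(E[ln lambda | a, E]) of the posterior
    gamma mixture; the percentile is found by root-finding on the mixture
    CDF (bracketed by the component percentiles, tolerance 1e-6).
    """
    if e <= 0:
        raise ValueError("E must be positive")
    comps = _posterior_mixture(a, e, prior)
    mean_log = sum(q * (special.digamma(shape) - math.log(rate))
                   for q, shape, rate in comps)
    ebgm = math.exp(mean_log)

    lo = min(stats.gamma.ppf(quantile, shape, scale=1.0 / rate) for _, shape, rate in comps)
    hi = max(stats.gamma.ppf(quantile, shape, scale=1.0 / rate) for _, shape, rate in comps)

    def cdf(x: float) -> float:
        return sum(q * stats.gamma.cdf(x, shape, scale=1.0 / rate)
                   for q, shape, rate in comps) - quantile

    if hi - lo < 1e-12:
        return ebgm, lo
    root = optimize.brentq(cdf, lo * (1 - 1e-9), hi * (1 + 1e-9), xtol=1e-6, rtol=1e-10)
    return ebgm, float(root)


def posterior_ebgm_many(
    pairs: Sequence[PairExpected], prior: GPSPrior, quantile: float = 0.05
) -> list[tuple[float, float]]:
    return [posterior_ebgm(p.a, p.e, prior, quantile) for p in pairs]
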