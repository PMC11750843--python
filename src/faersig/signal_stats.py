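"""Disproportionality statistics and the four-algorithm conjunction rule.

For every (cohort, preferred term) pair a 2x2 contingency table is formed
against the background of all other deduplicated reports in the loaded
universe::

                     target PT     other PTs
    target cohort        a             b
    background           c             d

Four signal-detection algorithms are computed per table:

* **ROR** — reporting odds ratio ``a*d / (b*c)`` with a Woolf 95% CI;
  criterion ``a >= 3`` and lower CI bound > 1.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-square; criterion ``a >= 3``, PRR >= 2, chi2 >= 4.
* **BCPNN IC** — Bayesian information component, the shrunk log2
  observed-to-expected reporting ratio under symmetric unit-style beta
  hyperpriors (closed-form posterior moments); criterion IC025 > 0.
* **MGPS EBGM** — empirical-Bayes geometric mean of the relative reporting
  rate under a two-component gamma-Poisson mixture prior fitted by marginal
  maximum likelihood across all pairs; criterion EB05 > 2.

A pair is a *significant signal* only when all four criteria hold
simultaneously (conjunction rule). All thresholds are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from faersig.cohort import CohortAssignment, TumorLexicon
from faersig.faers_io import SafetyReport

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case 2x2 counts for one (cohort, PT) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class GpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must lie in (0, 1)")


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm significance thresholds (the conventional values)."""

    min_a: int = 3
    ror_lo95_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    eb05_gt: float = 2.0
    mgps_metric: str = "eb05"  # or "ebgm"
    yates: bool = False


@dataclass(frozen=True)
class SignalResult:
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_mgps: bool
    significant: bool
    corrected: bool = False


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Apply the 0.5 continuity correction to all cells iff any cell is 0."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True
    return float(t.a), float(t.b), float(t.c), float(t.d), False


def ror_stat(t: ContingencyTable, criteria: SignalCriteria = SignalCriteria()
             ) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with Woolf (log-normal) 95% CI.

    ror = (a d)/(b c); CI = exp(ln ror +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).
    Zero cells get a 0.5 correction on all four cells.
    """
    a, b, c, d, _ = _corrected_cells(t)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - Z_95 * se)
    hi = math.exp(math.log(ror) + Z_95 * se)
    passed = t.a >= criteria.min_a and lo > criteria.ror_lo95_gt
    return ror, lo, hi, passed


def chi2_stat(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square on the 2x2 table (optional Yates correction)."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / margins


def prr_stat(t: ContingencyTable, criteria: SignalCriteria = SignalCriteria()
             ) -> tuple[float, float, bool]:
    """Proportional reporting ratio and Pearson chi-square."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("PRR undefined: empty target or background margin")
    if t.c == 0 or t.a == 0:
        a, b, c, d, _ = _corrected_cells(t)
    else:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = chi2_stat(t, yates=criteria.yates)
    passed = t.a >= criteria.min_a and prr >= criteria.prr_min and chi2 >= criteria.chi2_min
    return prr, chi2, passed


# BCPNN hyperpriors: symmetric unit-style priors on the joint and marginal
# reporting probabilities (gamma11 = alpha1 = beta1 = 1, alpha = beta = 2),
# with the joint prior scale tied to the marginals so that IC has prior
# expectation 0.
_G11, _A1, _B1, _AA, _BB = 1.0, 1.0, 1.0, 2.0, 2.0


def bcpnn_ic(t: ContingencyTable, criteria: SignalCriteria = SignalCriteria()
             ) -> tuple[float, float, bool]:
    """Closed-form posterior moments of the Bayesian information component.

    E(IC) estimates log2 of the observed-to-expected reporting ratio shrunk
    toward 0; the moments are exact under the independent-beta posterior
    (digamma/trigamma), and IC025 = E(IC) - 2 sqrt(V(IC)). Small tables are
    pulled to 0, so no continuity handling is needed even at a = 0.
    """
    a = float(t.a)
    n1 = float(t.a + t.b)  # target-cohort margin
    m1 = float(t.a + t.c)  # target-PT margin
    n = float(t.n)
    # joint prior scale tied to the marginals so the prior IC expectation is 0
    gamma = _G11 * (n + _AA) * (n + _BB) / ((n1 + _A1) * (m1 + _B1))
    # IC = log2 p11 - log2(p1. p.1) with independent beta posteriors;
    # E[ln Beta(x, y)] = psi(x) - psi(x+y), Var = psi1(x) - psi1(x+y)
    psi, psi1 = special.digamma, special.polygamma
    e_ic = (
        psi(a + _G11) - psi(n + gamma)
        - psi(n1 + _A1) + psi(n + _AA)
        - psi(m1 + _B1) + psi(n + _BB)
    ) / math.log(2)
    v_ic = (
        psi1(1, a + _G11) - psi1(1, n + gamma)
        + psi1(1, n1 + _A1) - psi1(1, n + _AA)
        + psi1(1, m1 + _B1) - psi1(1, n + _BB)
    ) / math.log(2) ** 2
    ic025 = float(e_ic) - 2.0 * math.sqrt(float(v_ic))
    return float(e_ic), ic025, ic025 > criteria.ic025_gt


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log P(a | E) marginally under lambda ~ Gamma(alpha, rate beta)."""
    return (
        special.gammaln(alpha + a) - special.gammaln(alpha) - special.gammaln(a + 1)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def _gps_nll(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_p = np.clip(params, -12.0, 12.0)
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    p = float(np.clip(special.expit(logit_p), 1e-12, 1 - 1e-12))
    l1 = _nb_logpmf(a, e, a1, b1) + math.log(p)
    l2 = _nb_logpmf(a, e, a2, b2) + math.log1p(-p)
    return -float(np.sum(np.logaddexp(l1, l2)))


DEFAULT_GPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def fit_gps_prior(
    tables: Sequence[ContingencyTable] | Sequence[tuple[str, ContingencyTable]],
    starts: Sequence[tuple[float, float, float, float, float]] | None = None,
) -> GpsPrior:
    """Fit the two-component gamma mixture prior by marginal maximum
    likelihood over all (PT, table) pairs.

    Multi-start optimization on log/logit-transformed parameters; the
    default start is (alpha1, beta1, alpha2, beta2, p) = (0.2, 0.1, 2.0,
    4.0, 1/3).
    """
    tabs = [t[1] if isinstance(t, tuple) else t for t in tables]
    if not tabs:
        raise ValueError("no contingency tables supplied")
    if len(tabs) < 20:
        logger.warning("GPS prior fitted on only %d pairs; >=20 recommended", len(tabs))
    a = np.array([t.a for t in tabs], dtype=float)
    e = np.array([t.expected for t in tabs], dtype=float)
    return fit_gps_prior_counts(a, e, starts=starts)


def fit_gps_prior_counts(
    a: np.ndarray,
    expected: np.ndarray,
    starts: Sequence[tuple[float, float, float, float, float]] | None = None,
) -> GpsPrior:
    """Marginal-ML prior fit directly from observed and expected counts."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]
    if a.size == 0:
        raise ValueError("all tables have zero expected count")

    if starts is None:
        starts = [
            DEFAULT_GPS_START,
            (1.0, 1.0, 1.0, 1.0, 0.5),
            (0.5, 0.5, 5.0, 5.0, 0.2),
        ]
    best = None
    for s in starts:
        x0 = np.array([math.log(s[0]), math.log(s[1]), math.log(s[2]),
                       math.log(s[3]), special.logit(s[4])])
        res = optimize.minimize(
            _gps_nll, x0, args=(a, e), method="L-BFGS-B",
            bounds=[(-12, 12)] * 4 + [(-12, 12)],
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    # simplex polish from the quasi-Newton optimum (mixture likelihoods are
    # ridge-prone; the polish also recovers from a stalled L-BFGS-B run)
    res = optimize.minimize(
        _gps_nll, best.x, args=(a, e), method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
    )
    if res.fun <= best.fun:
        best = res
        converged = converged or bool(res.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("GPS prior fit failed from all starts")
    if not converged:
        raise RuntimeError(
            f"GPS prior fit did not converge from any start (best nll={best.fun:.4f})")
    # the mixture may degenerate to one component on null-like data; clamp
    # the mixing weight away from the boundary (weight ~0/1 is equivalent)
    la1, lb1, la2, lb2, logit_p = np.clip(best.x, -12.0, 12.0)
    logit_p = float(np.clip(logit_p, -11.5, 11.5))
    return GpsPrior(
        alpha1=float(np.exp(la1)), beta1=float(np.exp(lb1)),
        alpha2=float(np.exp(la2)), beta2=float(np.exp(lb2)),
        p_mix=float(special.expit(logit_p)),
        loglik=-float(best.fun), converged=True,
    )


def _posterior_mixture(t: ContingencyTable, prior: GpsPrior
                       ) -> tuple[float, float, float, float, float]:
    """Posterior (weight1, shape1, rate1, shape2, rate2) for lambda | a."""
    a, e = float(t.a), t.expected
    l1 = _nb_logpmf(np.array([a]), np.array([e]), prior.alpha1, prior.beta1)[0] \
        + math.log(prior.p_mix)
    l2 = _nb_logpmf(np.array([a]), np.array([e]), prior.alpha2, prior.beta2)[0] \
        + math.log1p(-prior.p_mix)
    q1 = math.exp(l1 - np.logaddexp(l1, l2))
    return q1, prior.alpha1 + a, prior.beta1 + e, prior.alpha2 + a, prior.beta2 + e


def ebgm_stat(t: ContingencyTable, prior: GpsPrior,
              criteria: SignalCriteria = SignalCriteria()) -> tuple[float, float, bool]:
    """Empirical-Bayes geometric mean and 5th posterior percentile.

    The posterior of the relative reporting rate is a two-component gamma
    mixture; EBGM = exp(E[ln lambda | a]) and EB05 solves the mixture CDF
    at 0.05 by root-finding (tolerance 1e-8).
    """
    if t.expected <= 0:
        raise ValueError("expected count must be positive")
    q1, s1, r1, s2, r2 = _posterior_mixture(t, prior)
    mean_log = q1 * (special.digamma(s1) - math.log(r1)) \
        + (1 - q1) * (special.digamma(s2) - math.log(r2))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) \
            + (1 - q1) * stats.gamma.cdf(x, s2, scale=1 / r2)

    hi = max(stats.gamma.ppf(0.9999, s1, scale=1 / r1),
             stats.gamma.ppf(0.9999, s2, scale=1 / r2))
    lo = 1e-12
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-8))

    metric = eb05 if criteria.mgps_metric == "eb05" else ebgm
    return ebgm, eb05, metric > criteria.eb05_gt


def conjunction(pass_ror: bool, pass_prr: bool, pass_bcpnn: bool, pass_mgps: bool) -> bool:
    """The all-four significance rule."""
    return pass_ror and pass_prr and pass_bcpnn and pass_mgps


def score_table(t: ContingencyTable, prior: GpsPrior,
                criteria: SignalCriteria = SignalCriteria()) -> SignalResult:
    """Compute all four algorithms and the conjunction flag for one table."""
    ror, lo, hi, p_ror = ror_stat(t, criteria)
    prr, chi2, p_prr = prr_stat(t, criteria)
    ic, ic025, p_ic = bcpnn_ic(t, criteria)
    ebgm, eb05, p_eb = ebgm_stat(t, prior, criteria)
    corrected = min(t.a, t.b, t.c, t.d) == 0
    return SignalResult(
        ror=ror, ror_lo95=lo, ror_hi95=hi, prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=ebgm, eb05=eb05,
        pass_ror=p_ror, pass_prr=p_prr, pass_bcpnn=p_ic, pass_mgps=p_eb,
        significant=conjunction(p_ror, p_prr, p_ic, p_eb), corrected=corrected,
    )


def build_tables(
    reports: Sequence[SafetyReport],
    assignments: Mapping[str, CohortAssignment],
    lexicon: TumorLexicon,
    group: str,
) -> list[tuple[str, ContingencyTable]]:
    """Case/non-case tables for every lexicon PT reported at least once in
    the target group. Background = all other reports in the universe.
    A report contributes at most 1 to cell a per PT."""
    in_group = [assignments[r.case_id].group == group for r in reports]
    n_target = sum(in_group)
    n_background = len(reports) - n_target
    if n_background == 0:
        raise ValueError(f"background for group {group!r} is empty")
    if n_target == 0:
        return []

    target_counts: dict[str, int] = {}
    background_counts: dict[str, int] = {}
    for r, is_target in zip(reports, in_group):
        pts = {rx.pt for rx in r.reactions if rx.pt in lexicon}
        bucket = target_counts if is_target else background_counts
        for pt in pts:
            bucket[pt] = bucket.get(pt, 0) + 1

    out = []
    for pt in lexicon.pts:
        a = target_counts.get(pt, 0)
        if a == 0:
            continue
        c = background_counts.get(pt, 0)
        out.append((pt, ContingencyTable(a=a, b=n_target - a, c=c, d=n_background - c)))
    return out


def evaluate_signals(
    tables: Sequence[tuple[str, ContingencyTable]],
    prior: GpsPrior,
    lexicon: TumorLexicon,
    criteria: SignalCriteria = SignalCriteria(),
) -> pd.DataFrame:
    """Score every (PT, table) pair; returns the machine-readable signal
    table (one row per PT with counts, statistics, pass flags, conjunction)."""
    rows = []
    for pt, t in tables:
        s = score_table(t, prior, criteria)
        rows.append({
            "pt": pt, "soc": lexicon.soc(pt),
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": s.ror, "ror_lo95": s.ror_lo95, "ror_hi95": s.ror_hi95,
            "prr": s.prr, "chi2": s.chi2, "ic": s.ic, "ic025": s.ic025,
            "ebgm": s.ebgm, "eb05": s.eb05,
            "pass_ror": s.pass_ror, "pass_prr": s.pass_prr,
            "pass_bcpnn": s.pass_bcpnn, "pass_mgps": s.pass_mgps,
            "significant": s.significant, "corrected": s.corrected,
        })
    cols = ["pt", "soc", "a", "b", "c", "d", "ror", "ror_lo95", "ror_hi95",
            "prr", "chi2", "ic", "ic025", "ebgm", "eb05", "pass_ror",
            "pass_prr", "pass_bcpnn", "pass_mgps", "significant", "corrected"]
    return pd.DataFrame(rows, columns=cols)
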