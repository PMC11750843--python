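"""Time-to-onset analysis: Weibull failure-type classification, rank-sum
comparison and cumulative incidence with the log-rank test.

Time to onset is the event date minus the therapy start date of the target
drug, in days; only reports carrying both dates at day precision contribute.
The Weibull shape parameter (WSP) classifies the hazard profile: a 95% CI
for the shape entirely below 1 means *early failure* (decreasing hazard),
an interval containing 1 means *random failure* (constant hazard), and an
interval entirely above 1 means *wear-out failure* (increasing hazard).

Spontaneous reports exist only because the event occurred, so every onset
record is an observed event — there is no censoring model here; cumulative
incidence is the empirical CDF of onset times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import optimize, stats

from faersig.cohort import CohortAssignment
from faersig.faers_io import SafetyReport

FAILURE_TYPES = ("early", "random", "wear_out")

#: histogram bands in days: 0-1 year, 1-5 years, >5 years
DEFAULT_YEAR_BANDS = ((0, 365), (365, 1826), (1826, None))


@dataclass(frozen=True)
class OnsetRecord:
    case_id: str
    group: str
    onset_days: int

    def __post_init__(self) -> None:
        if self.onset_days < 0:
            raise ValueError("onset_days must be non-negative")


@dataclass(frozen=True)
class WeibullFit:
    shape: float
    scale: float  # days
    shape_lo95: float
    shape_hi95: float
    scale_lo95: float
    scale_hi95: float
    failure_type: str
    n: int
    loglik: float


def compute_onsets(
    reports: Sequence[SafetyReport],
    assignments: Mapping[str, CohortAssignment],
    names_a: set[str],
    names_b: set[str],
    groups: Sequence[str] = ("A_only", "B_only", "A_plus_B"),
) -> tuple[list[OnsetRecord], dict[str, int]]:
    """Onset records for each grouped report with day-precision dates.

    The therapy start is the earliest start date among the report's target
    drug entries (drug A for A_only, drug B for B_only, either for the
    combination group). Negative onsets are excluded and counted.
    """
    records: list[OnsetRecord] = []
    excluded = {"missing_dates": 0, "negative": 0}
    target_names = {"A_only": names_a, "B_only": names_b, "A_plus_B": names_a | names_b}
    for r in reports:
        a = assignments.get(r.case_id)
        if a is None or a.group not in groups:
            continue
        names = target_names.get(a.group, names_a | names_b)
        starts = [d.start_date for d in r.drugs
                  if d.name_std in names and d.start_date is not None]
        if not starts or r.event_date is None:
            excluded["missing_dates"] += 1
            continue
        onset = (r.event_date - min(starts)).days
        if onset < 0:
            excluded["negative"] += 1
            continue
        records.append(OnsetRecord(case_id=r.case_id, group=a.group, onset_days=onset))
    return records, excluded


def _weibull_nll(theta: np.ndarray, t: np.ndarray) -> float:
    log_k, log_lam = theta
    k, lam = math.exp(log_k), math.exp(log_lam)
    z = t / lam
    return -float(np.sum(np.log(k / lam) + (k - 1) * np.log(z) - z**k))


def weibull_fit(onsets: Iterable[float], min_n: int = 10) -> WeibullFit:
    """Maximum-likelihood Weibull fit with a normal-approximation 95% CI for
    the shape on the log scale, and the failure-type label.

    Uses the profile likelihood: the shape solves the standard 1-D score
    equation, the scale follows in closed form; the CI comes from the
    observed information at the optimum.
    """
    t = np.asarray(sorted(onsets), dtype=float)
    if t.size < min_n:
        raise ValueError(f"need at least {min_n} onsets for classification, got {t.size}")
    if np.any(t <= 0):
        raise ValueError("onset times must be positive for the Weibull fit")
    if t[0] == t[-1]:
        raise ValueError("degenerate likelihood: all onset values identical")

    log_t = np.log(t)
    mean_log = float(log_t.mean())

    def score(k: float) -> float:
        w = t**k
        return 1.0 / k + mean_log - float(np.sum(w * log_t) / np.sum(w))

    lo, hi = 1e-3, 1.0
    while score(hi) > 0 and hi < 1e3:
        hi *= 2.0
    k_hat = float(optimize.brentq(score, lo, hi, xtol=1e-12))
    lam_hat = float(np.mean(t**k_hat) ** (1.0 / k_hat))

    theta = np.array([math.log(k_hat), math.log(lam_hat)])
    # observed information via central finite differences on (log k, log lam)
    h = 1e-4
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * h
            e_j = np.eye(2)[j] * h
            hess[i, j] = (
                _weibull_nll(theta + e_i + e_j, t) - _weibull_nll(theta + e_i - e_j, t)
                - _weibull_nll(theta - e_i + e_j, t) + _weibull_nll(theta - e_i - e_j, t)
            ) / (4 * h * h)
    cov = np.linalg.inv(hess)
    se_logk, se_loglam = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    z = 1.959963984540054
    shape_lo, shape_hi = k_hat * math.exp(-z * se_logk), k_hat * math.exp(z * se_logk)
    scale_lo, scale_hi = lam_hat * math.exp(-z * se_loglam), lam_hat * math.exp(z * se_loglam)

    if shape_hi < 1.0:
        ftype = "early"
    elif shape_lo > 1.0:
        ftype = "wear_out"
    else:
        ftype = "random"

    return WeibullFit(
        shape=k_hat, scale=lam_hat,
        shape_lo95=shape_lo, shape_hi95=shape_hi,
        scale_lo95=scale_lo, scale_hi95=scale_hi,
        failure_type=ftype, n=int(t.size), loglik=-_weibull_nll(theta, t),
    )


def _rank_sum_normal(a: np.ndarray, b: np.ndarray, continuity: bool = True
                     ) -> tuple[float, float]:
    """Tie-corrected normal approximation of the Wilcoxon rank-sum test."""
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:na].sum())
    mean_w = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return 0.0, 1.0
    diff = w - mean_w
    cc = 0.5 * np.sign(diff) if continuity else 0.0
    z = (diff - cc) / math.sqrt(var_w)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(z), float(p)


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive enumeration of the rank-sum null distribution (midranks,
    so ties are handled); two-sided p = P(|W - E W| >= |w_obs - E W|)."""
    na = a.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:na].sum())
    mean_w = na * (pooled.size + 1) / 2.0
    d_obs = abs(w_obs - mean_w)
    hits = total = 0
    for idx in combinations(range(pooled.size), na):
        w = float(ranks[list(idx)].sum())
        total += 1
        if abs(w - mean_w) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def rank_sum_compare(a: Sequence[float], b: Sequence[float],
                     exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two onset samples.

    Exact enumeration when both samples have at most ``exact_max_n``
    observations; tie-corrected normal approximation (with continuity
    correction) otherwise. Returns (z, p).
    """
    arr_a = np.asarray(list(a), dtype=float)
    arr_b = np.asarray(list(b), dtype=float)
    if arr_a.size == 0 or arr_b.size == 0:
        raise ValueError("both samples must be non-empty")
    z, p_norm = _rank_sum_normal(arr_a, arr_b)
    if arr_a.size <= exact_max_n and arr_b.size <= exact_max_n:
        return z, _rank_sum_exact(arr_a, arr_b)
    return z, p_norm


def cumulative_incidence(
    groups: Mapping[str, Sequence[float]]
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Empirical cumulative incidence per group plus the log-rank test.

    Every onset is an observed event (no censoring). Returns the per-group
    step functions (columns ``time``, ``cum_incidence``; nondecreasing from
    0 to 1) and the log-rank chi-square and p (chi2_1 for two groups).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    steps: dict[str, pd.DataFrame] = {}
    for g, vals in groups.items():
        v = np.asarray(sorted(vals), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {g!r} has no onsets")
        times, counts = np.unique(v, return_counts=True)
        cum = np.cumsum(counts) / v.size
        steps[g] = pd.DataFrame({
            "time": np.concatenate([[0.0], times]),
            "cum_incidence": np.concatenate([[0.0], cum]),
        })

    names = list(groups)
    if len(names) == 2:
        res = logrank_test(
            np.asarray(groups[names[0]], dtype=float),
            np.asarray(groups[names[1]], dtype=float),
        )
    else:
        times = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
        labels = np.concatenate([[g] * len(groups[g]) for g in names])
        res = multivariate_logrank_test(times, labels)
    return steps, float(res.test_statistic), float(res.p_value)


def onset_summary(
    onsets: Sequence[float],
    bands: Sequence[tuple[int, int | None]] = DEFAULT_YEAR_BANDS,
    method: str = "linear",
) -> dict:
    """Median and quartiles (linear-interpolation convention by default;
    ``method`` takes any numpy quantile method name) plus counts per
    onset band in days."""
    v = np.asarray(list(onsets), dtype=float)
    if v.size == 0:
        raise ValueError("no onsets to summarize")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method=method)
    band_counts = []
    for lo, hi in bands:
        label = f"{lo}-{hi} d" if hi is not None else f">={lo} d"
        inb = (v >= lo) & (v < hi) if hi is not None else v >= lo
        band_counts.append({"band": label, "count": int(inb.sum())})
    return {
        "n": int(v.size),
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "bands": pd.DataFrame(band_counts, columns=["band", "count"]),
    }
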