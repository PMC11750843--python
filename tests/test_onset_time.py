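"""Onset computation, Weibull shape classification, rank-sum and log-rank."""

from __future__ import annotations

import math
from datetime import date
from itertools import combinations

import numpy as np
import pytest

from faersig.cohort import assign_groups
from faersig.faers_io import DrugEntry, ReactionEntry, SafetyReport
from faersig.onset_time import (
    _rank_sum_exact,
    _rank_sum_normal,
    compute_onsets,
    cumulative_incidence,
    onset_summary,
    rank_sum_compare,
    weibull_fit,
)

A = {"infliximab", "remicade"}
B = {"azathioprine"}


def _report(case_id: str, start: date | None, event: date | None,
            drug: str = "infliximab", role: str = "PS") -> SafetyReport:
    return SafetyReport(
        case_id=case_id, version_key=(1, 0, 0), event_date=event,
        therapy_start_date=start,
        drugs=(DrugEntry(drug.upper(), drug, role, start_date=start),),
        reactions=(ReactionEntry("Lymphoma"),),
    )


class TestComputeOnsets:
    def test_date_arithmetic(self):
        reps = [_report("1", date(2020, 1, 1), date(2020, 1, 31))]
        asn = assign_groups(reps, A, B)
        recs, excl = compute_onsets(reps, asn, A, B)
        assert len(recs) == 1
        assert recs[0].onset_days == 30
        assert excl == {"missing_dates": 0, "negative": 0}

    def test_event_before_start_excluded(self):
        reps = [_report("1", date(2020, 2, 1), date(2020, 1, 1))]
        asn = assign_groups(reps, A, B)
        recs, excl = compute_onsets(reps, asn, A, B)
        assert recs == []
        assert excl["negative"] == 1

    def test_missing_dates_counted(self):
        reps = [_report("1", None, date(2020, 1, 1)),
                _report("2", date(2020, 1, 1), None)]
        asn = assign_groups(reps, A, B)
        recs, excl = compute_onsets(reps, asn, A, B)
        assert recs == []
        assert excl["missing_dates"] == 2

    def test_earliest_start_of_multiple_therapy_episodes(self):
        rep = SafetyReport(
            case_id="1", version_key=(1, 0, 0), event_date=date(2020, 6, 1),
            drugs=(DrugEntry("REMICADE", "remicade", "PS", start_date=date(2020, 3, 1)),
                   DrugEntry("INFLIXIMAB", "infliximab", "SS", start_date=date(2020, 1, 1))),
            reactions=(ReactionEntry("Lymphoma"),),
        )
        asn = assign_groups([rep], A, B)
        recs, _ = compute_onsets([rep], asn, A, B)
        assert recs[0].onset_days == (date(2020, 6, 1) - date(2020, 1, 1)).days


class TestWeibullFit:
    def test_exponential_special_case_consistency(self):
        rng = np.random.default_rng(21)
        t = 900.0 * rng.weibull(1.0, 10_000)
        fit = weibull_fit(t)
        assert abs(fit.shape - 1.0) < 0.03  # <3% bias at n = 1e4
        assert fit.scale == pytest.approx(t.mean(), rel=0.03)  # shape=1: mean=scale
        assert fit.failure_type == "random"

    def test_sampled_median_matches_closed_form(self):
        rng = np.random.default_rng(22)
        t = 1000.0 * rng.weibull(1.0, 5000)
        assert np.median(t) == pytest.approx(1000.0 * math.log(2), rel=0.10)

    def test_interval_rule_labels(self):
        rng = np.random.default_rng(23)
        early = weibull_fit(900.0 * rng.weibull(0.5, 2000))
        wear = weibull_fit(900.0 * rng.weibull(2.0, 2000))
        assert early.failure_type == "early" and early.shape_hi95 < 1.0
        assert wear.failure_type == "wear_out" and wear.shape_lo95 > 1.0

    def test_ci_matches_profile_likelihood(self):
        # normal-approximation CI on log-shape vs profile-likelihood CI
        rng = np.random.default_rng(24)
        t = 500.0 * rng.weibull(1.3, 200)
        fit = weibull_fit(t)

        log_t = np.log(t)

        def profile_ll(k: float) -> float:
            lam = float(np.mean(t**k) ** (1.0 / k))
            z = t / lam
            return float(np.sum(np.log(k / lam) + (k - 1) * np.log(z) - z**k))

        ll_max = profile_ll(fit.shape)
        from scipy.optimize import brentq
        cut = ll_max - 1.9207294  # chi2_1(0.95)/2
        lo = brentq(lambda k: profile_ll(k) - cut, 1e-3, fit.shape)
        hi = brentq(lambda k: profile_ll(k) - cut, fit.shape, 10.0)
        assert fit.shape_lo95 == pytest.approx(lo, rel=0.05)
        assert fit.shape_hi95 == pytest.approx(hi, rel=0.05)

    def test_degenerate_and_small_samples_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            weibull_fit([5.0] * 50)
        with pytest.raises(ValueError, match="at least"):
            weibull_fit([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="positive"):
            weibull_fit([0.0] + list(range(1, 20)))


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        z, p = rank_sum_compare([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        # all 20 rank assignments enumerable by hand: one-sided tail 1/20
        z, p = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)

    def test_normal_approximation_close_to_exact_partitions(self):
        # spot-check 60 of the 924 partitions here; the exhaustive sweep is
        # in the acceptance suite
        vals = np.arange(1.0, 13.0)
        for i, idx in enumerate(combinations(range(12), 6)):
            if i % 15:
                continue
            a = vals[list(idx)]
            b = np.delete(vals, list(idx))
            _, p_norm = _rank_sum_normal(a, b)
            p_exact = _rank_sum_exact(a, b)
            assert abs(p_norm - p_exact) <= 0.02

    def test_z_sign_flips_with_group_order(self):
        z1, _ = rank_sum_compare(list(range(20)), list(range(10, 30)))
        z2, _ = rank_sum_compare(list(range(10, 30)), list(range(20)))
        assert z1 == pytest.approx(-z2)


class TestCumulativeIncidence:
    def test_identical_groups_null_statistic(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        _, chi2, p = cumulative_incidence({"x": vals, "y": list(vals)})
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_step_functions_are_proper_cdfs(self):
        rng = np.random.default_rng(25)
        steps, _, _ = cumulative_incidence(
            {"x": 900 * rng.weibull(1.0, 50), "y": 700 * rng.weibull(0.8, 40)})
        for df in steps.values():
            inc = df["cum_incidence"].to_numpy()
            assert inc[0] == 0.0
            assert inc[-1] == pytest.approx(1.0)
            assert (np.diff(inc) >= 0).all()

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(26)
        x = list(900 * rng.weibull(1.0, 30))
        y = list(900 * rng.weibull(1.2, 25))
        _, c1, p1 = cumulative_incidence({"x": x, "y": y})
        _, c2, p2 = cumulative_incidence({"y": y, "x": x})
        assert c1 == pytest.approx(c2)
        assert p1 == pytest.approx(p2)

    def test_matches_brute_force_risk_set_tally(self):
        # hand-computable 10-event dataset, all events observed
        g1 = [1.0, 3.0, 5.0, 7.0, 9.0]
        g2 = [2.0, 4.0, 6.0, 8.0, 10.0]
        times = sorted(g1 + g2)
        o_minus_e = 0.0
        var = 0.0
        for t in times:
            n1 = sum(1 for v in g1 if v >= t)
            n2 = sum(1 for v in g2 if v >= t)
            n = n1 + n2
            d = 1  # all event times distinct
            o1 = sum(1 for v in g1 if v == t)
            e1 = n1 * d / n
            o_minus_e += o1 - e1
            if n > 1:
                var += n1 * n2 * d * (n - d) / (n**2 * (n - 1))
        brute_chi2 = o_minus_e**2 / var
        _, chi2, _ = cumulative_incidence({"g1": g1, "g2": g2})
        assert chi2 == pytest.approx(brute_chi2, rel=1e-9)


class TestOnsetSummary:
    def test_odd_and_even_medians(self):
        assert onset_summary([100, 200, 300])["median"] == 200
        assert onset_summary([1, 2, 3, 4])["median"] == 2.5

    def test_quartiles_match_interpolation_oracle(self):
        rng = np.random.default_rng(27)
        for _ in range(100):
            v = rng.integers(1, 3000, size=int(rng.integers(5, 60))).astype(float)
            s = onset_summary(v)
            srt = np.sort(v)

            def oracle(q: float) -> float:
                h = (len(srt) - 1) * q
                lo = int(math.floor(h))
                hi = min(lo + 1, len(srt) - 1)
                return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

            assert s["q25"] == pytest.approx(oracle(0.25))
            assert s["median"] == pytest.approx(oracle(0.5))
            assert s["q75"] == pytest.approx(oracle(0.75))

    def test_year_band_histogram(self):
        s = onset_summary([10, 400, 2000])
        assert list(s["bands"]["count"]) == [1, 1, 1]
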