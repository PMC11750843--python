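"""Disproportionality statistics against closed forms, brute-force oracles,
sampling oracles, and the documented invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import special, stats

from faersig.cohort import assign_groups
from faersig.faers_io import DrugEntry, ReactionEntry, SafetyReport
from faersig.signal_stats import (
    ContingencyTable,
    GpsPrior,
    _G11, _A1, _B1, _AA, _BB,
    bcpnn_ic,
    build_tables,
    chi2_stat,
    conjunction,
    ebgm_stat,
    fit_gps_prior,
    fit_gps_prior_counts,
    prr_stat,
    ror_stat,
    score_table,
)

REFERENCE_PRIOR = GpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, p_mix=1 / 3)


def _random_tables(n: int, seed: int) -> list[ContingencyTable]:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(ContingencyTable(
            a=int(rng.integers(1, 80)), b=int(rng.integers(20, 5000)),
            c=int(rng.integers(1, 800)), d=int(rng.integers(500, 100_000))))
    return out


class TestBuildTables:
    def _reports(self, spec: list[tuple[str, list[tuple[str, str]], tuple[str, ...]]]):
        return [
            SafetyReport(case_id=cid, version_key=(1, 0, 0),
                         drugs=tuple(DrugEntry(n.upper(), n, r) for n, r in drugs),
                         reactions=tuple(ReactionEntry(p) for p in pts))
            for cid, drugs, pts in spec
        ]

    def test_direct_counts(self, lexicon):
        reports = self._reports([
            ("1", [("infliximab", "PS")], ("Lymphoma",)),
            ("2", [("infliximab", "PS")], ("Headache",)),
            ("3", [("aspirin", "PS")], ("Headache",)),
            ("4", [("aspirin", "PS")], ("Nausea",)),
        ])
        asn = assign_groups(reports, {"infliximab"}, {"azathioprine"})
        tabs = dict(build_tables(reports, asn, lexicon, "A_only"))
        assert (tabs["Lymphoma"].a, tabs["Lymphoma"].b,
                tabs["Lymphoma"].c, tabs["Lymphoma"].d) == (1, 1, 0, 2)

    def test_repeated_pt_counts_once(self, lexicon):
        reports = self._reports([
            ("1", [("infliximab", "PS")], ("Lymphoma", "Lymphoma")),
            ("2", [("aspirin", "PS")], ("Headache",)),
        ])
        asn = assign_groups(reports, {"infliximab"}, {"azathioprine"})
        tabs = dict(build_tables(reports, asn, lexicon, "A_only"))
        assert tabs["Lymphoma"].a == 1

    def test_empty_background_is_fatal(self, lexicon):
        reports = self._reports([("1", [("infliximab", "PS")], ("Lymphoma",))])
        asn = assign_groups(reports, {"infliximab"}, {"azathioprine"})
        with pytest.raises(ValueError, match="background"):
            build_tables(reports, asn, lexicon, "A_only")


class TestRor:
    def test_symmetric_table_is_null(self):
        ror, lo, hi, passed = ror_stat(ContingencyTable(10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        assert not passed

    def test_hand_evaluated_closed_form(self):
        ror, lo, hi, passed = ror_stat(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(math.exp(math.log(11.0) - 1.959963984540054 * se))
        assert hi == pytest.approx(math.exp(math.log(11.0) + 1.959963984540054 * se))
        assert passed

    def test_point_estimate_scale_invariant_ci_tightens(self):
        r_small = ror_stat(ContingencyTable(3, 1, 1, 3))
        r_big = ror_stat(ContingencyTable(30, 10, 10, 30))
        assert r_small[0] == pytest.approx(9.0)
        assert r_big[0] == pytest.approx(9.0)
        assert (r_big[2] - r_big[1]) < (r_small[2] - r_small[1])

    def test_zero_cell_corrected_and_not_significant(self):
        ror, lo, hi, passed = ror_stat(ContingencyTable(0, 100, 50, 5000))
        assert math.isfinite(ror) and ror > 0
        assert not passed


class TestPrr:
    def test_tenfold_reporting_rate(self):
        prr, chi2, passed = prr_stat(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0)
        assert passed

    def test_exact_independence(self):
        prr, chi2, _ = prr_stat(ContingencyTable(10, 90, 90, 810))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_brute_force_expected_counts(self):
        for t in _random_tables(20, seed=2):
            observed = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
            rows = observed.sum(axis=1, keepdims=True)
            cols = observed.sum(axis=0, keepdims=True)
            expected = rows @ cols / observed.sum()
            brute = float(((observed - expected) ** 2 / expected).sum())
            assert chi2_stat(t) == pytest.approx(brute, rel=1e-12)


class TestBcpnn:
    def test_independence_limit(self):
        ic, ic025, passed = bcpnn_ic(ContingencyTable(1000, 9000, 9000, 81000))
        assert abs(ic) < 0.05
        assert not passed

    def test_asymptotic_consistency(self):
        # scale a tenfold-overreported table up; IC -> log2(relative rate)
        base = (10, 90, 100, 9900)
        rr = 10 / ContingencyTable(*base).expected
        scaled = ContingencyTable(*(x * 1000 for x in base))
        ic, _, _ = bcpnn_ic(scaled)
        assert ic == pytest.approx(math.log2(rr), abs=0.01)

    def test_moments_match_posterior_sampling(self):
        # 2e5 posterior draws per table; the full-size oracle run lives in
        # the acceptance suite
        rng = np.random.default_rng(3)
        for t in _random_tables(5, seed=4):
            a, n1, m1, n = t.a, t.a + t.b, t.a + t.c, t.n
            gamma = _G11 * (n + _AA) * (n + _BB) / ((n1 + _A1) * (m1 + _B1))
            p11 = rng.beta(a + _G11, n - a + gamma - _G11, 200_000)
            p1 = rng.beta(n1 + _A1, n - n1 + _AA - _A1, 200_000)
            p2 = rng.beta(m1 + _B1, n - m1 + _BB - _B1, 200_000)
            draws = np.log2(p11 / (p1 * p2))
            ic, ic025, _ = bcpnn_ic(t)
            assert ic == pytest.approx(float(draws.mean()), abs=0.05)
            assert ic025 == pytest.approx(float(draws.mean() - 2 * draws.std()), abs=0.1)


class TestGpsPrior:
    def test_null_data_concentrates_near_one(self):
        # a = E exactly, large counts -> prior mass piles up at lambda = 1
        e = np.full(400, 50.0)
        a = np.full(400, 50.0)
        prior = fit_gps_prior_counts(a, e)
        w = prior.p_mix
        mean = w * prior.alpha1 / prior.beta1 + (1 - w) * prior.alpha2 / prior.beta2
        assert mean == pytest.approx(1.0, abs=0.1)

    def test_optimum_beats_default_start(self):
        tabs = _random_tables(200, seed=6)
        prior = fit_gps_prior(tabs)
        a = np.array([t.a for t in tabs], dtype=float)
        e = np.array([t.expected for t in tabs])
        from faersig.signal_stats import _gps_nll, DEFAULT_GPS_START
        s = DEFAULT_GPS_START
        x0 = np.array([math.log(s[0]), math.log(s[1]), math.log(s[2]),
                       math.log(s[3]), special.logit(s[4])])
        assert prior.loglik >= -_gps_nll(x0, a, e) - 1e-9
        assert prior.converged

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_gps_prior([])
        with pytest.raises(ValueError):
            GpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, p_mix=1.5)


class TestEbgm:
    def test_single_component_conjugacy_limit(self):
        prior = GpsPrior(alpha1=2.0, beta1=4.0, alpha2=2.0, beta2=4.0, p_mix=0.5)
        t = ContingencyTable(10, 90, 100, 9900)
        ebgm, eb05, _ = ebgm_stat(t, prior)
        shape, rate = 2.0 + t.a, 4.0 + t.expected
        assert ebgm == pytest.approx(math.exp(special.digamma(shape) - math.log(rate)),
                                     rel=1e-10)
        assert eb05 == pytest.approx(stats.gamma.ppf(0.05, shape, scale=1 / rate),
                                     abs=1e-6)

    def test_zero_count_shrinks_below_one(self):
        ebgm, eb05, passed = ebgm_stat(ContingencyTable(0, 100, 50, 5000),
                                       REFERENCE_PRIOR)
        assert ebgm < 1.0
        assert not passed

    def test_eb05_matches_posterior_draws(self):
        rng = np.random.default_rng(8)
        from faersig.signal_stats import _posterior_mixture
        for t in _random_tables(5, seed=9):
            q1, s1, r1, s2, r2 = _posterior_mixture(t, REFERENCE_PRIOR)
            comp = rng.random(500_000) < q1
            lam = np.where(comp, rng.gamma(s1, 1 / r1, 500_000),
                           rng.gamma(s2, 1 / r2, 500_000))
            _, eb05, _ = ebgm_stat(t, REFERENCE_PRIOR)
            assert eb05 == pytest.approx(float(np.percentile(lam, 5)), abs=0.05)


class TestInvariants:
    def test_monotone_in_a_with_margins_refilled(self):
        # holding b, c, d fixed, every statistic is nondecreasing in a
        b, c, d = 400, 120, 20_000
        prev = None
        for a in (1, 3, 8, 20, 50):
            t = ContingencyTable(a, b, c, d)
            cur = (ror_stat(t)[0], prr_stat(t)[0], bcpnn_ic(t)[0],
                   ebgm_stat(t, REFERENCE_PRIOR)[0])
            if prev is not None:
                assert all(x >= p - 1e-12 for x, p in zip(cur, prev))
            prev = cur

    def test_shrinkage_bounds(self):
        # upper bound holds for any elevated table; the lower bound needs
        # enough evidence (a >= 10) for the posterior to clear the null
        for t in _random_tables(300, seed=10):
            rr = t.a / t.expected
            if rr <= 1.0:
                continue
            ic = bcpnn_ic(t)[0]
            ebgm = ebgm_stat(t, REFERENCE_PRIOR)[0]
            assert ic <= math.log2(rr) + 1e-9
            assert ebgm <= rr + 1e-9
            if t.a >= 10 and rr >= 1.5:
                assert ic >= -1e-9
                assert ebgm >= 1.0 - 1e-9


@pytest.mark.parametrize(
    ("flags", "expected"),
    [((True, True, True, True), True),
     ((False, True, True, True), False),
     ((True, True, False, True), False),
     ((False, False, False, False), False)],
)
def test_conjunction_rule(flags, expected):
    assert conjunction(*flags) is expected


def test_score_table_flags_are_consistent():
    t = ContingencyTable(25, 500, 40, 20_000)
    s = score_table(t, REFERENCE_PRIOR)
    assert s.significant == (s.pass_ror and s.pass_prr and s.pass_bcpnn and s.pass_mgps)
    assert s.ror_lo95 <= s.ror <= s.ror_hi95
    assert s.ic025 <= s.ic
    assert s.eb05 <= s.ebgm
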