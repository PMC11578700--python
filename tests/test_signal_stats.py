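"""Disproportionality statistics against independent oracles and invariants."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from bptox.cohort import CaseFlag
from bptox.signal_stats import (
    ContingencyTable,
    DEFAULT_CRITERIA,
    DEFAULT_MGPS_START,
    MgpsPrior,
    ReportUniverse,
    SignalCriteria,
    bcpnn_ic,
    build_table,
    build_table_for_ids,
    ebgm,
    fit_mgps_prior,
    mgps_marginal_loglik,
    prr_chi2,
    ror,
    scan,
    score_table,
)
from bptox.io_faers import PtSocMap, SmqDefinition
from bptox.synth import packaged_pt_soc_map, packaged_smq

import pandas as pd


def random_tables(rng, n, low=1, high=400):
    tables = []
    while len(tables) < n:
        a, b, c, d = (int(rng.integers(low, high)) for _ in range(4))
        tables.append(ContingencyTable(a, b, c, d))
    return tables


def universe_of(pairs):
    df = pd.DataFrame(pairs, columns=["primaryid", "pt"])
    return ReportUniverse(df, df["primaryid"].unique())


class TestBuildTable:
    def test_event_vs_case_level_counting(self):
        # one report with two SMQ PTs: 2 events but 1 case
        pairs = [("1", "OESOPHAGITIS"), ("1", "DYSPHAGIA"), ("2", "HEADACHE"), ("3", "RASH")]
        uni = universe_of(pairs)
        flags = [CaseFlag("1", "ALN", frozenset({"OESOPHAGITIS", "DYSPHAGIA"}))]
        ev = build_table(flags, uni, "ALN", {"OESOPHAGITIS", "DYSPHAGIA"}, "event")
        ca = build_table(flags, uni, "ALN", {"OESOPHAGITIS", "DYSPHAGIA"}, "case")
        assert (ev.a, ev.b) == (2, 0)
        assert (ca.a, ca.b) == (1, 0)
        assert ev.c == 0 and ev.d == 2
        assert ca.n == 3  # three reports

    def test_absent_target_drug(self):
        uni = universe_of([("1", "HEADACHE")])
        t = build_table([], uni, "ALN", {"OESOPHAGITIS"}, "event")
        assert t.a == 0 and t.b == 0

    def test_matches_brute_force_double_loop(self, rng):
        pts = [f"PT{i}" for i in range(6)]
        pairs = sorted({(str(rng.integers(20)), pts[rng.integers(6)]) for _ in range(60)})
        uni = universe_of(pairs)
        target = {str(i) for i in range(8)}
        events = {"PT0", "PT1"}
        for level in ("event", "case"):
            t = build_table_for_ids(uni, target, events, level)
            if level == "event":
                a = sum(1 for pid, pt in pairs if pid in target and pt in events)
                b = sum(1 for pid, pt in pairs if pid in target and pt not in events)
                c = sum(1 for pid, pt in pairs if pid not in target and pt in events)
                d = len(pairs) - a - b - c
            else:
                reports = {pid for pid, _ in pairs}
                with_event = {pid for pid, pt in pairs if pt in events}
                a = len(with_event & target & reports)
                b = len(target & reports) - a
                c = len(with_event - target)
                d = len(reports) - a - b - c
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_negative_or_empty_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestRor:
    def test_symmetric_table_is_null(self):
        est, lo, hi = ror(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_known_value_and_ci_formula(self):
        est, lo, hi = ror(ContingencyTable(20, 10, 10, 20))
        assert est == pytest.approx(4.0)
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert lo == pytest.approx(4.0 * math.exp(-1.96 * se), rel=1e-4)
        assert hi == pytest.approx(4.0 * math.exp(1.96 * se), rel=1e-4)

    def test_row_swap_inverts(self):
        est, _, _ = ror(ContingencyTable(20, 10, 10, 20))
        inv, _, _ = ror(ContingencyTable(10, 20, 20, 10))
        assert inv == pytest.approx(1.0 / est)

    def test_zero_cell_incomputable_without_correction(self):
        assert all(math.isnan(x) for x in ror(ContingencyTable(0, 10, 10, 10)))
        est, lo, hi = ror(ContingencyTable(0, 10, 10, 10), continuity_correction=True)
        assert math.isfinite(est) and lo < est < hi

    def test_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for t in random_tables(rng, 50):
            table2x2 = sm.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
            est, lo, hi = ror(t)
            assert est == pytest.approx(table2x2.oddsratio, rel=1e-10)
            sm_lo, sm_hi = table2x2.oddsratio_confint(0.05)
            assert lo == pytest.approx(sm_lo, rel=1e-8)
            assert hi == pytest.approx(sm_hi, rel=1e-8)


class TestPrrChi2:
    def test_independence_gives_null(self):
        prr, chi2 = prr_chi2(ContingencyTable(10, 30, 20, 60))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_chi2_matches_scipy_oracle(self, rng):
        for t in random_tables(rng, 50):
            _, chi2 = prr_chi2(t)
            oracle, _, _, _ = stats.chi2_contingency(
                np.array([[t.a, t.b], [t.c, t.d]]), correction=False
            )
            assert chi2 == pytest.approx(oracle, rel=1e-10)

    def test_doubling_cells_fixes_prr_doubles_chi2(self):
        t1 = ContingencyTable(20, 10, 10, 20)
        t2 = ContingencyTable(40, 20, 20, 40)
        p1, c1 = prr_chi2(t1)
        p2, c2 = prr_chi2(t2)
        assert p2 == pytest.approx(p1)
        assert c2 == pytest.approx(2 * c1)

    def test_degenerate_margin_incomputable(self):
        prr, _ = prr_chi2(ContingencyTable(5, 5, 0, 10))
        assert math.isnan(prr)


class TestBcpnn:
    def test_depletion_direction(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(0, 1000, 1000, 100000))
        assert ic < 0 and ic025 < ic

    def test_independence_limit(self):
        # a equals expected exactly; IC -> 0 as N grows
        prev = abs(bcpnn_ic(ContingencyTable(10, 90, 90, 810))[0])
        for scale in (10, 100):
            t = ContingencyTable(10 * scale, 90 * scale, 90 * scale, 810 * scale)
            cur = abs(bcpnn_ic(t)[0])
            assert cur < prev
            prev = cur
        assert prev < 0.01

    def test_matches_monte_carlo_posterior(self, rng):
        """Closed-form IC and IC025 vs a 10^6-draw beta posterior sampler."""
        draws = 1_000_000
        for _ in range(10):
            a = int(rng.integers(50, 400))
            b = int(rng.integers(200, 2000))
            c = int(rng.integers(200, 2000))
            d = int(rng.integers(5000, 50000))
            t = ContingencyTable(a, b, c, d)
            n, r1, c1 = t.n, a + b, a + c
            gamma = (n + 2.0) * (n + 2.0) / ((r1 + 1.0) * (c1 + 1.0))
            p11 = rng.beta(a + 1.0, gamma + n - a - 1.0, size=draws)
            p1 = rng.beta(r1 + 1.0, 2.0 - 1.0 + n - r1, size=draws)
            p2 = rng.beta(c1 + 1.0, 2.0 - 1.0 + n - c1, size=draws)
            ic_draws = np.log2(p11 / (p1 * p2))
            ic, ic025 = bcpnn_ic(t)
            assert ic == pytest.approx(float(ic_draws.mean()), abs=0.02)
            assert ic025 == pytest.approx(float(ic_draws.mean() - 2 * ic_draws.std()), abs=0.02)


TRUE_PRIOR = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def simulate_from_prior(prior, n_pairs, rng):
    e = rng.uniform(0.5, 50.0, size=n_pairs)
    comp = rng.random(n_pairs) < prior.p_mix
    lam = np.where(
        comp,
        rng.gamma(prior.alpha1, 1.0 / prior.beta1, size=n_pairs),
        rng.gamma(prior.alpha2, 1.0 / prior.beta2, size=n_pairs),
    )
    a = rng.poisson(lam * e)
    return a, e


class TestMgps:
    def test_optimizer_contract_and_recovery(self, rng):
        a, e = simulate_from_prior(TRUE_PRIOR, 2000, rng)
        fitted = fit_mgps_prior((a, e))
        ll_fit = mgps_marginal_loglik(fitted, a, e)
        ll_true = mgps_marginal_loglik(TRUE_PRIOR, a, e)
        ll_start = mgps_marginal_loglik(DEFAULT_MGPS_START, a, e)
        assert ll_fit >= ll_start - 1e-6
        assert ll_fit >= ll_true - 1.0

    def test_null_data_concentrates_near_one(self, rng):
        e = rng.uniform(500, 5000, size=400)
        a = np.rint(e).astype(int)  # observed equals expected, huge counts
        fitted = fit_mgps_prior((a, e))
        point, _ = ebgm((float(a[0]), float(e[0])), fitted)
        assert point == pytest.approx(1.0, abs=0.05)

    def test_too_few_strata_rejected(self):
        with pytest.raises(ValueError):
            fit_mgps_prior(([5.0], [2.0]))

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            MgpsPrior(0.2, -0.1, 2.0, 4.0, 0.3)
        with pytest.raises(ValueError):
            MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.5)


class TestEbgm:
    def test_single_component_matches_quadrature(self, rng):
        """Degenerate mixture: EBGM equals the digamma closed form and both
        match numerical integration of the gamma posterior."""
        prior = MgpsPrior(2.0, 1.0, 2.0, 1.0, 0.5)  # both components identical
        for _ in range(10):
            a = float(rng.integers(0, 60))
            e = float(rng.uniform(0.5, 30))
            point, q05 = ebgm((a, e), prior)
            shape, rate = 2.0 + a, 1.0 + e
            closed = math.exp(special.digamma(shape) - math.log(rate))
            assert point == pytest.approx(closed, rel=1e-10)
            num, _ = integrate.quad(
                lambda lam: math.log(lam) * stats.gamma.pdf(lam, shape, scale=1 / rate), 0, np.inf
            )
            assert point == pytest.approx(math.exp(num), rel=1e-7)
            assert stats.gamma.cdf(q05, shape, scale=1 / rate) == pytest.approx(0.05, abs=1e-9)

    def test_posterior_cdf_at_ebgm05(self, rng):
        for _ in range(20):
            a = float(rng.integers(0, 200))
            e = float(rng.uniform(0.5, 100))
            _, q05 = ebgm((a, e), TRUE_PRIOR)
            w = _posterior_cdf(TRUE_PRIOR, a, e, q05)
            assert w == pytest.approx(0.05, abs=1e-6)

    def test_shrinkage_toward_null_and_convergence(self):
        # small a: EBGM pulled toward 1 relative to a/E; large a: EBGM -> a/E
        small = ebgm((4.0, 1.0), TRUE_PRIOR)[0]
        assert 1.0 < small < 4.0
        big = ebgm((4000.0, 1000.0), TRUE_PRIOR)[0]
        assert big == pytest.approx(4.0, rel=0.01)

    def test_zero_count_shrinks_below_one(self):
        point, _ = ebgm((0.0, 50.0), TRUE_PRIOR)
        assert point < 1.0


def _posterior_cdf(prior, a, e, q):
    from bptox.signal_stats import _posterior_mixture

    (w1, w2), shapes, rates = _posterior_mixture(prior, a, e)
    return w1 * stats.gamma.cdf(q, shapes[0], scale=1 / rates[0]) + w2 * stats.gamma.cdf(
        q, shapes[1], scale=1 / rates[1]
    )


class TestFlags:
    def test_minimum_count_rule(self):
        # huge ROR but a = 2: no algorithm may flag via ROR/PRR
        s = score_table(ContingencyTable(2, 1, 1, 10000), TRUE_PRIOR)
        assert not s.flag_ror and not s.flag_prr and not s.joint_significant

    def test_independence_all_false(self):
        s = score_table(ContingencyTable(10, 90, 90, 810), TRUE_PRIOR)
        assert not any((s.flag_ror, s.flag_prr, s.flag_bcpnn, s.flag_mgps))

    def test_strong_signal_all_true(self):
        s = score_table(ContingencyTable(200, 800, 250, 20000), TRUE_PRIOR)
        assert s.joint_significant
        assert s.ror_ci_low < s.ror < s.ror_ci_high
        assert s.ic025 < s.ic
        assert s.ebgm05 < s.ebgm

    def test_flags_monotone_in_a_with_margins_fixed(self):
        """Growing a (swapping b out) never turns a true ROR/PRR flag false."""
        prev = None
        for a in range(3, 60, 8):
            s = score_table(ContingencyTable(a, 500 - a, 100, 10000), TRUE_PRIOR)
            if prev is not None and prev.flag_ror:
                assert s.flag_ror
            if prev is not None and prev.flag_prr:
                assert s.flag_prr
            prev = s


class TestScan:
    def _flags_universe(self):
        pairs = (
            [(f"t{i}", "OESOPHAGITIS") for i in range(30)]
            + [(f"t{i}", "NAUSEA") for i in range(30, 40)]
            + [(f"u{i}", pt) for i in range(400) for pt in [f"PT{i % 12}"]]
            + [(f"u{i}", "OESOPHAGITIS") for i in range(8)]
        )
        uni = universe_of(pairs)
        flags = [
            CaseFlag(f"t{i}", "ALN", frozenset({"OESOPHAGITIS"}) if i < 30 else frozenset())
            for i in range(40)
        ]
        return flags, uni

    def test_single_pt_smq_scan(self):
        flags, uni = self._flags_universe()
        smq = SmqDefinition("S", frozenset({"OESOPHAGITIS"}))
        pt_soc = PtSocMap({"OESOPHAGITIS": "GI", "NAUSEA": "GI"})
        out = scan(flags, uni, ["PT"], pt_soc, smq, prior=TRUE_PRIOR)
        assert [s.term for s in out["PT"]] == ["OESOPHAGITIS"]
        assert out["PT"][0].a == 30

    def test_top_k_ranking_by_a_desc(self):
        flags, uni = self._flags_universe()
        smq = SmqDefinition("S", frozenset({f"PT{i}" for i in range(12)} | {"OESOPHAGITIS"}))
        pt_soc = PtSocMap({})
        out = scan(flags, uni, ["PT"], pt_soc, smq, prior=TRUE_PRIOR, top_k=10)
        rows = out["PT"]
        assert len(rows) == 10
        assert all(rows[i].a >= rows[i + 1].a for i in range(9))

    def test_soc_totals_reconcile_with_build_table(self):
        flags, uni = self._flags_universe()
        smq = SmqDefinition("S", frozenset({"OESOPHAGITIS"}))
        pt_soc = PtSocMap({"OESOPHAGITIS": "GI", "NAUSEA": "GI"})
        out = scan(flags, uni, ["SOC", "SMQ"], pt_soc, smq, prior=TRUE_PRIOR)
        # accounting identity: sum of per-SOC a equals the drug's total pairs
        target_ids = {f.primaryid for f in flags}
        total_target_pairs = int(uni.pairs["primaryid"].isin(target_ids).sum())
        assert sum(s.a for s in out["SOC"]) == total_target_pairs
        # unmapped PTs land in the UNMAPPED bucket
        assert any(s.term == "UNMAPPED" for s in out["SOC"])
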