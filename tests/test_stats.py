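"""Disproportionality statistics against independent numeric oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats as sps

from pvsignals.cohort import build_index
from pvsignals.stats import (ContingencyTable, MgpsPrior, build_contingency,
                             classify_signals, compute_ebgm, compute_ic,
                             compute_ror, fit_mgps_prior, ic025_closed_form,
                             EbgmResult, IcResult, RorResult, SignalResult)

from conftest import demo

FIXED_PRIOR = MgpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0,
                        p=1.0 / 3.0, converged=True)


def table_from_margins(a, n_drug, n_event, N):
    return ContingencyTable(a=a, b=n_drug - a, c=n_event - a,
                            d=N - n_drug - n_event + a)


class TestContingency:
    def test_margin_arithmetic(self):
        kept = [demo(str(i)) for i in range(100)]
        ps = {str(i): {"dX"} for i in range(10)}
        gip = {str(i): {"PT1"} for i in range(5, 25)}
        idx = build_index(kept, ps, gip)
        t = build_contingency(idx, "dX", "PT1")
        assert (t.a, t.b, t.c, t.d) == (5, 5, 15, 75)
        assert t.N == 100 and t.E == pytest.approx(10 * 20 / 100)

    def test_zero_overlap(self):
        kept = [demo(str(i)) for i in range(100)]
        ps = {str(i): {"dX"} for i in range(10)}
        gip = {str(i): {"PT1"} for i in range(50, 70)}
        t = build_contingency(build_index(kept, ps, gip), "dX", "PT1")
        assert (t.a, t.b, t.c, t.d) == (0, 10, 20, 70)

    def test_unknown_drug_raises(self):
        idx = build_index([demo("1")], {"1": {"dX"}}, {"1": {"PT1"}})
        with pytest.raises(KeyError):
            build_contingency(idx, "nope", "PT1")


class TestRor:
    def test_symmetric_table_is_null(self):
        r = compute_ror(ContingencyTable(5, 95, 5, 95))
        assert r.ror == pytest.approx(1.0)
        assert not r.significant

    def test_wald_interval(self):
        # exp(ln 11 - 1.96*sqrt(1/10+1/90+1/100+1/9900)) = 5.559515
        r = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert r.ror == pytest.approx(11.0)
        assert r.ror05 == pytest.approx(5.559515, abs=1e-5)
        assert r.ror95 == pytest.approx(21.7645, abs=1e-3)
        assert r.significant

    def test_case_floor_blocks_single_report(self):
        r = compute_ror(ContingencyTable(1, 1, 1, 100_000))
        assert r.ror05 > 1 and not r.significant

    def test_zero_cell_undefined_not_significant(self):
        r = compute_ror(ContingencyTable(0, 10, 20, 70))
        assert not r.defined and not r.significant
        assert math.isnan(r.ror)


class TestIc:
    def test_equal_shrunk_counts_give_zero(self):
        t = table_from_margins(1, 10, 10, 100)  # E = 1
        assert compute_ic(t).ic == pytest.approx(0.0)

    def test_point_and_quantile_oracle(self):
        t = table_from_margins(8, 10, 10, 100)  # a=8, E=1
        ic = compute_ic(t)
        assert ic.ic == pytest.approx(math.log2(8.5 / 1.5), abs=1e-12)
        # independent gamma-quantile oracle on the natural scale
        lo = sps.gamma.ppf(0.025, 8.5, scale=1 / 1.5)
        assert ic.ic025 == pytest.approx(math.log2(lo), abs=1e-12)
        assert abs(ic.ic025 - ic.ic025_approx) < 0.1
        assert ic.significant

    def test_zero_count_negative_and_non_significant(self):
        t = table_from_margins(0, 10, 20, 100)  # E = 2
        ic = compute_ic(t)
        assert ic.ic < 0 and not ic.significant

    def test_closed_form_matches_quantile_on_grid(self):
        for a in [3, 5, 8, 15, 40, 100, 500]:
            for E in [0.1, 0.5, 1, 5, 20, 100]:
                exact = math.log2(sps.gamma.ppf(0.025, a + 0.5,
                                                scale=1 / (E + 0.5)))
                assert abs(exact - ic025_closed_form(a, E)) < 0.1, (a, E)

    def test_interval_ordering(self):
        ic = compute_ic(table_from_margins(4, 20, 30, 500))
        assert ic.ic025 < ic.ic < ic.ic975


def quadrature_ebgm(a, E, prior):
    """Independent oracle: numeric integration of E[ln lambda] over the
    posterior mixture density."""
    l1 = (special.gammaln(a + prior.alpha1) - special.gammaln(prior.alpha1)
          - special.gammaln(a + 1)
          + prior.alpha1 * math.log(prior.beta1 / (prior.beta1 + E))
          + a * math.log(E / (prior.beta1 + E)) + math.log(prior.p))
    l2 = (special.gammaln(a + prior.alpha2) - special.gammaln(prior.alpha2)
          - special.gammaln(a + 1)
          + prior.alpha2 * math.log(prior.beta2 / (prior.beta2 + E))
          + a * math.log(E / (prior.beta2 + E)) + math.log(1 - prior.p))
    q = 1.0 / (1.0 + math.exp(l2 - l1))

    def pdf(x):
        return (q * sps.gamma.pdf(x, prior.alpha1 + a,
                                  scale=1 / (prior.beta1 + E))
                + (1 - q) * sps.gamma.pdf(x, prior.alpha2 + a,
                                          scale=1 / (prior.beta2 + E)))

    val, _ = integrate.quad(lambda x: math.log(x) * pdf(x), 0, np.inf,
                            limit=300)
    return math.exp(val)


class TestEbgm:
    def test_golden_fixture_matches_quadrature(self):
        # a=5, E=1 under the conventional prior; value frozen from the
        # quadrature oracle
        t = table_from_margins(5, 10, 10, 100)
        r = compute_ebgm(t, FIXED_PRIOR)
        assert r.ebgm == pytest.approx(3.81118500, rel=1e-6)
        assert r.q == pytest.approx(0.902430, abs=1e-6)
        assert r.ebgm05 == pytest.approx(0.979806, abs=1e-5)
        assert r.ebgm95 == pytest.approx(9.427950, abs=1e-5)
        assert r.ebgm == pytest.approx(quadrature_ebgm(5, 1.0, FIXED_PRIOR),
                                       rel=1e-6)

    def test_large_count_consistency(self):
        # a=1000, E=100: shrinkage is negligible, EBGM ~ a/E = 10
        t = table_from_margins(1000, 10_000, 10_000, 1_000_000)
        r = compute_ebgm(t, FIXED_PRIOR)
        assert r.ebgm == pytest.approx(10.0, rel=0.05)

    def test_zero_count_ordering_and_non_significance(self):
        t = table_from_margins(0, 10, 50, 1000)
        r = compute_ebgm(t, FIXED_PRIOR)
        assert r.ebgm05 < r.ebgm < r.ebgm95
        assert not r.significant

    def test_shrinkage_releases_with_information(self):
        # fixed a/E = 5; the posterior mean climbs toward 5 as a grows
        prev = 0.0
        for a in (1, 5, 25, 125):
            # margins 10a/10a over N=500a give E = a/5 exactly
            t = table_from_margins(a, 10 * a, 10 * a, 500 * a)
            assert t.E == pytest.approx(a / 5)
            r = compute_ebgm(t, FIXED_PRIOR)
            assert r.ebgm > prev
            prev = r.ebgm
        assert prev > 4.0

    def test_refuses_unconverged_prior(self):
        bad = MgpsPrior(0.2, 0.1, 2, 4, 0.3, converged=False)
        with pytest.raises(ValueError):
            compute_ebgm(table_from_margins(5, 10, 10, 100), bad)


class TestMgpsFit:
    def test_pair_floor_enforced(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_mgps_prior([1, 2, 3], [1.0, 1.0, 1.0])

    def test_single_component_pushes_weight_to_boundary(self):
        rng = np.random.default_rng(11)
        E = rng.uniform(0.5, 5, 4000)
        lam = rng.gamma(2.0, 1 / 4.0, 4000)
        a = rng.poisson(lam * E)
        prior = fit_mgps_prior(a, E, seed=2)
        assert prior.converged
        # effectively all weight on one Gamma(2,4)-like component
        w_comp1 = prior.p
        mean1, mean2 = prior.alpha1 / prior.beta1, prior.alpha2 / prior.beta2
        dominant = mean1 if w_comp1 > 0.5 else mean2
        assert max(w_comp1, 1 - w_comp1) > 0.85
        assert dominant == pytest.approx(0.5, rel=0.25)


class TestMonotonicity:
    """For fixed margins, all three statistics increase strictly in a."""

    N, n_drug, n_event = 10_000, 200, 300

    def _tables(self):
        return [table_from_margins(a, self.n_drug, self.n_event, self.N)
                for a in range(2, 30, 3)]

    def test_ror_monotone(self):
        vals = [compute_ror(t).ror for t in self._tables()]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_ic_monotone(self):
        vals = [compute_ic(t).ic for t in self._tables()]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_ebgm_monotone(self):
        vals = [compute_ebgm(t, FIXED_PRIOR).ebgm for t in self._tables()]
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestClassify:
    def _result(self, drug, event, sig):
        t = table_from_margins(5, 10, 10, 100)
        r_ror, r_ic, r_ebgm = sig
        return SignalResult(
            drug=drug, event=event, table=t,
            ror=RorResult(2, 1.5, 3, 5, r_ror),
            ic=IcResult(1, 0.5 if r_ic else -0.5, 2, r_ic),
            ebgm=EbgmResult(3, 2.5 if r_ebgm else 1, 5, 0.9, r_ebgm))

    def test_counts_and_overlap(self):
        results = [self._result("d1", "p1", (True, True, True)),
                   self._result("d1", "p2", (True, True, False)),
                   self._result("d1", "p3", (False, False, False))]
        s = classify_signals(results)["d1"]
        assert (s.n_sig_ror, s.n_sig_ic, s.n_sig_ebgm) == (2, 2, 1)
        assert s.in_overlap

    def test_all_false(self):
        s = classify_signals([self._result("d", "p",
                                           (False, False, False))])["d"]
        assert (s.n_sig_ror, s.n_sig_ic, s.n_sig_ebgm) == (0, 0, 0)
        assert not s.in_overlap
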