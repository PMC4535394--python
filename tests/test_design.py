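"""Sample-space enumeration, exact pmf and operating characteristics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from simon2stage import (
    ConfigurationError,
    InfeasibleDesignError,
    InvalidOutcomeError,
    SimonDesign,
    SupportError,
    TrialOutcome,
    enumerate_paths,
    operating_characteristics,
    pmf,
    pmf_or_zero,
    reject_h0,
    search_design,
)
from simon2stage.design import support_paths


class TestDesignInvariants:
    def test_derived_n2(self, gi_design):
        assert gi_design.n2 == 20

    @pytest.mark.parametrize("kwargs", [
        dict(r1=5, n1=5, rt=6, nt=10),       # r1 must be < n1
        dict(r1=3, n1=5, rt=2, nt=10),       # rt must be >= r1
        dict(r1=1, n1=5, rt=5, nt=5),        # nt must exceed rt and n1
        dict(r1=1, n1=5, rt=5, nt=10, pi0=0.4, pi1=0.3),
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimonDesign(**kwargs)

    def test_outcome_consistency_checked(self, gi_design):
        with pytest.raises(InvalidOutcomeError):
            TrialOutcome(m=1, x1=5).validate(gi_design)  # 5 > r1 cannot stop
        with pytest.raises(InvalidOutcomeError):
            TrialOutcome(m=2, x1=2, x2=1, n2_actual=6).validate(gi_design)
        with pytest.raises(InvalidOutcomeError):
            TrialOutcome(m=2, x1=5, x2=9, n2_actual=6)

    def test_serialization_round_trip(self, gi_design):
        assert SimonDesign.from_dict(gi_design.to_dict()) == gi_design


class TestPmf:
    def test_tiny_design_closed_form(self, tiny_design):
        """Three paths: f(1,0)=1-p, f(2,1)=p(1-p), f(2,2)=p^2, summing to 1."""
        for p in (0.0, 0.1, 0.5, 0.9, 1.0):
            f10 = pmf(tiny_design, 1, 1, 0, p)
            f21 = pmf(tiny_design, 1, 2, 1, p)
            f22 = pmf(tiny_design, 1, 2, 2, p)
            assert f10 == pytest.approx(1 - p, abs=1e-15)
            assert f21 == pytest.approx(p * (1 - p), abs=1e-15)
            assert f22 == pytest.approx(p**2, abs=1e-15)
            assert f10 + f21 + f22 == pytest.approx(1.0, abs=1e-12)

    def test_stage1_path_is_binomial_mass(self, gi_design):
        # oracle: direct binomial pmf C(19,2) 0.15^2 0.85^17
        expect = math.comb(19, 2) * 0.15**2 * 0.85**17
        assert pmf(gi_design, 6, 1, 2, 0.15) == pytest.approx(expect, rel=1e-12)

    def test_out_of_support_raises_named_boundary(self, gi_design):
        with pytest.raises(SupportError, match="r1"):
            pmf(gi_design, 6, 1, 5, 0.5)
        with pytest.raises(SupportError):
            pmf(gi_design, 6, 2, 2, 0.5)   # s below r1+1 at stage 2
        with pytest.raises(SupportError):
            pmf(gi_design, 6, 2, 26, 0.5)  # s above n1 + n2_actual
        assert pmf_or_zero(gi_design, 6, 1, 5, 0.5) == 0.0

    def test_stage1_marginal_matches_binomial_cdf(self, gi_design):
        """Total stage-1 mass equals P(Bin(n1, p) <= r1)."""
        for p in (0.1, 0.37, 0.8):
            mass = sum(pmf(gi_design, 6, 1, s, p) for s in range(gi_design.r1 + 1))
            assert mass == pytest.approx(binom.cdf(gi_design.r1, gi_design.n1, p),
                                         abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 6), st.integers(2, 14), st.integers(1, 30),
           st.floats(0.0, 1.0, allow_nan=False))
    def test_normalization_property(self, r1, extra_n1, n2_actual, p):
        """Enumerated probabilities sum to one for arbitrary configurations."""
        n1 = r1 + extra_n1
        design = SimonDesign(r1=r1, n1=n1, rt=r1 + 1, nt=n1 + 5)
        dist = enumerate_paths(design, n2_actual, p)
        assert dist.total() == pytest.approx(1.0, abs=1e-12)
        assert len(dist) == (r1 + 1) + (n1 + n2_actual - r1)

    def test_support_size_for_observed_trial(self, gi_design):
        assert len(support_paths(gi_design, 6)) == 26

    def test_degenerate_rates(self, gi_design):
        dist = enumerate_paths(gi_design, 6, 0.0)
        probs = dict(((m, s), p) for m, s, p in dist)
        assert probs[(1, 0)] == 1.0
        assert sum(probs.values()) == 1.0


class TestRejectionRule:
    def test_stage1_stop_never_rejects(self, gi_design):
        assert reject_h0(gi_design, TrialOutcome(m=1, x1=2)) is False

    def test_planned_size_reduces_to_threshold(self, gi_design):
        rt, n2 = gi_design.rt, gi_design.n2
        at_boundary = TrialOutcome(m=2, x1=4, x2=rt - 4, n2_actual=n2)
        above = TrialOutcome(m=2, x1=4, x2=rt - 3, n2_actual=n2)
        assert reject_h0(gi_design, at_boundary) is False
        assert reject_h0(gi_design, above) is True

    def test_threshold_equivalence_exhaustive(self, small_designs):
        """At the planned stage-2 size the conditional criterion is exactly
        the design's threshold rule on every path."""
        for d in small_designs:
            dd = d.with_rates(pi0=0.3, pi1=0.6)
            for x1 in range(dd.r1 + 1, dd.n1 + 1):
                for x2 in range(dd.n2 + 1):
                    o = TrialOutcome(m=2, x1=x1, x2=x2, n2_actual=dd.n2)
                    assert reject_h0(dd, o) == (x1 + x2 > dd.rt)

    def test_deviated_size_requires_pi0(self, gi_design, gi_outcome):
        bare = SimonDesign(r1=3, n1=19, rt=8, nt=39)
        with pytest.raises(ConfigurationError):
            reject_h0(bare, gi_outcome)
        assert isinstance(reject_h0(gi_design, gi_outcome), bool)


class TestOperatingCharacteristics:
    def test_certain_response(self, gi_design):
        oc = operating_characteristics(gi_design, 1.0)
        assert oc.reject_prob == pytest.approx(1.0, abs=1e-12)
        assert oc.pet == 0.0
        assert oc.expected_n == gi_design.nt

    def test_pet_is_binomial_cdf(self):
        d = SimonDesign(r1=3, n1=17, rt=10, nt=37)
        oc = operating_characteristics(d, 0.2)
        assert oc.pet == pytest.approx(binom.cdf(3, 17, 0.2), abs=1e-14)
        assert oc.expected_n == pytest.approx(17 + (1 - oc.pet) * 20, abs=1e-12)

    def test_reject_prob_consistent_with_pathwise_rule(self, small_designs):
        """Summing pmf over paths the decision rule rejects reproduces the
        closed-form rejection probability."""
        for d in small_designs:
            dd = d.with_rates(pi0=0.25, pi1=0.5)
            for p in (0.2, 0.5, 0.85):
                dist = enumerate_paths(dd, dd.n2, p)
                total = 0.0
                for x1 in range(dd.r1 + 1, dd.n1 + 1):
                    for x2 in range(dd.n2 + 1):
                        o = TrialOutcome(m=2, x1=x1, x2=x2, n2_actual=dd.n2)
                        if reject_h0(dd, o):
                            total += (binom.pmf(x1, dd.n1, p)
                                      * binom.pmf(x2, dd.n2, p))
                assert total == pytest.approx(
                    operating_characteristics(dd, p).reject_prob, abs=1e-12)


class TestDesignSearch:
    def _brute_force(self, pi0, pi1, alpha, beta, n_max):
        """Independent exhaustive search used as an oracle."""
        feasible = []
        for nt in range(2, n_max + 1):
            for n1 in range(1, nt):
                n2 = nt - n1
                for rt in range(0, nt):
                    for r1 in range(0, min(n1 - 1, rt) + 1):
                        xs = np.arange(r1 + 1, n1 + 1)
                        a = float(np.sum(binom.pmf(xs, n1, pi0)
                                         * binom.sf(rt - xs, n2, pi0)))
                        if a > alpha:
                            continue
                        pw = float(np.sum(binom.pmf(xs, n1, pi1)
                                          * binom.sf(rt - xs, n2, pi1)))
                        if pw < 1 - beta:
                            continue
                        en = n1 + (1 - binom.cdf(r1, n1, pi0)) * n2
                        feasible.append((en, nt, n1, r1, rt))
        return feasible

    def test_optimal_matches_brute_force(self):
        pi0, pi1, alpha, beta = 0.1, 0.5, 0.1, 0.2
        got = search_design(pi0, pi1, alpha, beta, criterion="optimal", n_max=16)
        feas = self._brute_force(pi0, pi1, alpha, beta, 16)
        en, nt, n1, r1, rt = min(feas)
        assert (got.r1, got.n1, got.rt, got.nt) == (r1, n1, rt, nt)
        oc0 = operating_characteristics(got, pi0)
        assert oc0.expected_n == pytest.approx(en, abs=1e-10)

    def test_minimax_minimizes_total_size(self):
        pi0, pi1, alpha, beta = 0.1, 0.5, 0.1, 0.2
        got = search_design(pi0, pi1, alpha, beta, criterion="minimax", n_max=16)
        feas = self._brute_force(pi0, pi1, alpha, beta, 16)
        assert got.nt == min(nt for _, nt, *_ in feas)

    def test_returned_design_satisfies_constraints(self):
        d = search_design(0.2, 0.5, 0.1, 0.2, n_max=25)
        assert operating_characteristics(d, 0.2).reject_prob <= 0.1
        assert operating_characteristics(d, 0.5).reject_prob >= 0.8

    def test_vacuous_constraints_return_smallest_design(self):
        d = search_design(0.2, 0.4, 0.9999, 0.9999, n_max=10)
        assert (d.r1, d.n1, d.rt, d.nt) == (0, 1, 0, 2)

    def test_infeasible_raises(self):
        with pytest.raises(InfeasibleDesignError):
            search_design(0.2, 0.25, 0.05, 0.1, n_max=12)
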