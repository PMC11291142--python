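"""Closed-form monoecious recursions, equilibria, and invasion thresholds."""

import math

import numpy as np
import pytest

from parentaldrive import (
    DriveParams,
    MonoeciousState,
    critical_ratio,
    critical_selfing,
    delta_p,
    equilibrium_Y,
    equilibrium_Y_fixed_point,
    internal_equilibrium_p,
    mean_fitness,
    neutral_fixation_index,
    oracle_step,
    step,
    step_pY,
)
from parentaldrive.monoecy import implicit_equilibrium_residual
from conftest import random_params, random_simplex_states


class TestRecursions:
    def test_closed_forms_match_oracle(self, rng):
        """Genotype recursion, (p, Y) recursion, and brute-force enumeration
        agree to machine precision over random states and parameters."""
        for v in random_simplex_states(rng, 400):
            state = MonoeciousState(*v)
            params = random_params(rng)
            a = oracle_step(state, params)
            b = step(state, params)
            pn, Yn, wbar = step_pY(state.p, state.Y, params)
            assert abs(a.X - b.X) < 1e-12
            assert abs(a.Y - b.Y) < 1e-12
            assert abs(a.Z - b.Z) < 1e-12
            assert abs(a.p - pn) < 1e-12
            assert abs(a.Y - Yn) < 1e-12
            assert wbar == pytest.approx(
                float(mean_fitness(state.p, state.Y, params)), abs=1e-14
            )

    def test_no_heterozygotes_no_selection(self):
        """Y = 0 gives wbar = 1 and conserved p; under complete selfing the
        genotype frequencies themselves are frozen."""
        state = MonoeciousState(0.3, 0.0, 0.7)
        frozen = step(state, DriveParams(k1=1.0, k2=1.0, S=1.0))
        assert (frozen.X, frozen.Y, frozen.Z) == pytest.approx((0.3, 0.0, 0.7), abs=1e-14)
        mixed = step(state, DriveParams(k1=1.0, k2=1.0, S=0.5))
        assert mixed.p == pytest.approx(state.p, abs=1e-14)
        assert float(mean_fitness(state.p, 0.0, DriveParams(k1=1, k2=1, S=0.5))) == 1.0

    def test_equal_penetrance_mean_fitness(self, rng):
        """For k1 = k2 = k, mean fitness collapses to 1 - Y k / 2."""
        for _ in range(20):
            p, k, S = rng.uniform(), rng.uniform(), rng.uniform()
            Y = rng.uniform(0, 2 * min(p, 1 - p))
            params = DriveParams(k1=k, k2=k, S=S)
            assert float(mean_fitness(p, Y, params)) == pytest.approx(
                1 - Y * k / 2, abs=1e-14
            )

    def test_random_mating_equal_penetrance_is_neutral(self, rng):
        """Hedrick's result: with S = 0 and k1 = k2, p' = p for every p."""
        params = DriveParams(k1=0.9, k2=0.9, S=0.0)
        for _ in range(20):
            p = rng.uniform()
            Y = rng.uniform(0, 2 * min(p, 1 - p))
            pn, _, _ = step_pY(p, Y, params)
            assert pn == pytest.approx(p, abs=1e-14)

    def test_outcrossing_restores_heterozygotes(self):
        """From Y = 0, one generation gives Y' = (1-S) 2pq / wbar > 0."""
        params = DriveParams(k1=0.9, k2=0.5, S=0.7)
        p = 0.3
        pn, Yn, wbar = step_pY(p, 0.0, params)
        assert Yn == pytest.approx((1 - 0.7) * 2 * 0.3 * 0.7 / wbar)
        assert Yn > 0

    def test_single_medea_update_form(self, rng):
        """With k2 = 0: p' = p / wbar, wbar = 1 - (Y k1/2)(S/2 + (1-S) q)."""
        for _ in range(20):
            p, k1, S = rng.uniform(), rng.uniform(), rng.uniform()
            Y = rng.uniform(0, 2 * min(p, 1 - p))
            params = DriveParams(k1=k1, k2=0.0, S=S)
            pn, _, wbar = step_pY(p, Y, params)
            expected_w = 1 - (Y * k1 / 2) * (S / 2 + (1 - S) * (1 - p))
            assert wbar == pytest.approx(expected_w, abs=1e-14)
            assert pn == pytest.approx(p / wbar, abs=1e-14)


class TestInternalEquilibrium:
    def test_equal_penetrance_equilibrium_is_half(self):
        for S in (0.0, 0.3, 0.9, 1.0):
            assert internal_equilibrium_p(S, 1.0) == 0.5

    def test_published_value(self):
        phat = internal_equilibrium_p(0.6, 1.8)
        assert round(phat, 2) == 0.28
        assert abs(float(implicit_equilibrium_residual(phat, 0.6, 1.8))) < 1e-10

    def test_no_equilibrium_under_obligate_outcrossing(self):
        assert internal_equilibrium_p(0.0, 2.0) is None
        assert internal_equilibrium_p(0.0, 0.3) is None

    def test_complete_selfing_limit(self):
        assert internal_equilibrium_p(1.0, 2.0) == pytest.approx(1 / 3)
        # continuity of the limit
        assert internal_equilibrium_p(1 - 1e-9, 2.0) == pytest.approx(1 / 3, abs=1e-6)

    def test_threshold_increases_with_selfing(self):
        vals = [internal_equilibrium_p(S, 2.0) for S in np.arange(0.05, 1.0, 0.05)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1 / 3

    def test_agrees_with_dynamical_bisection_oracle(self):
        """Independent oracle: bisect for the p where the full recursion
        leaves p unchanged (at fixed Y), without using the equilibrium
        formula at all."""
        for S, r in [(0.3, 2.0), (0.6, 1.8), (0.8, 5.0), (0.5, 0.4)]:
            params = DriveParams(k1=min(1.0, r), k2=min(1.0, r) / r, S=S)

            def net_change(p):
                Y = 0.9 * 2 * min(p, 1 - p)  # any Y > 0 works
                return step_pY(p, Y, params)[0] - p

            lo, hi = 1e-9, 1 - 1e-9
            assert net_change(lo) * net_change(hi) < 0
            for _ in range(200):
                mid = (lo + hi) / 2
                if net_change(lo) * net_change(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            assert internal_equilibrium_p(S, r) == pytest.approx(
                (lo + hi) / 2, abs=1e-8
            )

    def test_depends_only_on_penetrance_ratio(self):
        a = internal_equilibrium_p(0.4, 1.0 / 0.5)
        params1 = DriveParams(k1=1.0, k2=0.5, S=0.4)
        params2 = DriveParams(k1=0.5, k2=0.25, S=0.4)
        for params in (params1, params2):
            assert abs(float(implicit_equilibrium_residual(a, 0.4, params.r))) < 1e-10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            internal_equilibrium_p(0.5, 0.0)
        with pytest.raises(ValueError):
            internal_equilibrium_p(1.5, 2.0)


class TestEquilibriumHeterozygosity:
    def test_published_equal_penetrance_value(self):
        """Ternary-plot equilibrium: Y-hat ~ 0.61 at p = 0.5, k = 0.9, S = 0.3."""
        val = equilibrium_Y(0.5, DriveParams(k1=0.9, k2=0.9, S=0.3))
        assert round(val, 2) == 0.61

    def test_published_unequal_penetrance_value(self):
        params = DriveParams(k1=0.9, k2=0.5, S=0.6)
        phat = internal_equilibrium_p(0.6, params.r)
        assert round(equilibrium_Y(phat, params), 2) == 0.27

    def test_complete_selfing_gives_zero(self):
        assert equilibrium_Y(0.4, DriveParams(k1=0.8, k2=0.6, S=1.0)) == pytest.approx(
            0.0, abs=1e-14
        )

    @pytest.mark.parametrize("p,k1,k2,S", [
        (0.5, 0.9, 0.9, 0.3),
        (0.28029366598359207, 0.9, 0.5, 0.6),
        (0.7, 0.4, 0.8, 0.2),
        (0.2, 1.0, 1.0, 0.8),
    ])
    def test_fixed_point_iteration_confirms_closed_form(self, p, k1, k2, S):
        params = DriveParams(k1=k1, k2=k2, S=S)
        closed = equilibrium_Y(p, params)
        iterated = equilibrium_Y_fixed_point(p, params, tol=1e-12)
        assert closed == pytest.approx(iterated, abs=1e-8)

    def test_equal_penetrance_reduction(self):
        """The equal-penetrance expression (K = k) agrees with the general
        one at p = q = 0.5."""
        for k, S in [(0.9, 0.3), (0.5, 0.7), (1.0, 0.1)]:
            general = equilibrium_Y(0.5, DriveParams(k1=k, k2=k, S=S))
            reduced = (1 - S / 2 - math.sqrt(S**2 / 4 + (1 - S) + (S - 1) * k)) / k
            assert general == pytest.approx(reduced, abs=1e-14)

    def test_heterozygote_excess_boundary(self):
        """At p = 0.5 with equal penetrance k, the fixation index
        F = 1 - Y-hat/(2pq) is negative exactly when S < k/2."""
        k = 0.9
        for S, expect_negative in [(0.30, True), (0.44, True), (0.46, False), (0.8, False)]:
            Yhat = equilibrium_Y(0.5, DriveParams(k1=k, k2=k, S=S))
            F = 1 - Yhat / (2 * 0.5 * 0.5)
            assert (F < 0) == expect_negative

    def test_rejects_boundary_p(self):
        with pytest.raises(ValueError):
            equilibrium_Y(0.0, DriveParams(k1=0.9, k2=0.9, S=0.3))

    def test_rejects_neutral_locus(self):
        with pytest.raises(ValueError, match="no toxin"):
            equilibrium_Y(0.5, DriveParams(k1=0.0, k2=0.0, S=0.3))


class TestInvasionThresholds:
    def test_critical_selfing_worked_example(self):
        """An invader at p = 0.01, fifty-fold more penetrant, is eliminated
        once S exceeds ~0.66; dynamics confirm the bracket."""
        sc = critical_selfing(0.01, 50.0)
        assert sc == pytest.approx(0.6644, abs=1e-4)
        params = DriveParams(k1=1.0, k2=0.02)
        for S, invades in [(sc - 0.02, True), (sc + 0.02, False)]:
            p, Y = 0.01, 0.0
            for _ in range(200):
                p, Y, _ = step_pY(p, Y, params.with_(S=S))
            assert (p > 0.01) == invades

    def test_critical_selfing_figure_value(self):
        assert round(critical_selfing(0.2, 0.9 / 0.5), 2) == 0.37

    def test_equal_penetrance_has_zero_threshold(self):
        assert critical_selfing(0.3, 1.0) == 0.0

    def test_critical_selfing_consistent_with_equilibrium(self):
        """S_C is exactly the selfing rate whose internal equilibrium sits at
        the invader's frequency."""
        for p, r in [(0.01, 50.0), (0.2, 1.8), (0.1, 4.0)]:
            sc = critical_selfing(p, r)
            assert internal_equilibrium_p(sc, r) == pytest.approx(p, abs=1e-10)

    def test_critical_ratio_worked_example(self):
        """At S = 0.9 an invader at p = 0.01 needs more than ~81x the
        resident's penetrance to sweep."""
        rc = critical_ratio(0.01, 0.9)
        assert round(rc) == 81
        assert rc == pytest.approx(81.328, abs=1e-3)

    def test_critical_ratio_symmetry_and_limits(self):
        assert critical_ratio(0.5, 0.3) == pytest.approx(1.0)
        assert critical_ratio(0.2, 0.0) == pytest.approx(1.0)
        assert critical_ratio(0.3, 1.0) == math.inf
        assert critical_ratio(0.0, 0.5) == math.inf

    def test_critical_ratio_consistent_with_equilibrium(self):
        for p, S in [(0.01, 0.9), (0.2, 0.5)]:
            rc = critical_ratio(p, S)
            assert internal_equilibrium_p(S, rc) == pytest.approx(p, abs=1e-10)


class TestFrequencyDependence:
    def test_delta_p_sign_structure(self):
        """Positive frequency dependence for equal penetrances under partial
        selfing: the common allele gains, the rare allele loses."""
        params = DriveParams(k1=0.9, k2=0.9, S=0.5)
        assert delta_p(0.5, 0.4, params) == pytest.approx(0.0, abs=1e-14)
        assert delta_p(0.3, 0.4, params) < 0
        assert delta_p(0.7, 0.4, params) > 0

    def test_single_medea_sweeps_for_all_selfing_rates(self):
        """A lone element invades from p = 0.04 and fixes whenever S < 1."""
        for S in (0.0, 0.3, 0.7, 0.95):
            params = DriveParams(k1=1.0, k2=0.0, S=S)
            p, Y = 0.04, 0.0
            prev = p
            for _ in range(3000):
                p, Y, _ = step_pY(p, Y, params)
                assert p >= prev - 1e-15
                prev = p
            assert p > 0.999

    def test_bistability_around_internal_equilibrium(self):
        """Starting above p-hat fixes M1; starting below loses it."""
        params = DriveParams(k1=0.9, k2=0.5, S=0.6)
        phat = internal_equilibrium_p(0.6, params.r)
        for p0, fixes in [(phat + 0.02, True), (phat - 0.02, False)]:
            p, Y = p0, 0.0
            for _ in range(2000):
                p, Y, _ = step_pY(p, Y, params)
            assert (p > 0.999) == fixes
            assert (p < 0.001) == (not fixes)

    def test_exactly_at_equilibrium_stays(self):
        """The equilibrium is unstable, so float round-off eventually leaks,
        but a population placed exactly at p-hat shows no systematic motion
        over a hundred generations regardless of heterozygosity."""
        params = DriveParams(k1=0.9, k2=0.5, S=0.6)
        phat = internal_equilibrium_p(0.6, params.r)
        p, Y = phat, 0.2
        for _ in range(100):
            p, Y, _ = step_pY(p, Y, params)
        assert p == pytest.approx(phat, abs=1e-6)


def test_neutral_fixation_index():
    assert neutral_fixation_index(0.0) == 0.0
    assert neutral_fixation_index(1.0) == 1.0
    assert neutral_fixation_index(0.5) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        neutral_fixation_index(1.2)
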