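"""Closed-form recovery curves: limits, values and regime degeneracies."""

import math

import numpy as np
import pytest

from frapkit import PhysicalParams
from frapkit.analytic import (recovery_effective_diffusion,
                              recovery_first_order,
                              recovery_pure_diffusion,
                              recovery_rapid_equilibration,
                              recovery_reaction_limited, soumpasis,
                              soumpasis_series)


def soumpasis_by_series(z: float, terms: int = 60) -> float:
    """Independent oracle: direct power-series summation of I0 and I1."""
    i0 = sum((z / 2) ** (2 * k) / math.factorial(k) ** 2
             for k in range(terms))
    i1 = sum((z / 2) ** (2 * k + 1) / (math.factorial(k)
                                       * math.factorial(k + 1))
             for k in range(terms))
    return math.exp(-z) * (i0 + i1)


class TestSoumpasis:
    def test_limits(self):
        assert soumpasis(0.0) == pytest.approx(1.0)
        assert soumpasis(1e-12) == pytest.approx(1.0, abs=1e-10)
        assert soumpasis(1e12) == pytest.approx(0.0, abs=1e-5)
        assert soumpasis(np.inf) == 0.0

    def test_value_at_one_against_series_oracle(self):
        expected = soumpasis_by_series(1.0)
        assert expected == pytest.approx(0.6736, abs=5e-4)
        assert soumpasis(1.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            soumpasis(-0.1)

    def test_no_overflow_at_huge_argument(self):
        v = soumpasis(np.array([1e4, 1e8, 1e300]))
        assert np.all(np.isfinite(v)) and np.all(v >= 0)

    def test_strictly_decreasing(self):
        z = np.logspace(-6, 6, 400)
        f = soumpasis(z)
        assert np.all(np.diff(f) < 0)

    def test_agrees_with_asymptotic_series_at_crossover(self):
        # the two evaluation routes must agree where a crossover would sit
        for z in (500.0, 700.0, 1000.0):
            a, b = soumpasis(z), soumpasis_series(z, n_terms=3)
            assert abs(a - b) <= 1e-6 * a


class TestReactionLimited:
    def test_start_and_end(self, fig_re_params):
        assert recovery_reaction_limited(fig_re_params, 0.0) == \
            pytest.approx(1 / 3)
        assert recovery_reaction_limited(fig_re_params, 1e6) == \
            pytest.approx(1.0)

    def test_half_life_value(self, fig_re_params):
        # k_off = 1: at t = ln 2 the bleached bound pool has halved
        assert recovery_reaction_limited(fig_re_params, math.log(2.0)) == \
            pytest.approx(2 / 3, rel=1e-12)

    def test_monotone_increasing(self, fig_re_params):
        t = np.linspace(0, 20, 500)
        f = recovery_reaction_limited(fig_re_params, t)
        assert np.all(np.diff(f) > 0)


class TestRapidEquilibration:
    def test_full_recovery(self, fig_re_params):
        assert recovery_rapid_equilibration(fig_re_params, 0.5, 1e9) == \
            pytest.approx(1.0, abs=1e-6)

    def test_immobile_bound_negligible_roi(self, fig_re_params):
        # with D_v = 0 and r_n²/(2 D_u t) ≈ 0 only the exchange term remains
        val = recovery_rapid_equilibration(fig_re_params, 1e-4, 1.0)
        assert val == pytest.approx(1 - (2 / 3) * math.exp(-1.0), rel=1e-4)

    def test_degenerates_to_reaction_limited_at_high_eta(self):
        # η ≥ 1e4 with immobile bound state: uniform 1e-3 agreement.
        # The free-diffusion transient must clear before the first sample,
        # so the small bleach radius (large η at fixed D_u) is essential.
        r_n, eta = 0.1, 1e4
        D_u = 30.0
        k_on = D_u / (r_n**2 * eta)
        p = PhysicalParams(D_u, 0.0, k_on, k_on)
        t = np.linspace(0.1, 15.0, 300)
        full = recovery_rapid_equilibration(p, r_n, t)
        reduced = recovery_reaction_limited(p, t)
        assert np.max(np.abs(full - reduced)) <= 1e-3


class TestFirstOrder:
    def test_reduces_to_reaction_limited_at_large_D_u(self):
        t = np.linspace(0.1, 10, 50)
        p_big = PhysicalParams(1e9, 0.0, 2.0, 1.0)
        np.testing.assert_allclose(
            recovery_first_order(p_big, 0.5, t),
            recovery_reaction_limited(p_big, t), atol=1e-9)

    def test_correction_scales_linearly_in_radius(self, fig_re_params):
        t = np.linspace(0.1, 10, 50)
        base = recovery_reaction_limited(fig_re_params, t)
        d1 = np.abs(recovery_first_order(fig_re_params, 0.5, t) - base)
        d2 = np.abs(recovery_first_order(fig_re_params, 1.0, t) - base)
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-9, atol=1e-15)

    def test_long_time_limit(self, fig_re_params):
        assert recovery_first_order(fig_re_params, 0.5, 1e6) == \
            pytest.approx(1.0)

    def test_zero_D_u_rejected(self):
        with pytest.raises(ValueError):
            recovery_first_order(PhysicalParams(0.0, 0.0, 2.0, 1.0), 0.5,
                                 1.0)


class TestDiffusiveCurves:
    def test_pure_diffusion_value(self):
        # r_n²/(2 D t) = 1
        assert recovery_pure_diffusion(0.125, 0.5, 1.0) == pytest.approx(
            soumpasis_by_series(1.0), rel=1e-12)

    def test_pure_diffusion_short_time_and_scaling(self):
        assert recovery_pure_diffusion(1.0, 0.5, 1e-15) == pytest.approx(
            0.0, abs=1e-6)
        t = np.linspace(0.01, 10, 30)
        np.testing.assert_allclose(
            recovery_pure_diffusion(3.0, 0.5, t),
            recovery_pure_diffusion(12.0, 1.0, t), rtol=1e-14)

    def test_invalid_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            recovery_pure_diffusion(0.0, 0.5, 1.0)

    def test_effective_diffusion_matches_pure_diffusion(self, fig_se_params):
        t = np.linspace(0.05, 15, 80)
        d_eff = (1000.0 * 0.374 + 5000.0 * 15.0) / 6000.0
        np.testing.assert_allclose(
            recovery_effective_diffusion(fig_se_params, 0.5, t),
            recovery_pure_diffusion(d_eff, 0.5, t), rtol=1e-9)

    @pytest.mark.parametrize("kappa,target_D", [(1e9, 15.0), (1e-9, 0.374)])
    def test_rate_asymmetry_collapses_to_single_species(self, kappa,
                                                        target_D):
        p = PhysicalParams(15.0, 0.374, 1.0, kappa)
        t = np.linspace(0.05, 15, 60)
        np.testing.assert_allclose(
            recovery_effective_diffusion(p, 0.5, t),
            recovery_pure_diffusion(target_D, 0.5, t), rtol=1e-6)


class TestGlobalCurveProperties:
    def test_curves_bounded_and_recovering(self, rng):
        # every analytic curve maps [0, ∞) into [0, 1] and tends to 1
        t = np.concatenate([np.logspace(-3, 6, 120)])
        for _ in range(300):
            D_u = rng.uniform(0.1, 50.0)
            delta = rng.uniform(0.0, 0.1)
            k_on = 10.0 ** rng.uniform(-3, 3)
            kappa = 4.0 ** rng.uniform(-1, 1)
            p = PhysicalParams(D_u, delta * D_u, k_on, kappa * k_on)
            for curve in (
                    recovery_rapid_equilibration(p, 0.5, t),
                    recovery_reaction_limited(p, t),
                    recovery_effective_diffusion(p, 0.5, t)):
                c = np.asarray(curve)
                assert np.all(c >= -1e-12) and np.all(c <= 1 + 1e-12)
                assert c[-1] == pytest.approx(1.0, abs=1e-3)
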