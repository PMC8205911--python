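"""Forward model: discretisation, regime limits, protocol determinism."""

import numpy as np
import pytest
from scipy.special import j0, jn_zeros

from frapkit import (ExperimentDesign, PhysicalParams, SampleSpec,
                     add_noise, build_grid, initial_guess,
                     recovery_from_spatial, sample_parameters,
                     simulate_frap, simulate_recovery)
from frapkit.analytic import (recovery_effective_diffusion,
                              recovery_pure_diffusion,
                              recovery_rapid_equilibration)
from frapkit.core import dimensionless
from frapkit.simulate import (RecoveryCurve, SpatialField, laplacian_radial,
                              roi_weights)


class TestDesign:
    def test_derived_defaults(self):
        d = ExperimentDesign()
        assert d.dt == pytest.approx(15.0 / 1024)
        assert d.dr == pytest.approx(0.025)
        assert d.R_domain == pytest.approx(10.0)
        assert len(d.times) == 1024 and d.times[0] == pytest.approx(d.dt)

    def test_explicit_dt_governs_duration(self):
        d = ExperimentDesign(n_frames=100, dt=1e-2)
        assert d.duration == pytest.approx(1.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(dr=0.5)          # dr == r_n
        with pytest.raises(ValueError):
            ExperimentDesign(R_domain=0.4)    # smaller than r_n
        with pytest.raises(ValueError):
            ExperimentDesign(ic_mode="gaussian")


class TestGridAndLaplacian:
    def test_node_count_and_uniformity(self):
        d = ExperimentDesign(r_n=0.5, dr=0.05, R_domain=5.0)
        grid = build_grid(d)
        assert grid.n == 101
        assert grid.r[0] == 0.0 and grid.r[-1] == 5.0
        assert np.all(np.abs(np.diff(grid.r) - grid.dr) < 1e-12)

    def test_constant_field_in_kernel(self):
        grid = build_grid(ExperimentDesign())
        np.testing.assert_allclose(laplacian_radial(np.ones(grid.n), grid),
                                   0.0, atol=1e-10)

    def test_parabola_curvature(self):
        # ∇²(r²) = 4 in polar coordinates, including at the origin
        grid = build_grid(ExperimentDesign(dr=0.0125))
        lap = laplacian_radial(grid.r**2, grid)
        np.testing.assert_allclose(lap[:-1], 4.0, atol=1e-6)

    def test_bessel_eigenfunction(self):
        # J0(λr) with J1(λR) = 0 satisfies zero flux and ∇²f = −λ²f
        grid = build_grid(ExperimentDesign(dr=0.0125))
        lam = jn_zeros(1, 1)[0] / grid.R
        f = j0(lam * grid.r)
        lap = laplacian_radial(f, grid)
        np.testing.assert_allclose(lap, -lam**2 * f, atol=2e-4)

    def test_roi_normalisation_and_step_frame(self):
        grid = build_grid(ExperimentDesign())
        c = roi_weights(grid, 0.5)
        assert np.ones(grid.n) @ c == pytest.approx(1.0, rel=1e-14)
        w_step = (grid.r > 0.5).astype(float)
        assert w_step @ c == pytest.approx(0.0, abs=1e-14)


class TestSimulatorPhysics:
    def test_pure_diffusion_matches_soumpasis(self, default_design):
        p = PhysicalParams(10.0, 0.0, 0.0, 0.0)
        fld = simulate_frap(p, default_design)
        F = recovery_from_spatial(fld, default_design.r_n)
        exact = recovery_pure_diffusion(10.0, default_design.r_n, F.times)
        assert np.max(np.abs(F.values - exact)) <= 2e-2

    def test_rapid_equilibration_limit(self, default_design):
        D_u, r_n = 30.0, default_design.r_n
        k_on = D_u / (r_n**2 * 1e3)
        p = PhysicalParams(D_u, 1e-3 * D_u, k_on, k_on)
        F = simulate_recovery(p, default_design)
        exact = recovery_rapid_equilibration(p, r_n, F.times)
        assert np.max(np.abs(F.values - exact)) <= 2e-2

    def test_effective_diffusion_limit(self, default_design):
        D_u, r_n = 30.0, default_design.r_n
        k_on = D_u / (r_n**2 * 1e-3)
        p = PhysicalParams(D_u, 1e-3 * D_u, k_on, k_on)
        F = simulate_recovery(p, default_design)
        exact = recovery_effective_diffusion(p, r_n, F.times)
        assert np.max(np.abs(F.values - exact)) <= 2e-2

    def test_large_kappa_limit_is_free_diffusion(self, default_design):
        D_u, r_n = 30.0, default_design.r_n
        k_on = D_u / (r_n**2 * 1e2)
        p = PhysicalParams(D_u, 1e-3 * D_u, k_on, 1e3 * k_on)
        F = simulate_recovery(p, default_design)
        exact = recovery_pure_diffusion(D_u, r_n, F.times)
        assert np.max(np.abs(F.values - exact)) <= 2e-2

    def test_mass_conservation(self, default_design):
        p = PhysicalParams(5.0, 0.2, 3.0, 1.0)
        fld = simulate_frap(p, default_design)
        mass = fld.w @ fld.grid.annulus_weights()
        assert np.max(np.abs(mass / mass[0] - 1.0)) <= 1e-5

    def test_noiseless_curves_non_decreasing(self, default_design, rng):
        spec = SampleSpec()
        for _ in range(20):
            p = sample_parameters(spec, default_design.r_n, rng=rng)
            F = simulate_recovery(p, default_design)
            assert np.min(np.diff(F.values)) >= -1e-4

    def test_grid_refinement_convergence(self):
        p = PhysicalParams(18.1, 0.0718, 38.3, 68.2)
        coarse = ExperimentDesign()
        fine = ExperimentDesign(dr=coarse.dr / 2)
        Fc = simulate_recovery(p, coarse)
        Ff = simulate_recovery(p, fine)
        assert np.max(np.abs(Fc.values - Ff.values)) <= 1e-3

    def test_backends_agree(self, default_design):
        p = PhysicalParams(18.1, 0.0718, 38.3, 68.2)
        Fe = simulate_recovery(p, default_design, backend="eig")
        Fl = simulate_recovery(p, default_design, backend="lsoda")
        assert np.max(np.abs(Fe.values - Fl.values)) <= 1e-4

    def test_fast_path_equals_field_readout(self, default_design):
        p = PhysicalParams(18.1, 0.0718, 38.3, 68.2)
        fast = simulate_recovery(p, default_design)
        full = recovery_from_spatial(simulate_frap(p, default_design),
                                     default_design.r_n)
        np.testing.assert_allclose(fast.values, full.values, atol=1e-12)

    def test_far_field_sits_at_equilibrium(self, default_design):
        p = PhysicalParams(2.0, 0.1, 3.0, 1.0)
        fld = simulate_frap(p, default_design)
        assert fld.u[0, -1] == pytest.approx(0.25, abs=1e-3)
        assert fld.v[0, -1] == pytest.approx(0.75, abs=1e-3)


class TestBleachPhase:
    def test_zero_bleach_rate_keeps_equilibrium(self, small_design):
        import dataclasses
        d = dataclasses.replace(small_design, ic_mode="bleach_phase",
                                bleach_rate=0.0)
        p = PhysicalParams(5.0, 0.1, 2.0, 1.0)
        fld = simulate_frap(p, d)
        np.testing.assert_allclose(fld.w, 1.0, atol=1e-8)

    def test_finite_bleach_depletes_roi(self, small_design):
        import dataclasses
        d = dataclasses.replace(small_design, ic_mode="bleach_phase",
                                bleach_rate=10.0, t_bleach=1.0)
        p = PhysicalParams(5.0, 0.1, 2.0, 1.0)
        F = recovery_from_spatial(simulate_frap(p, d), d.r_n)
        assert F.values[0] < 0.6            # bleached well below pre-bleach
        assert F.values[-1] > F.values[0]   # and recovering


class TestSyntheticProtocol:
    def test_noise_contract(self, default_design):
        base = RecoveryCurve(times=np.arange(1.0, 5.0),
                             values=np.array([0.1, 0.2, 0.3, 0.4]))
        assert np.array_equal(add_noise(base, 0.0, seed=1).values,
                              base.values)
        a = add_noise(base, 0.05, seed=42)
        b = add_noise(base, 0.05, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.sigmas is not None and np.all(a.sigmas == 0.05)

    def test_noise_variance_matches_sigma(self):
        n = 10_000
        base = RecoveryCurve(times=np.arange(1, n + 1, dtype=float),
                             values=np.zeros(n))
        noisy = add_noise(base, 0.2, seed=7)
        assert np.var(noisy.values) == pytest.approx(0.04, rel=0.05)

    def test_sample_ranges(self, rng):
        spec = SampleSpec()
        for _ in range(2000):
            p = sample_parameters(spec, 0.5, rng=rng)
            dl = dimensionless(p, 0.5)
            assert 0 < p.D_u <= 50.0
            assert 0.25 - 1e-12 <= dl.kappa <= 4.0 + 1e-12
            assert 0.0 <= dl.delta <= 0.1
            assert 1e-3 / 1.001 <= dl.eta <= 1e3 * 1.001

    def test_sample_regime_filter_and_determinism(self):
        spec = SampleSpec(eta_log_range=(1.7, 3.0), seed=5)
        draws = [sample_parameters(spec, 0.5) for _ in range(2)]
        assert draws[0] == draws[1]
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = sample_parameters(spec, 0.5, rng=rng)
            assert dimensionless(p, 0.5).eta >= 10.0 ** 1.7 / 1.001

    def test_empty_sample_window_rejected(self):
        with pytest.raises(ValueError):
            SampleSpec(eta_log_range=(2.0, 1.0))

    def test_precise_guess_contract(self, rng):
        truth = PhysicalParams(10.0, 0.5, 2.0, 1.0)
        for _ in range(500):
            g = initial_guess(truth, "precise", rng=rng)
            ratio = g.as_array() / truth.as_array()
            assert np.all(ratio >= 1.0) and np.all(ratio <= 1.5)
        g1 = initial_guess(truth, "precise", rng=123)
        g2 = initial_guess(truth, "precise", rng=123)
        assert g1 == g2

    def test_regime_random_guess_respects_window(self, rng):
        truth = PhysicalParams(10.0, 0.5, 2.0, 1.0)
        spec = SampleSpec(eta_log_range=(-3.0, -1.0))
        for _ in range(100):
            g = initial_guess(truth, "regime_random", rng=rng, spec=spec,
                              r_n=0.5)
            assert dimensionless(g, 0.5).eta <= 0.1 * 1.001
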