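"""Property engines: B2 quadrature, PMF sampling, EOS analysis, diffusion."""

import numpy as np
import pytest

from idpdesign.property_engines import (EOSCurve, FitWindow, MCConfig,
                                        PMFCurve, PropertyRecord, Trajectory,
                                        b2_from_pmf, default_r_grid,
                                        diffusion_from_msd, eos_phase_analysis,
                                        hard_sphere_pmf, homopolymer_scaling,
                                        pair_pmf_exact, reference_scales,
                                        square_well_pmf, two_chain_pmf_mc)
from idpdesign.forcefield import KB_KCAL

KT300 = KB_KCAL * 300.0


class TestB2Quadrature:
    def test_ideal_gas_zero(self):
        g = default_r_grid()
        assert b2_from_pmf(PMFCurve(g, np.zeros_like(g))) == 0.0

    def test_hard_sphere_closed_form(self):
        got = b2_from_pmf(hard_sphere_pmf(10.0))
        want = 2 * np.pi * 10.0**3 / 3
        assert got == pytest.approx(want, rel=1e-3)

    def test_square_well_closed_form(self):
        sigma, lam, depth = 10.0, 1.51, 0.5 * KT300
        got = b2_from_pmf(square_well_pmf(sigma, lam, depth))
        want = (2 * np.pi / 3) * (sigma**3 - (lam**3 - 1) * sigma**3
                                  * (np.exp(0.5) - 1))
        assert got == pytest.approx(want, rel=1e-3)

    def test_deeper_well_never_increases_b2(self, rng):
        """Pointwise-deeper attractive wells make B2 more negative."""
        g = default_r_grid()
        u = np.where((g > 8) & (g < 15), -0.3, 0.0)
        base = PMFCurve(g, u)
        for _ in range(5):
            extra = -rng.uniform(0, 0.5) * ((g > 8) & (g < 15))
            assert b2_from_pmf(PMFCurve(g, u + extra)) <= b2_from_pmf(base)


class TestExactPairPMF:
    def test_neutral_pair_is_pure_vdw(self, params):
        from idpdesign.forcefield import vdw_pair_energy
        pmf = pair_pmf_exact("G", "G", params)
        assert np.allclose(pmf.u, vdw_pair_energy(pmf.r, "G", "G", params))

    def test_ek_attractive_tail(self, params):
        pmf = pair_pmf_exact("E", "K", params)
        tail = (pmf.r > 8) & (pmf.r < 20)
        assert np.all(pmf.u[tail] < 0)

    def test_decay_at_r_max(self, params):
        for pair in [("E", "K"), ("W", "W")]:
            pmf = pair_pmf_exact(*pair, params)
            assert abs(pmf.u[-1]) < 2e-6


class TestMonteCarloPMF:
    def test_single_beads_match_exact_potential(self, params):
        """For one-residue chains the COM PMF is the pair potential; the
        reweighting estimator reproduces it with zero variance."""
        mc = two_chain_pmf_mc("E", "K", params, MCConfig(n_samples=50), seed=3)
        exact = pair_pmf_exact("E", "K", params)
        sampled = np.isfinite(mc.u) & (np.abs(exact.u) < 10)
        assert np.allclose(mc.u[sampled], exact.u[sampled], atol=1e-9)
        assert np.all(mc.u_se[sampled] < 1e-12)

    def test_repulsive_pair_nonnegative(self, params):
        """E-E: lambda_ij = 0 vdW plus like-charge electrostatics."""
        mc = two_chain_pmf_mc("E", "E", params, MCConfig(n_samples=50), seed=0)
        assert np.all(mc.u[np.isfinite(mc.u)] >= -1e-9)

    def test_seed_determinism(self, params):
        a = two_chain_pmf_mc("EK", "GS", params, MCConfig(n_samples=40), seed=11)
        b = two_chain_pmf_mc("EK", "GS", params, MCConfig(n_samples=40), seed=11)
        np.testing.assert_array_equal(a.u, b.u)

    def test_flexible_chains_have_finite_well(self, params):
        mc = two_chain_pmf_mc("WWW", "WWW", params, MCConfig(n_samples=200), seed=5)
        mid = np.isfinite(mc.u)
        assert mid.sum() > 100
        assert abs(mc.u[-1]) < 0.05  # decays at large separation

    def test_chain_length_cap(self, params):
        with pytest.raises(ValueError, match="exceeds MC maximum"):
            two_chain_pmf_mc("W" * 11, "W", params)


class TestEOSAnalysis:
    def _curve(self, f, se=0.01):
        rho = np.linspace(0.2, 1.2, 11)
        return EOSCurve(rho, f(rho), np.full(rho.shape, se))

    def test_monotonic_positive_not_separating(self):
        res = eos_phase_analysis(self._curve(lambda r: 0.5 + 2.0 * r))
        assert not res.phase_separates and res.rho_c is None

    def test_planted_cubic_roots(self):
        """p(rho) = a (rho - 0.3)(rho - 0.8)(rho + 0.1): highest root 0.8."""
        res = eos_phase_analysis(
            self._curve(lambda r: 4.0 * (r - 0.3) * (r - 0.8) * (r + 0.1)),
            n_boot=50, seed=0)
        assert res.phase_separates
        assert res.rho_c == pytest.approx(0.8, rel=0.01)
        assert res.rho_c_se is not None and res.rho_c_se < 0.05

    def test_zero_variance_bootstrap(self):
        res = eos_phase_analysis(
            self._curve(lambda r: 4.0 * (r - 0.3) * (r - 0.8) * (r + 0.1), se=0.0),
            n_boot=50, seed=1)
        assert res.rho_c_se == pytest.approx(0.0, abs=1e-12)

    def test_point_order_irrelevant(self):
        rho = np.linspace(0.2, 1.2, 9)
        p = 3.0 * (rho - 0.35) * (rho - 0.9) * (rho + 0.2)
        perm = np.random.default_rng(0).permutation(len(rho))
        r1 = eos_phase_analysis(EOSCurve(rho, p), n_boot=0)
        r2 = eos_phase_analysis(EOSCurve(rho[perm], p[perm]), n_boot=0)
        assert r1.rho_c == pytest.approx(r2.rho_c)

    def test_all_negative_unresolved(self):
        with pytest.warns(UserWarning, match="not bracketed"):
            res = eos_phase_analysis(self._curve(lambda r: -1.0 - r))
        assert res.unresolved

    def test_root_bracketing_against_sign_scan(self, rng):
        """rho_c agrees with a dense brute-force sign scan of the spline."""
        from scipy.interpolate import CubicSpline
        for _ in range(5):
            a, b = sorted(rng.uniform(0.25, 1.15, 2))
            rho = np.linspace(0.2, 1.2, 12)
            p = 2.0 * (rho - a) * (rho - b) * (rho + 0.3)
            res = eos_phase_analysis(EOSCurve(rho, p), n_boot=0)
            spline = CubicSpline(rho, p)
            grid = np.linspace(0.2, 1.2, 200001)
            vals = spline(grid)
            sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            brute = grid[sign_change[-1]]
            assert res.rho_c == pytest.approx(brute, abs=1e-4)


def brownian_trajectory(d_true, n_frames, n_chains, dt, rng):
    steps = rng.normal(0.0, np.sqrt(2 * d_true * dt), (n_frames - 1, n_chains, 3))
    pos = np.concatenate([np.zeros((1, n_chains, 3)), np.cumsum(steps, 0)], 0)
    return Trajectory(times=dt * np.arange(n_frames), com_positions=pos)


class TestDiffusion:
    def test_recovers_planted_diffusivity(self, rng):
        traj = brownian_trajectory(1.0, 2000, 100, 1.0, rng)
        res = diffusion_from_msd(traj, FitWindow(max_lag_frac=0.05))
        assert res.D == pytest.approx(1.0, rel=0.05)
        assert not res.anomalous

    def test_immobile_particles(self):
        traj = Trajectory(times=np.arange(50.0),
                          com_positions=np.ones((50, 5, 3)))
        res = diffusion_from_msd(traj)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_ballistic_flagged(self):
        t = np.arange(200.0)
        pos = np.zeros((200, 3, 3))
        pos[:, :, 0] = t[:, None] * np.array([1.0, 2.0, 0.5])
        with pytest.warns(UserWarning, match="exponent"):
            res = diffusion_from_msd(Trajectory(times=t, com_positions=pos))
        assert res.anomalous and res.msd_exponent > 1.3


class TestReferenceScales:
    def test_pervaded_volume_n50(self, params):
        assert round(reference_scales(50, params=params).V0) == 5529

    def test_rouse_diffusivity_n50(self, params):
        d0 = reference_scales(50, 300.0, params).D0
        assert round(d0 * 1e9, 2) == 0.42

    def test_volume_scaling_in_chain_length(self, params):
        r1 = reference_scales(10, params=params)
        r4 = reference_scales(40, params=params)
        assert r4.V0 / r1.V0 == pytest.approx(8.0)


class TestHomopolymerScaling:
    def _records_on_law(self, c=1.0e-13):
        out = []
        for n in (20, 30, 40, 50):
            for b2 in (-3e3, -1e4, -5e4, -2e5):
                out.append((n, b2, c / (np.sqrt(n) * -b2)))
        return out

    def test_exact_law_gives_unit_correlation(self):
        fit = homopolymer_scaling(self._records_on_law())
        assert abs(fit.correlation) == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-1.0, abs=1e-10)

    def test_chain_length_factor_improves_correlation(self):
        fit = homopolymer_scaling(self._records_on_law())
        assert abs(fit.correlation) > abs(fit.correlation_unscaled)

    def test_single_length_subset_factor_is_inert(self):
        recs = [(30, b2, 1e-13 / (np.sqrt(30) * -b2))
                for b2 in (-3e3, -1e4, -5e4, -2e5)]
        fit = homopolymer_scaling(recs)
        assert abs(fit.correlation) == pytest.approx(abs(fit.correlation_unscaled))

    def test_positive_b2_excluded(self):
        recs = self._records_on_law() + [(20, 5e3, 1e-16)]
        with pytest.warns(UserWarning, match="excluded"):
            fit = homopolymer_scaling(recs)
        assert fit.n_used == 16


class TestPropertyRecord:
    def test_diffusivity_gate(self):
        with pytest.raises(ValueError):
            PropertyRecord("AA", B2=-1.0, phase_separates=True)
        with pytest.raises(ValueError):
            PropertyRecord("AA", B2=1.0, phase_separates=False, D=1e-10)
        rec = PropertyRecord("AA", B2=-1.0, phase_separates=True, D=1e-10)
        assert rec.D == 1e-10
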