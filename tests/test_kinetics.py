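"""Bell-Evans rates, ramp densities, hysteresis convolution, hopping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hairpinfs import (RampSpec, TwoStateParams, hopping_rates_at_separation,
                       hysteresis_density, ramp_density, rate_fold,
                       rate_unfold, thermal_energy)
from hairpinfs.constants import kj_per_mol_to_pn_nm
from hairpinfs.errors import ConfigurationError, DomainError, GridError
from hairpinfs.kinetics import (ForceDensity, coexistence_force,
                                equal_occupancy_separation,
                                ode_survival_density)
from hairpinfs import datasets as ds


class TestRates:
    def test_zero_force_rates_are_k0_and_k1(self, dna10_params):
        p = dna10_params
        kbt = thermal_energy()
        assert rate_unfold(p, 0.0) == p.k0_per_s
        assert rate_fold(p, 0.0) == pytest.approx(
            p.k0_per_s * math.exp(p.dG_pn_nm() / kbt), rel=1e-12)

    def test_unit_exponent_force(self, dna10_params):
        p = dna10_params
        f = thermal_energy() / p.x_fwd_nm
        assert rate_unfold(p, f) == pytest.approx(p.k0_per_s * math.e, rel=1e-12)

    def test_hand_computed_unfolding_rate(self):
        # 2e-4 * exp(6.3*4.4/kBT) with kBT at 29 C
        p = TwoStateParams(L_nm=14.8, x_fwd_nm=4.4, dG_kj_mol=83.0,
                           k0_per_s=2e-4)
        assert rate_unfold(p, 6.3) == pytest.approx(0.1537, rel=1e-3)

    def test_rates_cross_at_dG_over_L(self, rna10_params):
        f_star = coexistence_force(rna10_params)
        assert f_star == pytest.approx(
            kj_per_mol_to_pn_nm(rna10_params.dG_kj_mol) / rna10_params.L_nm)
        assert rate_unfold(rna10_params, f_star) == pytest.approx(
            rate_fold(rna10_params, f_star), rel=1e-9)

    def test_fold_rate_monotone_decreasing(self, dna10_params):
        forces = np.linspace(0, 20, 50)
        assert np.all(np.diff(rate_fold(dna10_params, forces)) < 0)

    @given(force=st.floats(0.0, 25.0), x=st.floats(2.0, 6.0),
           dg=st.floats(60.0, 130.0))
    @settings(max_examples=50, deadline=None)
    def test_detailed_balance_identity(self, force, x, dg):
        p = TwoStateParams(L_nm=16.0, x_fwd_nm=x, dG_kj_mol=dg, k0_per_s=1e-4)
        kbt = thermal_energy()
        lhs = math.log(rate_unfold(p, force)) - math.log(rate_fold(p, force))
        rhs = (force * p.L_nm - p.dG_pn_nm()) / kbt
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_nu0_barrier_consistency_enforced(self):
        kbt = thermal_energy()
        e_kj = 40.0
        nu0 = 1e-4 / math.exp(-kj_per_mol_to_pn_nm(e_kj) / kbt)
        TwoStateParams(14.8, 4.4, 83.0, 1e-4, nu0_per_s=nu0, E_kj_mol=e_kj)
        with pytest.raises(ConfigurationError, match="inconsistent"):
            TwoStateParams(14.8, 4.4, 83.0, 1e-4, nu0_per_s=2 * nu0,
                           E_kj_mol=e_kj)


class TestRampDensity:
    def test_normalisation_mass_plus_escape(self, all_reference_sets):
        for name, p, c, rec in all_reference_sets:
            for direction in ("stretch", "release"):
                d = ramp_density(p, RampSpec(3.0, 0.0, rec.ramp_F_max_pn,
                                             direction))
                d.validate(tol=1e-6)

    def test_fast_ramp_escape_mass_tends_to_one(self, dna10_params):
        d = ramp_density(dna10_params, RampSpec(1e9, 0.0, 20.0, "stretch"))
        assert d.escape_mass > 0.999

    def test_mode_matches_analytic_formula(self, dna10_params):
        p, r = dna10_params, 2.5
        kbt = thermal_energy()
        d = ramp_density(p, RampSpec(r, 0.0, 20.0, "stretch"))
        mode_analytic = (kbt / p.x_fwd_nm) * math.log(
            r * p.x_fwd_nm / (p.k0_per_s * kbt))
        mode_grid = d.grid_pn[np.argmax(d.density_per_pn)]
        assert mode_grid == pytest.approx(mode_analytic, abs=2 * d.step_pn)

    def test_closed_form_matches_ode_oracle(self, dna10_params):
        ramp = RampSpec(2.5, 0.0, 20.0, "stretch")
        closed = ramp_density(dna10_params, ramp)
        ode = ode_survival_density(dna10_params, ramp)
        assert np.max(np.abs(closed.density_per_pn - ode.density_per_pn)) < 1e-6

    def test_too_coarse_grid_raises(self, rna10_params):
        with pytest.raises(GridError, match="grid"):
            ramp_density(rna10_params, RampSpec(3.0, 0.0, 25.0, "stretch"),
                         grid_step_pn=1.0)


def _gaussian_density(grid, mu, sigma):
    d = np.exp(-0.5 * ((grid - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    return ForceDensity(grid_pn=grid, density_per_pn=d,
                        escape_mass=1.0 - np.trapezoid(d, grid))


class TestHysteresisDensity:
    def test_gaussian_convolution_closed_form(self):
        grid = 0.01 * np.arange(3001)
        s = _gaussian_density(grid, 20.0, 1.0)
        r = _gaussian_density(grid, 12.0, 0.8)
        h = hysteresis_density(s, r)
        h.validate(tol=1e-4)
        mu = h.mean()
        var = np.trapezoid((h.grid_pn - mu) ** 2 * h.density_per_pn,
                           h.grid_pn) / h.mass()
        assert mu == pytest.approx(8.0, abs=1e-3)
        assert var == pytest.approx(1.0 + 0.64, rel=1e-3)
        expected = np.exp(-0.5 * (h.grid_pn - 8.0) ** 2 / 1.64) / math.sqrt(
            2 * math.pi * 1.64)
        assert np.max(np.abs(h.density_per_pn - expected)) < 1e-4

    def test_identical_narrow_densities_concentrate_at_zero(self):
        grid = 0.01 * np.arange(3001)
        s = _gaussian_density(grid, 15.0, 0.05)
        h = hysteresis_density(s, s)
        assert abs(h.mean()) < 1e-6

    def test_mean_hysteresis_increases_with_loading_rate(self, rna10_params):
        means = []
        for r in (1.0, 3.0, 10.0, 30.0):
            s = ramp_density(rna10_params, RampSpec(r, 0.0, 25.0, "stretch"))
            rel = ramp_density(rna10_params, RampSpec(r, 0.0, 25.0, "release"))
            means.append(hysteresis_density(s, rel).mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_incommensurate_grids_rejected(self):
        a = _gaussian_density(0.01 * np.arange(1001), 5.0, 0.5)
        b = _gaussian_density(0.02 * np.arange(501), 5.0, 0.5)
        with pytest.raises(GridError, match="grid"):
            hysteresis_density(a, b)


class TestHopping:
    def test_equal_rates_give_half_occupancy(self, rna10_params,
                                             rna10_construct):
        sep = equal_occupancy_separation(rna10_params, rna10_construct)
        k_u, k_f, occ = hopping_rates_at_separation(rna10_params,
                                                    rna10_construct, sep)
        assert k_u == pytest.approx(k_f, rel=1e-5)
        assert occ == pytest.approx(0.5, abs=1e-5)

    def test_trap_relaxation_correction_slows_both_rates(self, rna10_params,
                                                         rna10_construct):
        sep = equal_occupancy_separation(rna10_params, rna10_construct)
        k_u, k_f, _ = hopping_rates_at_separation(rna10_params,
                                                  rna10_construct, sep)
        k_u_c, k_f_c, _ = hopping_rates_at_separation(
            rna10_params, rna10_construct, sep, correction="trap_relaxation")
        assert k_u_c < k_u and k_f_c < k_f

    def test_dna_vs_rna_equal_occupancy_dwells_differ_by_order_of_magnitude(
            self, dna10_params, dna10_construct, rna10_params, rna10_construct):
        # published hopping traces: RNA10 dwells ~1.8-3.1 s vs DNA10 ~0.1-0.25 s
        sep_d = equal_occupancy_separation(dna10_params, dna10_construct)
        sep_r = equal_occupancy_separation(rna10_params, rna10_construct)
        k_d, _, _ = hopping_rates_at_separation(dna10_params, dna10_construct,
                                                sep_d)
        k_r, _, _ = hopping_rates_at_separation(rna10_params, rna10_construct,
                                                sep_r)
        ratio = (1.0 / k_r) / (1.0 / k_d)
        assert 4.0 < ratio < 40.0

    def test_mean_dwell_matches_exponential_sampling(self, dna10_params,
                                                     dna10_construct):
        # simulator dwell oracle: mean dwell ~ 1/k within 2 standard errors
        from hairpinfs import SimulationConfig, simulate_constant_extension
        from hairpinfs.traces import dwell_analysis

        sep = equal_occupancy_separation(dna10_params, dna10_construct)
        k_u, k_f, _ = hopping_rates_at_separation(dna10_params,
                                                  dna10_construct, sep)
        cfg = SimulationConfig(params=dna10_params, construct=dna10_construct,
                               seed=2024, noise_sd_pn=0.0,
                               sample_rate_hz=2000.0)
        trace = simulate_constant_extension(cfg, sep, 700.0,
                                            cfg.molecule_rng(0))
        summary = dwell_analysis(trace, deadband_pn=0.2)
        n = len(summary.dwells_folded_s)
        assert n > 500
        se = (1.0 / k_u) / math.sqrt(n)
        assert summary.mean_folded_s == pytest.approx(1.0 / k_u, abs=2 * se)
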