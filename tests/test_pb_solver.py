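import numpy as np
import pytest

import gausspb as g
from gausspb.gaussian_dielectric import DielectricMaps, dielectric_maps, traditional_dielectric_maps
from gausspb.pb_solver import ConvergenceError, _sor, discrete_residual

from conftest import born_energy, coulomb_kt


class TestChargeSpread:
    def test_charge_on_node_stays_on_node(self, small_grid):
        s = g.single_ion(center=(0.0, 0.0, 0.0))  # node (8,8,8)
        ch = g.charge_spread(s, small_grid)
        assert ch.values[8, 8, 8] == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(ch.values) == 1

    def test_charge_at_cell_center_splits_evenly(self, small_grid):
        s = g.single_ion(center=(0.5, 0.5, 0.5))
        ch = g.charge_spread(s, small_grid)
        nonzero = ch.values[ch.values != 0]
        assert len(nonzero) == 8
        np.testing.assert_allclose(nonzero, 0.125, rtol=1e-12)

    def test_total_charge_conserved_for_random_atoms(self, small_grid):
        rng = np.random.default_rng(7)
        atoms = [
            g.Atom(name=f"A{i}", position=tuple(rng.uniform(-6, 6, 3)), radius=1.5,
                   charge=float(rng.uniform(-2, 2)))
            for i in range(5)
        ]
        s = g.Structure(atoms=atoms)
        ch = g.charge_spread(s, small_grid)
        assert ch.values.sum() == pytest.approx(s.total_charge, abs=1e-9)

    def test_charged_atom_outside_grid_rejected(self, small_grid):
        s = g.single_ion(center=(50.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="outside the grid"):
            g.charge_spread(s, small_grid)


class TestPoisson:
    def test_coulomb_oracle_uniform_dielectric(self):
        ion = g.single_ion()
        cfg = g.SolverConfig(spacing=0.5, min_margin=12.0)
        grid = cfg.grid_for(ion)
        phi = g.solve_poisson(80.0, g.charge_spread(ion, grid), cfg)
        r = np.array([3.0, 5.0, 7.0, 10.0])
        pts = np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=1)
        ana = coulomb_kt(1.0, 80.0, r)
        num = phi.interpolate(pts)
        assert np.all(np.abs(num - ana) / ana < 0.02)

    def test_zero_charge_zero_boundary_gives_zero(self, small_grid):
        s = g.single_ion(charge=0.0)
        cfg = g.SolverConfig(boundary="zero")
        phi = g.solve_poisson(80.0, g.charge_spread(s, small_grid), cfg)
        assert np.allclose(phi.values, 0.0)

    def test_operator_linearity_in_charge(self, small_grid):
        cfg = g.SolverConfig(tolerance=1e-12, boundary="debye_huckel")
        one = g.charge_spread(g.single_ion(charge=1.0), small_grid)
        two = g.charge_spread(g.single_ion(charge=2.0), small_grid)
        phi1 = g.solve_poisson(80.0, one, cfg).values
        phi2 = g.solve_poisson(80.0, two, cfg).values
        assert np.max(np.abs(phi2 - 2 * phi1)) / np.max(np.abs(phi1)) < 1e-10

    def test_discrete_flux_conservation(self, small_grid, params, born_ion):
        cfg = g.SolverConfig(tolerance=1e-12)
        maps = dielectric_maps(born_ion, small_grid, params)
        charge = g.charge_spread(born_ion, small_grid)
        phi = g.solve_poisson(maps, charge, cfg)
        resid = discrete_residual(maps, phi, charge, cfg)
        source_scale = np.abs(charge.values).max() * 4 * np.pi * g.KCOUL / g.kT_kcal(cfg.temperature)
        assert np.abs(resid).max() / source_scale < 1e-9

    def test_solution_unique_across_initializations(self, small_grid):
        cfg = g.SolverConfig(tolerance=1e-9, boundary="zero")
        charge = g.charge_spread(g.single_ion(), small_grid)
        maps = DielectricMaps.uniform(80.0, small_grid)
        rng = np.random.default_rng(3)
        phi_a, _, _ = _sor(maps, charge, cfg)
        phi_b, _, _ = _sor(maps, charge, cfg, phi0=rng.normal(0, 5, small_grid.shape))
        assert np.max(np.abs(phi_a - phi_b)) <= 10 * cfg.tolerance

    def test_nonpositive_dielectric_rejected(self, small_grid):
        charge = g.charge_spread(g.single_ion(), small_grid)
        maps = DielectricMaps.uniform(80.0, small_grid)
        maps.face_x[0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            g.solve_poisson(maps, charge, g.SolverConfig())

    def test_nonconvergence_carries_residual(self, small_grid):
        cfg = g.SolverConfig(tolerance=1e-14, max_iterations=2)
        charge = g.charge_spread(g.single_ion(), small_grid)
        with pytest.raises(ConvergenceError) as err:
            g.solve_poisson(80.0, charge, cfg)
        assert err.value.residual > 0


class TestPBE:
    def test_zero_salt_reduces_to_poisson(self, small_grid):
        cfg = g.SolverConfig()
        charge = g.charge_spread(g.single_ion(), small_grid)
        phi_p = g.solve_poisson(80.0, charge, cfg)
        phi_b = g.solve_pbe(80.0, charge, g.neutral_salt(0.0), config=cfg)
        np.testing.assert_allclose(phi_b.values, phi_p.values, atol=1e-12)

    def test_debye_screening_shortens_range(self, small_grid):
        cfg = g.SolverConfig(tolerance=1e-8)
        charge = g.charge_spread(g.single_ion(), small_grid)
        phi0 = g.solve_pbe(80.0, charge, [], config=cfg)
        phi_salt = g.solve_pbe(80.0, charge, g.neutral_salt(0.15), config=cfg)
        pt = np.array([[6.0, 0.0, 0.0]])
        assert phi_salt.interpolate(pt)[0] < phi0.interpolate(pt)[0]

    def test_infinite_penalty_recovers_poisson(self, small_grid):
        cfg = g.SolverConfig(boundary="zero", tolerance=1e-10)
        charge = g.charge_spread(g.single_ion(), small_grid)
        ions = g.neutral_salt(0.15)
        walls = [
            g.ScalarField(grid=small_grid, values=np.full(small_grid.shape, 1e6), role="penalty")
            for _ in ions
        ]
        phi_blocked = g.solve_pbe(80.0, charge, ions, walls, cfg)
        phi_poisson = g.solve_poisson(80.0, charge, cfg)
        np.testing.assert_allclose(phi_blocked.values, phi_poisson.values, atol=1e-8)

    def test_unbalanced_ions_rejected(self, small_grid):
        charge = g.charge_spread(g.single_ion(), small_grid)
        ions = [g.IonSpecies(valence=1, bulk_concentration=0.1)]
        with pytest.raises(ValueError, match="charge-balanced"):
            g.solve_pbe(80.0, charge, ions, config=g.SolverConfig())

    def test_nonlinear_agrees_with_linear_for_weak_potentials(self, small_grid):
        cfg_l = g.SolverConfig(mode="linear", tolerance=1e-9)
        cfg_n = g.SolverConfig(mode="nonlinear", tolerance=1e-9)
        charge = g.charge_spread(g.single_ion(charge=0.1), small_grid)
        ions = g.neutral_salt(0.15)
        phi_l = g.solve_pbe(80.0, charge, ions, config=cfg_l)
        phi_n = g.solve_pbe(80.0, charge, ions, config=cfg_n)
        scale = np.abs(phi_l.values).max()
        assert np.max(np.abs(phi_l.values - phi_n.values)) / scale < 0.02


class TestReactionField:
    def test_uniform_map_gives_zero_energy(self, small_grid, born_ion):
        cfg = g.SolverConfig()
        maps = DielectricMaps.uniform(2.0, small_grid)
        assert g.reaction_field_energy(born_ion, cfg, maps) == pytest.approx(0.0, abs=1e-9)

    def test_born_ion_on_sharp_map(self, params, born_ion):
        cfg = g.SolverConfig(params=params, spacing=0.5)
        grid = g.GridSpec.from_bounds(*born_ion.bounds(), 0.5, min_margin=8.0)
        maps = traditional_dielectric_maps(born_ion, grid, params)
        e = g.reaction_field_energy(born_ion, cfg, maps)
        ana = born_energy(1.0, 2.0, 2.0, 80.0)
        assert abs(e - ana) / abs(ana) < 0.08

    def test_energy_quadratic_in_charge(self, params):
        grid = g.GridSpec.from_bounds(np.full(3, -2.0), np.full(3, 2.0), 1.0, min_margin=8.0)
        cfg = g.SolverConfig(params=params, tolerance=1e-10)
        e = {}
        for q in (1.0, 2.0):
            ion = g.single_ion(charge=q)
            maps = traditional_dielectric_maps(ion, grid, params)
            e[q] = g.reaction_field_energy(ion, cfg, maps)
        assert e[2.0] == pytest.approx(4.0 * e[1.0], rel=1e-6)

    def test_gaussian_cavity_energy_bracketed_by_continuum_oracle(self, params, born_ion):
        # exact continuum limit for a point charge in a radial dielectric:
        # dG = (C q^2 / 2) * int (1/eps(r) - 1/eps_in) / r^2 dr  (spherical Gauss law)
        from scipy.integrate import quad

        sig_r = params.sigma * born_ion.atoms[0].radius

        def inv_eps_excess(r):
            eps = params.eps_in + (params.eps_out - params.eps_in) * (
                1.0 - np.exp(-(r * r) / sig_r**2)
            )
            return (1.0 / eps - 1.0 / params.eps_in) / max(r * r, 1e-24)

        continuum, _ = quad(inv_eps_excess, 1e-6, 60.0, limit=200)
        e_exact = 0.5 * g.KCOUL * continuum
        cfg = g.SolverConfig(params=params)
        energies = {}
        for h in (0.8, 0.5):
            grid = g.GridSpec.from_bounds(*born_ion.bounds(), h, min_margin=8.0)
            energies[h] = {
                "sharp": g.reaction_field_energy(
                    born_ion, cfg, traditional_dielectric_maps(born_ion, grid, params)
                ),
                "gauss": g.reaction_field_energy(
                    born_ion, cfg, dielectric_maps(born_ion, grid, params)
                ),
            }
        for h, e in energies.items():
            # the smooth cavity solvates harder than the sharp one: the
            # dielectric already rises inside r < R, so the grid energy lies
            # between the sharp Born value and the smooth continuum limit
            assert e_exact < e["gauss"] < e["sharp"] < 0.0
        # refinement moves the Gaussian-map energy toward its continuum limit
        assert abs(energies[0.5]["gauss"] - e_exact) < abs(energies[0.8]["gauss"] - e_exact)


class TestBindingEnergy:
    def test_empty_partner_gives_zero(self, params, born_ion):
        cfg = g.SolverConfig(params=params)
        assert g.binding_polar_energy(born_ion, born_ion, g.Structure(), cfg) == 0.0

    def test_atom_set_mismatch_rejected(self, params, two_atom_structure):
        a = g.Structure(atoms=[two_atom_structure.atoms[0]])
        b = g.Structure(atoms=[two_atom_structure.atoms[0]])  # wrong: duplicates A
        with pytest.raises(ValueError, match="labels"):
            g.binding_polar_energy(two_atom_structure, a, b, g.SolverConfig(params=params))

    def test_matches_stepwise_three_solve_evaluation(self, params):
        a, b = g.diatomic(distance=6.0, charges=(1.0, -1.0))
        complex_s = g.Structure(atoms=list(a.atoms) + list(b.atoms), label="complex")
        cfg = g.SolverConfig(params=params, spacing=1.0, tolerance=1e-8)
        ddg = g.binding_polar_energy(complex_s, a, b, cfg, sharp=True)
        # independent step-by-step recomputation on the same common grid
        lo = np.minimum.reduce([s.bounds()[0] for s in (complex_s, a, b)])
        hi = np.maximum.reduce([s.bounds()[1] for s in (complex_s, a, b)])
        grid = g.GridSpec.from_bounds(lo, hi, cfg.spacing, cfg.margin_fraction, cfg.min_margin)
        energies = [
            g.reaction_field_energy(s, cfg, traditional_dielectric_maps(s, grid, params))
            for s in (complex_s, a, b)
        ]
        assert ddg == pytest.approx(energies[0] - energies[1] - energies[2], abs=1e-9)

    def test_noninteracting_limit_for_neutral_dipoles(self, params):
        # neutral dipolar partners 34 Å apart: the cross reaction term decays
        # like 1/r^3 and falls below grid noise, so binding costs ~ nothing
        def dipole(x0, chain):
            return g.Structure(
                atoms=[
                    g.Atom(name="P", position=(x0, 0.0, 0.0), radius=2.0, charge=1.0, chain=chain),
                    g.Atom(name="M", position=(x0 + 2.0, 0.0, 0.0), radius=2.0, charge=-1.0, chain=chain),
                ],
                label=chain,
            )

        a, b = dipole(0.0, "A"), dipole(34.0, "B")
        complex_s = g.Structure(atoms=list(a.atoms) + list(b.atoms), label="complex")
        cfg = g.SolverConfig(
            params=params, spacing=1.0, tolerance=1e-8, margin_fraction=0.2, min_margin=8.0
        )
        ddg = g.binding_polar_energy(complex_s, a, b, cfg, sharp=True)
        lo, hi = complex_s.bounds()
        grid = g.GridSpec.from_bounds(lo, hi, cfg.spacing, cfg.margin_fraction, cfg.min_margin)
        parts = [
            g.reaction_field_energy(s, cfg, traditional_dielectric_maps(s, grid, params))
            for s in (a, b)
        ]
        assert abs(ddg) <= 0.02 * abs(sum(parts))
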