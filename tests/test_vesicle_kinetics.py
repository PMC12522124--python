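"""Unit and property tests of the compartment-exchange kinetic model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import translokin as tk
from translokin.vesicle_kinetics import rate_equations

from conftest import long_run_grid


# ---------------------------------------------------------------------------
# geometry


class TestGeometry:
    def test_membrane_volume_fraction_equals_lipid_volume(self, geometry):
        # 20 mg/mL lipid at density 1.0 g/mL occupies 2% of the sample
        assert geometry.phi_mem == pytest.approx(0.02, abs=1e-15)

    def test_volume_fractions_partition_unity(self, geometry):
        assert geometry.phi_in + geometry.phi_mem + geometry.phi_out == pytest.approx(
            1.0, abs=1e-12
        )

    def test_shell_volumes_match_sphere_formulas(self, geometry):
        # independent arithmetic oracle for the two sphere-shell volumes
        v_in = 4.0 / 3.0 * np.pi * 40.0**3
        v_mem = 4.0 / 3.0 * np.pi * (44.0**3 - 40.0**3)
        assert geometry.v_in == pytest.approx(v_in, rel=1e-12)
        assert geometry.v_mem == pytest.approx(v_mem, rel=1e-12)
        assert geometry.phi_in / geometry.phi_mem == pytest.approx(
            v_in / v_mem, rel=1e-12
        )

    def test_empty_membrane_limit(self):
        g = tk.derive_geometry(R=44.0, d=1e-9, c_lipid=0.0)
        assert g.phi_mem == 0.0
        assert g.phi_in == 0.0
        assert g.phi_out == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(R=44.0, d=44.0, c_lipid=20.0),  # d >= R
            dict(R=44.0, d=50.0, c_lipid=20.0),
            dict(R=44.0, d=4.0, c_lipid=1500.0),  # phi_mem > 1
            dict(R=44.0, d=4.0, c_lipid=300.0),  # phi_out <= 0 (phi_in > 0.9)
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tk.derive_geometry(**kwargs)


# ---------------------------------------------------------------------------
# rate equations


class TestRateEquations:
    def test_no_exchange_when_idle(self, geometry):
        state = tk.CompartmentState(c_o=0.01, c_m=0.0, c_i=0.0)
        params = tk.KineticParams(k_a=0.0, k_d=1e-3, c_sat=0.01)
        assert rate_equations(state, params, geometry) == (0.0, 0.0, 0.0)

    def test_saturation_shuts_off_adsorption(self, geometry):
        params = tk.KineticParams(k_a=0.5, k_d=1e-3, c_sat=0.01)
        state = tk.CompartmentState(c_o=0.01, c_m=params.c_sat, c_i=0.002)
        dco, dcm, dci = rate_equations(state, params, geometry)
        assert dcm == pytest.approx(-params.k_d * params.c_sat, rel=1e-14)
        # only desorption remains: both aqueous compartments gain
        assert dco > 0 and dci > 0

    def test_saturated_membrane_requires_positive_capacity(self):
        with pytest.raises(ValueError):
            tk.KineticParams(k_a=0.5, k_d=1e-3, c_sat=0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        c_o=st.floats(0, 0.05),
        c_m=st.floats(0, 0.01),
        c_i=st.floats(0, 0.05),
        k_a=st.floats(1e-4, 10),
        k_d=st.floats(1e-6, 1),
    )
    def test_phi_weighted_flux_balance(self, c_o, c_m, c_i, k_a, k_d):
        """Conservation oracle: the phi-weighted derivative sum vanishes."""
        g = tk.derive_geometry(R=44.0, d=4.0, c_lipid=20.0)
        params = tk.KineticParams(k_a=k_a, k_d=k_d, c_sat=0.01)
        state = tk.CompartmentState(c_o=c_o, c_m=c_m, c_i=c_i)
        dco, dcm, dci = rate_equations(state, params, g)
        total = g.phi_out * dco + g.phi_mem * dcm + g.phi_in * dci
        scale = max(abs(dco), abs(dcm), abs(dci), 1e-30)
        assert abs(total) <= 1e-14 * max(scale, 1.0)


# ---------------------------------------------------------------------------
# simulation


class TestSimulate:
    def test_no_adsorption_means_no_uptake(self, geometry):
        params = tk.KineticParams(k_a=0.0, k_d=1e-3, c_sat=0.01)
        traj = tk.simulate(params, geometry, 0.01, np.logspace(0, 5, 50))
        assert np.all(traj.c_m == 0)
        assert np.all(traj.c_i == 0)

    def test_mass_conservation_along_trajectories(self, preset_trajectories):
        for traj in preset_trajectories.values():
            assert traj.conservation_error() < 1e-8

    def test_membrane_never_exceeds_saturation(self, preset_trajectories):
        for traj in preset_trajectories.values():
            assert np.all(traj.c_m <= traj.params.c_sat * (1 + 1e-9))

    def test_passive_equilibration_inner_equals_outer(self, preset_trajectories):
        """Detailed balance forces c_i(inf) = c_o(inf) for every preset."""
        for traj in preset_trajectories.values():
            assert traj.c_i[-1] / traj.c_o[-1] == pytest.approx(1.0, rel=1e-6)

    def test_long_run_matches_closed_form_equilibrium(self, geometry):
        params = tk.KineticParams(k_a=0.02, k_d=1e-3, c_sat=0.05)
        grid = long_run_grid(params, geometry, 0.005)
        traj = tk.simulate(params, geometry, 0.005, grid)
        eq = tk.equilibrium(params, geometry, 0.005)
        assert traj.c_o[-1] == pytest.approx(eq.c_o, rel=1e-6)
        assert traj.c_m[-1] == pytest.approx(eq.c_m, rel=1e-6)
        assert traj.c_i[-1] == pytest.approx(eq.c_i, rel=1e-6)

    def test_two_step_log_curve(self, preset_trajectories):
        """ln(1 - f/f_max) falls fast early (adsorption) and slowly late
        (desorption-limited filling)."""
        traj = preset_trajectories["homogeneous_aap"]
        s0, s1 = tk.limiting_slopes(traj)
        assert s0 < 0 and s1 < 0
        assert abs(s0) > 10 * abs(s1)

    def test_non_monotone_grid_rejected(self, geometry, presets):
        sc = presets["homogeneous_aap"]
        with pytest.raises(ValueError):
            tk.simulate(sc.params, geometry, 0.01, np.array([1.0, 0.5, 2.0]))

    @pytest.mark.parametrize("scenario_idx", range(5))
    def test_agrees_with_fixed_step_rk4_oracle(self, geometry, scenario_idx):
        """Independent naive integrator (classical RK4, tiny fixed step) over
        the early adsorption window."""
        rng = np.random.default_rng(scenario_idx)
        ka = 10.0 ** rng.uniform(-2, 0)
        kd = 10.0 ** rng.uniform(-4, -3)
        cs = 10.0 ** rng.uniform(-2.5, -1)
        params = tk.KineticParams(ka, kd, cs)
        dt = 1e-4 * min(1.0 / ka, 1.0 / kd)
        n_steps = 2000
        t_grid = np.arange(1, n_steps + 1) * dt
        g = geometry
        a_o, a_i = g.phi_mem / g.phi_out, g.phi_mem / g.phi_in

        def rhs(y):
            c_o, c_m, c_i = y
            sat = 1 - c_m / cs
            ads_o, ads_i, des = ka * c_o * sat, ka * c_i * sat, kd * c_m
            return np.array(
                [a_o * (des / 2 - ads_o), ads_o + ads_i - des, a_i * (des / 2 - ads_i)]
            )

        y = np.array([0.01 / g.phi_out, 0.0, 0.0])
        ys = []
        for _ in range(n_steps):
            k1 = rhs(y)
            k2 = rhs(y + dt / 2 * k1)
            k3 = rhs(y + dt / 2 * k2)
            k4 = rhs(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            ys.append(y.copy())
        ys = np.array(ys)
        traj = tk.simulate(params, geometry, 0.01, t_grid)
        ref = np.column_stack([traj.c_o, traj.c_m, traj.c_i])
        scale = np.maximum(np.abs(ys), 1e-12 * ys.max())
        assert np.max(np.abs(ref - ys) / scale) < 1e-4

    def test_uptake_monotone_in_adsorption_rate(self, geometry):
        """Faster adsorption never lowers the normalized uptake curve."""
        grid = np.logspace(0, 5, 120)
        prev = None
        for ka in [0.02, 0.04, 0.08, 0.16, 0.32]:
            params = tk.KineticParams(ka, 5e-4, 0.01)
            f = tk.integrated_fraction(tk.simulate(params, geometry, 0.01, grid))
            if prev is not None:
                assert np.all(f >= prev - 1e-9)
            prev = f

    def test_membrane_count_monotone_in_capacity(self, geometry):
        grid = np.logspace(0, 5, 120)
        prev = None
        for cs in [0.005, 0.01, 0.02, 0.04]:
            traj = tk.simulate(tk.KineticParams(0.05, 5e-4, cs), geometry, 0.01, grid)
            n_mem, _ = tk.molecules_per_vesicle(traj, mw=12.0)
            if prev is not None:
                assert np.all(n_mem >= prev - 1e-9 * prev.max())
            prev = n_mem


# ---------------------------------------------------------------------------
# equilibrium and derived quantities


class TestEquilibrium:
    def test_weak_adsorption_limit(self, geometry):
        eq = tk.equilibrium(tk.KineticParams(1e-9, 1e-3, 0.01), geometry, 0.01)
        # c_m ~ (2 k_a/k_d) c -> 0 in the weak-adsorption limit
        assert eq.c_m == pytest.approx(0.0, abs=1e-7)
        assert eq.c_i == eq.c_o
        assert eq.c_o == pytest.approx(0.01 / (geometry.phi_out + geometry.phi_in), rel=1e-6)

    def test_linear_partition_limit(self, geometry):
        """c_sat -> inf: the balance equation gives c_m/c_o = 2 k_a/k_d."""
        params = tk.KineticParams(0.05, 1e-3, np.inf)
        eq = tk.equilibrium(params, geometry, 0.01)
        assert eq.c_m / eq.c_o == pytest.approx(2 * params.k_a / params.k_d, rel=1e-12)

    def test_partition_vanishes_with_adsorption(self, geometry):
        assert tk.partition_coefficient(
            tk.KineticParams(1e-10, 1e-3, 0.01), geometry, 0.01
        ) == pytest.approx(0.0, abs=1e-6)

    def test_partition_matches_simulated_long_run(self, geometry):
        params = tk.KineticParams(0.03, 8e-4, 0.03)
        grid = long_run_grid(params, geometry, 0.01)
        traj = tk.simulate(params, geometry, 0.01, grid)
        assert tk.partition_coefficient(params, geometry, 0.01) == pytest.approx(
            traj.c_m[-1] / traj.c_o[-1], rel=1e-6
        )

    def test_requires_positive_desorption(self, geometry):
        with pytest.raises(ValueError):
            tk.equilibrium(tk.KineticParams(0.05, 0.0, 0.01), geometry, 0.01)


class TestIntegratedFraction:
    def test_endpoints(self, preset_trajectories):
        f = tk.integrated_fraction(preset_trajectories["homogeneous_aap"])
        assert f[-1] == 1.0
        assert f[0] < 1e-2

    def test_matches_direct_recomputation(self, preset_trajectories):
        traj = preset_trajectories["amphiphilic_aap"]
        g = traj.geometry
        amount = g.phi_mem * traj.c_m + g.phi_in * traj.c_i
        np.testing.assert_allclose(
            tk.integrated_fraction(traj), amount / amount[-1], rtol=1e-14
        )

    def test_no_uptake_signalled(self, geometry):
        traj = tk.simulate(
            tk.KineticParams(0.0, 1e-3, 0.01), geometry, 0.01, np.logspace(0, 3, 20)
        )
        with pytest.raises(ValueError, match="uptake"):
            tk.integrated_fraction(traj)


class TestLimitingSlopes:
    def test_initial_slope_monotone_in_adsorption_rate(self, geometry):
        grid = np.logspace(-1, 5, 200)
        slopes = []
        for ka in [0.02, 0.04, 0.08, 0.16, 0.32]:
            traj = tk.simulate(tk.KineticParams(ka, 5e-4, 0.01), geometry, 0.01, grid)
            slopes.append(abs(tk.limiting_slopes(traj)[0]))
        assert np.all(np.diff(slopes) > 0)

    def test_terminal_slope_monotone_in_desorption_rate(self, geometry):
        slopes = []
        for kd in [1e-4, 2e-4, 4e-4, 8e-4, 1.6e-3]:
            params = tk.KineticParams(0.1, kd, 0.01)
            grid = long_run_grid(params, geometry, 0.01, horizon_factor=10.0)
            traj = tk.simulate(params, geometry, 0.01, grid)
            slopes.append(abs(tk.limiting_slopes(traj)[1]))
        assert np.all(np.diff(slopes) > 0)

    def test_flat_curve_signalled(self, geometry):
        traj = tk.simulate(
            tk.KineticParams(0.0, 1e-3, 0.01), geometry, 0.01, np.logspace(0, 3, 30)
        )
        with pytest.raises(ValueError):
            tk.limiting_slopes(traj)


class TestMoleculesPerVesicle:
    def test_zero_state_zero_counts(self, geometry):
        traj = tk.simulate(
            tk.KineticParams(0.0, 1e-3, 0.01), geometry, 0.01, np.logspace(0, 3, 20)
        )
        n_mem, n_in = tk.molecules_per_vesicle(traj, mw=12.0)
        assert np.all(n_mem == 0) and np.all(n_in == 0)

    def test_counts_inverse_in_molecular_weight(self, preset_trajectories):
        traj = preset_trajectories["homogeneous_aap"]
        n1 = tk.molecules_per_vesicle(traj, mw=6.0)
        n2 = tk.molecules_per_vesicle(traj, mw=12.0)
        np.testing.assert_allclose(n1[0], 2 * n2[0], rtol=1e-12)
        np.testing.assert_allclose(n1[1], 2 * n2[1], rtol=1e-12)

    def test_unit_conversion_oracle(self, preset_trajectories):
        """Hand unit chain: mass fraction -> g/cm^3 -> mol -> molecules."""
        traj = preset_trajectories["homogeneous_aap"]
        g = traj.geometry
        mw = 12.0  # kg/mol
        k = -1
        expected_mem = (
            traj.c_m[k] * 1.0 * (g.v_mem * 1e-21) / (mw * 1000.0) * 6.02214076e23
        )
        n_mem, _ = tk.molecules_per_vesicle(traj, mw=mw)
        assert n_mem[k] == pytest.approx(expected_mem, rel=1e-12)


class TestTranslocationTime:
    def test_censored_without_adsorption(self, geometry):
        traj = tk.simulate(
            tk.KineticParams(0.0, 1e-3, 0.01), geometry, 0.01, np.logspace(0, 3, 20)
        )
        t_star, censored = tk.translocation_time(traj)
        assert censored
        assert t_star == traj.times[-1]

    def test_faster_desorption_never_slows_translocation(self, geometry):
        t_stars = []
        for kd in [1e-4, 2e-4, 4e-4, 8e-4, 1.6e-3]:
            params = tk.KineticParams(0.1, kd, 0.01)
            grid = long_run_grid(params, geometry, 0.01, horizon_factor=20.0)
            traj = tk.simulate(params, geometry, 0.01, grid)
            t_star, censored = tk.translocation_time(traj)
            assert not censored
            t_stars.append(t_star)
        assert np.all(np.diff(t_stars) <= 0)

    def test_grid_refinement_stability(self, geometry, presets):
        sc = presets["homogeneous_aap"]
        lam = tk.equilibration_rate(sc.params, sc.geometry, sc.c_total)
        coarse = np.logspace(-1, np.log10(20 / lam), 80)
        fine = np.logspace(-1, np.log10(20 / lam), 800)
        t1, _ = tk.translocation_time(tk.simulate(sc.params, sc.geometry, sc.c_total, coarse))
        t2, _ = tk.translocation_time(tk.simulate(sc.params, sc.geometry, sc.c_total, fine))
        assert abs(t1 / t2 - 1) < 0.01
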