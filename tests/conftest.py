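import numpy as np
import pytest

import translokin as tk


@pytest.fixture(scope="session")
def geometry():
    """The measured vesicle geometry: 44 nm radius, 4 nm bilayer, 20 mg/mL lipid."""
    return tk.derive_geometry(R=44.0, d=4.0, c_lipid=20.0, rho_lipid=1.0)


@pytest.fixture(scope="session")
def presets():
    return {name: tk.get_preset(name) for name in tk.PRESETS}


@pytest.fixture(scope="session")
def homogeneous(presets):
    return presets["homogeneous_aap"]


def long_run_grid(params, geometry, c_total, horizon_factor=40.0, n=300):
    """Log grid reaching far past the slowest linearized relaxation."""
    lam = tk.equilibration_rate(params, geometry, c_total)
    t_end = horizon_factor / min(lam, params.k_d)
    return np.logspace(np.log10(min(0.01 / params.k_a, 1.0)), np.log10(t_end), n)


@pytest.fixture(scope="session")
def preset_trajectories(presets):
    out = {}
    for name, sc in presets.items():
        grid = long_run_grid(sc.params, sc.geometry, sc.c_total)
        out[name] = tk.simulate(sc.params, sc.geometry, sc.c_total, grid)
    return out
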