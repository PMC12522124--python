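"""Two-compartment saturating adsorption/desorption kinetics of polymer
exchange between the outer solution, the membrane, and the inner volume of
large unilamellar vesicles (LUVs).

The model tracks three mass-fraction concentrations: ``c_o`` in the outer
solution, ``c_m`` in the membrane, and ``c_i`` in the inner vesicle volume.
Polymer adsorbs into the membrane from both aqueous faces at rate ``k_a``
(throttled by a saturation factor ``1 - c_m/c_sat``) and desorbs at total
rate ``k_d``, split equally to the two faces.  All fluxes are written per
membrane volume, so the compartment equations carry the volume-fraction
ratios ``phi_mem/phi_in`` and ``phi_mem/phi_out``::

    dc_m/dt = k_a (c_o + c_i)(1 - c_m/c_sat) - k_d c_m
    dc_i/dt = (phi_mem/phi_in)  [ (k_d/2) c_m - k_a c_i (1 - c_m/c_sat) ]
    dc_o/dt = (phi_mem/phi_out) [ (k_d/2) c_m - k_a c_o (1 - c_m/c_sat) ]

The phi-weighted total concentration is conserved exactly, and detailed
balance forces ``c_i = c_o`` at equilibrium (passive, non-directional
transport).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import odeint

AVOGADRO = 6.02214076e23  # 1/mol

__all__ = [
    "PolymerSpec",
    "VesicleGeometry",
    "KineticParams",
    "CompartmentState",
    "Trajectory",
    "derive_geometry",
    "rate_equations",
    "simulate",
    "equilibrium",
    "equilibration_rate",
    "saturation_time",
    "integrated_fraction",
    "limiting_slopes",
    "molecules_per_vesicle",
    "translocation_time",
    "partition_coefficient",
]


@dataclass(frozen=True)
class PolymerSpec:
    """Descriptor of an alternating amphiphilic polymer P(C_m EG_n).

    Parameters
    ----------
    name : str
        Label, e.g. ``"P(C4EG4)2k"``.
    m : int or None
        Carbons per hydrophobic diacid unit (None for block architectures).
    n : int or None
        Ethylene-glycol monomers per hydrophilic unit.
    mw : float
        Molecular weight in kg/mol.
    lcst : float, optional
        Lower critical solution temperature in deg C (polarity proxy).
    triblock : bool
        True for blocky architectures (e.g. PEG-PPG-PEG) where m/n do not
        apply.
    """

    name: str
    mw: float
    m: Optional[int] = None
    n: Optional[int] = None
    lcst: Optional[float] = None
    triblock: bool = False

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.triblock:
            if self.m is not None or self.n is not None:
                raise ValueError("triblock polymers carry no (m, n) unit sizes")
        else:
            if self.m is None or self.n is None:
                raise ValueError("alternating polymers require m and n")
            if self.m < 0 or self.n < 0:
                raise ValueError("m and n must be non-negative")


@dataclass(frozen=True)
class VesicleGeometry:
    """Vesicle geometry and the compartment volume fractions it implies.

    The membrane volume fraction is identified with the lipid volume
    fraction, ``phi_mem = c_lipid / rho_lipid``; the vesicle number density
    and the inner volume fraction follow from the sphere-shell volumes.

    Parameters
    ----------
    R : float
        Outer vesicle radius (nm).
    d : float
        Bilayer thickness (nm).
    c_lipid : float
        Lipid mass concentration (mg/mL).
    rho_lipid : float
        Lipid mass density (g/mL).
    """

    R: float
    d: float
    c_lipid: float
    rho_lipid: float = 1.0
    v_in: float = field(init=False)
    v_mem: float = field(init=False)
    phi_mem: float = field(init=False)
    phi_in: float = field(init=False)
    phi_out: float = field(init=False)
    n_ves: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.d < self.R:
            raise ValueError(f"need 0 < d < R, got d={self.d}, R={self.R}")
        if self.c_lipid < 0 or self.rho_lipid <= 0:
            raise ValueError("c_lipid must be >= 0 and rho_lipid > 0")
        phi_mem = self.c_lipid / (1000.0 * self.rho_lipid)
        if phi_mem >= 1:
            raise ValueError("lipid volume fraction >= 1; c_lipid/rho_lipid too large")
        r_in = self.R - self.d
        v_in = 4.0 / 3.0 * np.pi * r_in**3
        v_mem = 4.0 / 3.0 * np.pi * (self.R**3 - r_in**3)
        n_ves = phi_mem / v_mem if v_mem > 0 else 0.0  # per nm^3
        phi_in = n_ves * v_in
        phi_out = 1.0 - phi_in - phi_mem
        if phi_out <= 0:
            raise ValueError("phi_out <= 0: suspension over-concentrated")
        object.__setattr__(self, "v_in", v_in)
        object.__setattr__(self, "v_mem", v_mem)
        object.__setattr__(self, "phi_mem", phi_mem)
        object.__setattr__(self, "phi_in", phi_in)
        object.__setattr__(self, "phi_out", phi_out)
        object.__setattr__(self, "n_ves", n_ves)


def derive_geometry(R: float, d: float, c_lipid: float, rho_lipid: float = 1.0) -> VesicleGeometry:
    """Build a :class:`VesicleGeometry` from radius, bilayer thickness and
    lipid loading.  See the class docstring for units and conventions."""
    return VesicleGeometry(R=R, d=d, c_lipid=c_lipid, rho_lipid=rho_lipid)


@dataclass(frozen=True)
class KineticParams:
    """Rate parameters of the exchange model.

    ``k_a`` (1/s) acts on the reservoir mass-fraction concentration at each
    membrane face; ``k_d`` (1/s) is the total desorption rate (split equally
    between the two faces); ``c_sat`` is the saturation membrane
    concentration (mass fraction) at which adsorption shuts off.
    """

    k_a: float
    k_d: float
    c_sat: float

    def __post_init__(self) -> None:
        if self.k_a < 0 or self.k_d < 0 or self.c_sat < 0:
            raise ValueError("rates and c_sat must be non-negative")
        if self.k_a > 0 and self.c_sat == 0:
            raise ValueError("c_sat must be positive when k_a > 0")


@dataclass(frozen=True)
class CompartmentState:
    """Snapshot of the three compartment concentrations (mass fractions)."""

    c_o: float
    c_m: float
    c_i: float

    def __post_init__(self) -> None:
        if min(self.c_o, self.c_m, self.c_i) < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class Trajectory:
    """Time course of the compartment concentrations.

    Attributes
    ----------
    times : ndarray
        Strictly increasing times (s).
    c_o, c_m, c_i : ndarray
        Compartment concentrations at each time.
    geometry : VesicleGeometry
    params : KineticParams
    c_total : float
        Conserved phi-weighted total concentration.
    """

    times: np.ndarray
    c_o: np.ndarray
    c_m: np.ndarray
    c_i: np.ndarray
    geometry: VesicleGeometry
    params: KineticParams
    c_total: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def state(self, idx: int) -> CompartmentState:
        return CompartmentState(self.c_o[idx], self.c_m[idx], self.c_i[idx])

    @property
    def total(self) -> np.ndarray:
        g = self.geometry
        return g.phi_out * self.c_o + g.phi_mem * self.c_m + g.phi_in * self.c_i

    def conservation_error(self) -> float:
        """Max relative deviation of phi-weighted total from ``c_total``."""
        return float(np.max(np.abs(self.total / self.c_total - 1.0)))


# ---------------------------------------------------------------------------
# rate equations and integration


def rate_equations(
    state: CompartmentState, params: KineticParams, geometry: VesicleGeometry
) -> tuple[float, float, float]:
    """Time derivatives ``(dc_o/dt, dc_m/dt, dc_i/dt)`` of the exchange model.

    Returned as a plain tuple (derivatives may be negative, so they are not a
    valid :class:`CompartmentState`).  The phi-weighted sum of the three
    derivatives is identically zero.
    """
    dco, dcm, dci = _rhs(
        (state.c_o, state.c_m, state.c_i), 0.0,
        params.k_a, params.k_d, params.c_sat,
        geometry.phi_mem / geometry.phi_out, geometry.phi_mem / geometry.phi_in,
    )
    return (dco, dcm, dci)


def _rhs(y, t, k_a, k_d, c_sat, a_o, a_i):
    c_o, c_m, c_i = y
    sat = 1.0 - c_m / c_sat if c_sat > 0 else 1.0
    ads_o = k_a * c_o * sat
    ads_i = k_a * c_i * sat
    des = k_d * c_m
    return (
        a_o * (0.5 * des - ads_o),
        ads_o + ads_i - des,
        a_i * (0.5 * des - ads_i),
    )


def _jac(y, t, k_a, k_d, c_sat, a_o, a_i):
    c_o, c_m, c_i = y
    inv_cs = 1.0 / c_sat if c_sat > 0 else 0.0
    sat = 1.0 - c_m * inv_cs
    return [
        [-a_o * k_a * sat, a_o * (0.5 * k_d + k_a * c_o * inv_cs), 0.0],
        [k_a * sat, -k_a * (c_o + c_i) * inv_cs - k_d, k_a * sat],
        [0.0, a_i * (0.5 * k_d + k_a * c_i * inv_cs), -a_i * k_a * sat],
    ]


def simulate(
    params: KineticParams,
    geometry: VesicleGeometry,
    c_total: float,
    t_grid: np.ndarray,
    initial_state: Optional[CompartmentState] = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the rate equations on ``t_grid``.

    The default initial condition places all polymer outside
    (``c_o(0) = c_total/phi_out``, empty membrane and inner volume), matching
    polymer added to a pre-formed vesicle suspension.  Integration uses LSODA
    with the analytic Jacobian; the k_a >> k_d regimes are stiff.

    Raises
    ------
    RuntimeError
        If the integrator fails; diagnostics are attached to the message.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D, strictly increasing, length >= 2")
    if c_total < 0:
        raise ValueError("c_total must be non-negative")
    if initial_state is None:
        y0 = (c_total / geometry.phi_out, 0.0, 0.0)
    else:
        y0 = (initial_state.c_o, initial_state.c_m, initial_state.c_i)
    ts = t_grid
    prepend = ts[0] > 0.0
    if prepend:
        ts = np.concatenate([[0.0], ts])
    args = (
        params.k_a, params.k_d, params.c_sat,
        geometry.phi_mem / geometry.phi_out, geometry.phi_mem / geometry.phi_in,
    )
    ys, info = odeint(
        _rhs, y0, ts, args=args, Dfun=_jac, rtol=rtol, atol=atol, full_output=True
    )
    if info["message"] != "Integration successful.":
        raise RuntimeError(
            f"ODE integration failed: {info['message']} (tcur={info.get('tcur')})"
        )
    if prepend:
        ys = ys[1:]
    ys = np.clip(ys, 0.0, None)  # clip integrator-tolerance negatives
    return Trajectory(
        times=t_grid,
        c_o=ys[:, 0],
        c_m=ys[:, 1],
        c_i=ys[:, 2],
        geometry=geometry,
        params=params,
        c_total=c_total,
    )


def equilibrium(
    params: KineticParams, geometry: VesicleGeometry, c_total: float
) -> CompartmentState:
    """Closed-form equilibrium state from detailed balance.

    At equilibrium each face balances individually, forcing
    ``c_i = c_o = c`` and ``c_m = k_a c / (k_d/2 + k_a c / c_sat)``; mass
    conservation then gives a quadratic in ``c`` whose positive root is
    returned.
    """
    if params.k_d <= 0:
        raise ValueError("equilibrium requires k_d > 0")
    g = geometry
    A = g.phi_out + g.phi_in
    B = g.phi_mem
    ka, kd, cs = params.k_a, params.k_d, params.c_sat
    if ka == 0:
        c = c_total / A
        return CompartmentState(c_o=c, c_m=0.0, c_i=c)
    if not np.isfinite(cs):
        # linear-partition limit: c_m = (2 k_a / k_d) c
        c = c_total / (A + 2.0 * B * ka / kd)
        return CompartmentState(c_o=c, c_m=2.0 * ka / kd * c, c_i=c)
    a = A * ka / cs
    b = A * kd / 2.0 + B * ka - c_total * ka / cs
    cc = -c_total * kd / 2.0
    # numerically stable positive root of a c^2 + b c + cc = 0 (cc <= 0)
    disc = np.sqrt(b * b - 4.0 * a * cc)
    c = (2.0 * cc) / (-b - disc) if b >= 0 else (-b + disc) / (2.0 * a)
    c_m = ka * c / (kd / 2.0 + ka * c / cs)
    return CompartmentState(c_o=c, c_m=c_m, c_i=c)


def equilibration_rate(
    params: KineticParams, geometry: VesicleGeometry, c_total: float
) -> float:
    """Linearized slow relaxation rate of the inner/outer imbalance (1/s).

    Treating the membrane as quasi-steady near equilibrium, the net
    outer-to-inner transfer is ``phi_mem * k_a (1 - c_m/c_sat) (c_o - c_i)/2``
    so the imbalance decays at

        lambda = (phi_mem/2) (1/phi_in + 1/phi_out) k_a (1 - c_m_eq/c_sat).

    Near membrane saturation this is throttled far below both k_a and k_d;
    it sets the horizon needed for full passive equilibration.
    """
    if params.k_a == 0:
        return 0.0
    eq = equilibrium(params, geometry, c_total)
    sat = 1.0 - (eq.c_m / params.c_sat if np.isfinite(params.c_sat) else 0.0)
    g = geometry
    return 0.5 * g.phi_mem * (1.0 / g.phi_in + 1.0 / g.phi_out) * params.k_a * sat


def saturation_time(
    params: KineticParams,
    geometry: VesicleGeometry,
    c_total: float,
    frac: float = 0.99,
    n_grid: int = 400,
) -> float:
    """First time the LUV-integrated amount reaches ``frac`` of its
    equilibrium value (the point where measured kinetics look saturated).

    Located on a dense log grid spanning both the adsorption and the slow
    equilibration time scale, with linear interpolation between grid points.
    """
    if params.k_a <= 0 or params.k_d <= 0:
        raise ValueError("saturation_time requires k_a > 0 and k_d > 0")
    lam = equilibration_rate(params, geometry, c_total)
    t_hi = 20.0 / min(lam, params.k_d) if lam > 0 else 20.0 / params.k_d
    t_lo = min(1e-3 / params.k_a, t_hi * 1e-9)
    grid = np.logspace(np.log10(t_lo), np.log10(t_hi), n_grid)
    traj = simulate(params, geometry, c_total, grid, rtol=1e-8)
    g = geometry
    eq = equilibrium(params, geometry, c_total)
    amount = g.phi_mem * traj.c_m + g.phi_in * traj.c_i
    target = frac * (g.phi_mem * eq.c_m + g.phi_in * eq.c_i)
    idx = np.searchsorted(amount >= target, True)
    if idx >= len(grid):
        return float(grid[-1])
    if idx == 0:
        return float(grid[0])
    a0, a1 = amount[idx - 1], amount[idx]
    w = (target - a0) / (a1 - a0)
    return float(grid[idx - 1] + w * (grid[idx] - grid[idx - 1]))


# ---------------------------------------------------------------------------
# derived observables


def integrated_fraction(traj: Trajectory) -> np.ndarray:
    """Normalized LUV-integrated amount f(t), the ideal kinetic observable.

    f(t) = [phi_mem c_m(t) + phi_in c_i(t)] / [same at t_max]; f(t_max) = 1.
    """
    g = traj.geometry
    amount = g.phi_mem * traj.c_m + g.phi_in * traj.c_i
    denom = amount[-1]
    if denom <= 0:
        raise ValueError("no LUV uptake: integrated amount is zero at t_max")
    return amount / denom


def limiting_slopes(
    traj: Trajectory,
    initial_frac: float = 0.15,
    terminal_frac: float = 0.25,
) -> tuple[float, float]:
    """Initial and terminal slopes of ln(1 - f(t)/f(t_max)).

    The initial slope tracks the adsorption rate (fast membrane loading of
    nearly empty LUVs), the terminal slope the desorption-limited filling of
    the inner volume.  Least-squares fits are taken over the first
    ``initial_frac`` and last ``terminal_frac`` of the points with finite
    log values.
    """
    f = integrated_fraction(traj)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(1.0 - f / f[-1])
    mask = np.isfinite(y)
    t, y = traj.times[mask], y[mask]
    if len(t) < 10:
        raise ValueError("degenerate trajectory: too few finite log points")
    n0 = max(int(round(initial_frac * len(t))), 5)
    n1 = max(int(round(terminal_frac * len(t))), 5)
    if n0 + n1 > len(t):
        raise ValueError("trajectory does not resolve two regimes")
    if np.sum(~mask) > 1:  # only the final point is expected to be excluded
        warnings.warn("non-finite log values excluded from slope fit")
    s0 = np.polyfit(t[:n0], y[:n0], 1)[0]
    s1 = np.polyfit(t[-n1:], y[-n1:], 1)[0]
    return float(s0), float(s1)


def molecules_per_vesicle(
    traj: Trajectory, mw: float, sample_density: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vesicle polymer counts in the membrane and in the inner volume.

    Mass fractions convert to mass concentrations through ``sample_density``
    (g/mL); counts are ``c * rho * V * N_A / M`` with compartment volumes in
    nm^3 and ``mw`` in kg/mol.
    """
    if mw <= 0:
        raise ValueError("mw must be positive")
    g = traj.geometry
    if g.n_ves <= 0:
        raise ValueError("geometry has no vesicles")
    nm3_to_cm3 = 1e-21
    scale = sample_density * nm3_to_cm3 * AVOGADRO / (mw * 1000.0)
    return traj.c_m * g.v_mem * scale, traj.c_i * g.v_in * scale


def translocation_time(traj: Trajectory) -> tuple[float, bool]:
    """Effective translocation time: first t with c_i >= (1 - 1/e) c_o.

    Returns ``(t_star, censored)``.  If the threshold is never reached within
    the trajectory, the last grid time is returned as an open lower bound
    with ``censored=True``.
    """
    thr = 1.0 - 1.0 / np.e
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(traj.c_o > 0, traj.c_i / traj.c_o, np.inf)
    if ratio[0] >= thr:
        raise ValueError("initial state already beyond the (1 - 1/e) threshold")
    above = ratio >= thr
    if not above.any():
        return float(traj.times[-1]), True
    idx = int(np.argmax(above))
    r0, r1 = ratio[idx - 1], ratio[idx]
    w = (thr - r0) / (r1 - r0)
    t_star = traj.times[idx - 1] + w * (traj.times[idx] - traj.times[idx - 1])
    return float(t_star), False


def partition_coefficient(
    params: KineticParams, geometry: VesicleGeometry, c_total: float
) -> float:
    """Equilibrium membrane/water partition coefficient c_pm / c_po."""
    eq = equilibrium(params, geometry, c_total)
    return eq.c_m / eq.c_o
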