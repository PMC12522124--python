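"""Specular neutron reflectometry of a supported lipid bilayer with solvent
and polymer penetration.

The sample is modeled as a stack of homogeneous slabs: Si substrate, SiO2,
a thin water layer, the inner headgroup/tail and outer tail/headgroup of the
bilayer, an optional polymer brush layer, and bulk solvent.  Each layer's
scattering length density (SLD) is the volume-fraction mixture of its base
material with solvent and polymer.  Reflectivity is computed by the exact
Parratt recursion with Nevot-Croce roughness factors and optional Gaussian
q-resolution smearing.  Composition extraction converts fitted volume
fractions into the polymer mass concentration of a membrane region.

SLD values are given throughout in units of 1e-6 A^-2; q in A^-1; lengths
in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf
from sklearn.base import BaseEstimator

AVOGADRO = 6.02214076e23

__all__ = [
    "Material",
    "Layer",
    "SlabStack",
    "SLDProfile",
    "ReflectivityCurve",
    "MATERIALS",
    "sld_from_scattering_length",
    "mixed_sld",
    "render_profile",
    "reflectivity",
    "fresnel_reflectivity",
    "joint_residual",
    "polymer_mass_fraction",
    "ReflectivityFitter",
]


@dataclass(frozen=True)
class Material:
    """Homogeneous material with neutron SLD (1e-6 A^-2) and mass density
    (g/cm^3, needed only for mass-concentration conversions)."""

    name: str
    sld: float
    mass_density: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.sld):
            raise ValueError("sld must be finite")
        if self.mass_density is not None and self.mass_density <= 0:
            raise ValueError("mass_density must be positive")


def sld_from_scattering_length(
    b_sum_fm: float, molar_mass: float, mass_density: float
) -> float:
    """SLD (1e-6 A^-2) from the summed coherent scattering length of one
    formula unit (fm), its molar mass (g/mol) and mass density (g/cm^3).

    Implements rho = n b with number density n = density * N_A / M.
    """
    n_per_A3 = mass_density * AVOGADRO / molar_mass * 1e-24
    return n_per_A3 * b_sum_fm * 1e-5 * 1e6


#: editable literature defaults; the deuterated POPC values refer to the
#: chain-perdeuterated lipid whose SLD sits close to D2O.
MATERIALS = {
    "si": Material("si", 2.07, 2.33),
    "sio2": Material("sio2", 3.47, 2.20),
    "h2o": Material("h2o", -0.56, 1.00),
    "d2o": Material("d2o", 6.36, 1.107),
    "popc_d82_tails": Material("popc_d82_tails", 6.9, 0.95),
    "popc_d82_heads": Material("popc_d82_heads", 6.5, 1.05),
    "peg": Material("peg", 0.64, 1.13),
    "ppg": Material("ppg", 0.34, 1.00),
    "aap": Material("aap", 0.55, 1.10),
}


@dataclass(frozen=True)
class Layer:
    """Slab with base material plus solvent and polymer volume fractions.

    ``roughness`` describes the interface to the *previous* (substrate-side)
    layer.  A pure solvent gap (the thin water layer under the bilayer) is a
    layer with ``phi_solvent = 1``.
    """

    thickness: float
    material: Material
    roughness: float = 0.0
    phi_solvent: float = 0.0
    phi_polymer: float = 0.0
    polymer: Optional[Material] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.thickness < 0 or self.roughness < 0:
            raise ValueError("thickness and roughness must be non-negative")
        if self.phi_solvent < 0 or self.phi_polymer < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.phi_solvent + self.phi_polymer > 1 + 1e-12:
            raise ValueError("phi_solvent + phi_polymer must not exceed 1")


@dataclass(frozen=True)
class SlabStack:
    """Ordered stack: semi-infinite fronting (substrate), finite layers,
    semi-infinite backing solvent (set per contrast at evaluation time).

    ``backing_roughness`` is the roughness of the final layer/solvent
    interface.  The shared structural parameters (thicknesses, roughnesses,
    volume fractions) are contrast-independent; only the solvent SLD changes
    between H2O and D2O.
    """

    fronting: Material
    layers: tuple[Layer, ...]
    backing_roughness: float = 0.0
    polymer: Optional[Material] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))

    def effective_slds(self, solvent: Material) -> np.ndarray:
        """Per-medium SLDs (fronting, layers..., solvent) at one contrast."""
        rho = [self.fronting.sld]
        rho += [mixed_sld(lay, solvent, lay.polymer or self.polymer) for lay in self.layers]
        rho.append(solvent.sld)
        return np.asarray(rho)

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([lay.thickness for lay in self.layers])

    @property
    def roughnesses(self) -> np.ndarray:
        """Roughness of each interface, substrate side first."""
        return np.array([lay.roughness for lay in self.layers] + [self.backing_roughness])


@dataclass
class SLDProfile:
    """Real-space SLD profile rho(z); z in Angstrom, rho in 1e-6 A^-2."""

    z: np.ndarray
    rho: np.ndarray


@dataclass
class ReflectivityCurve:
    """Specular reflectivity versus momentum transfer q_z = (4 pi/lambda) sin(theta)."""

    q: np.ndarray
    R: np.ndarray
    dR: Optional[np.ndarray] = None
    contrast: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if self.dR is not None:
            self.dR = np.asarray(self.dR, dtype=float)


def mixed_sld(layer: Layer, solvent: Material, polymer: Optional[Material] = None) -> float:
    """Effective SLD of a layer penetrated by solvent and polymer.

    rho_eff = (1 - phi_s - phi_p) rho_base + phi_s rho_solvent
              + phi_p rho_polymer
    """
    phi_s, phi_p = layer.phi_solvent, layer.phi_polymer
    if phi_s + phi_p > 1 + 1e-12:
        raise ValueError("volume fractions exceed 1")
    rho = (1.0 - phi_s - phi_p) * layer.material.sld + phi_s * solvent.sld
    if phi_p > 0:
        poly = polymer or layer.polymer
        if poly is None:
            raise ValueError("polymer material required when phi_polymer > 0")
        rho += phi_p * poly.sld
    return float(rho)


def render_profile(
    stack: SlabStack, contrast: Material, z_step: float = 0.5, pad: Optional[float] = None
) -> SLDProfile:
    """Real-space SLD profile with error-function smoothed interfaces.

    Each interface at depth z_k with roughness sigma_k contributes a smooth
    step ``(rho_{k+1} - rho_k) * 0.5 (1 + erf((z - z_k)/(sqrt(2) sigma_k)))``.
    A warning is issued when a roughness exceeds an adjacent thickness
    (overlapping interfaces render fine but are physically questionable).
    """
    rho = stack.effective_slds(contrast)
    d = stack.thicknesses
    sig = stack.roughnesses
    z_if = np.concatenate([[0.0], np.cumsum(d)])
    for k, s in enumerate(sig):
        neighbors = []
        if k > 0:
            neighbors.append(d[k - 1])
        if k < len(d):
            neighbors.append(d[k])
        if neighbors and s > min(neighbors) > 0:
            warnings.warn(f"roughness {s} A exceeds adjacent thickness at interface {k}")
    if pad is None:
        pad = 4.0 * max(sig.max(initial=0.0), 1.0) + 20.0
    z = np.arange(-pad, z_if[-1] + pad + z_step, z_step)
    prof = np.full_like(z, rho[0])
    for k in range(len(z_if)):
        s = sig[k]
        if s > 0:
            step = 0.5 * (1.0 + erf((z - z_if[k]) / (np.sqrt(2.0) * s)))
        else:
            step = (z >= z_if[k]).astype(float)
        prof = prof + (rho[k + 1] - rho[k]) * step
    return SLDProfile(z=z, rho=prof)


def _parratt_amplitude(q: np.ndarray, rho: np.ndarray, d: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Complex reflection amplitude via the Parratt recursion.

    ``rho`` per medium in 1e-6 A^-2 (fronting first), ``d`` per finite layer,
    ``sig`` per interface; Nevot-Croce factors on each interface amplitude.
    """
    q = np.asarray(q, dtype=float)
    kz0 = q / 2.0
    rho_abs = rho * 1e-6
    # kz in each medium, measured against the fronting
    kz = np.sqrt(kz0[None, :] ** 2 - 4.0 * np.pi * (rho_abs[:, None] - rho_abs[0]) + 0j)
    n_if = len(rho) - 1
    r_amp = np.zeros_like(kz0, dtype=complex)
    for i in range(n_if - 1, -1, -1):
        ki, kj = kz[i], kz[i + 1]
        r = (ki - kj) / (ki + kj) * np.exp(-2.0 * ki * kj * sig[i] ** 2)
        if i == n_if - 1:
            r_amp = r
        else:
            phase = np.exp(2j * kj * d[i])
            r_amp = (r + r_amp * phase) / (1.0 + r * r_amp * phase)
    return r_amp


def reflectivity(
    stack: SlabStack,
    contrast: Material,
    q: np.ndarray,
    resolution: Optional[float] = None,
    n_smear: int = 17,
) -> ReflectivityCurve:
    """Specular reflectivity of the stack at one solvent contrast.

    Parameters
    ----------
    q : array
        Momentum transfer grid (A^-1), positive increasing.
    resolution : float, optional
        Constant relative resolution dq/q (FWHM) for Gaussian smearing;
        None disables smearing (the instrument default here is 0.10,
        matching a 10% wavelength spread).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be positive and increasing")
    rho = stack.effective_slds(contrast)
    d = stack.thicknesses
    if np.any(d < 0):
        raise ValueError("negative layer thickness")
    sig = stack.roughnesses

    def compute(qv: np.ndarray) -> np.ndarray:
        return np.abs(_parratt_amplitude(qv, rho, d, sig)) ** 2

    if not resolution:
        R = compute(q)
    else:
        sigma_rel = resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        offsets = np.linspace(-2.5, 2.5, n_smear)
        w = np.exp(-0.5 * offsets**2)
        w /= w.sum()
        qs = q[None, :] * (1.0 + sigma_rel * offsets[:, None])
        R = w @ compute(qs.ravel()).reshape(n_smear, -1)
    return ReflectivityCurve(q=q, R=R, contrast=contrast.name)


def fresnel_reflectivity(
    q: np.ndarray, sld_front: float, sld_back: float, roughness: float = 0.0
) -> np.ndarray:
    """Closed-form Fresnel reflectivity of a single interface (with an
    optional Nevot-Croce roughness factor); oracle for the slab engine."""
    q = np.asarray(q, dtype=float)
    kz0 = q / 2.0
    kz1 = np.sqrt(kz0**2 - 4.0 * np.pi * (sld_back - sld_front) * 1e-6 + 0j)
    r = (kz0 - kz1) / (kz0 + kz1) * np.exp(-2.0 * kz0 * kz1 * roughness**2)
    return np.abs(r) ** 2


def joint_residual(
    stack: SlabStack,
    curves: Sequence[ReflectivityCurve],
    contrasts: Sequence[Material],
    resolution: Optional[float] = None,
) -> float:
    """Summed chi-square of the stack against multi-contrast data.

    The structural parameters are shared; only the solvent SLD differs per
    curve.  Points without dR get unit weights.
    """
    if len(curves) != len(contrasts):
        raise ValueError("need one contrast material per curve")
    chi2 = 0.0
    for curve, solvent in zip(curves, contrasts):
        model = reflectivity(stack, solvent, curve.q, resolution=resolution)
        w = curve.dR if curve.dR is not None else np.ones_like(curve.R)
        chi2 += float(np.sum(((curve.R - model.R) / w) ** 2))
    return chi2


def polymer_mass_fraction(
    layers: Sequence[Layer],
    polymer: Material,
    lipid: Optional[Material] = None,
    include_solvent: bool = False,
    solvent: Optional[Material] = None,
) -> float:
    """Polymer mass concentration (%) of a membrane region.

    Aggregates thickness-weighted over the selected layers:

        mass% = 100 * sum(d phi_p rho_p)
                      / sum(d (phi_p rho_p + phi_lipid rho_lipid [+ phi_s rho_s]))

    with ``phi_lipid = 1 - phi_solvent - phi_polymer``.  By default the mass
    basis is polymer + lipid only (solvent excluded); pass
    ``include_solvent=True`` with a solvent material for the
    solvent-inclusive variant.  Lipid densities come from each layer's base
    material unless ``lipid`` overrides them.
    """
    if polymer.mass_density is None:
        raise ValueError("polymer material needs a mass density")
    num = 0.0
    den = 0.0
    for lay in layers:
        base = lipid or lay.material
        if base.mass_density is None:
            raise ValueError(f"layer material {base.name!r} needs a mass density")
        phi_lip = 1.0 - lay.phi_solvent - lay.phi_polymer
        m_p = lay.thickness * lay.phi_polymer * polymer.mass_density
        m_l = lay.thickness * phi_lip * base.mass_density
        num += m_p
        den += m_p + m_l
        if include_solvent:
            if solvent is None or solvent.mass_density is None:
                raise ValueError("include_solvent requires a solvent with density")
            den += lay.thickness * lay.phi_solvent * solvent.mass_density
    if den <= 0:
        raise ValueError("zero total mass basis in the selected region")
    return 100.0 * num / den


class ReflectivityFitter(BaseEstimator):
    """Least-squares co-refinement of selected stack parameters across
    contrasts (plumbing around :func:`joint_residual`).

    Parameters
    ----------
    stack : SlabStack
        Starting model; shared across all contrasts.
    free : sequence of (layer_index, attribute) pairs
        Layer attributes to vary (``"thickness"``, ``"roughness"``,
        ``"phi_solvent"``, ``"phi_polymer"``).
    bounds : sequence of (lo, hi) pairs matching ``free``.
    resolution : float, optional
        dq/q FWHM smearing applied to the model.

    Attributes
    ----------
    stack_ : SlabStack
        Refined stack.
    chi2_ : float
        Final summed chi-square.
    params_ : ndarray
        Refined free-parameter values.
    """

    def __init__(self, stack=None, free=(), bounds=None, resolution=None):
        self.stack = stack
        self.free = free
        self.bounds = bounds
        self.resolution = resolution

    def _apply(self, values: np.ndarray) -> SlabStack:
        layers = list(self.stack.layers)
        for (idx, attr), val in zip(self.free, values):
            layers[idx] = replace(layers[idx], **{attr: float(val)})
        return replace(self.stack, layers=tuple(layers))

    def fit(self, curves: Sequence[ReflectivityCurve], contrasts: Sequence[Material]):
        if self.stack is None or not self.free:
            raise ValueError("stack and free parameters must be set")
        x0 = np.array([getattr(self.stack.layers[i], a) for i, a in self.free])
        if self.bounds is None:
            lo = np.zeros_like(x0)
            hi = np.full_like(x0, np.inf)
        else:
            lo, hi = np.asarray(self.bounds, dtype=float).T

        def residuals(x):
            st = self._apply(x)
            out = []
            for curve, solvent in zip(curves, contrasts):
                model = reflectivity(st, solvent, curve.q, resolution=self.resolution)
                w = curve.dR if curve.dR is not None else np.ones_like(curve.R)
                out.append((curve.R - model.R) / w)
            return np.concatenate(out)

        res = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi))
        self.params_ = res.x
        self.stack_ = self._apply(res.x)
        self.chi2_ = float(np.sum(res.fun**2))
        return self

    def predict(self, q, contrast: Material) -> np.ndarray:
        return reflectivity(self.stack_, contrast, np.asarray(q, dtype=float),
                            resolution=self.resolution).R
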