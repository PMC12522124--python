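"""Pulsed-field-gradient NMR observables for translocation kinetics.

Two measurement modes are covered:

* conventional diffusion PFG NMR — echo attenuation versus gradient encodes
  the self-diffusion coefficient, ``I(q^2)/I(0) = exp(-q^2 Delta D)`` with
  wavenumber ``q = gamma delta g``;
* kinetic (time-evolution) PFG NMR — the gradient is fixed high enough that
  the fast free-polymer signal is suppressed, so the residual echo amplitude
  tracks the LUV-integrated polymer amount over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .vesicle_kinetics import Trajectory

#: gyromagnetic ratios, rad s^-1 T^-1
GYROMAGNETIC = {"1H": 2.6752218744e8, "2H": 4.1066e7, "19F": 2.5181e8}

__all__ = [
    "GYROMAGNETIC",
    "PulseSequence",
    "EchoDecay",
    "KineticTrace",
    "wavenumber",
    "echo_attenuation",
    "fit_diffusion",
    "DiffusionFitter",
    "select_gradient",
    "trace_from_trajectory",
]


@dataclass(frozen=True)
class PulseSequence:
    """Stimulated-echo PFG sequence timing.

    Parameters
    ----------
    Delta : float
        Diffusion (observation) time, s.
    delta : float
        Gradient pulse length, s.
    g : float
        Gradient amplitude, T/m.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1 (default proton).
    """

    Delta: float = 0.100
    delta: float = 0.002
    g: float = 0.0
    gamma: float = GYROMAGNETIC["1H"]

    def __post_init__(self) -> None:
        if self.Delta <= 0 or self.delta <= 0 or self.gamma <= 0:
            raise ValueError("Delta, delta and gamma must be positive")
        if self.g < 0:
            raise ValueError("gradient amplitude must be non-negative")
        if self.delta >= self.Delta:
            raise ValueError("need delta < Delta")

    def with_gradient(self, g: float) -> "PulseSequence":
        return PulseSequence(Delta=self.Delta, delta=self.delta, g=g, gamma=self.gamma)


@dataclass
class EchoDecay:
    """Echo attenuation data: intensities versus q^2 (rad^2/m^2)."""

    q2_values: np.ndarray
    intensities: np.ndarray
    errors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q2_values = np.asarray(self.q2_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.q2_values.shape != self.intensities.shape:
            raise ValueError("q2 and intensity arrays must match")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.intensities.shape:
                raise ValueError("error array must match intensities")


@dataclass
class KineticTrace:
    """Normalized kinetic PFG-NMR trace I0(t)/I0(t_max) with noise levels."""

    times: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    sequence: Optional[PulseSequence] = None
    gradient: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), self.intensity.shape
        ).copy()
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must match")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


def wavenumber(seq: PulseSequence) -> float:
    """Gradient wavenumber q = gamma * delta * g (rad/m)."""
    return seq.gamma * seq.delta * seq.g


def echo_attenuation(D: float, seq: PulseSequence, stejskal_tanner: bool = False) -> float:
    """Echo intensity ratio I/I0 for diffusion coefficient ``D`` (m^2/s).

    Default is the simplified form ``exp(-q^2 Delta D)``; with
    ``stejskal_tanner=True`` the finite-pulse correction
    ``exp(-q^2 (Delta - delta/3) D)`` is used (sub-percent here, where
    delta/Delta = 2/100).
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    q = wavenumber(seq)
    t_eff = seq.Delta - seq.delta / 3.0 if stejskal_tanner else seq.Delta
    return float(np.exp(-(q**2) * t_eff * D))


class DiffusionFitter(RegressorMixin, BaseEstimator):
    """Weighted log-linear fit of an echo decay, slope = -D.

    Follows the scikit-learn estimator protocol: ``fit(X, y)`` with
    ``X = q^2 * Delta`` (s/m^2, column vector or 1-D) and ``y`` the
    normalized intensities.  Non-positive intensities are excluded with a
    warning.

    Attributes
    ----------
    D_ : float
        Fitted diffusion coefficient (m^2/s).
    D_err_ : float
        Standard error of ``D_`` from the weighted regression.
    intercept_ : float
        Fitted ln-intensity at q^2 = 0.
    """

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape or x.size < 3:
            raise ValueError("need >= 3 matching (q^2 Delta, intensity) points")
        keep = y > 0
        if not keep.all():
            warnings.warn("excluding non-positive intensities from diffusion fit")
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError("fewer than 3 positive intensities")
        logy = np.log(y)
        if sample_weight is None:
            w = np.ones_like(logy)
        else:
            w = np.asarray(sample_weight, dtype=float).reshape(-1)[keep]
        # weighted least squares on ln I = b - D x
        coef, cov = np.polyfit(x, logy, 1, w=np.sqrt(w), cov="unscaled")
        self.D_ = float(-coef[0])
        self.D_err_ = float(np.sqrt(cov[0, 0]))
        self.intercept_ = float(coef[1])
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.exp(self.intercept_ - self.D_ * x)


def fit_diffusion(decay: EchoDecay, Delta: float) -> tuple[float, float]:
    """Diffusion coefficient and its standard error from an echo decay.

    Thin wrapper over :class:`DiffusionFitter`; errors on intensities, when
    present, enter as inverse-variance weights on ln I.
    """
    x = decay.q2_values * Delta
    if decay.errors is not None:
        keep = decay.intensities > 0
        w = np.zeros_like(decay.intensities)
        w[keep] = (decay.intensities[keep] / np.where(keep, decay.errors, 1.0)[keep]) ** 2
        est = DiffusionFitter().fit(x, decay.intensities, sample_weight=w[keep])
    else:
        est = DiffusionFitter().fit(x, decay.intensities)
    return est.D_, est.D_err_


def select_gradient(
    D_free: float,
    seq: PulseSequence,
    suppression: float = 0.02,
    D_luv: Optional[float] = None,
    g_max: float = 30.0,
) -> tuple[float, Optional[float]]:
    """Smallest gradient suppressing the free-polymer echo to ``suppression``.

    Solves ``exp(-(gamma delta g)^2 Delta D_free) = suppression`` for ``g``.
    Returns ``(g, residual)`` where ``residual`` is the attenuation the
    LUV-bound species (``D_luv``) retains at that gradient, or None if
    ``D_luv`` is not given.

    Raises
    ------
    ValueError
        If the required gradient exceeds ``g_max`` (T/m).
    """
    if not 0 < suppression <= 1:
        raise ValueError("suppression must be in (0, 1]")
    if D_free <= 0:
        raise ValueError("D_free must be positive")
    if suppression == 1.0:
        g = 0.0
    else:
        g = float(np.sqrt(-np.log(suppression) / (seq.Delta * D_free)) / (seq.gamma * seq.delta))
    if g > g_max:
        raise ValueError(f"required gradient {g:.2f} T/m exceeds limit {g_max} T/m")
    residual = None
    if D_luv is not None:
        residual = echo_attenuation(D_luv, seq.with_gradient(g))
    return g, residual


def trace_from_trajectory(
    traj: Trajectory,
    seq: PulseSequence,
    D_free: float,
    D_luv: float,
    g: Optional[float] = None,
) -> KineticTrace:
    """Kinetic PFG-NMR trace implied by a model trajectory.

    The raw echo amplitude is the attenuation-weighted sum of the two
    species' signal amounts,

        S(t) = A_luv(t) att(D_luv) + A_free(t) att(D_free),

    with ``A_luv = phi_mem c_m + phi_in c_i`` and ``A_free = phi_out c_o``,
    normalized by its value at t_max.  With the free signal fully suppressed
    the trace reduces to :func:`integrated_fraction`.  The returned trace is
    noiseless (``sigma`` is a placeholder 1.0); noise is the synthetic-data
    generator's job.
    """
    seq_g = seq if g is None else seq.with_gradient(g)
    att_luv = echo_attenuation(D_luv, seq_g)
    att_free = echo_attenuation(D_free, seq_g)
    gm = traj.geometry
    a_luv = gm.phi_mem * traj.c_m + gm.phi_in * traj.c_i
    a_free = gm.phi_out * traj.c_o
    signal = a_luv * att_luv + a_free * att_free
    if signal[-1] <= 0:
        raise ValueError("zero signal at t_max")
    return KineticTrace(
        times=traj.times,
        intensity=signal / signal[-1],
        sigma=np.ones_like(signal),
        sequence=seq_g,
        gradient=seq_g.g,
        meta={"att_luv": att_luv, "att_free": att_free},
    )
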