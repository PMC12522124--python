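"""Bayesian inference of the exchange-rate parameters from kinetic traces.

The observable is the normalized LUV-integrated intensity I0(t)/I0(t_max).
Residuals against the model's integrated fraction are treated as i.i.d.
Gaussian; the three rate parameters (k_a, k_d, c_sat) are sampled in log10
space with a wide log-uniform prior using the affine-invariant ensemble
sampler (emcee).  The noise scale can either be taken from the trace's
per-point uncertainties or sampled as a fourth parameter.

Cross-sample utilities implement the error-weighted averaging used to pool
desorption rates across molecular weights, and the exponential molecular-
weight extrapolation used to predict filling kinetics for unmeasured chain
lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import emcee
import numpy as np
from sklearn.base import BaseEstimator

from .pfg_nmr import KineticTrace
from .vesicle_kinetics import (
    KineticParams,
    VesicleGeometry,
    integrated_fraction,
    simulate,
)

__all__ = [
    "PriorSpec",
    "Posterior",
    "WeightedEstimate",
    "FillingPrediction",
    "model_trace",
    "log_likelihood",
    "fit_mcmc",
    "KineticTraceFitter",
    "posterior_summary",
    "split_rhat",
    "weighted_average",
    "mw_extrapolate",
    "MWExtrapolator",
    "predict_filling",
]

PARAM_NAMES = ("k_a", "k_d", "c_sat")


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-uniform (default) or uniform box prior.

    Bounds are in natural parameter units; defaults are wide and
    uninformative relative to the decades spanned by measured rates.
    """

    k_a: tuple[float, float] = (1e-4, 1e2)
    k_d: tuple[float, float] = (1e-7, 1e-1)
    c_sat: tuple[float, float] = (1e-5, 1.0)
    sigma: tuple[float, float] = (1e-4, 1.0)  # used only when noise is fitted
    log_uniform: bool = True

    def __post_init__(self) -> None:
        for name in ("k_a", "k_d", "c_sat", "sigma"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"prior bounds for {name} must satisfy 0 < lo < hi")

    def bounds_log10(self, fit_sigma: bool = False) -> np.ndarray:
        names = PARAM_NAMES + (("sigma",) if fit_sigma else ())
        return np.log10([getattr(self, n) for n in names])


@dataclass
class Posterior:
    """MCMC samples over the kinetic parameters.

    ``chain`` has shape (n_steps, n_walkers, n_dim) and holds log10
    parameters in the order ``param_names``.
    """

    chain: np.ndarray
    log_prob: np.ndarray
    param_names: tuple[str, ...]
    acceptance_fraction: np.ndarray
    seed: Optional[int]
    burn_in: int

    @property
    def n_steps(self) -> int:
        return self.chain.shape[0]

    def flat(self, burn_in: Optional[int] = None, thin: int = 1) -> np.ndarray:
        """Post-burn-in samples on the natural (linear) scale, flattened to
        (n_samples, n_dim)."""
        b = self.burn_in if burn_in is None else burn_in
        if b >= self.n_steps:
            raise ValueError("burn_in must be smaller than the chain length")
        sub = self.chain[b::thin]
        return 10.0 ** sub.reshape(-1, sub.shape[-1])

    def map_params(self) -> np.ndarray:
        """Sample with the highest posterior density (linear scale)."""
        idx = np.unravel_index(np.argmax(self.log_prob), self.log_prob.shape)
        return 10.0 ** self.chain[idx]


@dataclass(frozen=True)
class WeightedEstimate:
    """Inverse-variance weighted mean with its standard uncertainty."""

    value: float
    uncertainty: float
    n_inputs: int


# ---------------------------------------------------------------------------
# likelihood


def model_trace(
    params: KineticParams,
    geometry: VesicleGeometry,
    c_total: float,
    times: np.ndarray,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Noiseless normalized kinetic trace at the given times.

    The model intensity is the integrated fraction normalized at the last
    time point, mirroring the experimental I0(t)/I0(t_max) normalization.
    """
    traj = simulate(params, geometry, c_total, times, rtol=rtol, atol=1e-13)
    return integrated_fraction(traj)


def log_likelihood(
    trace: KineticTrace,
    params: KineticParams,
    geometry: VesicleGeometry,
    c_total: float,
    sigma: Optional[float] = None,
    rtol: float = 1e-6,
) -> float:
    """Gaussian log-likelihood of a trace under the kinetic model.

    ``sigma`` overrides the per-point uncertainties stored on the trace
    (a single fitted noise scale).  Integrator failures and non-physical
    parameters map to ``-inf``.
    """
    try:
        mu = model_trace(params, geometry, c_total, trace.times, rtol=rtol)
    except (RuntimeError, ValueError) as err:
        warnings.warn(f"likelihood -inf: {err}")
        return -np.inf
    s = trace.sigma if sigma is None else np.full_like(trace.intensity, sigma)
    resid = (trace.intensity - mu) / s
    return float(-0.5 * np.sum(resid**2) - np.sum(np.log(s)) - 0.5 * len(s) * np.log(2 * np.pi))


def _make_log_prob(trace, geometry, c_total, prior, fit_sigma, rtol):
    lo, hi = prior.bounds_log10(fit_sigma).T
    times = trace.times
    data = trace.intensity
    sig_data = trace.sigma
    n = len(data)
    norm = -0.5 * n * np.log(2 * np.pi)

    def log_prob(theta: np.ndarray) -> float:
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        ka, kd, cs = 10.0 ** theta[:3]
        try:
            traj = simulate(
                KineticParams(ka, kd, cs), geometry, c_total, times, rtol=rtol, atol=1e-13
            )
            mu = integrated_fraction(traj)
        except (RuntimeError, ValueError):
            return -np.inf
        s = 10.0 ** theta[3] if fit_sigma else sig_data
        resid = (data - mu) / s
        if fit_sigma:
            log_s = n * theta[3] * np.log(10.0)
        else:
            log_s = np.sum(np.log(s))
        return float(-0.5 * np.sum(resid**2) - log_s + norm)

    return log_prob, lo, hi


def _initial_guess(log_prob, lo, hi, rng, n_scout: int = 192, n_refine: int = 4):
    """Coarse seeded scout search over the prior box followed by shrinking
    pattern searches from the best scouts; cheap and derivative-free, only
    needs to land the walker ball in the right posterior basin."""
    scouts = rng.uniform(lo, hi, size=(n_scout, len(lo)))
    vals = np.array([log_prob(t) for t in scouts])
    order = np.argsort(vals)[::-1]
    best, best_val = None, -np.inf

    def pattern(start, start_val):
        step = (hi - lo) / 8.0
        cur, cur_val = start.copy(), start_val
        for _ in range(5):
            improved = True
            while improved:
                improved = False
                for k in range(len(cur)):
                    for s in (+1, -1):
                        trial = cur.copy()
                        trial[k] = np.clip(trial[k] + s * step[k], lo[k], hi[k])
                        v = log_prob(trial)
                        if v > cur_val:
                            cur, cur_val, improved = trial, v, True
            step /= 3.0
        return cur, cur_val

    for idx in order[:n_refine]:
        cand, cand_val = pattern(scouts[idx], vals[idx])
        if cand_val > best_val:
            best, best_val = cand, cand_val
    return best


def fit_mcmc(
    trace: KineticTrace,
    geometry: VesicleGeometry,
    c_total: float,
    prior: Optional[PriorSpec] = None,
    n_walkers: int = 32,
    n_steps: int = 5000,
    burn_in: Optional[int] = None,
    seed: Optional[int] = None,
    fit_sigma: bool = False,
    rtol: float = 1e-6,
) -> Posterior:
    """Affine-invariant ensemble MCMC over (k_a, k_d, c_sat) in log10 space.

    Walkers start in a small Gaussian ball around a coarse seeded point
    estimate inside the prior box.  The run is bit-reproducible for a given
    seed.  Default chain settings are 32 walkers, 5000 steps and 20% burn-in.

    Raises
    ------
    RuntimeError
        If the ensemble is effectively stuck (mean acceptance < 1%).
    """
    prior = prior or PriorSpec()
    ndim = 4 if fit_sigma else 3
    if n_walkers < 2 * ndim:
        raise ValueError("need n_walkers >= 2 * n_params")
    if burn_in is None:
        burn_in = n_steps // 5
    if burn_in >= n_steps:
        raise ValueError("burn_in must be smaller than n_steps")
    rng = np.random.default_rng(seed)
    log_prob, lo, hi = _make_log_prob(trace, geometry, c_total, prior, fit_sigma, rtol)
    center = _initial_guess(log_prob, lo, hi, rng)
    p0 = center + 1e-2 * rng.standard_normal((n_walkers, ndim))
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    state = emcee.State(p0, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1) if seed is not None else None
    ).get_state())
    sampler.run_mcmc(state, n_steps, progress=False)
    acc = sampler.acceptance_fraction
    if np.mean(acc) < 0.01:
        raise RuntimeError("MCMC stuck: mean acceptance fraction below 1%")
    names = PARAM_NAMES + (("sigma",) if fit_sigma else ())
    return Posterior(
        chain=sampler.get_chain(),
        log_prob=sampler.get_log_prob(),
        param_names=names,
        acceptance_fraction=acc,
        seed=seed,
        burn_in=burn_in,
    )


def split_rhat(post: Posterior, burn_in: Optional[int] = None) -> np.ndarray:
    """Split-chain Gelman-Rubin convergence statistic per parameter.

    Each walker chain is split in half; values near 1 (< ~1.05) indicate
    convergence of the ensemble.
    """
    b = post.burn_in if burn_in is None else burn_in
    chain = post.chain[b:]
    n = chain.shape[0] // 2
    halves = np.concatenate([chain[:n], chain[n : 2 * n]], axis=1)  # (n, 2*walkers, d)
    mean_c = halves.mean(axis=0)
    var_c = halves.var(axis=0, ddof=1)
    W = var_c.mean(axis=0)
    B = n * mean_c.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return np.sqrt(var_hat / W)


def posterior_summary(
    post: Posterior, burn_in: Optional[int] = None, thin: int = 1
) -> dict:
    """Per-parameter medians, 68% and 95% credible intervals, and the MAP.

    Percentiles are taken on the natural (linear) parameter scale.
    """
    flat = post.flat(burn_in, thin)
    if flat.size == 0:
        raise ValueError("empty post-burn-in chain")
    qs = np.percentile(flat, [2.5, 16, 50, 84, 97.5], axis=0)
    out = {}
    for j, name in enumerate(post.param_names):
        out[name] = {
            "median": float(qs[2, j]),
            "ci68": (float(qs[1, j]), float(qs[3, j])),
            "ci95": (float(qs[0, j]), float(qs[4, j])),
        }
    map_p = post.map_params()
    for j, name in enumerate(post.param_names):
        out[name]["map"] = float(map_p[j])
    out["rhat"] = {n: float(r) for n, r in zip(post.param_names, split_rhat(post, burn_in))}
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator


class KineticTraceFitter(BaseEstimator):
    """Bayesian kinetic-trace fit as a scikit-learn estimator.

    Parameters mirror :func:`fit_mcmc`; the vesicle geometry and the total
    polymer concentration are model constants, not data, so they are
    constructor parameters.  ``fit(X, y)`` takes times (s) and normalized
    intensities; per-point noise goes in ``sigma``.

    Attributes
    ----------
    posterior_ : Posterior
    summary_ : dict
        Output of :func:`posterior_summary`.
    params_ : KineticParams
        Posterior medians.
    """

    def __init__(
        self,
        geometry: Optional[VesicleGeometry] = None,
        c_total: float = 0.01,
        prior: Optional[PriorSpec] = None,
        sigma: float = 0.02,
        n_walkers: int = 32,
        n_steps: int = 5000,
        burn_in: Optional[int] = None,
        fit_sigma: bool = False,
        rtol: float = 1e-6,
        random_state: Optional[int] = None,
    ):
        self.geometry = geometry
        self.c_total = c_total
        self.prior = prior
        self.sigma = sigma
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.burn_in = burn_in
        self.fit_sigma = fit_sigma
        self.rtol = rtol
        self.random_state = random_state

    def fit(self, X, y, sigma=None):
        if self.geometry is None:
            raise ValueError("geometry must be set before fitting")
        t = np.asarray(X, dtype=float).reshape(-1)
        trace = KineticTrace(
            times=t,
            intensity=np.asarray(y, dtype=float).reshape(-1),
            sigma=self.sigma if sigma is None else sigma,
        )
        self.posterior_ = fit_mcmc(
            trace,
            self.geometry,
            self.c_total,
            prior=self.prior,
            n_walkers=self.n_walkers,
            n_steps=self.n_steps,
            burn_in=self.burn_in,
            seed=self.random_state,
            fit_sigma=self.fit_sigma,
            rtol=self.rtol,
        )
        self.summary_ = posterior_summary(self.posterior_)
        self.params_ = KineticParams(
            *(self.summary_[n]["median"] for n in PARAM_NAMES)
        )
        self._t_max = t[-1]
        return self

    def predict(self, X):
        """Model trace at the posterior-median parameters, normalized at the
        training t_max."""
        t = np.asarray(X, dtype=float).reshape(-1)
        grid = np.unique(np.concatenate([t, [self._t_max]]))
        mu = model_trace(self.params_, self.geometry, self.c_total, grid, rtol=self.rtol)
        mu = mu / mu[np.searchsorted(grid, self._t_max)]
        return np.interp(t, grid, mu)


# ---------------------------------------------------------------------------
# aggregation and molecular-weight extrapolation


def weighted_average(values: Sequence[float], errors: Sequence[float]) -> WeightedEstimate:
    """Inverse-variance weighted mean; uncertainty = (sum of weights)^(-1/2)."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(errors, dtype=float)
    if v.shape != e.shape or v.ndim != 1 or v.size == 0:
        raise ValueError("values and errors must be matching non-empty 1-D arrays")
    if np.any(e <= 0):
        raise ValueError("errors must be positive")
    w = 1.0 / e**2
    return WeightedEstimate(
        value=float(np.sum(w * v) / np.sum(w)),
        uncertainty=float(1.0 / np.sqrt(np.sum(w))),
        n_inputs=int(v.size),
    )


class MWExtrapolator(BaseEstimator):
    """Molecular-weight extrapolation of a kinetic quantity.

    ``mode="exponential"`` fits ``value = A exp(B mw)`` by weighted linear
    regression of ln(value) on mw (used for adsorption rate and membrane
    concentration); ``mode="constant"`` is the error-weighted mean (used for
    the molecular-weight independent desorption rate).

    ``fit(X, y, y_err)`` with X the molecular weights (kg/mol).

    Attributes
    ----------
    coef_ : ndarray
        (ln A, B) for exponential mode; (value,) for constant mode.
    cov_ : ndarray
        Covariance of ``coef_``.
    """

    def __init__(self, mode: str = "exponential"):
        self.mode = mode

    def fit(self, X, y, y_err=None):
        mw = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        if y_err is None:
            e = np.ones_like(v)
        else:
            e = np.asarray(y_err, dtype=float).reshape(-1)
        if np.any(e <= 0):
            raise ValueError("errors must be positive")
        if self.mode == "constant":
            est = weighted_average(v, e)
            self.coef_ = np.array([est.value])
            self.cov_ = np.array([[est.uncertainty**2]])
            return self
        if self.mode != "exponential":
            raise ValueError("mode must be 'exponential' or 'constant'")
        if mw.size < 2:
            raise ValueError("exponential mode needs >= 2 points")
        if np.any(v <= 0):
            raise ValueError("exponential mode requires positive values")
        sig_ln = e / v  # delta-method error on ln(value)
        coef, cov = np.polyfit(mw, np.log(v), 1, w=1.0 / sig_ln, cov="unscaled")
        self.coef_ = coef[::-1].copy()  # (intercept=ln A, slope=B)
        self.cov_ = cov[::-1, ::-1].copy()
        return self

    def predict(self, X, return_std: bool = False):
        mw = np.atleast_1d(np.asarray(X, dtype=float))
        if self.mode == "constant":
            val = np.full_like(mw, self.coef_[0])
            std = np.full_like(mw, np.sqrt(self.cov_[0, 0]))
        else:
            lnv = self.coef_[0] + self.coef_[1] * mw
            design = np.stack([np.ones_like(mw), mw], axis=1)
            var_ln = np.einsum("ij,jk,ik->i", design, self.cov_, design)
            val = np.exp(lnv)
            std = val * np.sqrt(var_ln)
        if return_std:
            return val, std
        return val


def mw_extrapolate(
    series: Sequence[tuple[float, float, float]],
    target_mw: float,
    mode: str = "exponential",
) -> tuple[float, float]:
    """Predict a quantity at ``target_mw`` from (mw, value, error) triples.

    Thin wrapper over :class:`MWExtrapolator`; returns (value, uncertainty).
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("series must be (mw, value, error) triples")
    est = MWExtrapolator(mode=mode).fit(arr[:, 0], arr[:, 1], arr[:, 2])
    val, std = est.predict([target_mw], return_std=True)
    return float(val[0]), float(std[0])


# ---------------------------------------------------------------------------
# predicted filling curves


@dataclass
class FillingPrediction:
    """Inner-volume filling curve with a Monte-Carlo uncertainty band."""

    times: np.ndarray
    central: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    n_draws: int
    n_skipped: int
    draws: np.ndarray = field(repr=False, default=None)


def predict_filling(
    params: KineticParams,
    param_errors: dict,
    geometry: VesicleGeometry,
    c_total: float,
    t_grid: np.ndarray,
    n_draws: int = 200,
    seed: Optional[int] = None,
    rtol: float = 1e-7,
) -> FillingPrediction:
    """Filling curve c_i(t)/c_o(t) at extrapolated parameters with a band.

    The central curve is the simulation at the point estimates; the band is
    the 16-84 percentile envelope over ``n_draws`` Gaussian parameter draws
    (keys of ``param_errors``: standard deviations for ``k_a``, ``k_d``,
    ``c_sat``; missing keys mean no uncertainty).  Non-physical draws are
    skipped and counted.
    """
    if min(params.k_a, params.k_d, params.c_sat) <= 0:
        raise ValueError("extrapolated parameters must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)

    def ratio(p: KineticParams) -> np.ndarray:
        traj = simulate(p, geometry, c_total, t_grid, rtol=rtol)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(traj.c_o > 0, traj.c_i / traj.c_o, 0.0)

    central = ratio(params)
    sds = np.array([param_errors.get(n, 0.0) for n in PARAM_NAMES])
    means = np.array([params.k_a, params.k_d, params.c_sat])
    curves, skipped = [], 0
    for _ in range(n_draws):
        draw = means + sds * rng.standard_normal(3)
        if np.any(draw <= 0):
            skipped += 1
            continue
        try:
            curves.append(ratio(KineticParams(*draw)))
        except RuntimeError:
            skipped += 1
    if curves:
        stack = np.vstack(curves)
        lo, hi = np.percentile(stack, [16, 84], axis=0)
    else:
        stack = central[None, :]
        lo = hi = central
    return FillingPrediction(
        times=t_grid,
        central=central,
        band_lo=lo,
        band_hi=hi,
        n_draws=n_draws,
        n_skipped=skipped,
        draws=stack,
    )
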