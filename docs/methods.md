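# Methods

## Kinetic model

The transport model is a minimal three-compartment exchange scheme for a
polymer distributed between the outer solution, the bilayer membrane, and the
inner volume of large unilamellar vesicles. Its assumptions:

* Adsorption into the membrane happens at both faces with the same rate
  constant `k_a` (1/s), acting on the mass-fraction concentration of the
  adjacent reservoir, with fluxes expressed per membrane volume.
* The membrane holds at most `c_sat` (mass fraction); a single saturation
  factor `(1 − c_m/c_sat)` throttles adsorption from both sides.
* Desorption is first order with total rate `k_d` (1/s), split equally to
  the two faces. No direct outer↔inner pathway exists.
* Vesicles are monodisperse spheres (radius `R`, bilayer thickness `d`); the
  membrane volume is identified with the lipid volume,
  `φ_mem = c_lipid/ρ_lipid`, and the inner volume fraction follows from the
  vesicle number density. Defaults: `R = 44 nm`, `d = 4 nm`, 20 mg/mL lipid
  at 1.0 g/mL.

Because the same `k_a`, `k_d` act at both faces, detailed balance forces
`c_i = c_o` at equilibrium; the model transports passively and cannot pump.
The equilibrium is available in closed form (a quadratic in the common
aqueous concentration), and `simulate()` trajectories converge to it.

**Equilibration horizon.** Linearizing around equilibrium with the membrane
quasi-steady gives the slow inner/outer relaxation rate

    λ = (φ_mem/2)(1/φ_in + 1/φ_out) · k_a (1 − c_m_eq/c_sat).

When the membrane is nearly saturated (`c_m_eq → c_sat`, the regime that
produces pronounced two-step curves), λ is throttled orders of magnitude
below both `k_a` and `k_d`; full equilibration then takes many multiples of
`1/k_d`, not a fixed small multiple. Tests and horizon choices use λ
(`equilibration_rate`), and the generator's time grids extend to the time
where the integrated amount reaches 99% of equilibrium (`saturation_time`).

**Units.** Concentrations are mass fractions throughout (1 wt% = 0.01);
times are seconds internally. `molecules_per_vesicle` converts mass fraction
to mass concentration with a sample density of 1.0 g/mL by default
(configurable; D₂O buffers are ≈ 1.1 g/mL).

**Numerics.** LSODA with an analytic Jacobian; the public `simulate()`
default is rtol 1e−9 / atol 1e−12 (the `k_a ≫ k_d` regimes are stiff), the
likelihood path uses rtol 1e−6 for speed. Mass conservation holds to
~1e−15 relative. Tiny integrator-tolerance negatives are clipped to zero.
`limiting_slopes` fits the first 15% and last 25% of points with finite
`ln(1 − f/f_max)` values; the normalization point `f = f_max` itself is
excluded. `translocation_time` brackets the first crossing of
`c_i/c_o = 1 − 1/e` and interpolates linearly; if the threshold is not
reached the last grid time is returned flagged as a censored lower bound.

## PFG-NMR observables

Echo attenuation uses the simplified `exp(−q²ΔD)` with `q = γδg` by default;
the Stejskal–Tanner form `exp(−q²(Δ − δ/3)D)` is available behind a flag
(with δ/Δ = 2 ms/100 ms the correction is sub-percent). Both Δ = 100 ms and
Δ = 20 ms appear in practice; Δ is a plain configuration value, defaulting
to 100 ms. Diffusion coefficients come from an error-weighted linear
regression of ln I on q²Δ; the regression is intended for the log-linear
window (attenuation to roughly e⁻¹·⁵) — deeper decays reintroduce a small
Jensen bias of the log transform, which the weighting suppresses only
partially. The kinetic measurement is modeled as the attenuation-weighted
two-species sum, normalized at the saturation time; with the free-polymer
signal fully suppressed it equals the integrated fraction of the trajectory.
The default suppression target of the gradient selector is 0.02.

## Bayesian inference

The likelihood is i.i.d. Gaussian per point on the normalized trace —
additive spectrometer noise with a per-trace scale, matching how scan
averaging is tuned in practice. The noise scale can be fixed from the data
file or sampled as a fourth parameter (log-uniform). Parameters are sampled
in log10 space (they span decades) under independent log-uniform priors,
default bounds k_a ∈ [1e−4, 1e2], k_d ∈ [1e−7, 1e−1], c_sat ∈ [1e−5, 1].
The sampler is the emcee affine-invariant ensemble; walkers start in a
1e−2-decade Gaussian ball around a coarse point estimate found by a seeded
scout search (192 prior draws) refined with shrinking pattern searches from
the best four scouts — the searches only locate the posterior basin, the
prior stays uninformative. Runs are bit-reproducible given a seed.
Convergence is reported as split-chain R̂ (values ≲ 1.05 indicate
convergence; the recovery studies accept ≲ 1.2 at their chain lengths).
Library defaults are 32 walkers × 5000 steps with 20% burn-in. The shipped
studies use 16 walkers throughout: 700 steps (burn-in 300) where only
posterior medians are consumed — medians are chain-converged there — and
1200 steps (burn-in 500) for interval-based checks, giving enough effective
samples (the integrated autocorrelation time is ~25-40 steps) for stable
2.5/97.5 percentile endpoints; shorter chains leave the interval tails
noticeably jittery and cost interval coverage.

**Identifiability.** The membrane step contributes an amplitude
`φ_mem·c_sat` against the inner-volume amplitude `φ_in·c_i(∞)` in the
normalized trace. With 1 wt% total polymer, scenarios with `c_sat` near
0.001 put that step at a few percent of full scale — at 2% noise the
adsorption rate (and partly `c_sat`) is then only weakly identified, and
posterior medians can sit far from the generating value even though the
credible intervals remain honest. This mirrors the experimental situation:
adsorption rates cannot be pinned down when the membrane concentration is
small compared to the noise of the early measurement window. Truncating a
trace before the membrane-saturation crossover removes essentially all
desorption information and inflates the `k_d` interval several-fold, which
is the package's operational test for this degradation.

Cross-sample pooling uses inverse-variance weighting; molecular-weight
extrapolation fits `ln(value)` linearly in MW (errors propagated by the
delta method) or falls back to the weighted mean for MW-independent
quantities. Predicted filling curves propagate parameter uncertainty by
Gaussian Monte-Carlo draws (default 200, seeded; non-physical draws are
skipped and counted) rather than linearization, because the map from rates
to filling curves is strongly nonlinear.

## Neutron reflectometry

Reflectivity of the supported-bilayer stack (semi-infinite Si; SiO₂; thin
water gap; inner headgroup; inner tail; outer tail; outer headgroup;
optional hydrated polymer brush; semi-infinite solvent) is computed by the
exact Parratt recursion. Each layer's SLD is the volume-fraction mixture of
base material, solvent, and polymer; only the solvent SLD changes between
H₂O and D₂O contrasts, so multi-contrast co-refinement shares all structural
parameters. Interfacial roughness enters as Névot–Croce factors; profile
rendering uses error-function interfaces. Micro-slicing the rendered
profile and running the slab engine on the slices reproduces the
Névot–Croce curve to 1e−3 relative within the factors' validity window
(qσ ≲ 0.7); outside it the two descriptions genuinely differ at the few-e−3
level, which is a property of the roughness approximation, not of the
implementation. Resolution smearing is Gaussian with constant Δq/q (FWHM),
default 10% when enabled, off in unit tests.

Composition extraction reports the polymer mass concentration of a layer
region as `100·Σ d φ_p ρ_p / Σ d (φ_p ρ_p + φ_lipid ρ_lipid)`,
thickness-weighted, with solvent excluded from the mass basis by default
(the solvent-inclusive variant is one flag away). Which layers form a
"region" (tail region, outer leaflet, brush) is a user selection. The
shipped materials table (Si, SiO₂, H₂O, D₂O, chain-deuterated POPC heads
and tails, PEG, PPG, hydrogenous alternating polymer) carries editable
literature-style SLDs and densities.

## Synthetic data

The generators produce exactly the statistical structure the analysis
assumes: kinetic traces are forward simulations mapped through the
two-species echo model with additive Gaussian noise of constant σ (default
0.02) on the normalized intensity, on log-spaced grids that resolve both
the adsorption and the equilibration regime; echo decays are
multi-exponential with additive noise; reflectivity curves carry relative
Gaussian noise with populated dR columns. Three presets mirror the
qualitative mechanism classes at the shared measurement conditions (44 nm
LUVs, 20 mg/mL lipid, 1 wt% polymer):

| preset | k_a (1/s) | k_d (1/s) | c_sat | mechanism sketch |
|---|---|---|---|---|
| homogeneous_aap | 0.05 | 5e−4 | 0.01 | whole-chain solubilization, partition ≈ 1 |
| amphiphilic_aap | 0.2 | 5e−5 | 0.06 | hydrophobic-unit anchoring, high capacity |
| triblock | 1.0 | 2e−5 | 0.10 | very fast adsorption, slowest desorption |

The preset rate values are illustrative of those regimes, not fitted
constants. Recovery studies draw 20 scenarios log-uniformly over
k_a ∈ [1e−2, 1], k_d ∈ [1e−5, 1e−3], c_sat ∈ [1e−3, 0.1] with
k_a/k_d ∈ [10, 1e4].

What the synthetic data do **not** emulate: vesicle polydispersity,
convection and relaxation (T₁/T₂) weighting of the NMR amplitudes,
temperature drifts of the membrane concentration, baseline/phasing
artifacts, and instrument backgrounds or footprint effects in reflectivity.
Passing tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to these real-data effects.

## Study sizes

The shipped studies use 20 recovery scenarios (one fit each) and 50 noise
repetitions for interval coverage in the test suite (40 in the acceptance
script); coverage is judged against the same ≥90% bound regardless of
repetition count. These sizes put the
whole acceptance computation at roughly a quarter hour on a single CPU
while keeping the Monte-Carlo error of the reported fractions at the
few-percent level. Frequentist coverage of the 95% credible intervals at a
fixed generating parameter is itself a boundary quantity here: repeated
calibration runs place the worst-parameter coverage at roughly 80-95%
depending on the noise-seed series (the deficit concentrates in the
saturation concentration, whose posterior is mildly overconfident under
the model's nonlinearity), so coverage outcomes several points either side
of 90% are within the method's own run-to-run variation.

## Known limitations

* The exact functional form of the rate equations (surface-area vs volume
  normalization of adsorption, symmetry of the desorption split) is a
  modeling choice; it reproduces the two-step phenomenology and passive
  equilibration with the fewest parameters and is isolated behind
  `rate_equations` so alternatives can be swapped in.
* Whether membrane concentration is a mass or volume fraction is a
  convention; the package treats mass fractions and ships density-based
  conversion in the composition utilities.
* Lipid flip-flop, pore formation, endocytosis, charged polymers, and
  temperature-dependent membrane solubility are out of scope; LCST values
  are carried as descriptors only.
* At strong membrane saturation the model's equilibration is
  λ-limited (see above): fixed-multiple-of-1/k_d horizons overestimate how
  equilibrated a trajectory is.
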