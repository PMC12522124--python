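# translokin

Analysis toolkit for **passive macromolecular translocation through
phospholipid membranes**, built around time-resolved pulsed-field-gradient
(PFG) NMR and specular neutron reflectometry (NR) of polymers interacting
with large unilamellar vesicles (LUVs) and supported lipid bilayers.

It is written for membrane biophysicists who measure how water-soluble
amphiphilic polymers — e.g. alternating amphiphilic polymers P(C_mEG_n)
built from hydrophobic diacid units (C_m) and oligo(ethylene glycol) units
(EG_n), or PEG–PPG–PEG triblocks — adsorb into, saturate, and cross lipid
bilayers.

## The model

Polymer exchanges between three compartments: outer solution (`c_o`),
membrane (`c_m`) and inner vesicle volume (`c_i`), all mass fractions.
Adsorption acts at both membrane faces at rate `k_a` and is throttled as the
membrane fills toward its saturation concentration `c_sat`; desorption
releases polymer at total rate `k_d`, split equally to the two faces:

    dc_m/dt = k_a (c_o + c_i)(1 − c_m/c_sat) − k_d c_m
    dc_i/dt = (φ_mem/φ_in)  [ (k_d/2) c_m − k_a c_i (1 − c_m/c_sat) ]
    dc_o/dt = (φ_mem/φ_out) [ (k_d/2) c_m − k_a c_o (1 − c_m/c_sat) ]

The volume fractions φ follow from the vesicle geometry (radius R, bilayer
thickness d, lipid loading). The model conserves φ-weighted mass exactly and
equilibrates at `c_i = c_o` (passive, non-directional transport); the
membrane/water partition coefficient is `c_pm/c_po` at equilibrium.

The measured observable is the normalized LUV-integrated NMR intensity
`I₀(t)/I₀(t_max)` recorded at a fixed gradient that suppresses the
fast-diffusing free polymer (echo attenuation `exp(−q²ΔD)`, `q = γδg`).
Its log-plot `ln(1 − f/f_max)` is two-step: the initial slope tracks `k_a`,
the terminal slope tracks `k_d`, and the crossover level tracks `c_sat`.
Rate parameters are inferred by affine-invariant ensemble MCMC (emcee) with
a wide log-uniform prior.

The NR side computes specular reflectivity of a supported-bilayer slab stack
(Si / SiO₂ / thin water / headgroups / tails / optional polymer brush /
solvent) by exact Parratt recursion with Névot–Croce roughness factors,
renders scattering-length-density profiles, co-refines multi-contrast
(H₂O/D₂O) data, and converts fitted volume fractions into polymer mass
concentrations of membrane regions.

## Worked example

```python
import numpy as np
import translokin as tk

# 44 nm LUVs, 4 nm bilayer, 20 mg/mL POPC, 1 wt% polymer
geometry = tk.derive_geometry(R=44.0, d=4.0, c_lipid=20.0)
scenario = tk.get_preset("homogeneous_aap")        # k_a=0.05/s, k_d=5e-4/s, c_sat=1 wt%

# synthetic measurement: 100 log-spaced points, 2% Gaussian noise
trace = tk.gen_kinetic_trace(scenario, n_points=100, sigma=0.02, seed=11)

# Bayesian fit (sklearn-style estimator)
fit = tk.KineticTraceFitter(geometry=geometry, c_total=0.01, sigma=0.02,
                            n_walkers=16, n_steps=700, burn_in=300,
                            random_state=5)
fit.fit(trace.times, trace.intensity)
for name in ("k_a", "k_d", "c_sat"):
    s = fit.summary_[name]
    print(f"{name}: median {s['median']:.3g}, 95% CI "
          f"[{s['ci95'][0]:.3g}, {s['ci95'][1]:.3g}]")

traj = tk.simulate(fit.params_, geometry, 0.01, np.logspace(-1, 6, 300))
t_star, censored = tk.translocation_time(traj)
print(f"partition c_pm/c_po = {tk.partition_coefficient(fit.params_, geometry, 0.01):.2f}")
print(f"effective translocation time = {t_star/60:.0f} min (censored={censored})")
```

which prints (seeds as above):

```
k_a: median 0.0464, 95% CI [0.0419, 0.0512]
k_d: median 0.000506, 95% CI [0.000465, 0.000544]
c_sat: median 0.0101, 95% CI [0.00965, 0.0105]
partition c_pm/c_po = 1.00
effective translocation time = 276 min (censored=False)
```

The medians recover the generating rates within a few percent; the
partition coefficient ~1 says this polymer is about equally soluble in the
membrane interior and in water, and the (1 − 1/e) filling time of the inner
vesicle volume is about five hours.

A command-line interface covers the same workflows
(`translokin simulate|fit|translocation-time|mw-extrapolate|nr-forward|nr-compose|gen`),
reading a single YAML configuration and writing delimited-text outputs plus
a provenance record; starter configurations live in `examples/`:

```bash
translokin simulate --config examples/kinetics_config.yaml --out-dir out/
translokin nr-compose --stack examples/bilayer_stack.yaml --region tail
```

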