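# Supported-bilayer slab stack for `nr-forward` / `nr-compose`.
# Synthetic demonstration values (illustrative, not fitted to a measurement):
# thicknesses/roughness in Angstrom, phi_* are volume fractions.
fronting: si
polymer: aap
backing_roughness: 3.0
layers:
  - {name: sio2,       thickness: 12.0, material: sio2,           roughness: 3.0}
  - {name: water_gap,  thickness:  4.0, material: d2o,            roughness: 3.0, phi_solvent: 1.0}
  - {name: inner_head, thickness:  8.0, material: popc_d82_heads, roughness: 3.0, phi_solvent: 0.30}
  - {name: inner_tail, thickness: 14.0, material: popc_d82_tails, roughness: 3.0, phi_polymer: 0.02}
  - {name: outer_tail, thickness: 14.0, material: popc_d82_tails, roughness: 3.0, phi_polymer: 0.10}
  - {name: outer_head, thickness:  8.0, material: popc_d82_heads, roughness: 3.0, phi_solvent: 0.35, phi_polymer: 0.03}
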