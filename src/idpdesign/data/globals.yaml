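# Global force-field constants for the coarse-grained IDP model.
# bond_k      harmonic bond force constant, kcal/(mol A^2)
# bond_b0     equilibrium bond length, A
# epsilon     Lennard-Jones well depth, kcal/mol
# dielectric  relative dielectric constant of the implicit solvent
# debye_kappa Debye screening length, A
bond_k: 10.0
bond_b0: 3.82
epsilon: 0.2
dielectric: 80.0
debye_kappa: 10.0
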