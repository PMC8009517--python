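# Six-site rigid acetonitrile parameter set — SYNTHETIC STAND-IN.
# Physically sensible (net-neutral charges giving a ~4.1 D axial dipole,
# AMBER-like LJ radii, standard gas-phase geometry), assembled for testing
# and examples; it is NOT a published, validated force field.
# atoms: [name, mass_amu, charge_e, sigma_angstrom, epsilon_kJ_per_mol]
fragments:
  acetonitrile:
    rigid: true
    atoms:
      - [C1, 12.011, -0.080, 3.40, 0.458]
      - [H1,  1.008,  0.060, 2.65, 0.0657]
      - [H2,  1.008,  0.060, 2.65, 0.0657]
      - [H3,  1.008,  0.060, 2.65, 0.0657]
      - [C2, 12.011,  0.460, 3.40, 0.400]
      - [N,  14.007, -0.560, 3.25, 0.711]
    coords:
      - [ 0.000000,  0.000000,  0.000000]
      - [ 1.021600,  0.000000, -0.371800]
      - [-0.510800,  0.884732, -0.371800]
      - [-0.510800, -0.884732, -0.371800]
      - [ 0.000000,  0.000000,  1.458000]
      - [ 0.000000,  0.000000,  2.615000]
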