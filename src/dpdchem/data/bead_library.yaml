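# Packaged DPD bead library for neutral surfactant simulation.
#
# Each bead is a coarse-grained molecular fragment carrying:
#   ssips       -- surface site interaction point polarities epsilon
#                  ((kJ/mol)^(1/2) scale; + donor-like, - acceptor-like),
#                  sorted by decreasing |epsilon| (canonical order)
#   volume      -- van der Waals volume of the fragment (A^3)
#   liquid_conc -- molar concentration of the pure reference bead liquid (M),
#                  computed from the 25 C density and molar mass of the named
#                  reference molecule (provenance kept alongside each value)
#   a_self      -- self repulsion a_ii (kBT, DPD reduced units)
#   R_self      -- self contact radius R_ii (r_c)
#
# Primes in bead names are written with the ASCII apostrophe (AC', OH', ...).
schema: 1
beads:
  - name: W
    volume: 42.0
    ssips: [-4.5, -4.5, 2.8, 2.8]
    a_self: 25.00
    R_self: 1.000
    liquid_conc: 27.673
    conc_provenance:
      reference: water (one bead = two water molecules)
      density_g_cm3: 0.99705
      molar_mass: 18.015
      fraction_of_molecule_conc: 0.5
  - name: ES
    volume: 68.8
    ssips: [-5.5, -5.5, -2.6, 0.4, 0.4, 0.4, 0.4, 0.2, 0.2]
    a_self: 22.00
    R_self: 1.141
    liquid_conc: 12.518
    conc_provenance:
      reference: methyl acetate
      density_g_cm3: 0.9273
      molar_mass: 74.079
      fraction_of_molecule_conc: 1.0
  - name: EO
    volume: 48.7
    ssips: [-5.3, -5.3, 0.4, 0.4, 0.4, 0.4]
    a_self: 22.50
    R_self: 1.116
    liquid_conc: 4.792
    conc_provenance:
      reference: 1,2-dimethoxyethane (half of the molecular concentration)
      density_g_cm3: 0.8637
      molar_mass: 90.122
      fraction_of_molecule_conc: 0.5
  - name: AC'
    volume: 31.9
    ssips: [-4.4, -4.4, -4.4, -4.4, 0.4]
    a_self: 22.50
    R_self: 0.952
    liquid_conc: 4.792
    conc_provenance:
      reference: 1,2-dimethoxyethane (half of the molecular concentration)
      density_g_cm3: 0.8637
      molar_mass: 90.122
      fraction_of_molecule_conc: 0.5
  - name: AM2
    volume: 73.2
    ssips: [-7.9, -7.9, 2.9, -0.9, -0.9, 0.4, 0.4, 0.4, 0.4]
    a_self: 22.00
    R_self: 1.172
    liquid_conc: 13.094
    conc_provenance:
      reference: N-methylacetamide
      density_g_cm3: 0.9571
      molar_mass: 73.095
      fraction_of_molecule_conc: 1.0
  - name: AM3'
    volume: 85.6
    ssips: [-7.9, -7.9, -0.9, -0.9, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4]
    a_self: 22.00
    R_self: 1.236
    liquid_conc: 10.757
    conc_provenance:
      reference: N,N-dimethylacetamide
      density_g_cm3: 0.9372
      molar_mass: 87.122
      fraction_of_molecule_conc: 1.0
  - name: AM3
    volume: 92.1
    ssips: [-7.9, -7.9, -0.9, -0.9, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4]
    a_self: 22.00
    R_self: 1.266
    liquid_conc: 10.757
    conc_provenance:
      reference: N,N-dimethylacetamide
      density_g_cm3: 0.9372
      molar_mass: 87.122
      fraction_of_molecule_conc: 1.0
  - name: T1
    volume: 25.9
    ssips: [0.4, 0.4, 0.4, -0.3]
    a_self: 24.00
    R_self: 0.955
    liquid_conc: 0.765
    conc_provenance:
      reference: n-octane (one eighth of the molecular concentration)
      density_g_cm3: 0.6986
      molar_mass: 114.231
      fraction_of_molecule_conc: 0.125
  - name: T2
    volume: 45.2
    ssips: [0.4, 0.4, 0.4, 0.4, 0.4, -0.3, -0.3]
    a_self: 24.00
    R_self: 1.098
    liquid_conc: 1.529
    conc_provenance:
      reference: n-octane (one quarter of the molecular concentration)
      density_g_cm3: 0.6986
      molar_mass: 114.231
      fraction_of_molecule_conc: 0.25
  - name: C2
    volume: 38.9
    ssips: [0.4, 0.4, 0.4, 0.4, -0.3, -0.3]
    a_self: 22.00
    R_self: 1.074
    liquid_conc: 1.529
    conc_provenance:
      reference: n-octane (one quarter of the molecular concentration)
      density_g_cm3: 0.6986
      molar_mass: 114.231
      fraction_of_molecule_conc: 0.25
  - name: C2'
    volume: 32.2
    ssips: [0.4, 0.4, 0.4, -0.3, -0.3]
    a_self: 22.00
    R_self: 0.995
    liquid_conc: 1.529
    conc_provenance:
      reference: n-octane (one quarter of the molecular concentration)
      density_g_cm3: 0.6986
      molar_mass: 114.231
      fraction_of_molecule_conc: 0.25
  - name: OH1
    volume: 34.7
    ssips: [-5.3, -5.3, 2.7, 0.4, 0.4, -0.3]
    a_self: 14.00
    R_self: 0.980
    liquid_conc: 24.549
    conc_provenance:
      reference: methanol
      density_g_cm3: 0.7866
      molar_mass: 32.042
      fraction_of_molecule_conc: 1.0
  - name: OH'
    volume: 28.1
    ssips: [-5.3, -5.3, 2.7, 0.4, -0.3]
    a_self: 14.00
    R_self: 0.949
    liquid_conc: 24.549
    conc_provenance:
      reference: methanol
      density_g_cm3: 0.7866
      molar_mass: 32.042
      fraction_of_molecule_conc: 1.0
  - name: OH2
    volume: 43.8
    ssips: [-5.3, -5.3, 2.7, 0.4, 0.4, 0.4, -0.3]
    a_self: 18.00
    R_self: 1.012
    liquid_conc: 17.042
    conc_provenance:
      reference: ethanol
      density_g_cm3: 0.78509
      molar_mass: 46.069
      fraction_of_molecule_conc: 1.0
molecules: []
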