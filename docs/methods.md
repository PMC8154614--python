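# Methods

`dpdchem` turns a coarse-grained chemical description of neutral
surfactants into a complete dissipative-particle-dynamics (DPD) parameter
set, simulates aqueous self-assembly, and measures micellization
observables.  This note records the model, the numerical choices, and the
limits of what the shipped tests demonstrate.

## Bead model and units

A bead is a molecular fragment (one to six heavy atoms) with

- a multiset of surface site interaction points (SSIPs), each a scalar
  polarity ε on the (kJ/mol)^(1/2) scale — positive values are
  hydrogen-bond-donor-like surface patches, negative values acceptor-like;
- a van der Waals volume v (Å³);
- the molar concentration of a pure liquid of that fragment, approximated
  by a closely related reference molecule (methanol for the hydroxyl
  beads, N,N-dimethylacetamide for the tertiary amides, fractions of
  n-octane and dimethoxyethane for the alkyl and ether beads, and so on;
  the data file stores the 25 °C density and molar mass behind each
  value);
- a self-repulsion a_ii (k_BT) and self contact radius R_ii (r_c), shipped
  as data for the 14 stock beads.

Reduced units: length r_c (= 5.64 Å; one water bead is two waters, bead
density ρr_c³ = 3), energy k_BT = 1, mass 1.  `UnitMap` converts box
volumes and counts to mM and weight percent.

## Liquid speciation and transfer free energies

A liquid is a well-mixed bath of SSIPs.  Two sites x, y pair 1:1 with

    K(x, y) = exp(−(ε_x ε_y + E_vdW) / RT),   E_vdW = −5.6 kJ/mol,

so complementary (opposite-sign) pairs bind tightly while every contact
gains the constant van der Waals term.  Solving the coupled mass
balances x_f = 1/(1 + Σ_y K_xy y_f c_y) gives the free fraction of every
species (damped fixed-point iteration, relaxation 0.5, tolerance 1e-12,
with a Newton fallback; the map is a contraction for physical K but can
oscillate at high occupancy).  The solvation free energy of site x in
liquid i is

    ΔG_x(i) = RT ln x_f − RT ln x_f^(K=1)(θ),

where the second, confinement term is the free fraction the same bath
would have if every K were 1 at the same fractional occupancy
θ = Σc/300 M (closed-form quadratic).  A liquid with no preferential
interactions therefore solvates at exactly zero cost.  Bead transfer
free energies sum per-SSIP solvation differences, with the solute at
infinite dilution against the solvent's solved free-site concentrations.
ΔG_ii = 0 holds identically.

The exact algebraic forms above are the package's reconstruction,
validated against the published pairwise parameter tables: they
reproduce the sign structure and ordering of the water row (correlation
0.97 across the 13 pairs, including the amide ordering
Δa_AM3′–W < Δa_AM3–W < Δa_AM2–W < 0) but not the printed magnitudes,
which depend on reference-liquid conventions that are not recoverable.
Both readings of the water-bead SSIP concentration are implemented
(`SSIMPLEConfig.water_ssip_convention`); the default, one bead = two
waters at 27.7 M, agrees better with the published water row.  The
default parameter source for the stock beads is therefore the published
tables (`mode="table"`); the computed pipeline is for new beads and for
validation.

## From free energies to DPD parameters

- Mismatch:  Δa_ij = [(v_r/v_i) ΔG_ij + (v_r/v_j) ΔG_ji] / (2 c_P RT),
  with v_r the water-bead volume and c_P = 0.291 the matching constant
  appropriate for bead density 3.  Symmetric, zero on the diagonal.
- Combination rule:  a_ij = (a_ii + a_jj)/2 + Δa_ij.
- Contact radii:  R_ij = (R_ii + R_jj)/2; the pair interaction vanishes
  beyond R_ij.
- Bond calibration:  inside a bond the pair still feels the soft
  repulsion, so the harmonic rest length must undershoot the desired
  bond length.  Setting the total force to zero at r_target gives

      r_0 = r_target − (a_ij/k_b)(1 − r_target/R_ij)   for r_target < R_ij,

  and r_0 = r_target beyond the interaction range (the repulsion's
  derivative is zero there).  k_b = 150 k_BT and k_a = 5 k_BT throughout.
  Four published rows round-trip exactly through this formula with the
  tabulated inputs; the others deviate by up to ~0.02 r_c, consistent
  with unrounded upstream inputs, and the tests pin both facts.

Two internal inconsistencies of the published tables are documented in
`src/dpdchem/data/README.md` (an evident Δa sign slip for AM3–T1, which
the packaged data corrects, and two entries 0.02–0.003 off their own
mixing rules, which are shipped as printed and excepted in the tests).

## Topology builder

Fig-style coarse-grainings are encoded per family (ester: GLY, XYL;
amide: MEA, DEA, TEDA, MEGA, HEGA; sugar: GLUCO, MALTO, CYGLU, CYMAL).
Even-carbon tails become C2 beads with a terminal T2; ester/amide heads
absorb the carbonyl and alpha carbons; the cyclohexyl terminus of the
CY families is three C2′ beads.  Bond targets come from the packaged
published table where available, otherwise 0.445 r_c for alkyl–alkyl
bonds (the ethylene–ethylene equilibrium distance), 0.45 r_c for polyol
OH′–OH′ bonds, and documented defaults for the rest.  Chain angles along
the tail and through the head junction use θ_0 = 180° (trans-amide
representation); polyol head chains are left torsionally free.  The "OH"
bead of the MEA/DEA/HEGA rows is taken as OH1 (methanol-like); molar
masses are computed from the parent-compound condensation and match the
catalogue masses of the real surfactants.

## DPD engine

Groot–Warren conservative force a_ij(1 − r/R_ij) with per-pair ranges,
harmonic bonds, 1–3 harmonic angles (radian measure), and the pairwise
thermostat F_D = −γ w² (v·ê) ê, F_R = σ w ζ ê /√dt with w = 1 − r/R_ij,
γ = 4.5, σ = 3 (σ² = 2γk_BT at k_BT = 1; the production code these
parameters mirror does not publish them, and the observables, not the
thermostat internals, are the comparison surface).  Velocity-Verlet with
λ = ½.  Pair noise ζ is a unit-variance uniform deviate from a
counter-based hash of (seed, step, pair): trajectories are bitwise
reproducible, noise is symmetric in the pair, and only the second moment
of ζ matters for the thermostat.  Neighbour search uses linked cells
(≥3 cells per side, exact same pair set as the all-pairs path, which the
tests assert); nonbonded interactions between bonded beads stay active —
the bond calibration assumes exactly that.  Bead displacements larger
than L/2 in one step raise an instability error before positions wrap.

Initial conditions: chains placed as bond-length random walks, solvent
uniform, Maxwell velocities with the drift removed.  `start="clustered"`
seeds all surfactant chains in one compact ball so that monomer–micelle
coexistence is approached from the micellar side; in small boxes this
avoids the slow nucleation stage and is the default protocol for the
scaled-down self-assembly checks.

## Aggregate analysis

Two surfactants share an aggregate when any pair of their hydrophobic
tail beads (C2, C2′, T1, T2) lies within 1.0 r_c — the interaction range;
the cutoff is a flag, and the partition is by periodic-minimum-image
connected components.  P(N) pools post-equilibration frames; N_cut is
the midpoint of the first empty gap, or else the deepest interior local
minimum, between the two populations (unimodal distributions return a
no-micelle sentinel).  CMC is the time average of the concentration of
molecules in aggregates below N_cut (monomers included), in mM; N_agg is
the per-frame weight average ΣN²/ΣN over aggregates above N_cut with its
observed range.  Shapes use the mass-weighted gyration tensor of each
micelle's member beads, unwrapped about one member; semi-axes
(A, B, C) = √(5λ) under the uniform-ellipsoid convention (the ratios A/B
and B/C used for classification are convention-independent).  Classes:
sphere (both ratios < 1.5), prolate (A/B ≥ 1.5 only), oblate (B/C ≥ 1.5
only), irregular (both); the 1.5 boundary is configurable.  Unwrapping
about a single reference limits shape analysis to aggregates smaller
than half the box edge — adequate at the scales simulated here.

## Synthetic data and what the tests show

Planted trajectories place lattice-filled ellipsoids (spacing 0.55 r_c,
well under the clustering cutoff, so connectivity is guaranteed) plus
isolated monomers with ≥2 r_c clearance; their CMC, N_agg and shape
classes are known exactly and the pipeline must recover them exactly.
They emulate the geometry of micellar configurations, not their
dynamics: passing says the measurement chain is correct, not that the
engine produces realistic micelles.  That is probed separately at
reduced scale: AM3–OH′ dimers in solvent (the published glucamide head
bond) must average their bond length to r_target = 0.68 within 2% (the
central claim of the bond calibration, tested end-to-end through the
engine; measured +0.1%), a pure-water box must hold kinetic
temperature 1.00 ± 0.02 k_BT, and MEA8 versus MEA10 at 5 wt% in an
8.5 r_c box (30 000 steps, clustered start, second half analysed) must
show the free-surfactant concentration dropping at least five-fold with
the two extra tail carbons — the qualitative chain-length rule, at a
scale where one box holds only ~15–20 surfactants.  Full-scale CMC and
N_agg values come from 192 000-bead, 4×10⁶-step runs and are outside
desk scale by design; the configuration machinery supports those sizes
unchanged.  Problem sizes in the test suite were chosen as the smallest
that still demonstrate each effect.

## Known limitations

- The computed (SSIP-pipeline) Δa values match the published sign
  structure and ordering but not the printed magnitudes; table mode is
  the default for the stock beads.
- Charged head groups, electrostatics, pressure coupling and many-body
  DPD are out of scope; boxes are cubic and periodic only.
- Angle parameters beyond the trans-chain 180° default (e.g. measured
  θ_0 per family) are accepted as input but not packaged.
- Shape analysis assumes aggregates fit within half the box; percolating
  bilayers/worms at large scales would need a different unwrapping.
- The bond calibration balances only the forces *inside* the bonded
  pair.  The surrounding fluid adds a solvation contribution to the bond
  potential of mean force: solvent-matched or hydrophilic pairs sit on
  target (W–W within 4%, AM3–OH′ within 0.2%, OH′–OH′ within 1.7%), but
  a strongly hydrophobic pair in water (C2–C2, a_W,C2 ≈ 45) is squeezed
  up to ~10% below r_target at short targets.  Within a micelle core the
  environment is alkane-like, not water-like, so the calibration is used
  as published for all bonds.
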