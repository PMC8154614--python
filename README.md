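# dpdchem

Dissipative particle dynamics (DPD) parameters for neutral surfactants,
computed from chemical structure — plus a compact DPD simulator and a
micelle-analysis toolchain to turn those parameters into self-assembly
observables.

DPD coarse-grains molecules into soft beads: the conservative force
between beads i and j is a_ij(1 − r/R_ij) up to the contact radius R_ij,
bonded beads add a harmonic spring (k_b = 150 k_BT) and 1–3 angle
(k_a = 5 k_BT), and a pairwise drag/random thermostat holds k_BT = 1.
Simulating a *new* compound needs a full matrix of repulsion parameters
a_ij and calibrated bond lengths, which is where this package starts:

- **Nonbonded parameters from SSIPs.**  Each bead carries surface site
  interaction points (SSIPs) with polarities ε.  Liquids are speciated by
  solving the 1:1 pairing equilibria K = exp(−(ε_xε_y + E_vdW)/RT), giving
  solvation free energies ΔG_x = RT ln x_f − RT ln x_f^(K=1)(θ) and bead
  transfer free energies ΔG_ij.  These map onto the repulsion mismatch
  Δa_ij = [(v_r/v_i)ΔG_ij + (v_r/v_j)ΔG_ji]/(2 c_P RT), and
  a_ij = (a_ii + a_jj)/2 + Δa_ij.
- **Bonded parameters in closed form.**  Because bonded beads still repel
  each other, the spring rest length must undershoot the target bond
  length:  r_0 = r_target − (a_ij/k_b)(1 − r_target/R_ij).
- **Observables.**  Aggregates are detected by tail-bead clustering; the
  size distribution P(N) yields the premicelle threshold N_cut, the CMC
  (time-averaged free + submicellar concentration), the weight-average
  aggregation number N_agg = ΣN²/ΣN, and gyration-tensor shape classes
  (sphere / prolate / oblate / irregular from the A/B and B/C semi-axis
  ratios).

The package ships the 14-bead library (water, esters, ethers, amides,
hydroxyls, alkyls) with its published pairwise tables, topology builders
for eleven surfactant families (GLY, XYL, MEA, DEA, TEDA, MEGA, HEGA,
GLUCO, MALTO, CYGLU, CYMAL; C8–C12 tails), and deterministic synthetic
fixtures.  See `docs/methods.md` for the model details and limitations.

## Worked example

Transfer free energies and mismatch repulsions against water
(`python examples/transfer_free_energies.py`):

```
bead     dG(bead->W)  dG(W->bead)   Δa_bead,W   (kJ/mol, kJ/mol, kBT)
AM2         10.23       -9.35       -2.41
AM3'         8.12      -12.00       -5.56
AM3         12.71      -11.51       -3.96
ES          12.41       -1.06        4.52
C2          25.54       20.81       33.56
```

Both tertiary amides (AM3′, AM3) show a more negative water mismatch than
the secondary amide (AM2) — moving AM2 out of its own liquid costs
amide–amide hydrogen bonds — and the alkyl bead C2 is strongly
hydrophobic.  Analysis of a synthetic trajectory with known ground truth
(`python examples/planted_micelle_analysis.py`):

```
P(N): {1: 60, 30: 15, 40: 5}
N_cut = 15
CMC = 3.390 mM  (planted: 3.390 mM from 12 monomers)
N_agg = 33.08  (planted weight average: 33.08)
shape classes: {'sphere': 0.75, 'prolate': 0.25, 'oblate': 0.0, 'irregular': 0.0}
```

The pipeline recovers the planted monomer concentration, weight-average
aggregation number and shape classes exactly.  The other examples build a
full parameter set for MEGA-8 and run a scaled-down self-assembly
simulation (`examples/simulate_self_assembly.py`, a couple of minutes).

A thin CLI mirrors the library: `dpdchem params --family MEGA --tail 8`,
`dpdchem run --family XYL --tail 8 --box 8 -o traj.h5`,
`dpdchem analyze traj.h5`, `dpdchem transfer --bead-i ES --bead-j W`.

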