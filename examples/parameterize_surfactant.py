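"""Full parameter set for one surfactant: MEGA-8 (N-methylglucamide, C8 tail).

Assembles the coarse-grained topology, looks up the pairwise repulsions
and contact radii for the beads involved, and calibrates every bond's
spring rest length r0 so the simulated mean bond length lands on the
chemically derived target r_target despite the soft nonbonded repulsion
acting inside the bond.
"""

from dpdchem import build_paramset, build_surfactant, default_library

library = default_library()
mol = build_surfactant("MEGA", 8, library)
params = build_paramset(library, [mol])

print(f"{mol.name}: {mol.n_beads} beads, M = {mol.molar_mass} g/mol")
print("sequence:", " - ".join(mol.beads))
print("\npairwise repulsions a_ij (kBT):")
print(params.summary().round(2).to_string())
print("\nbond calibration (r0 < r_target compensates the repulsion):")
for bond, (rt, r0) in zip(mol.bonds, params.bond_params[0]):
    pair = f"{mol.beads[bond.i]}-{mol.beads[bond.j]}"
    print(f"  {pair:10s} r_target = {rt:.3f} r_c   r0 = {r0:.3f} r_c")
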