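"""Transfer free energies and mismatch repulsions from the SSIP model.

Builds the packaged bead library, computes the directed transfer free
energies of the three amide beads into water, and converts them into the
mismatch repulsion Δa.  More negative Δa means a stronger preference for
mixing with water; the tertiary amides (AM3', AM3) come out more
water-loving than the secondary amide (AM2) because transferring AM2 out
of its own liquid breaks amide-amide hydrogen bonds.
"""

from dpdchem import ParamConfig, default_library, delta_a, transfer_free_energy

library = default_library()
cfg = ParamConfig()
water = library.bead("W")

print("bead     dG(bead->W)  dG(W->bead)   Δa_bead,W   (kJ/mol, kJ/mol, kBT)")
for name in ("AM2", "AM3'", "AM3", "ES", "C2"):
    bead = library.bead(name)
    dg_ij = transfer_free_energy(bead, water, library, cfg.ssimple).dG
    dg_ji = transfer_free_energy(water, bead, library, cfg.ssimple).dG
    da = delta_a(bead, water, dg_ij, dg_ji, cfg)
    print(f"{name:5s}  {dg_ij:10.2f}  {dg_ji:10.2f}  {da:10.2f}")

print("\nNegative Δa: the bead prefers water contacts over the average of the")
print("two pure liquids; positive Δa (the alkyl bead C2) is hydrophobic.")
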