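# Packaged data

- `bead_library.yaml` — the 14 coarse-grained bead types (SSIP polarities,
  van der Waals volumes, reference-liquid concentrations with provenance,
  self-repulsions `a_ii`, self contact radii `R_ii`).
- `contact_radius_Rij.csv` — pairwise contact radii `R_ij` (r_c) for all
  bead combinations.
- `repulsion_aij.csv` — pairwise repulsion parameters `a_ij` (kBT).
- `repulsion_delta_aij.csv` — pairwise mismatch terms `Δa_ij` (kBT).
- `bond_parameters.csv` — per-family bond targets `r_target` and calibrated
  spring rest lengths `r0` (r_c). "OH" rows are assigned to OH1 (the
  methanol-like hydroxyl bead); see the topology builder for alternatives.

Known quirks of the published parameter set, kept as-is unless noted:

1. The Δa entry for AM3–T1 is stored as −0.68 (not +0.68): the repulsion
   table gives a_AM3,T1 = 22.32 = (22.00 + 24.00)/2 − 0.68, so the positive
   sign fails the combination rule by 1.36 kBT and is an evident sign slip.
2. The contact-radius entry W–OH2 (1.003) deviates from the diagonal mixing
   rule (1.006) by 0.003 r_c; every other OH2 pair is consistent with
   R_OH2 = 1.012. Stored as published.
3. a_AM3′,C2 (21.63) differs from the combination-rule value (21.61) by
   0.02 kBT, consistent with rounding of unrounded upstream inputs.
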