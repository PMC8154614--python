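"""Conversions between reduced DPD units and laboratory units.

The length scale follows from the water-bead volume at bead density 3:
one W bead stands for two water molecules and r_c = 5.64 A.
"""

from __future__ import annotations

from dataclasses import dataclass

AVOGADRO = 6.02214076e23
WATER_MOLAR_MASS = 18.015  # g/mol


@dataclass(frozen=True)
class UnitMap:
    r_c_angstrom: float = 5.64
    waters_per_bead: int = 2

    def __post_init__(self) -> None:
        if self.r_c_angstrom <= 0 or self.waters_per_bead <= 0:
            raise ValueError("unit scales must be positive")

    def box_volume_litres(self, L: float) -> float:
        """Volume of a cubic box of edge ``L`` (r_c) in litres."""
        edge_cm = L * self.r_c_angstrom * 1e-8
        return edge_cm ** 3 * 1e-3

    def counts_to_mM(self, n: float, L: float) -> float:
        """Molar concentration (mM) of ``n`` molecules in an ``L``-edge box."""
        return n / AVOGADRO / self.box_volume_litres(L) * 1e3

    def water_bead_mass(self) -> float:
        return self.waters_per_bead * WATER_MOLAR_MASS

    def wt_percent_to_count(self, wt_percent: float, molar_mass: float,
                            beads_per_molecule: int, L: float,
                            rho: float = 3.0) -> int:
        """Number of solute molecules giving the requested weight percent.

        The box holds ``rho * L^3`` beads in total; every bead not used by
        the solute is a W bead of mass two waters.  Solves the mass-balance
        exactly and rounds to the nearest whole molecule.
        """
        if not 0 <= wt_percent < 100:
            raise ValueError("wt_percent must be in [0, 100)")
        w = wt_percent / 100.0
        n_beads = rho * L ** 3
        m_w = self.water_bead_mass()
        n = w * n_beads * m_w / (molar_mass * (1 - w) + w * beads_per_molecule * m_w)
        return int(round(n))

    def count_to_wt_percent(self, n: int, molar_mass: float,
                            beads_per_molecule: int, L: float,
                            rho: float = 3.0) -> float:
        n_beads = rho * L ** 3
        n_w = n_beads - n * beads_per_molecule
        m = n * molar_mass
        return 100.0 * m / (m + n_w * self.water_bead_mass())
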