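"""Assembly of the complete DPD parameter set.

Converts per-pair transfer free energies and bead geometry into the
matrices a DPD engine consumes: mismatch terms ``Δa_ij``, repulsions
``a_ij`` (combination rule over the self terms), contact radii ``R_ij``
(arithmetic mixing of the self radii), and — for every bond — the spring
rest length ``r0`` calibrated so that the *simulated* mean bond length
lands on the chemically derived target ``r_target`` despite the soft
nonbonded repulsion the bonded pair still feels.

Two parameter sources are supported: ``"table"`` uses the packaged
published matrices for the 14 stock beads; ``"computed"`` runs the
SSIP-based pipeline of :mod:`dpdchem.ssimple`, which is how new beads
are parameterized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beads import (BeadLibraryFile, BeadType, MoleculeTopology, load_table)
from .ssimple import SSIMPLEConfig, transfer_free_energy

__all__ = [
    "ParamConfig",
    "ParamSet",
    "delta_a",
    "repulsion",
    "contact_radius",
    "bond_r0",
    "build_paramset",
]


@dataclass(frozen=True)
class ParamConfig:
    """Constants of the parameter pipeline.

    ``c_P`` matches free energies (in RT) to DPD repulsion units and is
    tied to the working bead density of 3; ``v_ref`` is the water-bead
    volume every transfer free energy is referenced to; ``k_bond`` and
    ``k_angle`` are the universal spring constants (kBT).
    """

    c_P: float = 0.291
    v_ref: float = 42.0     # A^3, W bead volume
    k_bond: float = 150.0   # kBT
    k_angle: float = 5.0    # kBT
    rho: float = 3.0        # beads per r_c^3
    ssimple: SSIMPLEConfig = field(default_factory=SSIMPLEConfig)

    def __post_init__(self) -> None:
        for label in ("c_P", "v_ref", "k_bond", "k_angle", "rho"):
            if not getattr(self, label) > 0:
                raise ValueError(f"{label} must be positive")


def _eq5_delta_a(dG_ij: float, dG_ji: float, v_i: float, v_j: float,
                 cfg: ParamConfig) -> float:
    """Mismatch repulsion from a pair of transfer free energies.

    This function is the single place where the free-energy-to-DPD map is
    defined.  Each direction of transfer is volume-referenced to the water
    bead and the symmetrized average is converted into repulsion units by
    the matching constant::

        Δa_ij = [ (v_r/v_i) ΔG_ij + (v_r/v_j) ΔG_ji ] / (2 c_P RT)

    with ΔG in kJ/mol and RT = 2.479 kJ/mol at 298 K, giving Δa in kBT.
    Symmetric under exchange of i and j, and zero when both transfers are
    free.
    """
    RT = cfg.ssimple.RT
    return (cfg.v_ref / v_i * dG_ij + cfg.v_ref / v_j * dG_ji) / (2.0 * cfg.c_P * RT)


def delta_a(bead_i: BeadType, bead_j: BeadType, dG_ij: float, dG_ji: float,
            cfg: ParamConfig | None = None) -> float:
    """Δa_ij (kBT) from the two directed transfer free energies (kJ/mol)."""
    cfg = cfg or ParamConfig()
    return _eq5_delta_a(dG_ij, dG_ji, bead_i.volume, bead_j.volume, cfg)


def repulsion(a_ii: float, a_jj: float, delta: float) -> float:
    """Combination rule: ``a_ij = (a_ii + a_jj)/2 + Δa_ij``.

    Emits a warning (but still returns) if the result is nonpositive,
    i.e. the soft potential has lost its repulsive core.
    """
    if a_ii <= 0 or a_jj <= 0:
        raise ValueError("self repulsions must be positive")
    a_ij = 0.5 * (a_ii + a_jj) + delta
    if a_ij <= 0:
        warnings.warn(f"combination rule gives nonpositive repulsion {a_ij:.3f}",
                      stacklevel=2)
    return a_ij


def contact_radius(R_ii: float, R_jj: float) -> float:
    """Arithmetic mixing of self contact radii: ``R_ij = (R_ii + R_jj)/2``."""
    if R_ii <= 0 or R_jj <= 0:
        raise ValueError("contact radii must be positive")
    return 0.5 * (R_ii + R_jj)


def bond_r0(r_target: float, a_ij: float, R_ij: float, k_b: float) -> float:
    """Spring rest length giving a mean simulated bond length of ``r_target``.

    The bonded pair sits at the minimum of spring plus soft repulsion, so
    setting the total force to zero at ``r_target`` gives::

        r0 = r_target - (a_ij / k_b) (1 - r_target / R_ij)    (r_target < R_ij)

    Beyond the repulsion range (``r_target >= R_ij``) the nonbonded force
    vanishes and ``r0 = r_target``.  Raises if the calibration would be
    unphysical (``r0 <= 0``).
    """
    if not (r_target > 0 and k_b > 0):
        raise ValueError("r_target and k_b must be positive")
    if a_ij < 0 or R_ij <= 0:
        raise ValueError("a_ij must be >= 0 and R_ij > 0")
    if r_target >= R_ij:
        return r_target
    r0 = r_target - (a_ij / k_b) * (1.0 - r_target / R_ij)
    if r0 <= 0:
        raise ValueError(
            f"bond calibration unphysical: r0 = {r0:.4f} for r_target {r_target}")
    return r0


@dataclass
class ParamSet:
    """All pairwise and bonded parameters for a set of molecules.

    ``names`` fixes the bead index order of the symmetric matrices ``a``
    (kBT), ``da`` (kBT) and ``R`` (r_c).  ``bond_params[m]`` holds, for
    molecule ``m`` of ``molecules``, one ``(r_target, r0)`` pair per bond;
    ``angle_params[m]`` one ``theta0`` (degrees) per angle.
    """

    names: tuple[str, ...]
    a: np.ndarray
    da: np.ndarray
    R: np.ndarray
    molecules: tuple[MoleculeTopology, ...] = ()
    bond_params: tuple[tuple[tuple[float, float], ...], ...] = ()
    angle_params: tuple[tuple[float, ...], ...] = ()
    k_bond: float = 150.0
    k_angle: float = 5.0

    def __post_init__(self) -> None:
        n = len(self.names)
        for label in ("a", "da", "R"):
            M = np.asarray(getattr(self, label), dtype=float)
            if M.shape != (n, n):
                raise ValueError(f"{label} must be {n}x{n}")
            if not np.allclose(M, M.T, atol=1e-12):
                raise ValueError(f"{label} must be symmetric")
            setattr(self, label, M)
        if not np.allclose(np.diag(self.da), 0.0, atol=1e-9):
            raise ValueError("Δa diagonal must be zero")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def pair(self, name_i: str, name_j: str) -> tuple[float, float]:
        """(a_ij, R_ij) for a bead-name pair."""
        i, j = self.index(name_i), self.index(name_j)
        return float(self.a[i, j]), float(self.R[i, j])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.names, columns=self.names)


def _table_matrices(names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a_tab, da_tab, R_tab = load_table("a"), load_table("delta_a"), load_table("R")
    missing = [n for n in names if n not in a_tab.index]
    if missing:
        raise KeyError(f"beads {missing} not present in the packaged tables")
    a = a_tab.loc[list(names), list(names)].to_numpy()
    da = da_tab.loc[list(names), list(names)].to_numpy()
    R = R_tab.loc[list(names), list(names)].to_numpy()
    return a, da, R


def _computed_matrices(names: tuple[str, ...], library: BeadLibraryFile,
                       cfg: ParamConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(names)
    beads = [library.bead(name) for name in names]
    da = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dG_ij = transfer_free_energy(beads[i], beads[j], library, cfg.ssimple).dG
            dG_ji = transfer_free_energy(beads[j], beads[i], library, cfg.ssimple).dG
            da[i, j] = da[j, i] = _eq5_delta_a(dG_ij, dG_ji, beads[i].volume,
                                               beads[j].volume, cfg)
    a_self = np.array([b.a_self for b in beads])
    R_self = np.array([b.R_self for b in beads])
    a = 0.5 * (a_self[:, None] + a_self[None, :]) + da
    R = 0.5 * (R_self[:, None] + R_self[None, :])
    return a, da, R


def build_paramset(library: BeadLibraryFile,
                   molecules: list[MoleculeTopology] | None = None,
                   cfg: ParamConfig | None = None,
                   mode: str = "table") -> ParamSet:
    """Build the full parameter set for a molecule collection.

    ``mode="table"`` (default for the stock beads) takes the pairwise
    matrices verbatim from the packaged published tables; ``"computed"``
    derives Δa from the SSIP pipeline and applies the combination and
    mixing rules to the library's self terms.  Bond rest lengths are
    always recomputed from each bond's ``r_target`` via :func:`bond_r0`.
    """
    cfg = cfg or ParamConfig()
    molecules = list(molecules or [])
    if mode not in ("table", "computed"):
        raise ValueError("mode must be 'table' or 'computed'")

    used = {"W"}
    for mol in molecules:
        used.update(mol.beads)
    names = tuple(n for n in library.beads if n in used) if mode == "computed" \
        else tuple(n for n in load_table("a").index if n in used)
    if set(names) != used:
        raise KeyError(f"beads {sorted(used - set(names))} unavailable in {mode} mode")

    if mode == "table":
        a, da, R = _table_matrices(names)
    else:
        a, da, R = _computed_matrices(names, library, cfg)

    bond_params = []
    angle_params = []
    for mol in molecules:
        per_bond = []
        for b in mol.bonds:
            i, j = names.index(mol.beads[b.i]), names.index(mol.beads[b.j])
            per_bond.append((b.r_target,
                             bond_r0(b.r_target, a[i, j], R[i, j], cfg.k_bond)))
        bond_params.append(tuple(per_bond))
        angle_params.append(tuple(a_.theta0 for a_ in mol.angles))

    return ParamSet(names=names, a=a, da=da, R=R,
                    molecules=tuple(molecules),
                    bond_params=tuple(bond_params),
                    angle_params=tuple(angle_params),
                    k_bond=cfg.k_bond, k_angle=cfg.k_angle)
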