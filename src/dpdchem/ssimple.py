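"""SSIP-level liquid speciation and solvation free energies.

A liquid phase is modelled as a well-mixed collection of surface site
interaction points (SSIPs).  Every pair of SSIP species associates 1:1
with an equilibrium constant set by the product of their polarities plus
a constant van der Waals term.  Solving the coupled pairing equilibria
yields, for each species, the fraction ``x_f`` of sites left unbound,
from which solvation free energies follow: the interaction term is
``RT ln x_f`` and a confinement reference — the free fraction the same
site would have in a phase of identical total SSIP occupancy but with
all association constants set to one — is subtracted so that a liquid
with no net preferential interactions solvates at zero cost.

Transfer free energies between bead liquids are sums of per-SSIP
solvation differences and feed the repulsion-parameter pipeline in
:mod:`dpdchem.params`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .beads import BeadLibraryFile, BeadType

__all__ = [
    "GAS_CONSTANT_KJ",
    "SSIMPLEConfig",
    "SSIPPhase",
    "TransferResult",
    "SpeciationError",
    "association_constant",
    "phase_for_bead",
    "solve_speciation",
    "confinement_free_fraction",
    "solvation_free_energy",
    "transfer_free_energy",
]

GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ mol^-1 K^-1


class SpeciationError(RuntimeError):
    """Speciation solve failed; carries the final mass-balance residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SSIMPLEConfig:
    """Model constants and solver controls.

    ``E_vdW`` is the constant van der Waals SSIP-SSIP interaction energy
    (kJ/mol); ``c_max`` the maximum possible SSIP concentration (M) against
    which fractional occupancy is measured; room temperature is assumed
    throughout (RT = 2.478 kJ/mol at 298 K).  ``water_ssip_convention``
    selects how the packaged W-bead liquid concentration maps onto SSIP
    concentrations: ``"per-bead"`` uses the bead concentration as stored
    (one bead = two waters), ``"per-molecule"`` doubles it so the four W
    SSIPs count once per water molecule.
    """

    E_vdW: float = -5.6
    c_max: float = 300.0
    temperature: float = 298.0
    tolerance: float = 1e-12
    max_iterations: int = 50_000
    relaxation: float = 0.5
    water_ssip_convention: str = "per-bead"

    def __post_init__(self) -> None:
        if not self.E_vdW < 0:
            raise ValueError("E_vdW must be negative")
        if not (self.c_max > 0 and self.tolerance > 0):
            raise ValueError("c_max and tolerance must be positive")
        if self.water_ssip_convention not in ("per-bead", "per-molecule"):
            raise ValueError("water_ssip_convention must be 'per-bead' or 'per-molecule'")

    @property
    def RT(self) -> float:
        """Thermal energy in kJ/mol."""
        return GAS_CONSTANT_KJ * self.temperature


def association_constant(eps_x: float, eps_y: float, cfg: SSIMPLEConfig) -> float:
    """1:1 association constant (M^-1, 1 M reference) between two SSIPs.

    This function is the single place where the pairing free energy is
    defined: the polar contribution is the product of the two site
    polarities (favourable for complementary donor/acceptor pairs, where
    ``eps_x * eps_y < 0``) and every contact additionally gains the
    constant van der Waals energy ``E_vdW``::

        K(x, y) = exp(-(eps_x * eps_y + E_vdW) / RT)

    Symmetric in its arguments, strictly increasing as the product of the
    polarities becomes more negative, and equal to ``exp(-E_vdW/RT)`` for
    two apolar sites.
    """
    return float(np.exp(-(eps_x * eps_y + cfg.E_vdW) / cfg.RT))


@dataclass
class SSIPPhase:
    """A liquid as a multiset of SSIP species.

    ``epsilons``/``concentrations`` describe the species (total molar
    concentrations); ``free_fractions`` is populated by
    :func:`solve_speciation`.
    """

    epsilons: np.ndarray
    concentrations: np.ndarray
    free_fractions: np.ndarray | None = None
    K: np.ndarray | None = field(default=None, repr=False)  # test hook

    def __post_init__(self) -> None:
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.epsilons.shape != self.concentrations.shape or self.epsilons.ndim != 1:
            raise ValueError("epsilons and concentrations must be matching 1-D arrays")
        if self.epsilons.size == 0:
            raise ValueError("phase needs at least one SSIP species")
        if np.any(self.concentrations < 0):
            raise ValueError("SSIP concentrations must be nonnegative")

    @property
    def theta(self) -> float:
        """Fractional SSIP occupancy, total concentration over ``c_max=300 M``."""
        return float(self.concentrations.sum()) / 300.0

    def theta_for(self, cfg: SSIMPLEConfig) -> float:
        return float(self.concentrations.sum()) / cfg.c_max

    @property
    def solved(self) -> bool:
        return self.free_fractions is not None


def phase_for_bead(bead: BeadType, cfg: SSIMPLEConfig) -> SSIPPhase:
    """Pure bead liquid: each distinct SSIP polarity becomes one species at
    (multiplicity x bead liquid concentration)."""
    conc = bead.liquid_conc
    if bead.name == "W" and cfg.water_ssip_convention == "per-molecule":
        conc *= 2.0
    eps, counts = np.unique(bead.epsilons, return_counts=True)
    return SSIPPhase(epsilons=eps, concentrations=counts * conc)


def _k_matrix(phase: SSIPPhase, cfg: SSIMPLEConfig) -> np.ndarray:
    if phase.K is not None:
        return np.asarray(phase.K, dtype=float)
    e = phase.epsilons
    return np.exp(-(np.outer(e, e) + cfg.E_vdW) / cfg.RT)


def _residual(xf: np.ndarray, K: np.ndarray, c: np.ndarray) -> float:
    return float(np.max(np.abs(xf * (1.0 + K @ (xf * c)) - 1.0)))


def solve_speciation(phase: SSIPPhase, cfg: SSIMPLEConfig | None = None) -> SSIPPhase:
    """Solve the coupled 1:1 pairing mass balances.

    For every species x the solved free fractions satisfy
    ``x_f = 1 / (1 + sum_y K_xy y_f c_y)`` simultaneously.  Damped
    fixed-point iteration (relaxation 0.5) with a Newton-type fallback;
    raises :class:`SpeciationError` carrying the residual on failure.
    """
    cfg = cfg or SSIMPLEConfig()
    K = _k_matrix(phase, cfg)
    c = phase.concentrations
    xf = np.ones_like(c)
    lam = cfg.relaxation
    for _ in range(cfg.max_iterations):
        target = 1.0 / (1.0 + K @ (xf * c))
        new = (1.0 - lam) * xf + lam * target
        if np.max(np.abs(new - xf)) < cfg.tolerance:
            xf = new
            break
        xf = new
    if _residual(xf, K, c) > max(cfg.tolerance * 10, 1e-10):
        sol = optimize.root(lambda v: v * (1.0 + K @ (v * c)) - 1.0, xf, method="hybr")
        xf = sol.x
        res = _residual(xf, K, c)
        if not sol.success or res > 1e-8 or np.any(xf <= 0) or np.any(xf > 1 + 1e-12):
            raise SpeciationError(f"speciation did not converge (residual {res:.3e})", res)
    return replace(phase, free_fractions=np.clip(xf, 0.0, 1.0))


def confinement_free_fraction(theta: float, cfg: SSIMPLEConfig | None = None) -> float:
    """Free fraction in the K=1 reference phase at occupancy ``theta``.

    With every association constant equal to one the mass balance collapses
    to a scalar quadratic ``x_f (1 + x_f c_tot) = 1`` with
    ``c_tot = theta * c_max``, solved in closed form.
    """
    cfg = cfg or SSIMPLEConfig()
    c_tot = theta * cfg.c_max
    if c_tot <= 0:
        return 1.0
    return float((-1.0 + np.sqrt(1.0 + 4.0 * c_tot)) / (2.0 * c_tot))


def solvation_free_energy(eps_x: float, phase: SSIPPhase,
                          cfg: SSIMPLEConfig | None = None) -> float:
    """Solvation free energy (kJ/mol) of SSIP ``x`` in a solved phase.

    The solute enters at infinite dilution: its free fraction is evaluated
    against the solvent's solved free-site concentrations, and the
    confinement reference is taken at the solvent's occupancy::

        dG_x = RT ln x_f  -  RT ln x_f^(K=1)(theta)

    so a phase whose association constants are all one solvates at zero
    cost, and the second term depends on ``theta`` only.
    """
    cfg = cfg or SSIMPLEConfig()
    if not phase.solved:
        raise ValueError("phase must be solved (call solve_speciation first)")
    if phase.K is not None:
        # test hook: an explicit K matrix only defines rows for the phase's
        # own species, so the solute must be one of them
        match = np.flatnonzero(np.isclose(phase.epsilons, eps_x))
        if match.size == 0:
            raise ValueError("with an explicit K matrix the solute SSIP must be "
                             "one of the phase species")
        k_row = np.asarray(phase.K, dtype=float)[match[0]]
    else:
        k_row = np.exp(-(eps_x * phase.epsilons + cfg.E_vdW) / cfg.RT)
    xf = 1.0 / (1.0 + float(k_row @ (phase.free_fractions * phase.concentrations)))
    xf_ref = confinement_free_fraction(phase.theta_for(cfg), cfg)
    return float(cfg.RT * (np.log(xf) - np.log(xf_ref)))


def _solvation_with_K(k_row: np.ndarray, phase: SSIPPhase, cfg: SSIMPLEConfig) -> float:
    xf = 1.0 / (1.0 + float(k_row @ (phase.free_fractions * phase.concentrations)))
    xf_ref = confinement_free_fraction(phase.theta_for(cfg), cfg)
    return float(cfg.RT * (np.log(xf) - np.log(xf_ref)))


@dataclass(frozen=True)
class TransferResult:
    """Transfer free energy of a bead between two pure bead liquids."""

    bead_i: str
    bead_j: str
    dG: float                       # kJ/mol
    per_ssip: tuple[tuple[float, float], ...]  # (epsilon, contribution)


def transfer_free_energy(bead_i: BeadType, bead_j: BeadType,
                         library: BeadLibraryFile | None = None,
                         cfg: SSIMPLEConfig | None = None) -> TransferResult:
    """Free energy (kJ/mol) to move bead *i* from its pure liquid to a
    dilute solution in the pure liquid of bead *j*.

    Each solvent phase is speciated on its own; the solute bead's SSIPs are
    then solvated at infinite dilution in each phase and the per-SSIP
    solvation differences are summed.  ``dG`` is zero (to solver tolerance)
    for the identity transfer.
    """
    cfg = cfg or SSIMPLEConfig()
    phase_i = solve_speciation(phase_for_bead(bead_i, cfg), cfg)
    phase_j = solve_speciation(phase_for_bead(bead_j, cfg), cfg)
    contributions = []
    total = 0.0
    for eps in bead_i.epsilons:
        d = (solvation_free_energy(float(eps), phase_j, cfg)
             - solvation_free_energy(float(eps), phase_i, cfg))
        contributions.append((float(eps), d))
        total += d
    return TransferResult(bead_i=bead_i.name, bead_j=bead_j.name,
                          dG=total, per_ssip=tuple(contributions))
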