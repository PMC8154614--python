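"""SSIP speciation and solvation: oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpdchem.beads import BeadType, SSIP
from dpdchem.ssimple import (SSIMPLEConfig, SSIPPhase, association_constant,
                             confinement_free_fraction, phase_for_bead,
                             solvation_free_energy, solve_speciation,
                             transfer_free_energy)

CFG = SSIMPLEConfig()


# ---------------------------------------------------------------------- K ---

@given(st.floats(-8, 8), st.floats(-8, 8))
@settings(deadline=None, max_examples=100)
def test_association_constant_symmetric_and_positive(ex, ey):
    assert association_constant(ex, ey, CFG) == association_constant(ey, ex, CFG)
    assert association_constant(ex, ey, CFG) > 0


def test_apolar_association_is_pure_van_der_waals():
    # independent scalar arithmetic: K(0,0) = exp(-E_vdW / RT)
    expected = math.exp(5.6 / (8.31446261815324e-3 * 298.0))
    assert association_constant(0.0, 0.0, CFG) == pytest.approx(expected, rel=1e-12)


def test_complementary_pairs_bind_tighter():
    assert association_constant(-4.5, 2.8, CFG) > association_constant(-0.3, 0.4, CFG)
    # strictly increasing as the polarity product becomes more negative
    ks = [association_constant(-e, e, CFG) for e in (0.5, 1.0, 2.0, 3.0)]
    assert all(a < b for a, b in zip(ks, ks[1:]))


# -------------------------------------------------------------- speciation ---

def test_dilute_single_species_is_fully_free():
    phase = solve_speciation(SSIPPhase(np.array([2.0]), np.array([1e-9])), CFG)
    assert phase.free_fractions[0] == pytest.approx(1.0, abs=1e-6)


def _bisect_two_species(K, c, tol=1e-13):
    """Brute-force oracle for the 2-species mass balance: bisection on x1
    with an inner bisection for x2."""

    def x2_of(x1):
        lo, hi = 1e-16, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mid * (1 + K[1][0] * x1 * c[0] + K[1][1] * mid * c[1]) - 1 > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo, hi = 1e-16, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        x2 = x2_of(mid)
        if mid * (1 + K[0][0] * mid * c[0] + K[0][1] * x2 * c[1]) - 1 > 0:
            hi = mid
        else:
            lo = mid
    x1 = 0.5 * (lo + hi)
    return x1, x2_of(x1)


def test_two_species_solution_matches_bisection_oracle():
    K = [[0.4, 1500.0], [1500.0, 0.01]]
    c = np.array([40.0, 25.0])
    phase = SSIPPhase(np.array([2.8, -4.5]), c, K=np.array(K))
    solved = solve_speciation(phase, CFG)
    x1, x2 = _bisect_two_species(K, c)
    assert solved.free_fractions[0] == pytest.approx(x1, rel=1e-6)
    assert solved.free_fractions[1] == pytest.approx(x2, rel=1e-6)


def test_mass_balance_conservation(library):
    # total = free + bound recomputed from the solved fractions
    for name in library.beads:
        phase = solve_speciation(phase_for_bead(library.bead(name), CFG), CFG)
        xf, c = phase.free_fractions, phase.concentrations
        K = np.exp(-(np.outer(phase.epsilons, phase.epsilons) + CFG.E_vdW) / CFG.RT)
        total = xf * c + (xf * c) * (K @ (xf * c))
        assert np.allclose(total, c, rtol=1e-8)


def test_speciation_residual_below_1e8_for_all_packaged_liquids(library):
    for name in library.beads:
        phase = solve_speciation(phase_for_bead(library.bead(name), CFG), CFG)
        xf, c = phase.free_fractions, phase.concentrations
        K = np.exp(-(np.outer(phase.epsilons, phase.epsilons) + CFG.E_vdW) / CFG.RT)
        residual = np.max(np.abs(xf * (1 + K @ (xf * c)) - 1))
        assert residual < 1e-8


def test_free_fraction_decreases_with_concentration_and_affinity():
    base = solve_speciation(SSIPPhase(np.array([1.0, -1.0]), np.array([10.0, 10.0])), CFG)
    richer = solve_speciation(SSIPPhase(np.array([1.0, -1.0]), np.array([10.0, 30.0])), CFG)
    assert richer.free_fractions[0] < base.free_fractions[0]
    stronger = solve_speciation(SSIPPhase(np.array([2.0, -2.0]), np.array([10.0, 10.0])), CFG)
    assert stronger.free_fractions[0] < base.free_fractions[0]


# --------------------------------------------------------------- solvation ---

def test_unit_constant_phase_solvates_at_zero_cost():
    c = np.array([30.0, 50.0])
    phase = SSIPPhase(np.array([1.5, -2.0]), c, K=np.ones((2, 2)))
    solved = solve_speciation(phase, CFG)
    for eps in (1.5, -2.0):
        assert solvation_free_energy(eps, solved, CFG) == pytest.approx(0.0, abs=1e-9)


def test_confinement_closed_form_agrees_with_unit_K_speciation():
    for theta in (0.05, 0.2, 0.5, 0.9):
        c_tot = theta * CFG.c_max
        solved = solve_speciation(
            SSIPPhase(np.array([0.3, -0.7]), np.array([c_tot / 2, c_tot / 2]),
                      K=np.ones((2, 2))), CFG)
        assert solved.free_fractions[0] == pytest.approx(
            confinement_free_fraction(theta, CFG), abs=1e-10)


def test_solvation_monotone_in_polarity_against_complementary_phase(library):
    phase = solve_speciation(phase_for_bead(library.bead("W"), CFG), CFG)
    donors = np.linspace(0.0, 4.0, 9)   # increasingly strong donors vs water acceptors
    energies = [solvation_free_energy(e, phase, CFG) for e in donors]
    assert all(b < a for a, b in zip(energies, energies[1:]))


def test_unsolved_phase_rejected():
    with pytest.raises(ValueError, match="solved"):
        solvation_free_energy(1.0, SSIPPhase(np.array([1.0]), np.array([5.0])), CFG)


# ---------------------------------------------------------------- transfer ---

def test_identity_transfer_is_zero_for_all_beads(library):
    for name in library.beads:
        bead = library.bead(name)
        res = transfer_free_energy(bead, bead, library, CFG)
        assert res.dG == pytest.approx(0.0, abs=1e-7)


def test_tertiary_amide_prefers_water_over_secondary():
    # the tertiary amide loses no amide-amide hydrogen bonds on transfer
    import dpdchem.beads as beads
    lib = beads.default_library()
    w = lib.bead("W")
    dg_am3p = transfer_free_energy(lib.bead("AM3'"), w, lib, CFG).dG
    dg_am2 = transfer_free_energy(lib.bead("AM2"), w, lib, CFG).dG
    assert dg_am3p < dg_am2


def test_ssip_order_does_not_matter(library):
    w = library.bead("W")
    shuffled = BeadType(name="ES2",
                        ssips=tuple(SSIP(e) for e in (0.4, -5.5, 0.2, 0.4, -2.6,
                                                      0.4, -5.5, 0.2, 0.4)),
                        volume=68.8, liquid_conc=12.518, a_self=22.0, R_self=1.141)
    ref = transfer_free_energy(library.bead("ES"), w, library, CFG).dG
    assert transfer_free_energy(shuffled, w, library, CFG).dG == pytest.approx(ref, abs=1e-9)


def test_two_ssip_toy_bead_matches_exhaustive_oracle():
    """Transfer of a 2-SSIP bead between two 2-species liquids, cross-checked
    against the bisection oracle applied to every speciation involved."""
    cfg = CFG
    bead_a = BeadType("A", (SSIP(1.2), SSIP(-1.2)), volume=40.0,
                      liquid_conc=10.0, a_self=22.0, R_self=1.0)
    bead_b = BeadType("B", (SSIP(2.2), SSIP(-2.2)), volume=40.0,
                      liquid_conc=20.0, a_self=22.0, R_self=1.0)

    def oracle_phase(bead):
        eps = np.sort(bead.epsilons)
        c = np.array([bead.liquid_conc, bead.liquid_conc])
        K = [[association_constant(eps[i], eps[j], cfg) for j in range(2)]
             for i in range(2)]
        x1, x2 = _bisect_two_species(K, c)
        return eps, c, np.array([x1, x2])

    def oracle_solvation(eps_x, eps, c, xf, theta):
        k_row = np.array([association_constant(eps_x, e, cfg) for e in eps])
        x = 1.0 / (1.0 + k_row @ (xf * c))
        return cfg.RT * (np.log(x) - np.log(confinement_free_fraction(theta, cfg)))

    ea, ca, xa = oracle_phase(bead_a)
    eb, cb, xb = oracle_phase(bead_b)
    expected = 0.0
    for eps in bead_a.epsilons:
        expected += oracle_solvation(eps, eb, cb, xb, cb.sum() / cfg.c_max)
        expected -= oracle_solvation(eps, ea, ca, xa, ca.sum() / cfg.c_max)

    lib_like = None  # transfer_free_energy ignores the library argument's content
    got = transfer_free_energy(bead_a, bead_b, lib_like, cfg).dG
    assert got == pytest.approx(expected, rel=1e-6, abs=1e-8)
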