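"""DPD engine: force laws, integration, thermostat, reproducibility."""

import numpy as np
import pytest

from dpdchem import _kernels
from dpdchem.beads import MoleculeTopology, Bond, Angle, build_surfactant
from dpdchem.engine import (InstabilityError, SimConfig, SimState, build_system,
                            conservative_force, run_simulation, step)
from dpdchem.params import build_paramset
from dpdchem.units import UnitMap

A1 = np.array([[25.0]])
R1 = np.array([[1.0]])


def _two_bead_state(r, params):
    L = 10.0
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    return SimState(pos=pos, vel=np.zeros((2, 3)),
                    types=np.zeros(2, np.int64), mol_id=np.arange(2),
                    mol_name=["W", "W"], params=params, L=L)


def test_conservative_force_vanishes_at_cutoff():
    assert np.allclose(conservative_force(np.array([1.0, 0, 0]), 25.0, 1.0), 0)
    assert np.allclose(conservative_force(np.array([1.7, 0, 0]), 25.0, 1.2), 0)


def test_conservative_force_soft_core_magnitude():
    f = conservative_force(np.array([1e-9, 0, 0]), 25.0, 1.0)
    assert np.linalg.norm(f) == pytest.approx(25.0, rel=1e-6)
    f = conservative_force(np.array([0.5, 0, 0]), 30.0, 1.0)
    assert f[0] == pytest.approx(30.0 * 0.5)


def test_coincident_beads_warn_and_stay_finite():
    with pytest.warns(UserWarning, match="coincident"):
        f = conservative_force(np.zeros(3), 25.0, 1.0)
    assert np.linalg.norm(f) == pytest.approx(25.0)


def test_force_is_negative_gradient_of_pair_potential():
    """Finite-difference oracle on U(r) = (a R / 2)(1 - r/R)^2."""
    a, R, L = 23.0, 1.1, 12.0
    types = np.zeros(2, np.int64)
    h = 1e-6
    for r in np.linspace(0.15, 1.05, 10):
        pos = np.array([[3.0, 3.0, 3.0], [3.0 + r, 3.0, 3.0]])
        up = pos.copy()
        up[1, 0] += h
        dn = pos.copy()
        dn[1, 0] -= h
        dudr = (_kernels.nonbonded_energy(up, types, np.array([[a]]), np.array([[R]]), L)
                - _kernels.nonbonded_energy(dn, types, np.array([[a]]), np.array([[R]]), L)) / (2 * h)
        f = _kernels.nonbonded_forces(pos, np.zeros((2, 3)), types, np.array([[a]]),
                                      np.array([[R]]), L, 0.0, 0.0, np.uint64(0), 0, False)
        assert f[1, 0] == pytest.approx(-dudr, abs=1e-6)


def test_bonded_forces_match_finite_difference():
    """Three-bead chain with a bent angle: forces vs energy gradient."""
    L = 20.0
    pos = np.array([[5.0, 5.0, 5.0], [5.7, 5.1, 4.9], [6.1, 5.9, 5.3]])
    bi = np.array([0, 1], np.int64)
    bj = np.array([1, 2], np.int64)
    br0 = np.array([0.6, 0.65])
    bk = np.array([150.0, 150.0])
    ai = np.array([0], np.int64)
    aj = np.array([1], np.int64)
    ak = np.array([2], np.int64)
    th0 = np.array([np.deg2rad(160.0)])
    ks = np.array([5.0])
    f = _kernels.bonded_forces(pos, L, bi, bj, br0, bk, ai, aj, ak, th0, ks)
    h = 1e-7
    for p in range(3):
        for d in range(3):
            up = pos.copy(); up[p, d] += h
            dn = pos.copy(); dn[p, d] -= h
            dU = (_kernels.bonded_energy(up, L, bi, bj, br0, bk, ai, aj, ak, th0, ks)
                  - _kernels.bonded_energy(dn, L, bi, bj, br0, bk, ai, aj, ak, th0, ks)) / (2 * h)
            assert f[p, d] == pytest.approx(-dU, abs=5e-5)
    # net force and torque of the isolated bonded cluster vanish
    assert np.allclose(f.sum(axis=0), 0, atol=1e-12)
    torque = np.cross(pos - pos.mean(axis=0), f).sum(axis=0)
    assert np.allclose(torque, 0, atol=1e-10)


def test_bond_at_rest_length_and_angle_at_equilibrium_give_zero_force():
    L = 20.0
    pos = np.array([[5.0, 5.0, 5.0], [5.6, 5.0, 5.0], [6.2, 5.0, 5.0]])
    f = _kernels.bonded_forces(pos, L, np.array([0, 1], np.int64),
                               np.array([1, 2], np.int64), np.array([0.6, 0.6]),
                               np.array([150.0, 150.0]), np.array([0], np.int64),
                               np.array([1], np.int64), np.array([2], np.int64),
                               np.array([np.pi]), np.array([5.0]))
    assert np.allclose(f, 0, atol=1e-9)


def test_collinear_angle_stays_finite_even_off_equilibrium():
    L = 20.0
    pos = np.array([[5.0, 5.0, 5.0], [5.6, 5.0, 5.0], [6.2, 5.0, 5.0]])
    f = _kernels.bonded_forces(pos, L, np.empty(0, np.int64), np.empty(0, np.int64),
                               np.empty(0), np.empty(0), np.array([0], np.int64),
                               np.array([1], np.int64), np.array([2], np.int64),
                               np.array([np.deg2rad(120.0)]), np.array([5.0]))
    assert np.all(np.isfinite(f))


def test_quiescent_far_apart_beads_do_not_move(water_params):
    state = _two_bead_state(3.0, water_params)
    cfg = SimConfig(L=10.0, steps=1, gamma=0.0, sigma=0.0)
    step(state, cfg)
    assert np.allclose(state.pos, _two_bead_state(3.0, water_params).pos)
    assert np.allclose(state.vel, 0)


def test_identical_seeds_give_bitwise_identical_trajectories(library, water_params):
    cfg = SimConfig(L=5.0, steps=300, seed=42, stride=50)
    t1 = run_simulation(library, water_params, cfg)
    t2 = run_simulation(library, water_params, cfg)
    assert np.array_equal(t1.frames, t2.frames)
    cfg3 = SimConfig(L=5.0, steps=300, seed=43, stride=50)
    t3 = run_simulation(library, water_params, cfg3)
    assert not np.array_equal(t1.frames, t3.frames)


def test_momentum_conserved_through_integration(library, water_params):
    cfg = SimConfig(L=5.0, steps=500, seed=9, stride=100)
    state = build_system(library, water_params, cfg)
    assert np.allclose(state.momentum(), 0, atol=1e-10)
    for _ in range(50):
        step(state, cfg)
    # accumulated drift stays at floating-point level: < 1e-8 per step per bead
    assert np.max(np.abs(state.momentum())) < 1e-8 * 50 * state.n


def test_cell_list_forces_equal_brute_force(rng):
    n, L = 200, 6.0
    pos = rng.uniform(0, L, (n, 3))
    vel = rng.normal(size=(n, 3))
    types = rng.integers(0, 2, n).astype(np.int64)
    A = np.array([[25.0, 30.0], [30.0, 22.0]])
    R = np.array([[1.0, 1.05], [1.05, 1.1]])
    args = (pos, vel, types, A, R, L, 4.5, 30.0, np.uint64(3), 17)
    f_cells = _kernels.nonbonded_forces(*args, True)
    f_brute = _kernels.nonbonded_forces(*args, False)
    assert np.allclose(f_cells, f_brute, rtol=1e-12, atol=1e-12)


def test_bead_counts_follow_density(library, water_params):
    cfg = SimConfig(L=10.0, steps=0)
    state = build_system(library, water_params, cfg)
    assert state.n == 3000
    assert SimConfig(L=40.0, steps=0).n_beads == 192_000


def test_weight_percent_round_trips_within_one_molecule(library):
    mol = build_surfactant("XYL", 8, library)
    params = build_paramset(library, [mol])
    units = UnitMap()
    for wt in (4.0, 5.0, 6.0):
        n = units.wt_percent_to_count(wt, mol.molar_mass, mol.n_beads, 12.0)
        back = units.count_to_wt_percent(n, mol.molar_mass, mol.n_beads, 12.0)
        n2 = units.wt_percent_to_count(back, mol.molar_mass, mol.n_beads, 12.0)
        assert abs(n2 - n) <= 1


def test_overfull_composition_rejected_before_integration(library):
    mol = build_surfactant("XYL", 8, library)
    params = build_paramset(library, [mol])
    cfg = SimConfig(L=3.0, steps=10, composition={"XYL8": 100})
    with pytest.raises(ValueError, match="composition"):
        build_system(library, params, cfg)


def test_runaway_velocity_triggers_instability_error(water_params):
    state = _two_bead_state(3.0, water_params)
    state.vel[0] = 1e6
    with pytest.raises(InstabilityError):
        step(state, SimConfig(L=10.0, steps=1))


def test_mismatched_fluctuation_dissipation_rejected():
    with pytest.raises(ValueError, match="fluctuation-dissipation"):
        SimConfig(L=5.0, steps=1, gamma=4.5, sigma=1.0)


def test_trajectory_archive_roundtrip(tmp_path, library, water_params):
    from dpdchem.engine import Trajectory
    cfg = SimConfig(L=5.0, steps=200, seed=4, stride=100)
    traj = run_simulation(library, water_params, cfg)
    p = tmp_path / "t.h5"
    traj.save(p)
    back = Trajectory.load(p)
    assert np.array_equal(back.frames, traj.frames)
    assert back.bead_names == traj.bead_names
    assert back.L == traj.L
    xyz = tmp_path / "t.xyz"
    traj.export_xyz(xyz)
    assert xyz.read_text().splitlines()[0] == str(traj.frames.shape[1])
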