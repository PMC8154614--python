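"""Compact DPD simulator.

Soft pairwise repulsion with per-pair interaction ranges, the standard
pairwise drag/random thermostat (momentum conserving, kBT = 1 set point),
harmonic bonds and 1-3 angles, velocity-Verlet integration and a periodic
cubic box with linked-cell neighbour search.  Heavy loops live in the
numba kernels of :mod:`dpdchem._kernels`; this module owns state setup,
composition handling and the trajectory container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import _kernels
from .beads import BeadLibraryFile, MoleculeTopology, HYDROPHOBIC_BEADS
from .params import ParamSet
from .units import UnitMap

__all__ = ["SimConfig", "SimState", "Trajectory", "conservative_force",
           "bonded_forces", "nonbonded_forces", "step", "build_system",
           "run_simulation", "InstabilityError"]


class InstabilityError(RuntimeError):
    """A bead moved more than half a box edge in one timestep."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol: box, composition, thermostat and schedule.

    ``composition`` maps molecule names (must match the ParamSet's
    molecules) to either counts (``{"XYL8": 40}``) or weight percents
    (``{"XYL8": "5%"}``); the remainder of the ``rho * L^3`` beads is
    solvent.  ``gamma = 4.5`` and ``sigma = 3`` satisfy the
    fluctuation-dissipation relation sigma^2 = 2 gamma kBT at kBT = 1.
    """

    L: float
    steps: int
    seed: int = 0
    rho: float = 3.0
    dt: float = 0.01
    stride: int = 1000
    gamma: float = 4.5
    sigma: float = 3.0
    composition: dict = field(default_factory=dict)
    units: UnitMap = field(default_factory=UnitMap)

    def __post_init__(self) -> None:
        if self.L <= 0 or self.dt <= 0 or self.steps < 0 or self.stride <= 0:
            raise ValueError("L, dt must be positive; steps, stride nonnegative")
        if abs(self.sigma ** 2 - 2.0 * self.gamma) > 1e-9:
            raise ValueError("fluctuation-dissipation requires sigma^2 = 2 gamma kBT "
                             f"(kBT=1): got sigma^2={self.sigma**2}, 2 gamma={2*self.gamma}")

    @property
    def n_beads(self) -> int:
        return int(round(self.rho * self.L ** 3))


@dataclass
class SimState:
    """Positions/velocities/topology of one simulation in progress."""

    pos: np.ndarray            # (N, 3), wrapped into [0, L)
    vel: np.ndarray            # (N, 3)
    types: np.ndarray          # (N,) int index into params.names
    mol_id: np.ndarray         # (N,) molecule id (waters get unique ids)
    mol_name: list             # per-molecule name token ("W" for solvent)
    params: ParamSet
    L: float
    bond_i: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    bond_j: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    bond_r0: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    bond_k: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    ang_i: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ang_j: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ang_k: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ang_th0: np.ndarray = field(default_factory=lambda: np.empty(0, float))  # radians
    ang_ks: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    step_count: int = 0

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def kinetic_temperature(self) -> float:
        ke = float(np.sum(self.vel ** 2))
        return ke / (3.0 * self.n - 3.0)

    def momentum(self) -> np.ndarray:
        return self.vel.sum(axis=0)


def conservative_force(r_ij: np.ndarray, a_ij: float, R_ij: float,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Soft repulsion on bead i from bead j separated by ``r_ij = r_i - r_j``.

    Magnitude ``a_ij (1 - r/R_ij)`` along the unit separation for
    ``r < R_ij`` and exactly zero beyond.  At zero separation the direction
    is an (optionally seeded) random unit vector, with a warning.
    """
    r_ij = np.asarray(r_ij, dtype=float)
    r = float(np.linalg.norm(r_ij))
    if r >= R_ij:
        return np.zeros(3)
    if r < 1e-12:
        warnings.warn("coincident beads: tie-breaking force direction randomly",
                      stacklevel=2)
        rng = rng or np.random.default_rng(0)
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        return a_ij * e
    return a_ij * (1.0 - r / R_ij) * (r_ij / r)


def nonbonded_forces(state: SimState, with_thermostat: bool = False,
                     gamma: float = 4.5, sigma: float = 3.0, dt: float = 0.01,
                     seed: int = 0, use_cells: bool = True) -> np.ndarray:
    """Pairwise forces on every bead (conservative, plus thermostat on request)."""
    g = gamma if with_thermostat else 0.0
    s = sigma / np.sqrt(dt) if with_thermostat else 0.0
    return _kernels.nonbonded_forces(state.pos, state.vel, state.types,
                                     state.params.a, state.params.R, state.L,
                                     g, s, np.uint64(seed),
                                     np.uint64(state.step_count), use_cells)


def bonded_forces(state: SimState) -> np.ndarray:
    """Harmonic bond + angle forces accumulated per bead."""
    return _kernels.bonded_forces(state.pos, state.L, state.bond_i, state.bond_j,
                                  state.bond_r0, state.bond_k, state.ang_i,
                                  state.ang_j, state.ang_k, state.ang_th0,
                                  state.ang_ks)


def step(state: SimState, cfg: SimConfig) -> SimState:
    """Advance the state by one velocity-Verlet step (in place; returned for
    chaining).  Reproducible: the pair noise depends only on (seed, step, pair)."""
    frames = np.empty((0, state.n, 3))
    temps = np.empty(0)
    rc = _kernels.run_steps(state.pos, state.vel, state.types, state.params.a,
                            state.params.R, state.L, cfg.dt, cfg.gamma, cfg.sigma,
                            np.uint64(cfg.seed), state.step_count, 1,
                            state.bond_i, state.bond_j, state.bond_r0, state.bond_k,
                            state.ang_i, state.ang_j, state.ang_k, state.ang_th0,
                            state.ang_ks, 10 ** 9, frames, temps, 0)
    if rc < 0:
        raise InstabilityError(f"displacement exceeded L/2 at step {state.step_count}")
    state.step_count += 1
    return state


def _resolve_counts(cfg: SimConfig, params: ParamSet) -> dict[str, int]:
    by_name = {m.name: m for m in params.molecules}
    counts: dict[str, int] = {}
    for name, spec in cfg.composition.items():
        if name not in by_name:
            raise KeyError(f"molecule {name!r} not in the parameter set")
        mol = by_name[name]
        if isinstance(spec, str) and spec.endswith("%"):
            wt = float(spec[:-1])
            counts[name] = cfg.units.wt_percent_to_count(
                wt, mol.molar_mass, mol.n_beads, cfg.L, cfg.rho)
        else:
            counts[name] = int(spec)
    return counts


def build_system(library: BeadLibraryFile, params: ParamSet, cfg: SimConfig,
                 start: str = "random") -> SimState:
    """Initial condition: surfactant chains as compact random walks, W fill,
    Maxwell velocities at kBT = 1 with the drift removed.

    ``start="clustered"`` seeds all surfactant chains inside one compact
    ball at the box centre instead of dispersing them: monomer-micelle
    coexistence is then approached from the micellar side, which avoids
    the slow nucleation stage in small boxes."""
    if "W" not in params.names:
        raise KeyError("parameter set must include the solvent bead W")
    rng = np.random.default_rng(cfg.seed)
    counts = _resolve_counts(cfg, params)
    by_name = {m.name: m for m in params.molecules}
    n_total = cfg.n_beads
    n_solute = sum(by_name[n].n_beads * c for n, c in counts.items())
    if n_solute > n_total:
        raise ValueError(f"composition needs {n_solute} beads but the box holds "
                         f"{n_total} at rho={cfg.rho}")

    pos = np.empty((n_total, 3))
    types = np.empty(n_total, dtype=np.int64)
    mol_id = np.empty(n_total, dtype=np.int64)
    mol_name: list[str] = []
    bi, bj, br0, bk = [], [], [], []
    ai, aj, ak, ath0 = [], [], [], []

    cursor = 0
    mol_counter = 0
    for name, c in counts.items():
        mol = by_name[name]
        m_idx = list(params.molecules).index(mol)
        bonds = params.bond_params[m_idx]
        for _ in range(c):
            base = cursor
            chain = np.empty((mol.n_beads, 3))
            if start == "clustered":
                blob_r = max(1.5, 0.4 * (3.0 * n_solute / (4 * np.pi * cfg.rho)) ** (1 / 3) * 2.5)
                chain[0] = cfg.L / 2 + rng.uniform(-blob_r, blob_r, size=3)
            else:
                chain[0] = rng.uniform(0, cfg.L, size=3)
            placed = {0}
            # walk the bond list so every bead is placed next to a bonded partner
            pending = list(range(len(mol.bonds)))
            while pending:
                progressed = False
                for pb in list(pending):
                    b = mol.bonds[pb]
                    if b.i in placed and b.j not in placed:
                        src, dst = b.i, b.j
                    elif b.j in placed and b.i not in placed:
                        src, dst = b.j, b.i
                    elif b.i in placed and b.j in placed:
                        pending.remove(pb)
                        continue
                    else:
                        continue
                    e = rng.normal(size=3)
                    e /= np.linalg.norm(e)
                    chain[dst] = chain[src] + bonds[pb][1] * e
                    placed.add(dst)
                    pending.remove(pb)
                    progressed = True
                if not progressed:
                    break
            pos[base:base + mol.n_beads] = chain % cfg.L
            for k, bead in enumerate(mol.beads):
                types[base + k] = params.index(bead)
                mol_id[base + k] = mol_counter
            for pb, b in enumerate(mol.bonds):
                bi.append(base + b.i)
                bj.append(base + b.j)
                br0.append(bonds[pb][1])
                bk.append(params.k_bond)
            for ang in mol.angles:
                ai.append(base + ang.i)
                aj.append(base + ang.j)
                ak.append(base + ang.k)
                ath0.append(np.deg2rad(ang.theta0))
            mol_name.append(name)
            mol_counter += 1
            cursor += mol.n_beads

    w_idx = params.index("W")
    n_w = n_total - cursor
    pos[cursor:] = rng.uniform(0, cfg.L, size=(n_w, 3))
    types[cursor:] = w_idx
    for _ in range(n_w):
        mol_id[cursor] = mol_counter
        mol_name.append("W")
        mol_counter += 1
        cursor += 1

    vel = rng.normal(size=(n_total, 3))
    vel -= vel.mean(axis=0)

    return SimState(
        pos=pos, vel=vel, types=types, mol_id=mol_id, mol_name=mol_name,
        params=params, L=cfg.L,
        bond_i=np.array(bi, np.int64), bond_j=np.array(bj, np.int64),
        bond_r0=np.array(br0, float), bond_k=np.array(bk, float),
        ang_i=np.array(ai, np.int64), ang_j=np.array(aj, np.int64),
        ang_k=np.array(ak, np.int64), ang_th0=np.array(ath0, float),
        ang_ks=np.full(len(ai), params.k_angle, float))


@dataclass
class Trajectory:
    """Frames (wrapped positions) plus the static per-bead metadata needed
    for aggregate analysis."""

    frames: np.ndarray         # (F, N, 3) float32
    temperatures: np.ndarray   # (F,)
    L: float
    dt: float
    stride: int
    types: np.ndarray
    mol_id: np.ndarray
    bead_names: tuple[str, ...]
    mol_names: tuple[str, ...] = ()
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def hydrophobic_mask(self) -> np.ndarray:
        names = np.array(self.bead_names)[self.types]
        return np.isin(names, sorted(HYDROPHOBIC_BEADS))

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs.update({"L": self.L, "dt": self.dt, "stride": self.stride,
                             "seed": self.seed})
            fh.create_dataset("frames", data=self.frames, compression="gzip")
            fh.create_dataset("temperatures", data=self.temperatures)
            fh.create_dataset("types", data=self.types)
            fh.create_dataset("mol_id", data=self.mol_id)
            fh.create_dataset("bead_names",
                              data=np.array(self.bead_names, dtype="S"))
            fh.create_dataset("mol_names",
                              data=np.array(self.mol_names, dtype="S"))

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        with h5py.File(path, "r") as fh:
            return cls(
                frames=fh["frames"][...],
                temperatures=fh["temperatures"][...],
                L=float(fh.attrs["L"]), dt=float(fh.attrs["dt"]),
                stride=int(fh.attrs["stride"]), seed=int(fh.attrs["seed"]),
                types=fh["types"][...], mol_id=fh["mol_id"][...],
                bead_names=tuple(s.decode() for s in fh["bead_names"][...]),
                mol_names=tuple(s.decode() for s in fh["mol_names"][...]))

    def export_xyz(self, path: str | Path, every: int = 1) -> None:
        names = np.array(self.bead_names)[self.types]
        with open(path, "w") as out:
            for f in range(0, self.n_frames, every):
                out.write(f"{len(names)}\nframe {f}\n")
                for nm, (x, y, z) in zip(names, self.frames[f]):
                    out.write(f"{nm.replace(chr(39), 'p')} {x:.4f} {y:.4f} {z:.4f}\n")


def run_simulation(library: BeadLibraryFile, params: ParamSet,
                   cfg: SimConfig, state: SimState | None = None) -> Trajectory:
    """Run the configured number of steps and collect frames every ``stride``.

    The composition is validated before any integration.  Trajectories are
    bitwise reproducible for a given config (counter-based pair noise).
    """
    state = state or build_system(library, params, cfg)
    n_frames = cfg.steps // cfg.stride
    frames = np.zeros((n_frames, state.n, 3), dtype=np.float64)
    temps = np.zeros(n_frames)
    rc = _kernels.run_steps(state.pos, state.vel, state.types, state.params.a,
                            state.params.R, state.L, cfg.dt, cfg.gamma, cfg.sigma,
                            np.uint64(cfg.seed), state.step_count, cfg.steps,
                            state.bond_i, state.bond_j, state.bond_r0, state.bond_k,
                            state.ang_i, state.ang_j, state.ang_k, state.ang_th0,
                            state.ang_ks, cfg.stride, frames, temps, 0)
    if rc < 0:
        raise InstabilityError("displacement exceeded L/2 during integration")
    state.step_count += cfg.steps
    return Trajectory(frames=frames[:rc].astype(np.float32),
                      temperatures=temps[:rc], L=cfg.L, dt=cfg.dt,
                      stride=cfg.stride, types=state.types.copy(),
                      mol_id=state.mol_id.copy(),
                      bead_names=tuple(params.names),
                      mol_names=tuple(state.mol_name), seed=cfg.seed)
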