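"""Deterministic generators for test inputs.

Planted-micelle trajectories have their CMC, aggregation numbers and
shape classes known exactly by construction: each planted aggregate is a
contiguous lattice fill of an ellipsoid with prescribed axis ratios
(lattice spacing well inside the clustering cutoff, so connectivity is
guaranteed), and free monomers are placed at least two cutoffs away from
everything else.  Scaled-down simulation configurations reproduce the
production protocol (bead density 3, dt 0.01, 5 wt%) in boxes small
enough for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .beads import BeadLibraryFile, build_surfactant, default_library
from .engine import SimConfig, Trajectory
from .params import ParamSet, build_paramset
from .units import UnitMap

__all__ = ["PlantedAggregate", "PlantedTrajectorySpec", "make_planted_trajectory",
           "make_small_sim_config", "build_small_system", "save_sim_config",
           "load_sim_config"]


@dataclass(frozen=True)
class PlantedAggregate:
    size: int
    ratio_ab: float = 1.0     # A/B
    ratio_bc: float = 1.0     # B/C
    center: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class PlantedTrajectorySpec:
    L: float
    aggregates: tuple[PlantedAggregate, ...]
    n_free: int = 0
    n_frames: int = 5
    seed: int = 0
    spacing: float = 0.55     # lattice spacing, must stay below the cutoff
    margin: float = 2.0       # minimum clearance between planted objects


def _ellipsoid_points(n: int, ratio_ab: float, ratio_bc: float,
                      spacing: float) -> np.ndarray:
    """``n`` lattice points filling an ellipsoid with semi-axes in the
    proportions (ab*bc) : bc : 1."""
    rx_u, ry_u, rz_u = ratio_ab * ratio_bc, ratio_bc, 1.0
    c0 = (3.0 * n * spacing ** 3 / (4.0 * np.pi * rx_u * ry_u * rz_u)) ** (1 / 3)
    # generous lattice extent, then keep the n sites closest in the
    # ellipsoidal metric -> contiguous, approximately the right shape
    ext = int(np.ceil((c0 * rx_u) / spacing)) + 2
    ax = np.arange(-ext, ext + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    metric = ((pts[:, 0] / rx_u) ** 2 + (pts[:, 1] / ry_u) ** 2
              + (pts[:, 2] / rz_u) ** 2)
    order = np.argsort(metric, kind="stable")
    return pts[order[:n]]


def make_planted_trajectory(spec: PlantedTrajectorySpec) -> Trajectory:
    """Build a trajectory whose aggregate statistics are known exactly.

    Every planted molecule is a single hydrophobic bead (C2), so the
    clustering partition equals the planted partition whenever the
    inter-object margins exceed the clustering cutoff.  All frames are
    identical (the planted truth is a static configuration), making
    frame-to-frame spreads exactly zero.  Raises when the objects cannot
    be placed in the box with the requested margins.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    placed_pts: list[np.ndarray] = []
    extents = []
    for agg in spec.aggregates:
        pts = _ellipsoid_points(agg.size, agg.ratio_ab, agg.ratio_bc,
                                spec.spacing)
        extents.append((pts, np.max(np.linalg.norm(pts, axis=1))))

    # deterministic center grid with capacity check
    radius_max = max((r for _, r in extents), default=0.0)
    cell = 2 * radius_max + spec.margin
    per_side = max(1, int(L // cell))
    if len(spec.aggregates) > per_side ** 3:
        raise ValueError(
            f"overcrowded spec: {len(spec.aggregates)} aggregates of extent "
            f"{radius_max:.2f} do not fit a {L}-edge box with margin {spec.margin}")
    centers_grid = [(i + 0.5) * L / per_side for i in range(per_side)]
    grid = [(x, y, z) for x in centers_grid for y in centers_grid for z in centers_grid]
    for k, (agg, (pts, _)) in enumerate(zip(spec.aggregates, extents)):
        center = np.array(agg.center if agg.center is not None else grid[k])
        placed_pts.append(pts + center)

    occupied = np.concatenate(placed_pts) if placed_pts else np.empty((0, 3))
    free_pts = []
    if spec.n_free:
        # free monomers on a shifted coarse grid, kept clear of everything
        m = int(np.ceil((spec.n_free + occupied.shape[0]) ** (1 / 3))) + 2
        candidates = [(i + 0.21) * L / m for i in range(m)]
        for x in candidates:
            for y in candidates:
                for z in candidates:
                    p = np.array([x, y, z])
                    if occupied.size:
                        d = occupied - p
                        d -= L * np.rint(d / L)
                        if np.min(np.linalg.norm(d, axis=1)) < spec.margin:
                            continue
                    if free_pts:
                        d = np.array(free_pts) - p
                        d -= L * np.rint(d / L)
                        if np.min(np.linalg.norm(d, axis=1)) < spec.margin:
                            continue
                    free_pts.append(p)
                    if len(free_pts) == spec.n_free:
                        break
                if len(free_pts) == spec.n_free:
                    break
            if len(free_pts) == spec.n_free:
                break
        if len(free_pts) < spec.n_free:
            raise ValueError("overcrowded spec: could not place free monomers "
                             "with the requested margin")

    all_pts = np.concatenate(placed_pts + [np.array(free_pts).reshape(-1, 3)]) \
        if (placed_pts or free_pts) else np.empty((0, 3))
    n = all_pts.shape[0]
    frames = np.repeat((all_pts % L)[None, :, :], spec.n_frames, axis=0)
    return Trajectory(frames=frames.astype(np.float32),
                      temperatures=np.ones(spec.n_frames),
                      L=L, dt=0.01, stride=1000,
                      types=np.zeros(n, dtype=np.int64),
                      mol_id=np.arange(n, dtype=np.int64),
                      bead_names=("C2",),
                      mol_names=tuple("planted" for _ in range(n)),
                      seed=spec.seed)


def make_small_sim_config(family: str, tail_carbons: int, box: float = 12.0,
                          steps: int = 200_000, seed: int = 2021,
                          wt_percent: float = 5.0) -> SimConfig:
    """Scaled-down self-assembly protocol: bead density 3, dt 0.01,
    trajectory stride 1000, the requested surfactant at ``wt_percent``."""
    name = f"{family}{tail_carbons}"
    return SimConfig(L=box, steps=steps, seed=seed, rho=3.0, dt=0.01,
                     stride=1000, composition={name: f"{wt_percent}%"})


def build_small_system(family: str, tail_carbons: int, box: float = 12.0,
                       steps: int = 200_000, seed: int = 2021,
                       wt_percent: float = 5.0,
                       library: BeadLibraryFile | None = None
                       ) -> tuple[BeadLibraryFile, ParamSet, SimConfig]:
    """Library, parameter set and config for one scaled-down surfactant run."""
    lib = library or default_library()
    mol = build_surfactant(family, tail_carbons, lib)
    params = build_paramset(lib, [mol])
    cfg = make_small_sim_config(family, tail_carbons, box, steps, seed, wt_percent)
    return lib, params, cfg


def save_sim_config(cfg: SimConfig, path) -> None:
    doc = {"L": cfg.L, "steps": cfg.steps, "seed": cfg.seed, "rho": cfg.rho,
           "dt": cfg.dt, "stride": cfg.stride, "gamma": cfg.gamma,
           "sigma": cfg.sigma, "composition": dict(cfg.composition),
           "units": {"r_c_angstrom": cfg.units.r_c_angstrom,
                     "waters_per_bead": cfg.units.waters_per_bead}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    units = UnitMap(**doc.pop("units", {}))
    return SimConfig(units=units, **doc)
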