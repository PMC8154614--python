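"""Trajectory post-processing: aggregates, CMC, N_agg and shape.

Aggregates are detected per frame by single-linkage clustering of
surfactant molecules through their hydrophobic tail beads (two molecules
are connected when any pair of their tail beads lies within a cutoff
under minimum-image distances); monomers count as aggregates of size 1.
From the pooled aggregate-size histogram P(N) a threshold ``N_cut``
separating premicelles from stable micelles is read off at the deepest
local minimum (or the first empty gap) between the monomer and micelle
populations.  The critical micelle concentration is the time-averaged
concentration of surfactant molecules in sub-``N_cut`` aggregates, the
mean aggregation number is the weight average sum(N^2)/sum(N) over
micelles, and micelle shape is classified from the ordered semi-axes
(A >= B >= C) of each aggregate's gyration tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .engine import Trajectory
from .units import UnitMap

__all__ = ["Aggregate", "AggregateFrame", "AggregateReport", "cluster_frame",
           "find_ncut", "NO_MICELLES", "cmc", "n_agg", "shape_descriptor",
           "classify_shapes", "analyze", "SHAPE_CLASSES"]

#: sentinel returned by find_ncut / n_agg when no micelle population exists
NO_MICELLES = -1

SHAPE_CLASSES = ("sphere", "prolate", "oblate", "irregular")


@dataclass
class Aggregate:
    molecules: np.ndarray        # molecule ids
    size: int
    center: np.ndarray           # unwrapped center of the member tail beads
    semi_axes: tuple[float, float, float] | None = None  # A >= B >= C
    degenerate: bool = False


@dataclass
class AggregateFrame:
    index: int
    aggregates: list[Aggregate]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([a.size for a in self.aggregates], dtype=int)


@dataclass
class AggregateReport:
    """Summary of a micellization trajectory."""

    histogram: dict[int, int]            # pooled P(N)
    n_cut: int
    cmc_mM: float
    cmc_std_mM: float
    cmc_series_mM: np.ndarray
    n_agg_mean: float
    n_agg_range: tuple[float, float]
    shape_fractions: dict[str, float]
    shape_histogram: np.ndarray          # 2D counts over (A/B, B/C)
    shape_bin_edges: np.ndarray
    equilibration_frame: int = 0
    extras: dict = field(default_factory=dict)


def _unwrap_about(pos: np.ndarray, ref: np.ndarray, L: float) -> np.ndarray:
    return ref + ((pos - ref + 0.5 * L) % L) - 0.5 * L


def cluster_frame(positions: np.ndarray, mol_id: np.ndarray,
                  hydrophobic: np.ndarray, L: float,
                  surfactant_mols: np.ndarray, cutoff: float = 1.0,
                  frame_index: int = 0) -> AggregateFrame:
    """Partition surfactant molecules of one frame into aggregates.

    ``positions`` are wrapped coordinates of *all* beads; ``hydrophobic``
    is a boolean mask of tail beads; ``surfactant_mols`` lists the
    molecule ids subject to clustering.  Connectivity: any tail-bead pair
    of two molecules within ``cutoff`` (minimum image).
    """
    surfactant_mols = np.asarray(surfactant_mols)
    if surfactant_mols.size == 0:
        return AggregateFrame(frame_index, [])
    sel = hydrophobic & np.isin(mol_id, surfactant_mols)
    if not np.any(sel):
        raise ValueError("no hydrophobic beads on the surfactant molecules; "
                         "tail annotation missing")
    idx = np.flatnonzero(sel)
    pts = positions[idx] % L
    tree = cKDTree(pts, boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    mols = mol_id[idx]
    uniq = np.unique(mols)
    mol_index = {m: k for k, m in enumerate(uniq)}
    rows = np.array([mol_index[m] for m in mols[pairs[:, 0]]], dtype=int) \
        if pairs.size else np.empty(0, int)
    cols = np.array([mol_index[m] for m in mols[pairs[:, 1]]], dtype=int) \
        if pairs.size else np.empty(0, int)
    nmol = uniq.size
    adj = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(nmol, nmol))
    ncomp, labels = sparse.csgraph.connected_components(adj, directed=False)

    # isolated surfactants whose tails had no neighbours still form size-1
    # aggregates; molecules without any tail bead cannot occur (checked above)
    aggregates = []
    for comp in range(ncomp):
        members = uniq[labels == comp]
        bead_sel = np.isin(mols, members)
        bead_pos = pts[bead_sel]
        ref = bead_pos[0]
        unwrapped = _unwrap_about(bead_pos, ref, L)
        center = unwrapped.mean(axis=0)
        aggregates.append(Aggregate(molecules=members, size=members.size,
                                    center=center))
    missing = np.setdiff1d(surfactant_mols, uniq)
    for m in missing:
        aggregates.append(Aggregate(molecules=np.array([m]), size=1,
                                    center=np.zeros(3)))
    return AggregateFrame(frame_index, aggregates)


def find_ncut(histogram: dict[int, int] | np.ndarray) -> int:
    """Aggregate-size threshold between premicelles and micelles.

    Works on a pooled P(N) histogram.  If an empty gap separates the
    small-aggregate population from the micelle population the midpoint of
    the first such gap is returned; otherwise the smallest N at the deepest
    local minimum between the monomer mode and the micelle mode.  Returns
    :data:`NO_MICELLES` when the distribution has no second population.
    """
    if isinstance(histogram, dict):
        if not histogram:
            raise ValueError("empty histogram")
        nmax = max(histogram)
        counts = np.zeros(nmax + 1)
        for n, c in histogram.items():
            counts[n] = c
    else:
        counts = np.asarray(histogram, dtype=float)
    sizes = np.flatnonzero(counts)
    if sizes.size == 0:
        raise ValueError("empty histogram")
    # gap route: first run of empty bins separating two populated regions,
    # provided the upper population looks micellar (extends beyond the gap)
    gaps = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        if b - a > 1:
            gaps.append((a, b))
    if gaps:
        a, b = gaps[0]
        return int((a + b) // 2)
    # minimum route: deepest interior local minimum
    if sizes.size < 3:
        return NO_MICELLES
    lo, hi = sizes[0], sizes[-1]
    interior = counts[lo:hi + 1]
    n_vals = np.arange(lo, hi + 1)
    best = None
    for k in range(1, len(interior) - 1):
        left_max = interior[:k].max()
        right_max = interior[k + 1:].max()
        if interior[k] < left_max and interior[k] < right_max:
            depth = min(left_max, right_max) - interior[k]
            if best is None or depth > best[0]:
                best = (depth, n_vals[k])
    if best is None:
        return NO_MICELLES
    return int(best[1])


def cmc(frames: list[AggregateFrame], n_cut: int, L: float,
        units: UnitMap | None = None, equilibration: int = 0
        ) -> tuple[float, float, np.ndarray]:
    """Critical micelle concentration (mM) and its frame-to-frame spread.

    Counts, per post-equilibration frame, the surfactant molecules living
    in aggregates of size < ``n_cut`` (monomers included) and converts to
    molarity via the box volume.  Returns (mean, std, per-frame series).
    """
    units = units or UnitMap()
    post = [f for f in frames if f.index >= equilibration]
    if not post:
        raise ValueError("no frames after the equilibration cutoff")
    series = []
    for fr in post:
        free = sum(a.size for a in fr.aggregates
                   if n_cut == NO_MICELLES or a.size < n_cut)
        series.append(units.counts_to_mM(free, L))
    series = np.array(series)
    return float(series.mean()), float(series.std()), series


def n_agg(frames: list[AggregateFrame], n_cut: int, equilibration: int = 0
          ) -> tuple[float, tuple[float, float]]:
    """Weight-average micelle size, time mean and observed (min, max) range.

    Per frame: sum(N_i^2) / sum(N_i) over aggregates with N > n_cut.
    Returns (:data:`NO_MICELLES`, (nan, nan)) when no frame has a micelle.
    """
    per_frame = []
    for fr in frames:
        if fr.index < equilibration:
            continue
        sizes = fr.sizes
        mic = sizes[sizes > n_cut] if n_cut != NO_MICELLES else np.empty(0)
        if mic.size:
            per_frame.append(float((mic ** 2).sum() / mic.sum()))
    if not per_frame:
        return float(NO_MICELLES), (float("nan"), float("nan"))
    arr = np.array(per_frame)
    return float(arr.mean()), (float(arr.min()), float(arr.max()))


def shape_descriptor(positions: np.ndarray, L: float | None = None
                     ) -> tuple[float, float, float]:
    """Ordered spheroid semi-axes (A >= B >= C) of one aggregate.

    Positions are unwrapped about the first member when a box edge is
    given.  The gyration tensor's eigenvalues l1 >= l2 >= l3 map onto the
    semi-axes of the uniform ellipsoid with the same second moments,
    (A, B, C) = sqrt(5 l).  The ratios A/B and B/C are independent of that
    convention.  Nearly degenerate aggregates get C floored at 1e-6.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("shape needs at least two beads")
    if L is not None:
        pts = _unwrap_about(pts, pts[0], L)
    centered = pts - pts.mean(axis=0)
    gyr = centered.T @ centered / pts.shape[0]
    eig = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    eig = np.clip(eig, 0.0, None)
    A, B, C = np.sqrt(5.0 * eig)
    return float(A), float(max(B, 1e-6)), float(max(C, 1e-6))


def classify_shapes(semi_axes: list[tuple[float, float, float]],
                    threshold: float = 1.5, bins: int = 20,
                    ratio_max: float = 5.0
                    ) -> tuple[dict[str, float], np.ndarray, np.ndarray]:
    """Class fractions and 2D histogram over the (A/B, B/C) plane.

    sphere: both ratios below ``threshold``; prolate: elongated only
    (A/B above); oblate: flattened only (B/C above); irregular: both.
    """
    if not semi_axes:
        return ({c: 0.0 for c in SHAPE_CLASSES}, np.zeros((bins, bins)),
                np.linspace(1.0, ratio_max, bins + 1))
    ab = np.array([a / b for a, b, c in semi_axes])
    bc = np.array([b / c for a, b, c in semi_axes])
    edges = np.linspace(1.0, ratio_max, bins + 1)
    hist, _, _ = np.histogram2d(np.clip(ab, 1, ratio_max - 1e-9),
                                np.clip(bc, 1, ratio_max - 1e-9),
                                bins=[edges, edges])
    elongated = ab >= threshold
    flattened = bc >= threshold
    n = ab.size
    fractions = {
        "sphere": float(np.sum(~elongated & ~flattened)) / n,
        "prolate": float(np.sum(elongated & ~flattened)) / n,
        "oblate": float(np.sum(~elongated & flattened)) / n,
        "irregular": float(np.sum(elongated & flattened)) / n,
    }
    return fractions, hist, edges


def analyze(traj: Trajectory, cutoff: float = 1.0, equilibration: int = 0,
            units: UnitMap | None = None, n_cut: int | None = None
            ) -> AggregateReport:
    """Full pipeline on a trajectory: cluster every frame, pool P(N),
    locate ``N_cut``, then compute CMC, N_agg and shape statistics."""
    units = units or UnitMap()
    surf = np.unique(traj.mol_id[traj.hydrophobic_mask])
    frames: list[AggregateFrame] = []
    shapes: list[tuple[float, float, float]] = []
    hydro = traj.hydrophobic_mask
    for f in range(traj.n_frames):
        frames.append(cluster_frame(traj.frames[f].astype(float), traj.mol_id,
                                    hydro, traj.L, surf, cutoff, frame_index=f))
    histogram: dict[int, int] = {}
    for fr in frames:
        if fr.index < equilibration:
            continue
        for a in fr.aggregates:
            histogram[a.size] = histogram.get(a.size, 0) + 1
    ncut_val = find_ncut(histogram) if n_cut is None else n_cut
    mean_cmc, std_cmc, series = cmc(frames, ncut_val, traj.L, units,
                                    equilibration)
    nagg_mean, nagg_range = n_agg(frames, ncut_val, equilibration)
    # shapes of micellar aggregates (all surfactant beads of each micelle)
    surf_sel_global = np.isin(traj.mol_id, surf)
    for fr in frames:
        if fr.index < equilibration:
            continue
        pos = traj.frames[fr.index].astype(float)
        for a in fr.aggregates:
            if ncut_val != NO_MICELLES and a.size > ncut_val:
                sel = surf_sel_global & np.isin(traj.mol_id, a.molecules)
                shapes.append(shape_descriptor(pos[sel], traj.L))
    fractions, hist2d, edges = classify_shapes(shapes)
    return AggregateReport(histogram=dict(sorted(histogram.items())),
                           n_cut=ncut_val, cmc_mM=mean_cmc,
                           cmc_std_mM=std_cmc, cmc_series_mM=series,
                           n_agg_mean=nagg_mean, n_agg_range=nagg_range,
                           shape_fractions=fractions, shape_histogram=hist2d,
                           shape_bin_edges=edges,
                           equilibration_frame=equilibration)
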