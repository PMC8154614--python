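"""Bead library: coarse-grained bead types, SSIP descriptions and molecule topologies.

A *bead* is a molecular fragment treated as a single DPD particle.  Its
nonbonded chemistry is carried by a multiset of surface site interaction
points (SSIPs), each a scalar polarity ``epsilon`` (positive values are
hydrogen-bond-donor-like sites, negative values acceptor-like), together
with the fragment's van der Waals volume and the molar concentration of
the pure reference liquid used to represent a phase of that bead.  The
self-repulsion ``a_self`` (kBT) and self contact radius ``R_self`` (r_c)
complete the data needed to build pairwise simulation parameters.

The packaged library ships the 14 bead types used for ester, amide and
sugar surfactants, and :func:`build_surfactant` assembles the packaged
coarse-grained topologies for the supported surfactant families.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SSIP",
    "BeadType",
    "Bond",
    "Angle",
    "MoleculeTopology",
    "BeadLibraryFile",
    "LibraryParseError",
    "LibraryValidationError",
    "load_bead_library",
    "save_bead_library",
    "default_library",
    "load_table",
    "load_bond_table",
    "build_surfactant",
    "FAMILIES",
]

SCHEMA_VERSION = 1

#: canonical bead order used by all packaged pairwise tables
BEAD_ORDER = ("W", "OH1", "OH'", "OH2", "ES", "EO", "AC'", "C2", "C2'",
              "T1", "T2", "AM2", "AM3'", "AM3")

#: bead names regarded as hydrophobic (alkyl-tail fragments) by the
#: clustering analysis
HYDROPHOBIC_BEADS = frozenset({"C2", "C2'", "T1", "T2"})


class LibraryParseError(ValueError):
    """Raised when a library/topology file cannot be parsed."""


class LibraryValidationError(ValueError):
    """Raised when a parsed library violates an invariant."""


def _canonical_ssip_order(epsilons: Iterable[float]) -> tuple[float, ...]:
    # descending |epsilon|; ties broken donor-before-acceptor
    return tuple(sorted((float(e) for e in epsilons), key=lambda e: (-abs(e), -e)))


@dataclass(frozen=True)
class SSIP:
    """A single surface site interaction point.

    ``epsilon`` is the site polarity on the (kJ/mol)^(1/2) scale; the sign
    encodes hydrogen-bond donor (+) versus acceptor (-) character.
    """

    epsilon: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.epsilon):
            raise LibraryValidationError("SSIP epsilon must be finite")


@dataclass(frozen=True)
class BeadType:
    """A coarse-grained fragment with its SSIP description and DPD self terms."""

    name: str
    ssips: tuple[SSIP, ...]
    volume: float          # van der Waals volume, A^3
    liquid_conc: float     # molar concentration of the pure bead liquid, M
    a_self: float          # self repulsion a_ii, kBT
    R_self: float          # self contact radius R_ii, r_c

    def __post_init__(self) -> None:
        for label, value in (("volume", self.volume),
                             ("liquid_conc", self.liquid_conc),
                             ("a_self", self.a_self),
                             ("R_self", self.R_self)):
            if not (np.isfinite(value) and value > 0):
                raise LibraryValidationError(
                    f"bead {self.name!r}: {label} must be positive, got {value!r}")
        canon = _canonical_ssip_order(s.epsilon for s in self.ssips)
        object.__setattr__(self, "ssips", tuple(SSIP(e) for e in canon))

    @property
    def epsilons(self) -> np.ndarray:
        """SSIP polarities in canonical (descending |epsilon|) order."""
        return np.array([s.epsilon for s in self.ssips], dtype=float)


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    r_target: float  # desired simulated bond length, r_c


@dataclass(frozen=True)
class Angle:
    i: int
    j: int
    k: int
    theta0: float    # equilibrium angle, degrees


@dataclass(frozen=True)
class MoleculeTopology:
    """Bead sequence, bonds and 1-3 angles of one coarse-grained molecule."""

    name: str
    beads: tuple[str, ...]
    bonds: tuple[Bond, ...]
    angles: tuple[Angle, ...] = ()
    molar_mass: float = 0.0  # g/mol, used for wt% compositions

    def __post_init__(self) -> None:
        n = len(self.beads)
        if n == 0:
            raise LibraryValidationError(f"molecule {self.name!r}: empty bead list")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n and b.i != b.j):
                raise LibraryValidationError(
                    f"molecule {self.name!r}: bond ({b.i},{b.j}) out of range")
            if not b.r_target > 0:
                raise LibraryValidationError(
                    f"molecule {self.name!r}: bond r_target must be > 0")
        for a in self.angles:
            idx = (a.i, a.j, a.k)
            if len(set(idx)) != 3 or not all(0 <= x < n for x in idx):
                raise LibraryValidationError(
                    f"molecule {self.name!r}: angle {idx} invalid")
            if not 0 < a.theta0 <= 180:
                raise LibraryValidationError(
                    f"molecule {self.name!r}: theta0 must be in (0, 180]")
        if n > 1:
            # bond graph must be connected (union-find)
            parent = list(range(n))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for b in self.bonds:
                parent[find(b.i)] = find(b.j)
            if len({find(i) for i in range(n)}) != 1:
                raise LibraryValidationError(
                    f"molecule {self.name!r}: bond graph is not connected")

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class BeadLibraryFile:
    """A validated library document: bead types plus molecule topologies."""

    beads: dict[str, BeadType]
    molecules: list[MoleculeTopology] = field(default_factory=list)
    schema: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not self.beads:
            raise LibraryValidationError("library has no beads")
        for mol in self.molecules:
            self._check_molecule(mol)

    def _check_molecule(self, mol: MoleculeTopology) -> None:
        unknown = set(mol.beads) - set(self.beads)
        if unknown:
            raise LibraryValidationError(
                f"molecule {mol.name!r} references unknown beads {sorted(unknown)}")

    def bead(self, name: str) -> BeadType:
        try:
            return self.beads[name]
        except KeyError:
            raise LibraryValidationError(f"unknown bead {name!r}") from None

    def add_molecule(self, mol: MoleculeTopology) -> None:
        self._check_molecule(mol)
        self.molecules.append(mol)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": self.schema,
            "beads": [
                {
                    "name": b.name,
                    "volume": b.volume,
                    "ssips": [s.epsilon for s in b.ssips],
                    "a_self": b.a_self,
                    "R_self": b.R_self,
                    "liquid_conc": b.liquid_conc,
                }
                for b in self.beads.values()
            ],
            "molecules": [_molecule_to_dict(m) for m in self.molecules],
        }

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _molecule_to_dict(mol: MoleculeTopology) -> dict:
    return {
        "name": mol.name,
        "beads": list(mol.beads),
        "bonds": [[b.i, b.j, b.r_target] for b in mol.bonds],
        "angles": [[a.i, a.j, a.k, a.theta0] for a in mol.angles],
        "molar_mass": mol.molar_mass,
    }


def _molecule_from_dict(doc: Mapping) -> MoleculeTopology:
    allowed = {"name", "beads", "bonds", "angles", "molar_mass"}
    unknown = set(doc) - allowed
    if unknown:
        raise LibraryParseError(f"molecule document has unknown fields {sorted(unknown)}")
    return MoleculeTopology(
        name=str(doc["name"]),
        beads=tuple(doc["beads"]),
        bonds=tuple(Bond(int(i), int(j), float(r)) for i, j, r in doc.get("bonds", [])),
        angles=tuple(Angle(int(i), int(j), int(k), float(t))
                     for i, j, k, t in doc.get("angles", [])),
        molar_mass=float(doc.get("molar_mass", 0.0)),
    )


_BEAD_FIELDS = {"name", "volume", "ssips", "a_self", "R_self", "liquid_conc",
                "conc_provenance"}


def _library_from_dict(doc: Mapping) -> BeadLibraryFile:
    if not isinstance(doc, Mapping):
        raise LibraryParseError("library document must be a mapping")
    unknown = set(doc) - {"schema", "beads", "molecules"}
    if unknown:
        raise LibraryParseError(f"library document has unknown fields {sorted(unknown)}")
    schema = int(doc.get("schema", -1))
    if schema != SCHEMA_VERSION:
        raise LibraryParseError(
            f"unsupported schema version {schema} (supported: {SCHEMA_VERSION})")
    beads: dict[str, BeadType] = {}
    for entry in doc.get("beads") or []:
        bad = set(entry) - _BEAD_FIELDS
        if bad:
            raise LibraryParseError(
                f"bead document has unknown fields {sorted(bad)}")
        bead = BeadType(
            name=str(entry["name"]),
            ssips=tuple(SSIP(float(e)) for e in entry["ssips"]),
            volume=float(entry["volume"]),
            liquid_conc=float(entry["liquid_conc"]),
            a_self=float(entry["a_self"]),
            R_self=float(entry["R_self"]),
        )
        if bead.name in beads:
            raise LibraryValidationError(f"duplicate bead name {bead.name!r}")
        beads[bead.name] = bead
    molecules = [_molecule_from_dict(m) for m in doc.get("molecules") or []]
    return BeadLibraryFile(beads=beads, molecules=molecules, schema=schema)


def load_bead_library(path: str | Path) -> BeadLibraryFile:
    """Load and validate a bead-library file (YAML).

    Raises :class:`LibraryParseError` (naming the offending line where the
    YAML parser provides one) or :class:`LibraryValidationError`.
    """
    text = Path(path).read_text(encoding="utf-8")
    return _loads(text)


def _loads(text: str) -> BeadLibraryFile:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise LibraryParseError(f"malformed library file{where}: {exc}") from exc
    return _library_from_dict(doc)


def save_bead_library(library: BeadLibraryFile, path: str | Path) -> None:
    Path(path).write_text(library.dumps(), encoding="utf-8")


def _data_text(name: str) -> str:
    return (importlib.resources.files("dpdchem.data") / name).read_text(encoding="utf-8")


def default_library() -> BeadLibraryFile:
    """The packaged 14-bead library."""
    return _loads(_data_text("bead_library.yaml"))


def load_table(which: str) -> pd.DataFrame:
    """Packaged pairwise table: ``"R"`` (contact radii, r_c), ``"a"``
    (repulsions, kBT) or ``"delta_a"`` (mismatch terms, kBT)."""
    fname = {"R": "contact_radius_Rij.csv",
             "a": "repulsion_aij.csv",
             "delta_a": "repulsion_delta_aij.csv"}[which]
    return pd.read_csv(StringIO(_data_text(fname)), index_col=0)


def load_bond_table() -> pd.DataFrame:
    """Packaged per-family bond parameters (r_target and calibrated r0)."""
    return pd.read_csv(StringIO(_data_text("bond_parameters.csv")))


# ---------------------------------------------------------------------------
# surfactant topology builder
# ---------------------------------------------------------------------------

# Head-group definitions.  ``beads`` lists the head bead sequence, ``bonds``
# are (i, j) pairs within the head whose r_target comes from the packaged
# bond table or from the chain defaults below, ``attach`` is the index of the
# bead the alkyl tail connects to, ``absorbed`` is the number of acyl-chain
# carbons already contained in the head bead (carbonyl + alpha carbon for
# ester/amide linkers), and ``head_mass`` is the molar mass of the parent
# polar fragment before condensation with the fatty acid / fatty alcohol.
FAMILIES: dict[str, dict] = {
    # ester surfactants
    "GLY":   {"beads": ["ES", "OH'", "OH'"],
              "bonds": [(0, 1), (1, 2)], "attach": 0, "absorbed": 2,
              "head_mass": 92.094, "linkage": "acid"},
    "XYL":   {"beads": ["ES", "OH'", "OH'", "OH'", "OH'"],
              "bonds": [(0, 1), (1, 2), (2, 3), (3, 4)], "attach": 0,
              "absorbed": 2, "head_mass": 152.146, "linkage": "acid"},
    # amide surfactants
    "MEA":   {"beads": ["OH1", "AM2"],
              "bonds": [(1, 0)], "attach": 1, "absorbed": 2,
              "head_mass": 61.083, "linkage": "acid"},
    "DEA":   {"beads": ["OH1", "AM3'", "OH1"],
              "bonds": [(1, 0), (1, 2)], "attach": 1, "absorbed": 2,
              "head_mass": 105.136, "linkage": "acid"},
    "TEDA":  {"beads": ["AM2", "EO", "EO", "EO", "OH2"],
              "bonds": [(0, 1), (1, 2), (2, 3), (3, 4)], "attach": 0,
              "absorbed": 2, "head_mass": 149.188, "linkage": "acid"},
    "MEGA":  {"beads": ["AM3", "OH'", "OH'", "OH'", "OH'", "OH'"],
              "bonds": [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)], "attach": 0,
              "absorbed": 2, "head_mass": 195.215, "linkage": "acid"},
    "HEGA":  {"beads": ["OH1", "AM3'", "OH'", "OH'", "OH'", "OH'", "OH'"],
              "bonds": [(1, 0), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6)],
              "attach": 1, "absorbed": 2, "head_mass": 225.241,
              "linkage": "acid"},
    # sugar surfactants
    "GLUCO": {"beads": ["AC'", "OH'", "OH'", "OH'", "OH'"],
              "bonds": [(0, 1), (1, 2), (2, 3), (3, 4)], "attach": 0,
              "absorbed": 0, "head_mass": 180.156, "linkage": "alcohol"},
    "MALTO": {"beads": ["AC'", "OH'", "OH'", "OH'",
                        "AC'", "OH'", "OH'", "OH'", "OH'"],
              "bonds": [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6),
                        (6, 7), (7, 8)],
              "attach": 0, "absorbed": 0, "head_mass": 342.297,
              "linkage": "alcohol"},
    "CYGLU": {"beads": ["AC'", "OH'", "OH'", "OH'", "OH'"],
              "bonds": [(0, 1), (1, 2), (2, 3), (3, 4)], "attach": 0,
              "absorbed": 0, "head_mass": 180.156, "linkage": "cyclo"},
    "CYMAL": {"beads": ["AC'", "OH'", "OH'", "OH'",
                        "AC'", "OH'", "OH'", "OH'", "OH'"],
              "bonds": [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6),
                        (6, 7), (7, 8)],
              "attach": 0, "absorbed": 0, "head_mass": 342.297,
              "linkage": "cyclo"},
}

#: bond-length targets (r_c) used when a pair is not listed in the packaged
#: bond table: alkyl-chain bonds use the ethylene-ethylene equilibrium
#: distance, polyol chains the ethylene-glycol value, everything else a
#: generic two-heavy-atom spacing.
TAIL_BOND_R_TARGET = 0.445
_CHAIN_DEFAULTS = {
    frozenset({"OH'", "OH'"}): 0.45,
    frozenset({"EO", "EO"}): 0.60,
    frozenset({"EO", "OH2"}): 0.60,
    frozenset({"AC'", "OH'"}): 0.55,
    frozenset({"AC'", "AC'"}): 0.60,
}
_GENERIC_R_TARGET = 0.60

_M_CH2 = 14.027
_M_H2O = 18.015


def _variable_mass(linkage: str, n: int) -> float:
    if linkage == "acid":        # condensation with CnH2nO2 fatty acid
        return _M_CH2 * n + 31.998 - _M_H2O
    if linkage == "alcohol":     # condensation with CnH2n+2O fatty alcohol
        return _M_CH2 * n + _M_H2O - _M_H2O
    if linkage == "cyclo":       # cyclohexyl-alkyl alcohol, C(n+6)H(2n+12)O
        return _M_CH2 * (n + 6) + 15.999 - _M_H2O
    raise ValueError(linkage)


def _bond_r_target(family: str, bead_i: str, bead_j: str,
                   bond_table: pd.DataFrame) -> float:
    rows = bond_table[(bond_table["family"] == family)]
    for _, row in rows.iterrows():
        if {row["bead_i"], row["bead_j"]} == {bead_i, bead_j}:
            return float(row["r_target"])
    if {bead_i, bead_j} <= HYDROPHOBIC_BEADS:
        return TAIL_BOND_R_TARGET
    return _CHAIN_DEFAULTS.get(frozenset({bead_i, bead_j}), _GENERIC_R_TARGET)


def build_surfactant(family: str, tail_carbons: int,
                     library: BeadLibraryFile | None = None) -> MoleculeTopology:
    """Assemble the packaged coarse-grained topology for one surfactant.

    ``family`` selects the head group (see :data:`FAMILIES`); ``tail_carbons``
    is the carbon count of the hydrophobic chain (the Cn label of the
    surfactant).  Even chain lengths from 4 to 12 are supported: the tail is
    built from C2 beads with a terminal T2 bead, ester/amide heads absorbing
    the carbonyl and alpha carbons.  The CYGLU/CYMAL families append a
    cyclohexyl terminus of three C2' beads to the alkyl linker.  Bond targets
    come from the packaged bond table where published, otherwise from the
    documented chain defaults; chain angles through the head-tail junction
    and along the tail use theta0 = 180 degrees (trans-amide representation).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown surfactant family {family!r}; "
                         f"known: {sorted(FAMILIES)}")
    fam = FAMILIES[family]
    n_eff = tail_carbons - fam["absorbed"]
    if fam["linkage"] == "cyclo":
        if not (2 <= tail_carbons <= 8 and tail_carbons % 2 == 0):
            raise ValueError(
                f"{family}: supported alkyl linkers are even C2-C8, got C{tail_carbons}")
        tail_beads = ["C2"] * (tail_carbons // 2) + ["C2'"] * 3
    else:
        if not (2 <= n_eff <= 12 and n_eff % 2 == 0):
            raise ValueError(
                f"{family}: supported tails are even C{fam['absorbed'] + 2}-"
                f"C{fam['absorbed'] + 12}, got C{tail_carbons}")
        tail_beads = ["C2"] * (n_eff // 2 - 1) + ["T2"]

    bond_table = load_bond_table()
    head_beads = list(fam["beads"])
    beads = head_beads + tail_beads
    bonds: list[Bond] = []
    for i, j in fam["bonds"]:
        bonds.append(Bond(i, j, _bond_r_target(family, beads[i], beads[j], bond_table)))
    # chain the tail onto the attachment bead
    prev = fam["attach"]
    for k in range(len(tail_beads)):
        idx = len(head_beads) + k
        bonds.append(Bond(prev, idx, _bond_r_target(family, beads[prev], beads[idx],
                                                    bond_table)))
        prev = idx

    # 1-3 angles along the main chain: head neighbour -> attach -> tail...
    chain = [fam["attach"]] + list(range(len(head_beads), len(beads)))
    head_neighbour = next((j for i, j in fam["bonds"] if i == fam["attach"]),
                          next((i for i, j in fam["bonds"] if j == fam["attach"]), None))
    if head_neighbour is not None:
        chain = [head_neighbour] + chain
    angles = tuple(Angle(chain[k], chain[k + 1], chain[k + 2], 180.0)
                   for k in range(len(chain) - 2))

    mol = MoleculeTopology(
        name=f"{family}{tail_carbons}",
        beads=tuple(beads),
        bonds=tuple(bonds),
        angles=angles,
        molar_mass=round(fam["head_mass"] + _variable_mass(fam["linkage"], tail_carbons), 2),
    )
    if library is not None:
        unknown = set(mol.beads) - set(library.beads)
        if unknown:
            raise LibraryValidationError(
                f"{mol.name}: beads {sorted(unknown)} missing from library")
    return mol
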