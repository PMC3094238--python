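"""Core domain types for pair-wise force distribution analysis.

The central object is the sparse pair-wise force matrix: for one time point
(or one averaging interval) it maps an atom pair ``(i, j)`` with ``i < j``
and an interaction type to a signed scalar force in kJ·mol⁻¹·nm⁻¹.

Sign convention (used everywhere in this package): **positive = repulsive**,
i.e. a positive pair force pushes the two atoms apart; a negative force is
attractive.  Storing signed scalar norms instead of force vectors makes the
values averageable over a trajectory despite global rotation/translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "InteractionType",
    "Atom",
    "Bond",
    "Angle",
    "Dihedral",
    "Topology",
    "TrajectoryFrame",
    "ForceTrajectoryHeader",
    "PairwiseForceMatrix",
    "ForceTrajectory",
    "PairKey",
    "TopologyError",
    "TrajectoryError",
    "ForceFormatError",
]


class TopologyError(ValueError):
    """Raised when a topology file cannot be parsed or violates an invariant."""


class TrajectoryError(ValueError):
    """Raised when a coordinate trajectory cannot be read or is inconsistent."""


class ForceFormatError(ValueError):
    """Raised on malformed binary/ASCII force-trajectory data."""


class InteractionType(IntEnum):
    """Codes identifying which potential produced a pair force.

    ``COMBINED`` marks entries where contributions of several types have been
    summed (it never appears in engine output or on disk).
    """

    COMBINED = 0
    BOND = 1
    ANGLE = 2
    DIHEDRAL = 3
    COULOMB = 4
    LJ = 5


#: key of one sparse entry: (i, j, interaction type) with i < j
PairKey = tuple[int, int, InteractionType]

_VALID_TYPE_CODES = {int(t) for t in InteractionType if t != InteractionType.COMBINED}


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    residue_index: int
    residue_name: str
    charge: float  # e
    sigma: float  # nm
    epsilon: float  # kJ/mol


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    b0: float  # nm
    kb: float  # kJ/mol/nm^2


@dataclass(frozen=True)
class Angle:
    i: int
    j: int
    k: int
    theta0: float  # rad
    ktheta: float  # kJ/mol/rad^2


@dataclass(frozen=True)
class Dihedral:
    i: int
    j: int
    k: int
    l: int
    kphi: float  # kJ/mol
    multiplicity: int
    phase: float  # rad


def _norm_pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class Topology:
    """Force-field side of the input: atoms, bonded terms and exclusions.

    Atom and residue indices are 0-based throughout; 1-based numbering only
    exists in PDB/GRO text and is converted at the file boundary.  Excluded
    pairs never receive non-bonded (Coulomb/LJ) evaluation.
    """

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    angles: list[Angle] = field(default_factory=list)
    dihedrals: list[Dihedral] = field(default_factory=list)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    #: True when exclusions were auto-generated (file had no [exclusions])
    exclusions_generated: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return self.atoms[-1].residue_index + 1 if self.atoms else 0

    def residue_of(self) -> np.ndarray:
        """0-based residue index per atom."""
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def bonded_exclusions(self) -> set[tuple[int, int]]:
        """All 1-2 and 1-3 pairs implied by the bond list."""
        neighbours: dict[int, set[int]] = {}
        excl: set[tuple[int, int]] = set()
        for b in self.bonds:
            neighbours.setdefault(b.i, set()).add(b.j)
            neighbours.setdefault(b.j, set()).add(b.i)
            excl.add(_norm_pair(b.i, b.j))
        for j, nbrs in neighbours.items():
            for i in nbrs:
                for k in nbrs:
                    if i < k:
                        excl.add((i, k))
        return excl

    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise TopologyError("topology has no atoms")
        for pos, a in enumerate(self.atoms):
            if a.index != pos:
                raise TopologyError(
                    f"atom indices must be 0..n-1 in order; got {a.index} at position {pos}"
                )
            if not a.sigma > 0:
                raise TopologyError(f"atom {a.index}: sigma must be > 0, got {a.sigma}")
            if a.epsilon < 0:
                raise TopologyError(f"atom {a.index}: epsilon must be >= 0, got {a.epsilon}")
        res = [a.residue_index for a in self.atoms]
        if any(b < a for a, b in zip(res, res[1:])):
            raise TopologyError("residue_index must be non-decreasing over atom_index")
        if res[0] < 0:
            raise TopologyError("residue_index must be >= 0")

        def _check_idx(term: str, *idx: int) -> None:
            for i in idx:
                if not 0 <= i < n:
                    raise TopologyError(f"{term} references atom {i} outside 0..{n - 1}")
            if len(set(idx)) != len(idx):
                raise TopologyError(f"{term} repeats an atom index: {idx}")

        for b in self.bonds:
            _check_idx("bond", b.i, b.j)
            if b.kb < 0:
                raise TopologyError(f"bond ({b.i},{b.j}): kb must be >= 0")
            if not b.b0 > 0:
                raise TopologyError(f"bond ({b.i},{b.j}): b0 must be > 0")
        for a in self.angles:
            _check_idx("angle", a.i, a.j, a.k)
            if a.ktheta < 0:
                raise TopologyError(f"angle ({a.i},{a.j},{a.k}): ktheta must be >= 0")
        for d in self.dihedrals:
            _check_idx("dihedral", d.i, d.j, d.k, d.l)
            if d.multiplicity < 1:
                raise TopologyError(
                    f"dihedral ({d.i},{d.j},{d.k},{d.l}): multiplicity must be >= 1"
                )
        for i, j in self.exclusions:
            _check_idx("exclusion", i, j)
            if i >= j:
                raise TopologyError(f"exclusion pair ({i},{j}) must satisfy i < j")
        missing = self.bonded_exclusions() - self.exclusions
        if missing:
            raise TopologyError(
                "exclusions must contain every 1-2 and 1-3 bonded pair; "
                f"missing {sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
            )


@dataclass
class TrajectoryFrame:
    """One coordinate frame: time in ps, (n_atoms, 3) coordinates in nm."""

    time: float
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError(
                f"coordinates must have shape (n_atoms, 3), got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("coordinates contain non-finite values")


MAGIC = b"FDA1"
FORMAT_VERSION = 1
SYNTAX_MODES = ("atom", "residue")


@dataclass(frozen=True)
class ForceTrajectoryHeader:
    n_atoms: int
    syntax_mode: str = "atom"
    format_version: int = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.n_atoms <= 0:
            raise ForceFormatError(f"n_atoms must be > 0, got {self.n_atoms}")
        if self.syntax_mode not in SYNTAX_MODES:
            raise ForceFormatError(f"syntax_mode must be one of {SYNTAX_MODES}")


@dataclass
class PairwiseForceMatrix:
    """Sparse signed pair forces for one frame or one averaging interval.

    ``entries`` maps ``(i, j, InteractionType)`` with ``i < j`` to a finite
    signed scalar (kJ·mol⁻¹·nm⁻¹, positive = repulsive).  Exact zeros are by
    convention not stored, which keeps interval averaging linear.
    """

    time: float
    entries: dict[PairKey, float] = field(default_factory=dict)

    def validate(self, n_atoms: int | None = None) -> None:
        for (i, j, t), f in self.entries.items():
            if not i < j:
                raise ForceFormatError(f"pair ({i},{j}) must satisfy i < j")
            if i < 0 or (n_atoms is not None and j >= n_atoms):
                raise ForceFormatError(f"pair ({i},{j}) out of range for n_atoms={n_atoms}")
            if int(t) not in _VALID_TYPE_CODES:
                raise ForceFormatError(f"invalid interaction type {t!r}")
            if not np.isfinite(f):
                raise ForceFormatError(f"non-finite force for pair ({i},{j})")

    def sorted_items(self) -> list[tuple[PairKey, float]]:
        return sorted(self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], int(kv[0][2])))

    def combined(self) -> dict[tuple[int, int], float]:
        """Signed sum over interaction types per pair."""
        out: dict[tuple[int, int], float] = {}
        for (i, j, _t), f in self.entries.items():
            out[(i, j)] = out.get((i, j), 0.0) + f
        return out

    def to_dense(self, n_atoms: int) -> np.ndarray:
        """Dense n×n export reproducing the classic triangle convention.

        Van der Waals (LJ) forces go to the upper triangle (column > row) and
        Coulomb forces to the lower triangle (row > column); bonded types are
        summed symmetrically into both triangles.
        """
        m = np.zeros((n_atoms, n_atoms))
        for (i, j, t), f in self.entries.items():
            if t == InteractionType.LJ:
                m[i, j] += f
            elif t == InteractionType.COULOMB:
                m[j, i] += f
            else:
                m[i, j] += f
                m[j, i] += f
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairwiseForceMatrix):
            return NotImplemented
        return self.time == other.time and self.entries == other.entries


@dataclass
class ForceTrajectory:
    """Time-ordered sequence of sparse pair-force blocks plus a header."""

    header: ForceTrajectoryHeader
    blocks: list[PairwiseForceMatrix] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.header.n_atoms

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[PairwiseForceMatrix]:
        return iter(self.blocks)

    def validate(self) -> None:
        for b in self.blocks:
            b.validate(self.header.n_atoms)
        times = [b.time for b in self.blocks]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ForceFormatError("blocks must be time-ordered")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ForceTrajectory):
            return NotImplemented
        return self.header == other.header and self.blocks == other.blocks


def pair_universe(trajs: Iterable[ForceTrajectory]) -> list[PairKey]:
    """Sorted union of entry keys across trajectories (absent = 0 by convention)."""
    keys: set[PairKey] = set()
    for tr in trajs:
        for b in tr.blocks:
            keys.update(b.entries)
    return sorted(keys, key=lambda k: (k[0], k[1], int(k[2])))
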