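"""File I/O: topologies, coordinate trajectories, force trajectories, PDB export.

Formats handled here
--------------------
* Topology: sectioned plain text (``[atoms]``, ``[bonds]``, ``[angles]``,
  ``[dihedrals]``, ``[exclusions]``), whitespace-separated fields, ``#``
  comments.  Missing ``[exclusions]`` are auto-generated from the bond graph
  (all 1-2 and 1-3 pairs) and flagged on the returned object.
* Coordinates: multi-model PDB (MODEL/ENDMDL, Å converted to nm) and GRO
  (nm), both read through :mod:`mdtraj`.  Frames missing a time stamp get
  the frame index in ps.
* Force trajectories: a little-endian sparse binary format (below) plus a
  full-precision ASCII dump.
* PDB b-factor export: per-atom scalars written into columns 61-66 of an
  existing PDB, all other bytes preserved verbatim.

Binary force-trajectory layout (little-endian)
----------------------------------------------
header : magic ``b"FDA1"``, u32 version=1, u32 n_atoms, u8 syntax_mode
         (0 = atom, 1 = residue)
block  : f64 time_ps, u32 n_entries, then n_entries × record
record : u64 packed pair index ``i·N + j`` (i < j), f64 force, u8 type code
"""

from __future__ import annotations

import os
import struct
import warnings
from typing import Iterable, Sequence

import numpy as np

from .core import (
    FORMAT_VERSION,
    MAGIC,
    SYNTAX_MODES,
    Angle,
    Atom,
    Bond,
    Dihedral,
    ForceFormatError,
    ForceTrajectory,
    ForceTrajectoryHeader,
    InteractionType,
    PairwiseForceMatrix,
    Topology,
    TopologyError,
    TrajectoryError,
    TrajectoryFrame,
)

__all__ = [
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_pdb_trajectory",
    "write_gro_trajectory",
    "write_force_trajectory",
    "read_force_trajectory",
    "dump_ascii",
    "parse_ascii",
    "write_pdb_bfactors",
]

_SECTIONS = ("atoms", "bonds", "angles", "dihedrals", "exclusions")


def read_topology(path: str | os.PathLike) -> Topology:
    """Parse and validate a topology file.

    If the file has no ``[exclusions]`` section, the 1-2 and 1-3 pairs implied
    by the bond list are generated automatically and
    ``Topology.exclusions_generated`` is set.
    """
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    angles: list[Angle] = []
    dihedrals: list[Dihedral] = []
    exclusions: set[tuple[int, int]] = set()
    seen_sections: set[str] = set()
    section: str | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip().lower()
                if section not in _SECTIONS:
                    raise TopologyError(f"{path}:{lineno}: unknown section [{section}]")
                seen_sections.add(section)
                continue
            if section is None:
                raise TopologyError(f"{path}:{lineno}: data before any [section] header")
            fields = line.split()
            try:
                if section == "atoms":
                    if len(fields) != 7:
                        raise ValueError("expected 7 fields: index name resid resname charge sigma epsilon")
                    atoms.append(
                        Atom(
                            index=int(fields[0]),
                            name=fields[1],
                            residue_index=int(fields[2]),
                            residue_name=fields[3],
                            charge=float(fields[4]),
                            sigma=float(fields[5]),
                            epsilon=float(fields[6]),
                        )
                    )
                elif section == "bonds":
                    if len(fields) != 4:
                        raise ValueError("expected 4 fields: i j b0 kb")
                    bonds.append(Bond(int(fields[0]), int(fields[1]), float(fields[2]), float(fields[3])))
                elif section == "angles":
                    if len(fields) != 5:
                        raise ValueError("expected 5 fields: i j k theta0 ktheta")
                    angles.append(
                        Angle(int(fields[0]), int(fields[1]), int(fields[2]), float(fields[3]), float(fields[4]))
                    )
                elif section == "dihedrals":
                    if len(fields) != 7:
                        raise ValueError("expected 7 fields: i j k l kphi multiplicity phase")
                    dihedrals.append(
                        Dihedral(
                            int(fields[0]),
                            int(fields[1]),
                            int(fields[2]),
                            int(fields[3]),
                            float(fields[4]),
                            int(fields[5]),
                            float(fields[6]),
                        )
                    )
                elif section == "exclusions":
                    if len(fields) != 2:
                        raise ValueError("expected 2 fields: i j")
                    i, j = int(fields[0]), int(fields[1])
                    exclusions.add((min(i, j), max(i, j)))
            except ValueError as exc:
                raise TopologyError(f"{path}:{lineno}: {exc}") from exc

    topo = Topology(atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals, exclusions=exclusions)
    if "exclusions" not in seen_sections:
        topo.exclusions = topo.bonded_exclusions()
        topo.exclusions_generated = True
    topo.validate()
    return topo


def write_topology(topology: Topology, path: str | os.PathLike) -> None:
    """Write a topology in the sectioned text format (inverse of read_topology)."""
    with open(path, "w") as fh:
        fh.write("# pairfda topology\n[atoms]\n")
        fh.write("# index name residue_index residue_name charge sigma epsilon\n")
        for a in topology.atoms:
            fh.write(
                f"{a.index} {a.name} {a.residue_index} {a.residue_name} "
                f"{a.charge!r} {a.sigma!r} {a.epsilon!r}\n"
            )
        if topology.bonds:
            fh.write("[bonds]\n")
            for b in topology.bonds:
                fh.write(f"{b.i} {b.j} {b.b0!r} {b.kb!r}\n")
        if topology.angles:
            fh.write("[angles]\n")
            for a in topology.angles:
                fh.write(f"{a.i} {a.j} {a.k} {a.theta0!r} {a.ktheta!r}\n")
        if topology.dihedrals:
            fh.write("[dihedrals]\n")
            for d in topology.dihedrals:
                fh.write(f"{d.i} {d.j} {d.k} {d.l} {d.kphi!r} {d.multiplicity} {d.phase!r}\n")
        fh.write("[exclusions]\n")
        for i, j in sorted(topology.exclusions):
            fh.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# coordinate trajectories
# ---------------------------------------------------------------------------


def read_trajectory(path: str | os.PathLike, n_atoms: int) -> list[TrajectoryFrame]:
    """Read a multi-model PDB or GRO trajectory as frames in nm / ps.

    PDB coordinates (Å) are converted to nm; GRO is native nm.  When the file
    carries no time information the frame index (in ps) is used.
    """
    import mdtraj as md

    path = os.fspath(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = md.load(path)
    except Exception as exc:  # mdtraj raises assorted types on malformed input
        raise TrajectoryError(f"cannot read trajectory {path!r}: {exc}") from exc
    if traj.n_atoms != n_atoms:
        raise TrajectoryError(
            f"{path!r}: atom count mismatch: file has {traj.n_atoms}, expected {n_atoms}"
        )
    times = np.asarray(traj.time, dtype=float)
    if times.size != traj.n_frames or not np.all(np.isfinite(times)):
        times = np.arange(traj.n_frames, dtype=float)
    xyz = np.asarray(traj.xyz, dtype=float)  # mdtraj is natively nm
    return [TrajectoryFrame(time=float(times[k]), coordinates=xyz[k]) for k in range(traj.n_frames)]


def write_pdb_trajectory(
    topology: Topology, frames: Sequence[TrajectoryFrame], path: str | os.PathLike
) -> None:
    """Write frames as a multi-model PDB (coordinates converted nm → Å)."""
    with open(path, "w") as fh:
        for model, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {model:4d}\n")
            for a, (x, y, z) in zip(topology.atoms, frame.coordinates * 10.0):
                element = a.name.strip()[:1].upper() or "C"
                fh.write(
                    f"ATOM  {a.index + 1:5d} {a.name[:4]:^4s} {a.residue_name[:3]:>3s} A"
                    f"{a.residue_index + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_gro_trajectory(
    topology: Topology,
    frames: Sequence[TrajectoryFrame],
    path: str | os.PathLike,
    box: float = 50.0,
) -> None:
    """Write frames as a concatenated GRO trajectory (nm), time in the title."""
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"pairfda t= {frame.time:.5f}\n{topology.n_atoms:5d}\n")
            for a, (x, y, z) in zip(topology.atoms, frame.coordinates):
                fh.write(
                    f"{a.residue_index + 1:5d}{a.residue_name[:5]:<5s}{a.name[:5]:>5s}"
                    f"{a.index + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{box:10.5f}{box:10.5f}{box:10.5f}\n")


# ---------------------------------------------------------------------------
# binary force-trajectory format
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<4sIIB")
_BLOCK_HEAD = struct.Struct("<dI")
_RECORD = struct.Struct("<QdB")


def write_force_trajectory(
    path: str | os.PathLike,
    header: ForceTrajectoryHeader,
    blocks: Iterable[PairwiseForceMatrix],
) -> None:
    """Serialize blocks to the sparse binary format; entries sorted by (i, j, type)."""
    n = header.n_atoms
    mode = SYNTAX_MODES.index(header.syntax_mode)
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, header.format_version, n, mode))
        for block in blocks:
            block.validate(n)
            items = block.sorted_items()
            fh.write(_BLOCK_HEAD.pack(block.time, len(items)))
            for (i, j, t), f in items:
                fh.write(_RECORD.pack(i * n + j, f, int(t)))


def read_force_trajectory(path: str | os.PathLike) -> ForceTrajectory:
    """Exact inverse of :func:`write_force_trajectory`."""
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise ForceFormatError(f"{path!r}: truncated header")
        magic, version, n_atoms, mode = _HEADER.unpack(head)
        if magic != MAGIC:
            raise ForceFormatError(f"{path!r}: bad magic {magic!r}, expected {MAGIC!r}")
        if version != FORMAT_VERSION:
            raise ForceFormatError(f"{path!r}: unsupported format version {version}")
        if mode >= len(SYNTAX_MODES):
            raise ForceFormatError(f"{path!r}: unknown syntax mode code {mode}")
        header = ForceTrajectoryHeader(
            n_atoms=n_atoms, syntax_mode=SYNTAX_MODES[mode], format_version=version
        )
        blocks: list[PairwiseForceMatrix] = []
        while True:
            bh = fh.read(_BLOCK_HEAD.size)
            if not bh:
                break
            if len(bh) < _BLOCK_HEAD.size:
                raise ForceFormatError(f"{path!r}: truncated block {len(blocks)}")
            time, n_entries = _BLOCK_HEAD.unpack(bh)
            payload = fh.read(n_entries * _RECORD.size)
            if len(payload) < n_entries * _RECORD.size:
                raise ForceFormatError(f"{path!r}: truncated block {len(blocks)}")
            entries: dict = {}
            for rec in range(n_entries):
                packed, force, code = _RECORD.unpack_from(payload, rec * _RECORD.size)
                if code not in {int(t) for t in InteractionType} or code == 0:
                    raise ForceFormatError(
                        f"{path!r}: unknown interaction-type code {code} in block {len(blocks)}"
                    )
                i, j = divmod(packed, n_atoms)
                if not i < j:
                    raise ForceFormatError(
                        f"{path!r}: invalid packed pair index {packed} in block {len(blocks)}"
                    )
                entries[(int(i), int(j), InteractionType(code))] = force
            blocks.append(PairwiseForceMatrix(time=time, entries=entries))
    return ForceTrajectory(header=header, blocks=blocks)


# ---------------------------------------------------------------------------
# ASCII dump
# ---------------------------------------------------------------------------


def dump_ascii(path_in: str | os.PathLike, path_out: str | os.PathLike) -> None:
    """Convert a binary force trajectory to its ASCII representation.

    One line per entry: ``time i j force type-name``, floats at full
    round-trip precision (17 significant digits).
    """
    traj = read_force_trajectory(path_in)
    with open(path_out, "w") as fh:
        fh.write("# pairfda force trajectory (ascii)\n")
        fh.write(f"# n_atoms {traj.header.n_atoms}\n")
        fh.write(f"# syntax_mode {traj.header.syntax_mode}\n")
        fh.write("# columns: time_ps i j force_kJ_mol_nm type\n")
        for block in traj.blocks:
            fh.write(f"# block {block.time:.17g} {len(block.entries)}\n")
            for (i, j, t), f in block.sorted_items():
                fh.write(f"{block.time:.17g} {i} {j} {f:.17g} {t.name}\n")


def parse_ascii(path: str | os.PathLike) -> ForceTrajectory:
    """Read an ASCII dump back into a ForceTrajectory (inverse of dump_ascii)."""
    n_atoms = None
    syntax_mode = "atom"
    blocks: list[PairwiseForceMatrix] = []
    current: PairwiseForceMatrix | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                fields = line[1:].split()
                if len(fields) == 2 and fields[0] == "n_atoms":
                    n_atoms = int(fields[1])
                elif len(fields) == 2 and fields[0] == "syntax_mode":
                    syntax_mode = fields[1]
                elif len(fields) == 3 and fields[0] == "block":
                    current = PairwiseForceMatrix(time=float(fields[1]), entries={})
                    blocks.append(current)
                continue
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ForceFormatError(f"{path}:{lineno}: expected 5 columns")
            time, i, j, force, tname = (
                float(fields[0]),
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
                fields[4],
            )
            try:
                itype = InteractionType[tname]
            except KeyError as exc:
                raise ForceFormatError(f"{path}:{lineno}: unknown type {tname!r}") from exc
            if current is None or time != current.time:
                current = PairwiseForceMatrix(time=time, entries={})
                blocks.append(current)
            current.entries[(i, j, itype)] = force
    if n_atoms is None:
        raise ForceFormatError(f"{path}: missing '# n_atoms' header line")
    return ForceTrajectory(
        header=ForceTrajectoryHeader(n_atoms=n_atoms, syntax_mode=syntax_mode), blocks=blocks
    )


# ---------------------------------------------------------------------------
# PDB b-factor export
# ---------------------------------------------------------------------------


def write_pdb_bfactors(
    reference_pdb: str | os.PathLike,
    values: Sequence[float],
    out: str | os.PathLike,
    scaling: str = "none",
) -> None:
    """Write per-atom scalars as b-factors into a copy of ``reference_pdb``.

    Only columns 61-66 (%6.2f) of ATOM/HETATM records are touched; every
    other byte of the file is preserved.  ``scaling="minmax"`` maps
    [min, max] affinely onto [0, 99.99] (all-equal input maps to 0).
    Values are matched to coordinate records in file order; multi-model
    files cycle through the values per model.
    """
    if scaling not in ("none", "minmax"):
        raise ValueError(f"scaling must be 'none' or 'minmax', got {scaling!r}")
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ValueError("values must be a 1-D sequence")
    if scaling == "minmax":
        lo, hi = vals.min(), vals.max()
        vals = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo) * 99.99
    else:
        for v in vals:
            if not -9.99 <= v <= 999.99:
                raise ValueError(
                    f"value {v} not representable in %6.2f b-factor columns; use scaling='minmax'"
                )

    with open(reference_pdb) as fh:
        lines = fh.readlines()
    n_coord = sum(1 for ln in lines if ln.startswith(("ATOM  ", "HETATM")))
    n_models = max(1, sum(1 for ln in lines if ln.startswith("MODEL")))
    if n_coord != len(vals) * n_models:
        raise ValueError(
            f"value count {len(vals)} does not match {n_coord} coordinate records "
            f"({n_models} model(s)) in {os.fspath(reference_pdb)!r}"
        )
    out_lines = []
    k = 0
    for ln in lines:
        if ln.startswith(("ATOM  ", "HETATM")):
            nl = "\n" if ln.endswith("\n") else ""
            body = ln.rstrip("\n").ljust(66)
            ln = body[:60] + f"{vals[k % len(vals)]:6.2f}" + body[66:] + nl
            k += 1
        out_lines.append(ln)
    with open(out, "w") as fh:
        fh.writelines(out_lines)
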