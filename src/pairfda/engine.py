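"""Pair-wise force engine.

Computes signed scalar pair forces per coordinate frame from a topology:

* harmonic bonds, ``V = ½·kb·(r − b0)²``
* harmonic angles, ``V = ½·kθ·(θ − θ0)²``, reduced to the (i, k) pair
* periodic proper dihedrals, ``V = kφ·(1 + cos(nφ − φs))``, reduced to (i, l)
* truncated Coulomb (no PME, no reaction field) and Lennard-Jones 12-6 with
  Lorentz–Berthelot combination, for non-excluded pairs within the cutoff

Sign convention: positive = repulsive (the force pushes the pair apart).

The multi-body angle and dihedral terms are mapped onto a single pair by
projecting the analytic atomic forces onto the i–k (angles) or i–l
(dihedrals) axis and averaging the two end-atom projections; contributions
on the middle atoms are discarded.  This is an approximation — it keeps the
pair representation but no longer resolves the full three/four-body force.
Geometries where the torsion/angle gradient is undefined (collinear atoms)
are skipped with a warning rather than failing the frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ForceTrajectory,
    ForceTrajectoryHeader,
    InteractionType,
    PairKey,
    PairwiseForceMatrix,
    Topology,
    TrajectoryFrame,
)

__all__ = [
    "F_ELEC",
    "EngineOptions",
    "lj_pair_force",
    "coulomb_pair_force",
    "bond_pair_force",
    "angle_pair_force",
    "dihedral_pair_force",
    "angle_atomic_forces",
    "dihedral_atomic_forces",
    "compute_frame",
    "run_fda",
    "atomic_forces",
    "reconstruct_atomic_vectors",
]

#: Coulomb conversion factor 1/(4πε0) in kJ·mol⁻¹·nm·e⁻²
F_ELEC = 138.935458

#: |sin| threshold below which angle/dihedral geometry is treated as degenerate
DEGENERATE_SIN = 1e-10

ALL_TYPES = frozenset(
    {
        InteractionType.BOND,
        InteractionType.ANGLE,
        InteractionType.DIHEDRAL,
        InteractionType.COULOMB,
        InteractionType.LJ,
    }
)


@dataclass(frozen=True)
class EngineOptions:
    """Engine parameters.

    cutoff : non-bonded cutoff in nm (plain truncation, no shifting).
    output_interval : number of frames averaged into one stored block.
    include_types : interaction types to evaluate.
    """

    cutoff: float = 1.0
    output_interval: int = 1
    include_types: frozenset = field(default_factory=lambda: ALL_TYPES)

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")
        if self.output_interval < 1:
            raise ValueError(f"output_interval must be >= 1, got {self.output_interval}")


# ---------------------------------------------------------------------------
# two-body kernels: signed scalar −dV/dr
# ---------------------------------------------------------------------------


def lj_pair_force(r: float, sigma: float, epsilon: float) -> float:
    """Lennard-Jones force −dV/dr for V = 4ε[(σ/r)¹² − (σ/r)⁶].

    Positive (repulsive) for r below the minimum at 2^(1/6)σ.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (12.0 * sr6 * sr6 - 6.0 * sr6) / r


def coulomb_pair_force(r: float, qi: float, qj: float) -> float:
    """Truncated Coulomb force f_elec·qi·qj/r²; like charges repel (positive)."""
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    return F_ELEC * qi * qj / (r * r)


def bond_pair_force(r: float, b0: float, kb: float) -> float:
    """Harmonic bond force −kb·(r − b0); a stretched bond pulls back (negative)."""
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    return -kb * (r - b0)


# ---------------------------------------------------------------------------
# angles: analytic atomic forces, then i–k projection
# ---------------------------------------------------------------------------


def angle_atomic_forces(ri, rj, rk, theta0: float, ktheta: float):
    """Analytic forces (F_i, F_j, F_k) of V = ½kθ(θ−θ0)² and the angle θ.

    Returns None when the geometry is degenerate (|sin θ| below threshold).
    """
    ri, rj, rk = (np.asarray(x, dtype=float) for x in (ri, rj, rk))
    rij = ri - rj
    rkj = rk - rj
    nij = np.linalg.norm(rij)
    nkj = np.linalg.norm(rkj)
    if nij == 0 or nkj == 0:
        return None
    uij = rij / nij
    ukj = rkj / nkj
    cos_t = float(np.clip(np.dot(uij, ukj), -1.0, 1.0))
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    if sin_t < DEGENERATE_SIN:
        return None
    theta = math.acos(cos_t)
    # ∇_i θ = −(û_kj − cosθ·û_ij)/(|r_ij|·sinθ); F = −kθ(θ−θ0)·∇θ
    coef = -ktheta * (theta - theta0)
    grad_i = -(ukj - cos_t * uij) / (nij * sin_t)
    grad_k = -(uij - cos_t * ukj) / (nkj * sin_t)
    fi = coef * grad_i
    fk = coef * grad_k
    fj = -(fi + fk)
    return fi, fj, fk, theta


def angle_pair_force(ri, rj, rk, theta0: float, ktheta: float) -> float | None:
    """Signed scalar pair force assigned to (i, k) for a harmonic angle.

    The analytic end-atom forces are projected onto the i–k axis and
    symmetrized: ½(F_i·û_ki + F_k·û_ik).  Positive = repulsive.  Returns
    None (with a warning) for degenerate collinear geometry.
    """
    res = angle_atomic_forces(ri, rj, rk, theta0, ktheta)
    if res is None:
        warnings.warn("degenerate angle geometry, entry skipped", stacklevel=2)
        return None
    fi, _fj, fk, _theta = res
    ri, rk = np.asarray(ri, dtype=float), np.asarray(rk, dtype=float)
    d = ri - rk
    nd = np.linalg.norm(d)
    if nd == 0:
        warnings.warn("coincident i/k atoms in angle, entry skipped", stacklevel=2)
        return None
    u_ki = d / nd  # unit vector from k to i
    return 0.5 * float(np.dot(fi, u_ki) + np.dot(fk, -u_ki))


# ---------------------------------------------------------------------------
# proper dihedrals: analytic atomic forces, then i–l projection
# ---------------------------------------------------------------------------


def dihedral_atomic_forces(ri, rj, rk, rl, kphi: float, multiplicity: int, phase: float):
    """Analytic forces (F_i, F_j, F_k, F_l) of V = kφ(1 + cos(nφ − φs)) and φ.

    Uses the standard torsion-gradient formulas on the plane normals
    m = b1×b2, n = b2×b3.  Returns None for degenerate (collinear) geometry.
    """
    ri, rj, rk, rl = (np.asarray(x, dtype=float) for x in (ri, rj, rk, rl))
    rij = ri - rj
    rkj = rk - rj
    rkl = rk - rl
    m = np.cross(rij, rkj)
    n = np.cross(rkj, rkl)
    m2 = float(np.dot(m, m))
    n2 = float(np.dot(n, n))
    nkj = float(np.linalg.norm(rkj))
    nij = float(np.linalg.norm(rij))
    nkl = float(np.linalg.norm(rkl))
    if nkj == 0 or nij == 0 or nkl == 0:
        return None
    # |m| = |r_ij||r_kj|·sin(i-j-k); degeneracy check on both plane normals
    if math.sqrt(m2) / (nij * nkj) < DEGENERATE_SIN or math.sqrt(n2) / (nkj * nkl) < DEGENERATE_SIN:
        return None
    phi = math.atan2(float(np.dot(np.cross(m, n), rkj)) / nkj, float(np.dot(m, n)))
    dV_dphi = -kphi * multiplicity * math.sin(multiplicity * phi - phase)
    dphi_dri = (nkj / m2) * m
    dphi_drl = -(nkj / n2) * n
    p = float(np.dot(rij, rkj)) / (nkj * nkj)
    q = float(np.dot(rkl, rkj)) / (nkj * nkj)
    dphi_drj = (p - 1.0) * dphi_dri - q * dphi_drl
    dphi_drk = (q - 1.0) * dphi_drl - p * dphi_dri
    fi = -dV_dphi * dphi_dri
    fj = -dV_dphi * dphi_drj
    fk = -dV_dphi * dphi_drk
    fl = -dV_dphi * dphi_drl
    return fi, fj, fk, fl, phi


def dihedral_pair_force(
    ri, rj, rk, rl, kphi: float, multiplicity: int, phase: float
) -> float | None:
    """Signed scalar pair force assigned to (i, l) for a proper dihedral.

    Projection ½(F_i·û_li + F_l·û_il) of the analytic end-atom forces onto
    the i–l axis; positive = repulsive.  None for degenerate geometry.
    """
    res = dihedral_atomic_forces(ri, rj, rk, rl, kphi, multiplicity, phase)
    if res is None:
        warnings.warn("degenerate dihedral geometry, entry skipped", stacklevel=2)
        return None
    fi, _fj, _fk, fl, _phi = res
    ri, rl = np.asarray(ri, dtype=float), np.asarray(rl, dtype=float)
    d = ri - rl
    nd = np.linalg.norm(d)
    if nd == 0:
        warnings.warn("coincident i/l atoms in dihedral, entry skipped", stacklevel=2)
        return None
    u_li = d / nd
    return 0.5 * float(np.dot(fi, u_li) + np.dot(fl, -u_li))


# ---------------------------------------------------------------------------
# frame evaluation
# ---------------------------------------------------------------------------


def _add(entries: dict[PairKey, float], i: int, j: int, itype: InteractionType, f: float) -> None:
    if f == 0.0:
        return
    if i > j:
        i, j = j, i
    key = (i, j, itype)
    entries[key] = entries.get(key, 0.0) + f


def compute_frame(
    frame: TrajectoryFrame, topology: Topology, options: EngineOptions | None = None
) -> PairwiseForceMatrix:
    """Evaluate all pair forces of one frame into a sparse matrix.

    Bonded terms contribute one entry per bond/angle/dihedral (same-pair,
    same-type contributions are summed); non-excluded pairs within the
    cutoff get COULOMB and LJ entries.  Exact zeros are not stored.
    """
    opt = options or EngineOptions()
    x = frame.coordinates
    if x.shape[0] != topology.n_atoms:
        raise ValueError(
            f"frame has {x.shape[0]} atoms, topology has {topology.n_atoms}"
        )
    entries: dict[PairKey, float] = {}
    types = opt.include_types

    if InteractionType.BOND in types:
        for b in topology.bonds:
            r = float(np.linalg.norm(x[b.i] - x[b.j]))
            _add(entries, b.i, b.j, InteractionType.BOND, bond_pair_force(r, b.b0, b.kb))
    if InteractionType.ANGLE in types:
        for a in topology.angles:
            f = angle_pair_force(x[a.i], x[a.j], x[a.k], a.theta0, a.ktheta)
            if f is not None:
                _add(entries, a.i, a.k, InteractionType.ANGLE, f)
    if InteractionType.DIHEDRAL in types:
        for d in topology.dihedrals:
            f = dihedral_pair_force(
                x[d.i], x[d.j], x[d.k], x[d.l], d.kphi, d.multiplicity, d.phase
            )
            if f is not None:
                _add(entries, d.i, d.l, InteractionType.DIHEDRAL, f)

    do_coul = InteractionType.COULOMB in types
    do_lj = InteractionType.LJ in types
    if do_coul or do_lj:
        q = topology.charges()
        sig = np.array([a.sigma for a in topology.atoms])
        eps = np.array([a.epsilon for a in topology.atoms])
        n = topology.n_atoms
        excl = topology.exclusions
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                r = float(np.linalg.norm(x[i] - x[j]))
                if r > opt.cutoff:
                    continue
                if do_coul and q[i] * q[j] != 0.0:
                    _add(entries, i, j, InteractionType.COULOMB, coulomb_pair_force(r, q[i], q[j]))
                if do_lj:
                    e_ij = math.sqrt(eps[i] * eps[j])  # Lorentz–Berthelot
                    if e_ij != 0.0:
                        s_ij = 0.5 * (sig[i] + sig[j])
                        _add(entries, i, j, InteractionType.LJ, lj_pair_force(r, s_ij, e_ij))
    return PairwiseForceMatrix(time=frame.time, entries=entries)


def atomic_forces(
    frame: TrajectoryFrame, topology: Topology, options: EngineOptions | None = None
) -> np.ndarray:
    """Exact analytic total force vector on every atom, shape (n_atoms, 3).

    Unlike the pair decomposition this keeps the full multi-body angle and
    dihedral forces (including middle atoms); degenerate angle/dihedral
    geometries contribute zero.  Used for equilibrium checks and as the
    reference in force-conservation tests.
    """
    opt = options or EngineOptions()
    x = frame.coordinates
    F = np.zeros_like(x)
    types = opt.include_types
    if InteractionType.BOND in types:
        for b in topology.bonds:
            d = x[b.i] - x[b.j]
            r = float(np.linalg.norm(d))
            f = bond_pair_force(r, b.b0, b.kb)
            u = d / r
            F[b.i] += f * u
            F[b.j] -= f * u
    if InteractionType.ANGLE in types:
        for a in topology.angles:
            res = angle_atomic_forces(x[a.i], x[a.j], x[a.k], a.theta0, a.ktheta)
            if res is not None:
                F[a.i] += res[0]
                F[a.j] += res[1]
                F[a.k] += res[2]
    if InteractionType.DIHEDRAL in types:
        for d in topology.dihedrals:
            res = dihedral_atomic_forces(
                x[d.i], x[d.j], x[d.k], x[d.l], d.kphi, d.multiplicity, d.phase
            )
            if res is not None:
                F[d.i] += res[0]
                F[d.j] += res[1]
                F[d.k] += res[2]
                F[d.l] += res[3]
    do_coul = InteractionType.COULOMB in types
    do_lj = InteractionType.LJ in types
    if do_coul or do_lj:
        q = topology.charges()
        sig = np.array([a.sigma for a in topology.atoms])
        eps = np.array([a.epsilon for a in topology.atoms])
        n = topology.n_atoms
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in topology.exclusions:
                    continue
                d = x[i] - x[j]
                r = float(np.linalg.norm(d))
                if r > opt.cutoff:
                    continue
                f = 0.0
                if do_coul and q[i] * q[j] != 0.0:
                    f += coulomb_pair_force(r, q[i], q[j])
                if do_lj:
                    e_ij = math.sqrt(eps[i] * eps[j])
                    if e_ij != 0.0:
                        f += lj_pair_force(r, 0.5 * (sig[i] + sig[j]), e_ij)
                if f != 0.0:
                    u = d / r
                    F[i] += f * u
                    F[j] -= f * u
    return F


def reconstruct_atomic_vectors(block: PairwiseForceMatrix, frame: TrajectoryFrame) -> np.ndarray:
    """Rebuild per-atom force vectors from a sparse pair block and coordinates.

    Each signed scalar F_ij becomes the vector F_ij·û_ij acting on atom i
    (û_ij pointing from j to i) and its negative on atom j, so Newton's
    third law holds exactly by construction.
    """
    x = frame.coordinates
    F = np.zeros_like(x)
    for (i, j, _t), f in block.entries.items():
        d = x[i] - x[j]
        r = float(np.linalg.norm(d))
        if r == 0:
            continue
        u = d / r
        F[i] += f * u
        F[j] -= f * u
    return F


def run_fda(
    frames: list[TrajectoryFrame],
    topology: Topology,
    options: EngineOptions | None = None,
) -> ForceTrajectory:
    """Compute a force trajectory, averaging frames over the output interval.

    Each stored block is the arithmetic mean over ``output_interval``
    consecutive frames (a pair absent from a frame contributes zero); the
    block carries the first frame's time stamp.  A trailing partial interval
    is averaged over its actual length.
    """
    opt = options or EngineOptions()
    if not frames:
        raise ValueError("run_fda requires at least one frame")
    header = ForceTrajectoryHeader(n_atoms=topology.n_atoms, syntax_mode="atom")
    blocks: list[PairwiseForceMatrix] = []
    step = opt.output_interval
    for start in range(0, len(frames), step):
        chunk = frames[start : start + step]
        acc: dict[PairKey, float] = {}
        for fr in chunk:
            for key, val in compute_frame(fr, topology, opt).entries.items():
                acc[key] = acc.get(key, 0.0) + val
        entries = {k: v / len(chunk) for k, v in acc.items() if v != 0.0}
        blocks.append(PairwiseForceMatrix(time=chunk[0].time, entries=entries))
    return ForceTrajectory(header=header, blocks=blocks)
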