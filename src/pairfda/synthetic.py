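"""Synthetic toy systems with known analytic force structure.

Every test input of this package is generated here: dimers and short chains
whose equilibrium geometry is an exact stationary point of the implemented
potential, thermal-noise coordinate sampling around it, and matched
reference/perturbed state pairs for end-to-end validation of the ΔF
pipeline.

Thermal sampling is i.i.d. isotropic positional jitter, not an MD
integrator: the force engine consumes coordinate frames and is agnostic to
how they were produced, and jitter reproduces the statistical feature that
matters for the analysis layer — fluctuating per-frame forces whose pair
means are nonzero.  What it does *not* reproduce is the time correlation,
anharmonic sampling and solvent effects of real trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import Angle, Atom, Bond, Dihedral, Topology, TrajectoryFrame
from .engine import EngineOptions, atomic_forces

__all__ = [
    "ToySystemSpec",
    "StatePair",
    "build_system",
    "sample_frames",
    "make_state_pair",
    "KINDS",
    "PERTURBATIONS",
]

KINDS = (
    "lj_dimer",
    "charged_dimer",
    "linear_chain",
    "bent_triple",
    "dihedral_quad",
    "two_residue_peptide",
)

PERTURBATIONS = ("charge_change", "external_tension", "parameter_change")

# shared force-field defaults (overridable through ToySystemSpec.parameters)
_DEFAULTS: dict[str, float] = {
    "b0": 0.15,  # nm
    "kb": 1.0e5,  # kJ/mol/nm^2
    "theta0": 1.9106332362490186,  # rad, ≈109.47°
    "ktheta": 400.0,  # kJ/mol/rad^2
    "kphi": 5.0,  # kJ/mol
    "multiplicity": 3,
    "phase": 0.0,  # rad → minimum at the planar-trans geometry built here
    "sigma": 0.3,  # nm
    "epsilon": 0.0,  # kJ/mol (LJ off unless asked for)
    "charge": 0.0,  # e; chains alternate +q/−q when nonzero
    "r": 1.0,  # nm, dimer separation
    "q": 1.0,  # e, charged-dimer magnitude
}


@dataclass
class ToySystemSpec:
    """Recipe for one toy system; ``seed`` fixes all randomness downstream."""

    kind: str
    n_atoms: int = 8
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    thermal_sigma: float = 0.0  # nm
    n_frames: int = 1
    n_runs: int = 1

    def param(self, name: str):
        return self.parameters.get(name, _DEFAULTS[name])

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown system kind {self.kind!r}; choose from {KINDS}")
        if self.thermal_sigma < 0:
            raise ValueError("thermal_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class StatePair:
    """Matched reference/perturbed inputs sharing everything but the
    perturbation."""

    ref_topology: Topology
    ref_coordinates: np.ndarray
    pert_topology: Topology
    pert_coordinates: np.ndarray


def _zigzag(n: int, b0: float, theta0: float) -> np.ndarray:
    """Planar zig-zag chain: bonds at b0, angles at theta0, dihedrals at π."""
    alpha = (math.pi - theta0) / 2.0
    pos = np.zeros((n, 3))
    for k in range(1, n):
        a = alpha if k % 2 == 1 else -alpha
        pos[k] = pos[k - 1] + b0 * np.array([math.cos(a), math.sin(a), 0.0])
    return pos


def _chain_topology(
    spec: ToySystemSpec,
    n: int,
    residue_size: int,
    residue_names: list[str] | None = None,
) -> Topology:
    q = spec.param("charge")
    atoms = []
    for i in range(n):
        rid = i // residue_size
        rname = residue_names[rid] if residue_names else f"R{rid}"
        charge = q * (1 if i % 2 == 0 else -1) if q else 0.0
        atoms.append(
            Atom(i, f"C{i + 1}", rid, rname, charge, spec.param("sigma"), spec.param("epsilon"))
        )
    bonds = [Bond(i, i + 1, spec.param("b0"), spec.param("kb")) for i in range(n - 1)]
    angles = [
        Angle(i, i + 1, i + 2, spec.param("theta0"), spec.param("ktheta")) for i in range(n - 2)
    ]
    dihedrals = [
        Dihedral(
            i,
            i + 1,
            i + 2,
            i + 3,
            spec.param("kphi"),
            int(spec.param("multiplicity")),
            spec.param("phase"),
        )
        for i in range(n - 3)
    ]
    topo = Topology(atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals)
    topo.exclusions = topo.bonded_exclusions()
    topo.exclusions_generated = True
    return topo


def build_system(spec: ToySystemSpec) -> tuple[Topology, np.ndarray]:
    """Build topology and equilibrium coordinates for a toy system.

    For the neutral defaults the returned coordinates are an exact
    stationary point of the implemented potential.  Systems with long-range
    terms switched on (``charge`` or ``epsilon`` on chains, the charged
    dimer) are built at the same reference geometry, which then is *not*
    force-free — they model a strained or interacting state on purpose.
    """
    kind = spec.kind
    if kind == "lj_dimer":
        sigma, eps = spec.param("sigma"), spec.parameters.get("epsilon", 1.0)
        atoms = [
            Atom(0, "AR1", 0, "AR", 0.0, sigma, eps),
            Atom(1, "AR2", 1, "AR", 0.0, sigma, eps),
        ]
        coords = np.array([[0.0, 0.0, 0.0], [2 ** (1 / 6) * sigma, 0.0, 0.0]])
        return Topology(atoms=atoms), coords
    if kind == "charged_dimer":
        q, r = spec.param("q"), spec.param("r")
        atoms = [
            Atom(0, "NA1", 0, "ION", +q, spec.param("sigma"), spec.param("epsilon")),
            Atom(1, "CL1", 1, "ION", -q, spec.param("sigma"), spec.param("epsilon")),
        ]
        coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        return Topology(atoms=atoms), coords
    if kind == "linear_chain":
        n = spec.n_atoms
        if n < 2:
            raise ValueError("linear_chain needs n_atoms >= 2")
        topo = _chain_topology(spec, n, residue_size=2)
        coords = np.zeros((n, 3))
        coords[:, 0] = spec.param("b0") * np.arange(n)
        # collinear equilibrium: angle terms sit at theta0 = π by construction
        for k, a in enumerate(topo.angles):
            topo.angles[k] = Angle(a.i, a.j, a.k, math.pi, a.ktheta)
        return topo, coords
    if kind == "bent_triple":
        spec2 = ToySystemSpec(kind="linear_chain", n_atoms=3, parameters=spec.parameters)
        topo = _chain_topology(spec2, 3, residue_size=3)
        coords = _zigzag(3, spec.param("b0"), spec.param("theta0"))
        return topo, coords
    if kind == "dihedral_quad":
        spec2 = ToySystemSpec(kind="linear_chain", n_atoms=4, parameters=spec.parameters)
        topo = _chain_topology(spec2, 4, residue_size=2)
        coords = _zigzag(4, spec.param("b0"), spec.param("theta0"))
        return topo, coords
    if kind == "two_residue_peptide":
        n = 6
        spec2 = ToySystemSpec(kind="linear_chain", n_atoms=n, parameters=spec.parameters)
        topo = _chain_topology(spec2, n, residue_size=3, residue_names=["ALA", "GLY"])
        coords = _zigzag(n, spec.param("b0"), spec.param("theta0"))
        return topo, coords
    raise ValueError(f"unknown system kind {kind!r}")


def sample_frames(
    topology: Topology,
    equilibrium: np.ndarray,
    thermal_sigma: float,
    n_frames: int,
    seed: int,
) -> list[TrajectoryFrame]:
    """Frames with i.i.d. isotropic Gaussian jitter of sd ``thermal_sigma``
    (nm) about the equilibrium; times are the frame index in ps."""
    if thermal_sigma < 0:
        raise ValueError("thermal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    eq = np.asarray(equilibrium, dtype=float)
    frames = []
    for k in range(n_frames):
        jitter = rng.normal(0.0, thermal_sigma, size=eq.shape) if thermal_sigma > 0 else 0.0
        frames.append(TrajectoryFrame(time=float(k), coordinates=eq + jitter))
    return frames


def _copy_topology(topology: Topology) -> Topology:
    return Topology(
        atoms=list(topology.atoms),
        bonds=list(topology.bonds),
        angles=list(topology.angles),
        dihedrals=list(topology.dihedrals),
        exclusions=set(topology.exclusions),
        exclusions_generated=topology.exclusions_generated,
    )


def _solve_tension_equilibrium(
    topology: Topology, coords: np.ndarray, tension: float
) -> np.ndarray:
    """Positions of a linear chain in static balance under terminal tension.

    Constant opposing external forces −T·x̂ on the first and +T·x̂ on the last atom;
    atom 0 is pinned (removes translation) and the remaining x positions are
    solved so every net atomic force vanishes.  Solved numerically so the
    result stays correct when nonbonded terms are active along the chain.
    """
    from scipy.optimize import root

    n = topology.n_atoms
    opt = EngineOptions()
    x0 = coords[:, 0].copy()

    def residual(xs: np.ndarray) -> np.ndarray:
        pos = coords.copy()
        pos[1:, 0] = xs
        F = atomic_forces(TrajectoryFrame(time=0.0, coordinates=pos), topology, opt)
        r = F[1:, 0].copy()
        r[-1] += tension  # external pull on the terminal atom
        return r

    guess = x0[1:] + (tension / topology.bonds[0].kb) * np.arange(1, n)
    sol = root(residual, guess, tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"tension equilibrium did not converge: {sol.message}")
    out = coords.copy()
    out[1:, 0] = sol.x
    return out


def make_state_pair(
    spec: ToySystemSpec,
    perturbation: str,
    magnitude: float,
    atom: int | None = None,
    bond: int | None = None,
) -> StatePair:
    """Build matched reference/perturbed inputs for a ΔF experiment.

    charge_change     : add ``magnitude`` (e) to one atom's charge
                        (default: the middle atom).
    external_tension  : re-solve a linear chain's equilibrium under constant
                        opposing terminal forces of ``magnitude``
                        (kJ·mol⁻¹·nm⁻¹); topology unchanged.
    parameter_change  : add ``magnitude`` (nm) to one bond's rest length b0
                        (default: the middle bond).
    """
    topo, coords = build_system(spec)
    if perturbation == "charge_change":
        a = atom if atom is not None else topo.n_atoms // 2
        pert = _copy_topology(topo)
        old = pert.atoms[a]
        pert.atoms[a] = Atom(
            old.index, old.name, old.residue_index, old.residue_name,
            old.charge + magnitude, old.sigma, old.epsilon,
        )
        return StatePair(topo, coords, pert, coords.copy())
    if perturbation == "external_tension":
        if spec.kind != "linear_chain":
            raise ValueError("external_tension applies to linear_chain systems only")
        stretched = _solve_tension_equilibrium(topo, coords, magnitude)
        return StatePair(topo, coords, _copy_topology(topo), stretched)
    if perturbation == "parameter_change":
        if not topo.bonds:
            raise ValueError("parameter_change needs a bonded system")
        b = bond if bond is not None else len(topo.bonds) // 2
        pert = _copy_topology(topo)
        old = pert.bonds[b]
        pert.bonds[b] = Bond(old.i, old.j, old.b0 + magnitude, old.kb)
        return StatePair(topo, coords, pert, coords.copy())
    raise ValueError(f"unknown perturbation {perturbation!r}; choose from {PERTURBATIONS}")
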