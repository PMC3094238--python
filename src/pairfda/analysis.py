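"""Statistics and aggregation on force trajectories.

This module implements the comparison machinery of force distribution
analysis.  Two simulated states of a system — a reference and a perturbed
one (with/without pulling force, apo/holo, a mutated charge, ...) — are each
summarized by time-averaged pair forces, and the difference

    ΔF_ij = ⟨F_ij⟩_pert − ⟨F_ij⟩_ref

localizes where the perturbation changed the internal force balance.  The
same subtraction between two *independent reference* runs gives a null map
ΔF_noise used to judge significance.  Normalizing by the cross-run standard
error ε_ij yields the dimensionless Δf_ij = ΔF_ij / ε_ij.

Projections down to atoms (absolute column sums), residue-pair aggregation
(signed scalar sums, or exact vector sums reconstructed from coordinates),
thresholded force networks and PCA over force time series complete the
toolbox.  A pair absent from a sparse matrix always counts as exact zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import (
    ForceTrajectory,
    InteractionType,
    PairKey,
    PairwiseForceMatrix,
    Topology,
    TrajectoryFrame,
    pair_universe,
)

__all__ = [
    "AveragedForceMatrix",
    "StandardErrorMatrix",
    "DeltaForceMap",
    "ResidueForceMatrix",
    "PCAResult",
    "average_trajectory",
    "standard_error",
    "combined_standard_error",
    "delta_force",
    "normalize_delta",
    "atom_projection",
    "residue_sum_scalar",
    "residue_sum_vector",
    "extract_network",
    "pca_forces",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edges_tsv",
    "write_edges_dot",
    "to_networkx",
]


@dataclass
class AveragedForceMatrix:
    """Per-pair mean and population variance over the blocks of one run."""

    entries: dict[PairKey, tuple[float, float]]  # (mean, variance)
    n_blocks: int
    n_atoms: int

    def means(self) -> dict[PairKey, float]:
        return {k: mv[0] for k, mv in self.entries.items()}


@dataclass
class StandardErrorMatrix:
    """Cross-run standard error ε per pair: sd of run means (ddof=1)/√n_runs."""

    entries: dict[PairKey, float]
    n_runs: int
    n_atoms: int


@dataclass
class DeltaForceMap:
    """Sparse per-pair force change; kind is 'raw', 'noise' or 'normalized'."""

    entries: dict[PairKey, float]
    kind: str
    n_atoms: int
    #: pairs dropped by normalize_delta because ε was zero there
    n_dropped: int = 0

    def combined(self) -> dict[tuple[int, int], float]:
        out: dict[tuple[int, int], float] = {}
        for (i, j, _t), v in self.entries.items():
            out[(i, j)] = out.get((i, j), 0.0) + v
        return out


@dataclass
class ResidueForceMatrix:
    """Residue-pair aggregation; scalar mode maps (u, v) → force, vector mode
    maps (u, v) → (x, y, z, norm)."""

    entries: dict[tuple[int, int], float] | dict[tuple[int, int], np.ndarray]
    mode: str  # "scalar" | "vector"
    n_residues: int
    time: float | None = None


def average_trajectory(traj: ForceTrajectory, combine_types: bool = False) -> AveragedForceMatrix:
    """Time-average a force trajectory: per-pair mean and population variance.

    A pair absent from a block contributes zero to both moments for that
    block.  ``combine_types`` first sums the interaction types of each pair
    within every block (the result is keyed with type COMBINED).
    """
    if len(traj.blocks) == 0:
        raise ValueError("cannot average an empty force trajectory")
    n = len(traj.blocks)
    s1: dict[PairKey, float] = {}
    s2: dict[PairKey, float] = {}
    for block in traj.blocks:
        items: Iterable[tuple[PairKey, float]]
        if combine_types:
            items = (
                ((i, j, InteractionType.COMBINED), v) for (i, j), v in block.combined().items()
            )
        else:
            items = block.entries.items()
        for key, v in items:
            s1[key] = s1.get(key, 0.0) + v
            s2[key] = s2.get(key, 0.0) + v * v
    entries = {}
    for key, tot in s1.items():
        mean = tot / n
        var = max(0.0, s2[key] / n - mean * mean)
        entries[key] = (mean, var)
    return AveragedForceMatrix(entries=entries, n_blocks=n, n_atoms=traj.n_atoms)


def standard_error(run_means: Sequence[AveragedForceMatrix]) -> StandardErrorMatrix:
    """Standard error ε of the mean force across independent runs.

    For every pair, ε = sd(run means, ddof=1)/√n_runs; runs missing a pair
    contribute a zero mean there.
    """
    if len(run_means) < 2:
        raise ValueError("standard_error requires at least 2 runs")
    n_atoms = run_means[0].n_atoms
    if any(r.n_atoms != n_atoms for r in run_means):
        raise ValueError("all runs must share the same atom count")
    keys: set[PairKey] = set()
    for r in run_means:
        keys.update(r.entries)
    n_runs = len(run_means)
    entries: dict[PairKey, float] = {}
    for key in keys:
        vals = np.array([r.entries.get(key, (0.0, 0.0))[0] for r in run_means])
        if np.all(vals == vals[0]):  # identical runs: exactly zero spread
            entries[key] = 0.0
        else:
            entries[key] = float(np.std(vals, ddof=1) / np.sqrt(n_runs))
    return StandardErrorMatrix(entries=entries, n_runs=n_runs, n_atoms=n_atoms)


def combined_standard_error(
    ref_eps: StandardErrorMatrix, pert_eps: StandardErrorMatrix
) -> StandardErrorMatrix:
    """Standard error of a *difference* of state means: √(ε_ref² + ε_pert²).

    Pooling the raw run means of both states into one spread would let a real
    signal inflate its own error estimate and suppress exactly the pairs that
    carry it; combining the within-state errors in quadrature avoids that.
    """
    if ref_eps.n_atoms != pert_eps.n_atoms:
        raise ValueError("atom-count mismatch between the two states")
    keys = set(ref_eps.entries) | set(pert_eps.entries)
    entries = {
        k: float(np.hypot(ref_eps.entries.get(k, 0.0), pert_eps.entries.get(k, 0.0)))
        for k in keys
    }
    return StandardErrorMatrix(
        entries=entries, n_runs=ref_eps.n_runs + pert_eps.n_runs, n_atoms=ref_eps.n_atoms
    )


def delta_force(
    ref: AveragedForceMatrix, pert: AveragedForceMatrix, kind: str = "raw"
) -> DeltaForceMap:
    """Per-pair signed force change ΔF = mean_pert − mean_ref.

    Pairs absent from one state use zero for that state; exact-zero
    differences are not stored.  Pass ``kind="noise"`` when both inputs are
    independent runs of the *same* state to build the null map ΔF_noise.
    """
    if ref.n_atoms != pert.n_atoms:
        raise ValueError(
            f"atom-count mismatch: ref has {ref.n_atoms}, pert has {pert.n_atoms}"
        )
    if kind not in ("raw", "noise"):
        raise ValueError("kind must be 'raw' or 'noise'")
    keys = set(ref.entries) | set(pert.entries)
    entries: dict[PairKey, float] = {}
    for key in keys:
        d = pert.entries.get(key, (0.0, 0.0))[0] - ref.entries.get(key, (0.0, 0.0))[0]
        if d != 0.0:
            entries[key] = d
    return DeltaForceMap(entries=entries, kind=kind, n_atoms=ref.n_atoms)


def normalize_delta(delta: DeltaForceMap, eps: StandardErrorMatrix) -> DeltaForceMap:
    """Δf = ΔF/ε per pair; pairs where ε = 0 (or is absent) are dropped.

    The number of dropped pairs is reported on the result (``n_dropped``).
    """
    if delta.kind != "raw":
        raise ValueError(f"normalize_delta expects a raw delta map, got kind={delta.kind!r}")
    entries: dict[PairKey, float] = {}
    dropped = 0
    for key, d in delta.entries.items():
        e = eps.entries.get(key, 0.0)
        if e > 0.0:
            entries[key] = d / e
        else:
            dropped += 1
    return DeltaForceMap(entries=entries, kind="normalized", n_atoms=delta.n_atoms, n_dropped=dropped)


def atom_projection(delta: DeltaForceMap, n_atoms: int | None = None) -> np.ndarray:
    """Project a pair map onto atoms: ΔF_j = Σ_i |ΔF_ij| (absolute column sum).

    Absolute values prevent opposite-sign pair changes from cancelling; the
    result is the per-atom mechanical coupling and is always ≥ 0.
    """
    n = n_atoms if n_atoms is not None else delta.n_atoms
    out = np.zeros(n)
    for (i, j, _t), v in delta.entries.items():
        out[i] += abs(v)
        out[j] += abs(v)
    return out


def _iter_values(matrix: AveragedForceMatrix | DeltaForceMap):
    if isinstance(matrix, AveragedForceMatrix):
        return ((k, mv[0]) for k, mv in matrix.entries.items())
    return iter(matrix.entries.items())


def residue_sum_scalar(
    matrix: AveragedForceMatrix | DeltaForceMap,
    topology: Topology,
    types: Iterable[InteractionType] | None = None,
    atom_filter: Callable[[int], bool] | None = None,
    use_abs: bool = False,
    include_intra: bool = False,
) -> ResidueForceMatrix:
    """Sum pair forces into residue pairs: F_uv = Σ_{i∈u, j∈v} F_ij.

    Signed summation by default (set ``use_abs`` to sum magnitudes).  The
    entry set can be restricted to interaction ``types`` and to atoms passing
    ``atom_filter`` (both pair atoms must pass).  Intra-residue (u = v)
    contributions are excluded unless ``include_intra`` is set.
    """
    res = topology.residue_of()
    tset = set(types) if types is not None else None
    entries: dict[tuple[int, int], float] = {}
    for (i, j, t), v in _iter_values(matrix):
        if tset is not None and t not in tset:
            continue
        if atom_filter is not None and not (atom_filter(i) and atom_filter(j)):
            continue
        u, w = int(res[i]), int(res[j])
        if u == w and not include_intra:
            continue
        key = (u, w) if u <= w else (w, u)
        entries[key] = entries.get(key, 0.0) + (abs(v) if use_abs else v)
    return ResidueForceMatrix(entries=entries, mode="scalar", n_residues=topology.n_residues)


def _match_frames(
    blocks: Sequence[PairwiseForceMatrix], frames: Sequence[TrajectoryFrame]
) -> list[TrajectoryFrame]:
    """Match one coordinate frame per force block by time, within half the
    block spacing."""
    if not frames:
        raise ValueError("no coordinate frames supplied")
    btimes = [b.time for b in blocks]
    # half the block spacing; a single block falls back to the 1 ps frame unit
    spacing = min((t2 - t1 for t1, t2 in zip(btimes, btimes[1:]) if t2 > t1), default=1.0)
    tol = spacing / 2.0
    out = []
    for b in blocks:
        best = min(frames, key=lambda fr: abs(fr.time - b.time))
        if abs(best.time - b.time) > tol:
            raise ValueError(
                f"no coordinate frame within {tol} ps of force block at t={b.time} ps"
            )
        out.append(best)
    return out


def residue_sum_vector(
    traj: ForceTrajectory,
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    types: Iterable[InteractionType] | None = None,
    atom_filter: Callable[[int], bool] | None = None,
    include_intra: bool = False,
) -> list[ResidueForceMatrix]:
    """Per-block residue-pair force *vectors* reconstructed from coordinates.

    Each scalar pair force is turned back into a vector F_ij·û_ij, where
    û_ij points from atom j to atom i — the force exerted on i, so that a
    positive (repulsive) scalar pushes i away from j — and the member-pair
    vectors are summed per residue pair.  Entries are (x, y, z, norm).
    """
    matched = _match_frames(traj.blocks, frames)
    res = topology.residue_of()
    tset = set(types) if types is not None else None
    out: list[ResidueForceMatrix] = []
    for block, frame in zip(traj.blocks, matched):
        x = frame.coordinates
        acc: dict[tuple[int, int], np.ndarray] = {}
        for (i, j, t), v in block.entries.items():
            if tset is not None and t not in tset:
                continue
            if atom_filter is not None and not (atom_filter(i) and atom_filter(j)):
                continue
            u, w = int(res[i]), int(res[j])
            if u == w and not include_intra:
                continue
            d = x[i] - x[j]
            nd = np.linalg.norm(d)
            if nd == 0:
                continue
            vec = v * d / nd
            key = (u, w) if u <= w else (w, u)
            acc[key] = acc.get(key, 0.0) + vec
        entries = {
            k: np.array([v[0], v[1], v[2], np.linalg.norm(v)]) for k, v in acc.items()
        }
        out.append(
            ResidueForceMatrix(
                entries=entries, mode="vector", n_residues=topology.n_residues, time=block.time
            )
        )
    return out


def extract_network(
    data: DeltaForceMap | ResidueForceMatrix, cutoff: float
) -> list[tuple[int, int, float]]:
    """Edges (i, j, weight) for every pair with |value| strictly above cutoff.

    For pair maps the interaction types are summed (signed) per pair first;
    for vector-mode residue matrices the norm is thresholded and used as the
    (non-negative) weight.  Edges come sorted by (i, j).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if isinstance(data, DeltaForceMap):
        values = data.combined()
    elif data.mode == "vector":
        values = {k: float(v[3]) for k, v in data.entries.items()}
    else:
        values = dict(data.entries)
    return [(i, j, v) for (i, j), v in sorted(values.items()) if abs(v) > cutoff]


# ---------------------------------------------------------------------------
# PCA on force time series
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """PCA of blocks × pairs force data.

    components : (k, p) orthonormal loading vectors over pairs (rows).
    explained_variance : (k,) non-increasing variances (ddof = 1).
    scores : (n_blocks, k) projections of the centered observations.
    pair_labels : the p pair keys, in column order.
    """

    components: np.ndarray
    explained_variance: np.ndarray
    scores: np.ndarray
    pair_labels: list

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.explained_variance.sum()
        if tot == 0:
            return np.zeros_like(self.explained_variance)
        return self.explained_variance / tot


def _block_matrix(
    trajs: Sequence[ForceTrajectory],
    topology: Topology | None,
    level: str,
) -> tuple[np.ndarray, list]:
    blocks: list[PairwiseForceMatrix] = [b for tr in trajs for b in tr.blocks]
    if level == "atom_pair":
        labels = sorted({pair for tr in trajs for b in tr.blocks for pair in b.combined()})
        index = {k: c for c, k in enumerate(labels)}
        X = np.zeros((len(blocks), len(labels)))
        for r, b in enumerate(blocks):
            for pair, v in b.combined().items():
                X[r, index[pair]] = v
    elif level == "residue_pair":
        if topology is None:
            raise ValueError("residue_pair level requires a topology")
        res = topology.residue_of()
        agg: list[dict[tuple[int, int], float]] = []
        for b in blocks:
            d: dict[tuple[int, int], float] = {}
            for (i, j), v in b.combined().items():
                u, w = int(res[i]), int(res[j])
                if u == w:
                    continue
                key = (u, w) if u <= w else (w, u)
                d[key] = d.get(key, 0.0) + v
            agg.append(d)
        labels = sorted({k for d in agg for k in d})
        index = {k: c for c, k in enumerate(labels)}
        X = np.zeros((len(blocks), len(labels)))
        for r, d in enumerate(agg):
            for key, v in d.items():
                X[r, index[key]] = v
    else:
        raise ValueError(f"unknown level {level!r}")
    return X, labels


def pca_forces(
    trajs: ForceTrajectory | Sequence[ForceTrajectory],
    topology: Topology | None = None,
    level: str = "atom_pair",
) -> PCAResult:
    """Principal component analysis over force time series.

    Observations are the trajectory blocks (concatenated across runs),
    variables the pairs (interaction types summed; residue-aggregated first
    when ``level="residue_pair"``).  Columns are centered but not scaled —
    all variables share force units, and scaling would distort relative
    coupling strengths.  Deterministic component signs: the largest-magnitude
    loading of each component is made positive.
    """
    if isinstance(trajs, ForceTrajectory):
        trajs = [trajs]
    X, labels = _block_matrix(trajs, topology, level)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 blocks in total")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention
    for r in range(Vt.shape[0]):
        lead = np.argmax(np.abs(Vt[r]))
        if Vt[r, lead] < 0:
            Vt[r] = -Vt[r]
            U[:, r] = -U[:, r]
    explained = S**2 / (n - 1)
    scores = U * S
    return PCAResult(
        components=Vt, explained_variance=explained, scores=scores, pair_labels=labels
    )


# ---------------------------------------------------------------------------
# tabular text serialization (TSV) used by the CLI
# ---------------------------------------------------------------------------

_KINDS = {"averaged", "stderr", "delta"}


def write_matrix_tsv(
    obj: AveragedForceMatrix | StandardErrorMatrix | DeltaForceMap | ResidueForceMatrix,
    path: str | os.PathLike,
) -> None:
    """Write a sparse matrix as TSV with a small ``#`` header; full precision."""
    with open(path, "w") as fh:
        if isinstance(obj, AveragedForceMatrix):
            fh.write(f"# pairfda averaged\n# n_atoms {obj.n_atoms}\n# n_blocks {obj.n_blocks}\n")
            fh.write("# i\tj\ttype\tmean\tvariance\n")
            for (i, j, t), (m, v) in sorted(obj.entries.items()):
                fh.write(f"{i}\t{j}\t{InteractionType(t).name}\t{m:.17g}\t{v:.17g}\n")
        elif isinstance(obj, StandardErrorMatrix):
            fh.write(f"# pairfda stderr\n# n_atoms {obj.n_atoms}\n# n_runs {obj.n_runs}\n")
            fh.write("# i\tj\ttype\teps\n")
            for (i, j, t), e in sorted(obj.entries.items()):
                fh.write(f"{i}\t{j}\t{InteractionType(t).name}\t{e:.17g}\n")
        elif isinstance(obj, DeltaForceMap):
            fh.write(
                f"# pairfda delta\n# n_atoms {obj.n_atoms}\n# kind {obj.kind}\n"
                f"# n_dropped {obj.n_dropped}\n# i\tj\ttype\tvalue\n"
            )
            for (i, j, t), v in sorted(obj.entries.items()):
                fh.write(f"{i}\t{j}\t{InteractionType(t).name}\t{v:.17g}\n")
        elif isinstance(obj, ResidueForceMatrix):
            fh.write(f"# pairfda residues\n# n_residues {obj.n_residues}\n# mode {obj.mode}\n")
            if obj.mode == "scalar":
                fh.write("# u\tv\tvalue\n")
                for (u, v), f in sorted(obj.entries.items()):
                    fh.write(f"{u}\t{v}\t{f:.17g}\n")
            else:
                fh.write("# u\tv\tx\ty\tz\tnorm\n")
                for (u, v), vec in sorted(obj.entries.items()):
                    fh.write(
                        f"{u}\t{v}\t{vec[0]:.17g}\t{vec[1]:.17g}\t{vec[2]:.17g}\t{vec[3]:.17g}\n"
                    )
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__}")


def read_matrix_tsv(path: str | os.PathLike):
    """Inverse of :func:`write_matrix_tsv` (averaged / stderr / delta kinds)."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    kind = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                fields = line[1:].split()
                if fields and fields[0] == "pairfda" and len(fields) > 1:
                    kind = fields[1]
                elif len(fields) == 2:
                    meta[fields[0]] = fields[1]
                continue
            if line.strip():
                rows.append(line.split("\t"))
    if kind not in _KINDS:
        raise ValueError(f"{os.fspath(path)!r}: not a pairfda matrix TSV (kind={kind!r})")
    n_atoms = int(meta["n_atoms"])
    if kind == "averaged":
        entries = {
            (int(r[0]), int(r[1]), InteractionType[r[2]]): (float(r[3]), float(r[4]))
            for r in rows
        }
        return AveragedForceMatrix(entries=entries, n_blocks=int(meta["n_blocks"]), n_atoms=n_atoms)
    if kind == "stderr":
        entries = {(int(r[0]), int(r[1]), InteractionType[r[2]]): float(r[3]) for r in rows}
        return StandardErrorMatrix(entries=entries, n_runs=int(meta["n_runs"]), n_atoms=n_atoms)
    entries = {(int(r[0]), int(r[1]), InteractionType[r[2]]): float(r[3]) for r in rows}
    return DeltaForceMap(
        entries=entries,
        kind=meta.get("kind", "raw"),
        n_atoms=n_atoms,
        n_dropped=int(meta.get("n_dropped", 0)),
    )


def write_edges_tsv(edges: Sequence[tuple[int, int, float]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# node_i\tnode_j\tweight\n")
        for i, j, w in edges:
            fh.write(f"{i}\t{j}\t{w:.17g}\n")


def write_edges_dot(
    edges: Sequence[tuple[int, int, float]], path: str | os.PathLike, name: str = "fda"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"graph {name} {{\n")
        for i, j, w in edges:
            fh.write(f'  n{i} -- n{j} [weight="{w:.6g}", label="{w:.6g}"];\n')
        fh.write("}\n")


def to_networkx(edges: Sequence[tuple[int, int, float]]):
    """Edge list → networkx.Graph with 'weight' attributes (for downstream
    graph analysis; betweenness etc. are left to the caller)."""
    import networkx as nx

    g = nx.Graph()
    for i, j, w in edges:
        g.add_edge(i, j, weight=w)
    return g
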