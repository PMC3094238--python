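"""Statistics layer: averaging, cross-run error, ΔF/Δf, projections,
residue aggregation, networks and PCA."""

import numpy as np
import pytest

from pairfda import (
    AveragedForceMatrix,
    DeltaForceMap,
    ForceTrajectory,
    ForceTrajectoryHeader,
    InteractionType,
    PairwiseForceMatrix,
    TrajectoryFrame,
    ToySystemSpec,
    atom_projection,
    average_trajectory,
    build_system,
    delta_force,
    extract_network,
    normalize_delta,
    pca_forces,
    residue_sum_scalar,
    residue_sum_vector,
    standard_error,
)
from pairfda.analysis import read_matrix_tsv, write_matrix_tsv

IT = InteractionType


def _traj(n_atoms, blocks_entries, t0=0.0):
    blocks = [
        PairwiseForceMatrix(time=t0 + k, entries=dict(e)) for k, e in enumerate(blocks_entries)
    ]
    return ForceTrajectory(header=ForceTrajectoryHeader(n_atoms=n_atoms), blocks=blocks)


def _avg(n_atoms, means, n_blocks=2):
    return AveragedForceMatrix(
        entries={k: (v, 0.0) for k, v in means.items()}, n_blocks=n_blocks, n_atoms=n_atoms
    )


KEY = (0, 1, IT.COULOMB)


# -- averaging ----------------------------------------------------------------


def test_single_block_average_has_zero_variance():
    traj = _traj(3, [{KEY: 4.0}])
    avg = average_trajectory(traj)
    assert avg.entries[KEY] == (4.0, 0.0)
    assert avg.n_blocks == 1


def test_pair_absent_from_block_counts_as_zero():
    traj = _traj(3, [{KEY: 10.0}, {}])
    avg = average_trajectory(traj)
    mean, var = avg.entries[KEY]
    assert mean == 5.0 and var == 25.0  # population stats of {10, 0}


def test_average_matches_dense_oracle_on_random_trajectories():
    rng = np.random.default_rng(99)
    n_atoms, n_blocks = 6, 12
    pairs = [(i, j, t) for i in range(n_atoms) for j in range(i + 1, n_atoms) for t in (IT.BOND, IT.LJ)]
    dense = np.zeros((n_blocks, len(pairs)))
    blocks = []
    for b in range(n_blocks):
        entries = {}
        for c, key in enumerate(pairs):
            if rng.random() < 0.5:
                v = float(rng.normal())
                entries[key] = v
                dense[b, c] = v
        blocks.append(entries)
    avg = average_trajectory(_traj(n_atoms, blocks))
    for c, key in enumerate(pairs):
        if key in avg.entries:
            mean, var = avg.entries[key]
            assert mean == pytest.approx(dense[:, c].mean(), abs=1e-12)
            assert var == pytest.approx(dense[:, c].var(), abs=1e-12)


def test_combine_types_sums_before_averaging():
    traj = _traj(3, [{(0, 1, IT.COULOMB): 2.0, (0, 1, IT.LJ): 3.0}])
    avg = average_trajectory(traj, combine_types=True)
    assert avg.entries == {(0, 1, IT.COMBINED): (5.0, 0.0)}


def test_averaging_linearity_over_concatenation():
    rng = np.random.default_rng(1)
    blocks = [{KEY: float(rng.normal()), (1, 2, IT.BOND): float(rng.normal())} for _ in range(4)]
    t1, t2 = _traj(3, blocks[:2]), _traj(3, blocks[2:])
    whole = average_trajectory(_traj(3, blocks))
    a1, a2 = average_trajectory(t1), average_trajectory(t2)
    for key in whole.entries:
        assert whole.entries[key][0] == pytest.approx(
            (a1.entries[key][0] + a2.entries[key][0]) / 2, abs=1e-14
        )


def test_empty_trajectory_cannot_be_averaged():
    with pytest.raises(ValueError):
        average_trajectory(_traj(3, []))


# -- standard error -----------------------------------------------------------


def test_identical_runs_have_zero_standard_error():
    runs = [_avg(3, {KEY: 7.0}), _avg(3, {KEY: 7.0}), _avg(3, {KEY: 7.0})]
    eps = standard_error(runs)
    assert eps.entries[KEY] == 0.0
    assert eps.n_runs == 3


def test_two_run_standard_error_value():
    eps = standard_error([_avg(3, {KEY: 8.0}), _avg(3, {KEY: 12.0})])
    # sd({8,12}, ddof=1)/√2 = 2.828.../1.414... = 2.0
    assert eps.entries[KEY] == pytest.approx(2.0)


def test_standard_error_matches_textbook_formula_on_random_input():
    rng = np.random.default_rng(8)
    vals = rng.normal(size=5)
    runs = [_avg(3, {KEY: float(v)}) for v in vals]
    eps = standard_error(runs)
    assert eps.entries[KEY] == pytest.approx(np.std(vals, ddof=1) / np.sqrt(5))


def test_standard_error_requires_two_runs():
    with pytest.raises(ValueError):
        standard_error([_avg(3, {KEY: 1.0})])


# -- delta maps ---------------------------------------------------------------


def test_delta_of_identical_states_is_empty():
    a = _avg(3, {KEY: 10.0})
    assert delta_force(a, a).entries == {}


def test_delta_is_signed_subtraction_with_absent_as_zero():
    d = delta_force(_avg(3, {KEY: 10.0}), _avg(3, {KEY: 14.0, (1, 2, IT.LJ): 3.0}))
    assert d.entries[KEY] == 4.0
    assert d.entries[(1, 2, IT.LJ)] == 3.0


def test_delta_antisymmetry():
    rng = np.random.default_rng(4)
    a = _avg(4, {(i, j, IT.LJ): float(rng.normal()) for i in range(3) for j in range(i + 1, 4)})
    b = _avg(4, {(i, j, IT.LJ): float(rng.normal()) for i in range(3) for j in range(i + 1, 4)})
    ab, ba = delta_force(a, b), delta_force(b, a)
    assert set(ab.entries) == set(ba.entries)
    for k in ab.entries:
        assert ab.entries[k] == -ba.entries[k]


def test_delta_atom_count_mismatch():
    with pytest.raises(ValueError):
        delta_force(_avg(3, {KEY: 1.0}), _avg(4, {KEY: 1.0}))


def test_normalize_divides_and_drops_zero_eps():
    d = DeltaForceMap(entries={KEY: 4.0, (1, 2, IT.LJ): 4.0}, kind="raw", n_atoms=3)
    eps = standard_error([_avg(3, {KEY: 8.0}), _avg(3, {KEY: 12.0})])  # ε=2 for KEY only
    norm = normalize_delta(d, eps)
    assert norm.kind == "normalized"
    assert norm.entries == {KEY: 2.0}
    assert norm.n_dropped == 1


# -- atom projection ----------------------------------------------------------


def test_projection_is_absolute_column_sum():
    d = DeltaForceMap(
        entries={(0, 1, IT.LJ): 3.0, (0, 2, IT.LJ): -4.0}, kind="raw", n_atoms=3
    )
    np.testing.assert_allclose(atom_projection(d), [7.0, 3.0, 4.0])


def test_projection_empty_map_is_zero_and_sign_flip_invariant():
    empty = DeltaForceMap(entries={}, kind="raw", n_atoms=4)
    assert atom_projection(empty).sum() == 0.0
    rng = np.random.default_rng(2)
    entries = {(i, j, IT.COULOMB): float(rng.normal()) for i in range(3) for j in range(i + 1, 4)}
    d = DeltaForceMap(entries=entries, kind="raw", n_atoms=4)
    flipped = DeltaForceMap(
        entries={k: -v for k, v in entries.items()}, kind="raw", n_atoms=4
    )
    np.testing.assert_allclose(atom_projection(d), atom_projection(flipped))


# -- residue aggregation ------------------------------------------------------


@pytest.fixture
def peptide():
    return build_system(ToySystemSpec(kind="two_residue_peptide"))


def test_residue_scalar_signed_sum_and_type_filter(peptide):
    topo, _ = peptide
    d = DeltaForceMap(
        entries={(0, 3, IT.COULOMB): 5.0, (1, 4, IT.LJ): -3.0, (0, 1, IT.BOND): 99.0},
        kind="raw",
        n_atoms=topo.n_atoms,
    )
    res = residue_sum_scalar(d, topo)
    assert res.entries == {(0, 1): 2.0}  # intra-residue (0,1) excluded, 5-3
    only_c = residue_sum_scalar(d, topo, types={IT.COULOMB})
    assert only_c.entries == {(0, 1): 5.0}
    absolute = residue_sum_scalar(d, topo, use_abs=True)
    assert absolute.entries == {(0, 1): 8.0}


def test_residue_vector_sum_collinear_and_orthogonal(peptide):
    topo, _ = peptide
    n = topo.n_atoms
    base = np.zeros((n, 3))
    # atoms 0,1 belong to residue 0; atoms 3,4 to residue 1; others far away
    base[0] = [0, 0, 0]
    base[1] = [0, 0.5, 0]
    base[2] = [0, 5, 5]
    base[3] = [1, 0, 0]  # attractive (0,3) force on atom 0 points along +x
    base[5] = [5, 5, 0]
    collinear = base.copy()
    collinear[4] = [1, 0.5, 0]  # (1,4) force also along +x
    traj = _traj(n, [{(0, 3, IT.COULOMB): -3.0, (1, 4, IT.COULOMB): -3.0}])
    vec = residue_sum_vector(traj, [TrajectoryFrame(0.0, collinear)], topo)[0].entries[(0, 1)]
    assert vec[3] == pytest.approx(6.0)
    orthogonal = base.copy()
    orthogonal[4] = [0, 1.5, 0]  # (1,4) force along +y
    traj2 = _traj(n, [{(0, 3, IT.COULOMB): -3.0, (1, 4, IT.COULOMB): -4.0}])
    vec2 = residue_sum_vector(traj2, [TrajectoryFrame(0.0, orthogonal)], topo)[0].entries[(0, 1)]
    assert vec2[3] == pytest.approx(5.0)


def test_residue_vector_norm_bounded_by_scalar_abs_sum(peptide):
    topo, coords = peptide
    rng = np.random.default_rng(6)
    frame = TrajectoryFrame(0.0, coords + rng.normal(0, 0.02, coords.shape))
    entries = {
        (i, j, IT.COULOMB): float(rng.normal())
        for i in range(topo.n_atoms)
        for j in range(i + 1, topo.n_atoms)
    }
    traj = _traj(topo.n_atoms, [entries])
    vec = residue_sum_vector(traj, [frame], topo)[0]
    d = DeltaForceMap(entries=entries, kind="raw", n_atoms=topo.n_atoms)
    abs_sum = residue_sum_scalar(d, topo, use_abs=True)
    for key, v in vec.entries.items():
        assert v[3] <= abs_sum.entries[key] + 1e-12
        assert v[3] == pytest.approx(np.linalg.norm(v[:3]), rel=1e-12)


def test_residue_vector_requires_matching_frame(peptide):
    topo, coords = peptide
    traj = _traj(topo.n_atoms, [{(0, 3, IT.COULOMB): 1.0}], t0=100.0)
    with pytest.raises(ValueError, match="frame"):
        residue_sum_vector(traj, [TrajectoryFrame(0.0, coords)], topo)


# -- network extraction -------------------------------------------------------


def test_network_thresholding_is_strict_and_sorted():
    d = DeltaForceMap(
        entries={(0, 1, IT.LJ): -5.0, (1, 2, IT.LJ): 2.0, (0, 2, IT.LJ): 3.0},
        kind="raw",
        n_atoms=3,
    )
    assert extract_network(d, 3.0) == [(0, 1, -5.0)]  # |3.0| not > 3.0
    assert extract_network(d, 10.0) == []
    assert extract_network(d, 0.0) == [(0, 1, -5.0), (0, 2, 3.0), (1, 2, 2.0)]


def test_network_combines_types_per_pair():
    d = DeltaForceMap(
        entries={(0, 1, IT.LJ): 2.0, (0, 1, IT.COULOMB): 2.5}, kind="raw", n_atoms=2
    )
    assert extract_network(d, 4.0) == [(0, 1, 4.5)]


# -- PCA ----------------------------------------------------------------------


def test_pca_identical_blocks_have_zero_variance():
    blocks = [{KEY: 2.0, (1, 2, IT.LJ): -1.0}] * 4
    res = pca_forces(_traj(3, blocks))
    np.testing.assert_allclose(res.explained_variance, 0.0, atol=1e-24)


def test_pca_rank_one_antisymmetric_mode():
    rng = np.random.default_rng(3)
    blocks = []
    for _ in range(40):
        x = float(rng.normal())
        blocks.append({(0, 1, IT.LJ): x, (1, 2, IT.LJ): -x})
    res = pca_forces(_traj(3, blocks))
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)
    np.testing.assert_allclose(
        np.abs(res.components[0]), [1 / np.sqrt(2)] * 2, rtol=1e-10
    )
    assert res.components[0][0] * res.components[0][1] < 0  # (1,−1)/√2 pattern


def test_pca_recovers_planted_correlated_mode():
    rng = np.random.default_rng(12)
    pairs = [(i, i + 1, IT.LJ) for i in range(9)]
    support = np.zeros(9)
    support[[1, 4, 7]] = [1.0, -1.0, 1.0]
    support /= np.linalg.norm(support)
    blocks = []
    for _ in range(200):
        z = rng.normal() * 10.0  # strong common mode
        noise = rng.normal(size=9) * 0.1
        vals = z * support + noise
        blocks.append({p: float(v) for p, v in zip(pairs, vals)})
    res = pca_forces(_traj(10, blocks))
    loading = res.components[0]
    cos = abs(loading @ support)
    assert cos > 0.99


def test_pca_variance_conservation_and_orthonormality():
    rng = np.random.default_rng(21)
    blocks = [
        {(i, j, IT.COULOMB): float(rng.normal()) for i in range(4) for j in range(i + 1, 5)}
        for _ in range(15)
    ]
    traj = _traj(5, blocks)
    res = pca_forces(traj)
    X = np.array([[b[k] for k in sorted(b)] for b in blocks])
    total_var = X.var(axis=0, ddof=1).sum()
    assert res.explained_variance.sum() == pytest.approx(total_var, rel=1e-8)
    gram = res.components @ res.components.T
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
    assert np.all(np.diff(res.explained_variance) <= 1e-12)


def test_pca_residue_level_aggregates_pairs(peptide):
    topo, _ = peptide
    rng = np.random.default_rng(9)
    blocks = []
    for _ in range(10):
        blocks.append(
            {
                (0, 3, IT.COULOMB): float(rng.normal()),
                (1, 4, IT.COULOMB): float(rng.normal()),
                (0, 1, IT.BOND): float(rng.normal()),  # intra-residue, dropped
            }
        )
    res = pca_forces(_traj(topo.n_atoms, blocks), topology=topo, level="residue_pair")
    assert res.pair_labels == [(0, 1)]


def test_pca_requires_two_blocks():
    with pytest.raises(ValueError):
        pca_forces(_traj(3, [{KEY: 1.0}]))


# -- TSV round trips ----------------------------------------------------------


def test_matrix_tsv_round_trip(tmp_path):
    avg = AveragedForceMatrix(entries={KEY: (1.5, 0.25)}, n_blocks=4, n_atoms=3)
    eps = standard_error([_avg(3, {KEY: 8.0}), _avg(3, {KEY: 12.0})])
    d = DeltaForceMap(entries={KEY: -0.125}, kind="noise", n_atoms=3, n_dropped=2)
    for obj in (avg, eps, d):
        p = tmp_path / "m.tsv"
        write_matrix_tsv(obj, p)
        back = read_matrix_tsv(p)
        assert back.entries == obj.entries
        assert back.n_atoms == obj.n_atoms
    assert read_matrix_tsv(p).kind == "noise"
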