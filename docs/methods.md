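# Methods

## Pair-wise forces as the observable

`pairfda` post-processes coordinate trajectories: for each frame it
evaluates every force-field term and records, per atom pair and interaction
type, a *signed scalar* force.  Storing scalars rather than vectors is what
makes time averaging meaningful — global rotation and translation of the
molecule would scramble vector averages, while the scalar norm along the
pair axis is frame-invariant.  The sign keeps the physics: **positive =
repulsive** (the interaction pushes the pair apart), negative = attractive.
This convention is arbitrary but must be fixed for any two datasets to be
comparable; it is applied consistently in the engine, the vector
reconstruction (û<sub>ij</sub> points from j to i, so a positive scalar
pushes i away from j) and the analysis layer.

Atom-wise total forces are deliberately *not* the observable: they average
to zero in equilibrium and carry no information about transmitted strain.
The static-chain test makes this concrete: a chain in mechanical balance
under terminal tension T has zero net force on every atom, yet every bond's
pair force equals −T.

## Force-field terms and the pairwise approximation

Two-body terms are exact:

| term | potential | pair force (−dV/dr) |
|---|---|---|
| bond | ½k<sub>b</sub>(r−b₀)² | −k<sub>b</sub>(r−b₀) |
| Coulomb | f<sub>elec</sub>q<sub>i</sub>q<sub>j</sub>/r | f<sub>elec</sub>q<sub>i</sub>q<sub>j</sub>/r² |
| Lennard-Jones | 4ε[(σ/r)¹²−(σ/r)⁶] | 4ε(12σ¹²/r¹³ − 6σ⁶/r⁷) |

with f<sub>elec</sub> = 138.935458 kJ·mol⁻¹·nm·e⁻².  Coulomb is plainly
truncated at the cutoff (default 1.0 nm) with no reaction field, switching
or lattice-sum correction: beyond ~1 nm the potential is flat enough that
pair-force *changes* there are negligible, and lattice-sum electrostatics
has no pair decomposition.  Lennard-Jones parameters combine by
Lorentz–Berthelot rules (arithmetic σ, geometric ε).  Pairs listed in the
topology's exclusions never receive non-bonded entries; any pair *not*
excluded interacts at full strength (no 1-4 scaling — a deliberate
simplification relative to common biomolecular force fields, where 1-4
terms are scaled).

Multi-body terms are reduced to a single pair.  For an angle i–j–k the full
analytic atomic forces of V = ½k<sub>θ</sub>(θ−θ₀)² are computed, then
projected onto the i–k axis and symmetrized:

  F<sub>ik</sub> = ½(F<sub>i</sub>·û<sub>ki</sub> + F<sub>k</sub>·û<sub>ik</sub>)

and analogously i–l for a proper dihedral V = k<sub>φ</sub>(1+cos(nφ−φ<sub>s</sub>)).
The symmetrization makes the scalar invariant under relabelling
(i,j,k) ↔ (k,j,i); the projections of F<sub>i</sub> and F<sub>k</sub> differ
in general, and no principled reason singles out either atom.  The forces
on the middle atoms (j; j,k) are discarded — the decomposition is an
approximation that keeps the pair representation at the cost of the full
three/four-body force.  Improper dihedrals have no natural end-atom pair
and are not supported.  Geometries where the angle or torsion gradient is
undefined (|sin| < 1e-10 of the relevant angle) are skipped with a warning
rather than failing the frame; a collinear chain at its equilibrium is the
canonical case, and the skipped terms contribute exactly zero force there.

Dihedral atomic forces use the standard torsion-gradient formulas on the
plane normals m = r<sub>ij</sub>×r<sub>kj</sub>, n = r<sub>kj</sub>×r<sub>kl</sub>;
every kernel is validated against central-difference differentiation
(h = 1e-6 nm) of an independently restated potential, to 1e-5 relative.

## Sparse storage and averaging

Per frame (or per averaging interval) forces live in a sparse map
(i < j, type) → value.  Exact zeros are not stored, and *only* exact zeros
are pruned — any magnitude threshold would break the linearity of interval
averaging.  An absent pair therefore always means "exactly zero", which is
also the convention in every downstream subtraction and average.

The engine can average `output_interval` consecutive frames into one stored
block (arithmetic mean, absent-in-frame = 0; block time = first frame's
time; a trailing partial interval is averaged over its actual length).

On disk a force trajectory is a little-endian binary stream:
header (`FDA1`, u32 version, u32 n_atoms, u8 syntax mode), then per block
f64 time, u32 entry count, and per entry a u64 packed index i·N+j, f64
force, u8 type code (BOND=1, ANGLE=2, DIHEDRAL=3, COULOMB=4, LJ=5).
Entries are written sorted by (i, j, type), which makes serialization
byte-reproducible.  The ASCII dump prints one line per entry at 17
significant digits (full float64 round trip) plus one `# block` marker per
block so empty blocks survive the text round trip.  In the dense-matrix
export the classic triangle convention is reproduced: LJ in the upper
triangle, Coulomb in the lower, bonded types symmetric.

## Statistics

With reference and perturbed states each sampled by several independent
runs:

- run average: per-pair mean and *population* variance over that run's
  blocks (the blocks of one run are the population actually averaged);
- cross-run standard error: ε = sd(run means, ddof=1)/√n — sample
  statistics, because independent runs are few;
- ΔF = pert − ref per pair, signed; the same operation on two reference
  runs yields ΔF<sup>noise</sup>, the empirical null;
- Δf = ΔF/ε.  For the ε of a *difference* of state means the two states'
  standard errors are combined in quadrature
  (`combined_standard_error`): pooling the raw run means of both states
  would let a genuine signal inflate its own error estimate and suppress
  exactly the pairs that carry it.  Pairs with ε = 0 are dropped and
  counted, never divided.
- atom projection ΔF<sub>j</sub> = Σ|ΔF<sub>ij</sub>|: absolute values stop
  opposite-sign changes from cancelling; the result is the per-atom
  mechanical coupling, exportable as PDB b-factors (columns 61–66 only,
  optional min–max scaling onto [0, 99.99]).
- residue aggregation: signed scalar sums F<sub>uv</sub> = ΣF<sub>ij</sub>
  (with an optional magnitude mode), or exact per-block force *vectors*
  F<sub>ij</sub>·û<sub>ij</sub> reconstructed from a time-matched coordinate
  frame (matched within half a block interval).  Intra-residue pairs are
  excluded by default — inter-residue coupling is the object of interest —
  and re-enabled by a flag.  Summing signed scalars across differently
  oriented pairs is itself an approximation; the vector mode is the exact
  alternative.
- networks: edges wherever |value| > cutoff, strictly; weights keep their
  sign; deterministic (i, j) ordering.
- PCA: observations are blocks (concatenated across runs), variables are
  pairs (types summed; residue-aggregated first at residue level), columns
  centered but *not* scaled — all variables share force units and scaling
  would distort relative coupling strengths.  Computed by SVD; component
  signs are fixed by making each component's largest-magnitude loading
  positive, so results are reproducible run to run.

## Synthetic systems

The generator produces topology + equilibrium pairs whose neutral defaults
are exact stationary points of the implemented potential (verified to
< 1e-8 kJ·mol⁻¹·nm⁻¹ net atomic force): an LJ dimer at 2^(1/6)σ, linear
chains (collinear, θ₀ = π), a bent triple, a torsional quad and a
two-residue peptide built as planar zig-zags sitting at b₀/θ₀/φ = π.
Defaults: b₀ = 0.15 nm, k<sub>b</sub> = 1e5 kJ·mol⁻¹·nm⁻²,
θ₀ ≈ 109.47°, k<sub>θ</sub> = 400 kJ·mol⁻¹·rad⁻², k<sub>φ</sub> = 5
kJ·mol⁻¹ (n = 3, φ<sub>s</sub> = 0), σ = 0.3 nm, ε = 0, charges 0 — bonded
constants in the range of united-atom carbon chains; non-bonded terms are
off unless a system switches them on (the charged dimer, chains with the
`charge` parameter alternating ±q).  Such systems are then deliberately
*not* force-free at the reference geometry.

Sampling is i.i.d. isotropic Gaussian jitter about the equilibrium, not MD
integration: the engine is agnostic to how frames were produced, and jitter
reproduces the one statistical feature the analysis layer needs —
fluctuating per-frame forces with well-defined nonzero pair means.  It does
**not** reproduce time correlation, Boltzmann-weighted anharmonic sampling,
solvent damping or conformational transitions, so passing tests demonstrate
the correctness of the machinery, not convergence behaviour on real
trajectories.  σ = 0 reproduces the equilibrium exactly; a fixed seed fixes
every frame.

State pairs for ΔF experiments share everything except the stated
perturbation: a charge increment on one atom, a bond-length change, or an
external terminal tension whose stretched equilibrium is re-solved
numerically (`scipy.optimize.root` on the atomic positions, so the result
stays correct when non-bonded terms act along the chain).

The validation experiments use desk-scale sizes chosen once: 1000 random
kernel draws, a 20-atom random two-body system, a 10-atom chain under
T = 120 kJ·mol⁻¹·nm⁻¹, and a charge-perturbation experiment of 3 + 3 runs
× 15 frames of an 8-atom chain (±0.25 e alternating, +0.5 e on atom 4,
σ = 0.005 nm jitter).  These sizes give large detection margins (signal Δf
≈ 40–70× the noise 95th percentile) while keeping the whole suite in
seconds.

## Numerical choices and degenerate inputs

- degeneracy threshold |sin| < 1e-10 for angle/torsion gradients; skipped
  terms warn and contribute nothing;
- ε = 0 is treated exactly (identical run means short-circuit to zero, so
  "identical runs → ε = 0" holds despite floating-point re-summation);
- min–max b-factor scaling of an all-equal vector maps to 0;
- cutoff comparison is r ≤ cutoff; enlarging the cutoff only adds entries;
- all atom and residue indices are 0-based internally; 1-based numbering
  exists only inside PDB/GRO text.

## Limitations

No periodic boundary conditions or minimum-image convention (toy systems
are non-periodic); no lattice-sum electrostatics, improper dihedrals,
Urey–Bradley/CMAP terms or virtual sites; no 1-4 scaling; no binary
XTC/TRR/DCD trajectory input; no time-resolved (windowed) analysis — the
statistics assume converged time averages and will not be meaningful for
systems undergoing conformational transitions on the sampling timescale.
Byte compatibility with other force-trajectory layouts is not promised; the
format here is self-describing and fully specified above.
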