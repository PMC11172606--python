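# Methods

## The model

`pacsab` simulates small protein solutions with a coarse-grained model
that keeps the backbone atomistic — particles N, H(amide), CA, C(carbonyl)
and O per residue — and lumps each side chain into a single bead at the
side-chain heavy-atom centroid (glycine has no bead, proline no amide H).
The atomistic backbone exists for one reason: backbone hydrogen bonding,
which dominates the secondary-structure content of disordered-protein
ensembles, is treated with an explicit directional term rather than
absorbed into bead parameters.

A solution is represented by two copies of one chain in a cubic box with
periodic boundary conditions. The box side follows from the target molar
concentration, `C = n / (N_A L^3)` with n = 2; 5 mM corresponds to an
87 A box and 0.5 mM to 188 A. Chains are limited to 200 residues (a
speed constraint; `allow_long=True` overrides).

## Potential energy

The nonbonded potential is a two-term pairwise decomposition per particle
pair,

    V(r_ij) = w_vdW * V_vdW(r_ij) + w_solv * V_solv(r_ij),

with the hydrophobicity weights `w_vdW` (attraction/packing) and `w_solv`
(implicit solvation) interpolated linearly in sequence separation between
a short-range plateau (|i-j| <= 4, more hydrophobic — disordered chains
form local helices) and a long-range plateau (|i-j| >= 8); intermolecular
pairs always use the long-range values. Raising `w_vdW` makes the force
field more hydrophobic; raising `w_solv` makes it less so.

* `V_vdW`: Lennard-Jones 12-6 with Lorentz-Berthelot combination. Bead
  parameters are pairwise-additive aggregates of the constituent
  side-chain heavy atoms: bead epsilon is the sum of atomic epsilons,
  bead sigma is the tabulated side-chain gyration radius plus a 2.5 A
  base radius.
* `V_solv`: a pairwise Gaussian solvent-exclusion term in the
  Lazaridis–Karplus spirit. Each particle carries a solvation reference
  energy dG (beads: Kyte–Doolittle hydropathy times `solv_scale`,
  positive = hydrophobic; backbone N and O mildly hydrophilic); a
  neighbour at distance r buries `exp(-((r-sigma_ij)/lambda)^2)` of the
  pair's summed dG, saturating inside the contact distance. Burial of
  hydrophilic particles is penalised, of hydrophobic ones rewarded.
  Electrostatics is not a separate term; its mean-field effect lives in
  the per-particle dG values.
* Hydrogen bonds: `E = eps_HB cos^2(theta_NHO) u(r_HO)` for theta > 90
  deg, where u is a 10-12 well with its minimum at 1.9 A, switched off
  smoothly by 4.5 A. The well depth is identical at every sequence
  separation. Donors are all amide N-H groups except the N-terminus and
  proline; acceptors are all carbonyl O; intramolecular pairs need
  |i-j| >= 2.
* Structure-based (Go) option: residue pairs with |i-j| >= 3 whose
  minimum heavy-atom distance in the reference structure is below 8 A
  get a 12-10 well of depth `eps_go` at the reference CA-CA distance
  (plus an SC-SC well where both residues have beads). Used to stabilise
  folded proteins; meaningless for disordered ones.
* Bonded terms: harmonic bonds, cosine-harmonic angles
  (`V = (k/2)(cos t - cos t0)^2`, chosen over the plain harmonic form
  because its gradient has no 1/sin singularity at collinear
  geometries), and `V = k (1 - cos(phi - phi0))` torsions restraining
  only peptide-bond planarity (omega), the carbonyl-O improper and the
  amide-H improper; phi/psi stay free. Equilibrium values are measured
  from the input structure at build time, so any valid input is a
  minimum of its own bonded terms; stiffnesses are global force-field
  parameters applied at evaluation time (a restart can change every
  force-field number without rebuilding the model).

All nonbonded terms are cut off at 10 A, multiplied by a C1 smoothstep
over the outermost 2 A (the LJ term is additionally shifted), so energies
and forces are continuous at the cutoff. 1-2 and 1-3 bonded pairs are
excluded; 1-4 pairs are scaled by 0.5.

### Parameter provenance

The published parameter tables of the original coarse-grained force field
this architecture follows are not reproduced here; every numeric default
in `ForceFieldParams` and the residue tables is a declared package value,
overridable through a key-value parameter file. The omega weights, well
depths and the solvation scale were balanced against the package's own
qualitative physics suite — the hydrophobic/hydrophilic association
contrast, helix melting under the unfolding preset, and fold retention
under the Go term — not against any published trajectory. Presets:

* `default` — the values in `ForceFieldParams`.
* `server_2024` — both vdW weights x 0.97: a 3% less hydrophobic force
  field, which raises the dissociation rate of transient dimers and so
  yields richer association statistics.
* `unfolding` — w_vdW x 0.5, w_solv x 2.0, eps_HB x 0.2: very
  hydrophilic with almost no hydrogen bonding; a ~10 ns run under this
  preset melts a folded input into a random coil to start a
  disordered-protein simulation.

## Dynamics

BAOAB Langevin integration at dt = 10 fs, T = 300 K, friction
gamma = 10 / ps. The friction is several-fold below water's, which is the
point of the implicit solvent: diffusion and conformational sampling are
much faster than in explicit solvent. (A yet lower friction samples
faster still, but in strongly cohesive aggregates the weakly damped light
particles accumulate energy in the stiffest local modes at this timestep;
gamma = 10 / ps is the value at which multi-ns aggregate trajectories are
reliably stable across seeds, and it is exposed in `SimulationConfig`.) Amide-hydrogen mass is repartitioned from the bonded
nitrogen (H 8, N 7 amu) so the N-H stretch and the hydrogen-bond well
stay below the stability limit at 10 fs.

Positions are integrated unwrapped; the minimum-image convention is
applied inside every nonbonded evaluation; saved frames re-wrap each
molecule rigidly around its CA centroid so analysis never sees a split
molecule. A run writes exactly `n_frames` frames (default 1000) at
spacing tF (>= 10 ps, an integer multiple of dt) regardless of length.
Velocities start from the Maxwell-Boltzmann distribution.

Nonbonded pairs come from a Verlet list with a 2 A skin, rebuilt by a
single O(N^2) scan whenever any particle has moved half a skin (N is at
most ~2500 particles, where cell structures gain nothing in the inner
loop; the public `build_neighbor_list` is a genuine cell-list
implementation). Pairs are iterated lexicographically and pairs between
the cutoff and the list cutoff contribute exact zeros, which makes a
Verlet-list run bit-identical to a brute-force-neighbor run, and the
Gaussian noise is consumed as one sequential stream, which makes a
checkpoint restart bit-identical to an uninterrupted run — for every
seed, by construction.

Random-coil starting structures are relaxed by a clamped steepest-descent
minimisation before dynamics; a displacement of more than 2 A in a single
step aborts the run with the step and particle identified (a checkpoint
is saved first if checkpointing is on).

## Synthetic fixtures

`make_polypeptide` builds ideal-geometry chains by internal-coordinate
extension (canonical bond lengths/angles; N-CA-C set to the tetrahedral
109.5 deg, which puts the helical rise at ~1.55 A/residue and the
O(i)...H(i+4) distance at 1.92 A, right at the hydrogen-bond optimum):
helix is (phi, psi) = (-57, -47) deg, extended (-120, 120) deg, and coil
samples the broad allowed Ramachandran basins with seeded clash
rejection. Only CB is generated for side chains, so beads sit exactly on
CB. `make_sequence_pair` returns matched 20-mers — hydrophilic
(S/Q/D/E/K, mean hydropathy < 0) and hydrophobic (L/V/F/I/A, > 0) — for
the aggregation contrast.

What the fixtures do **not** emulate: real side-chain rotamer packing
(one rigid bead), sequence-specific electrostatics and salt bridges,
proline/glycine backbone irregularity, or any experimentally derived
structure. Passing the qualitative suite therefore shows the model's
*directional* physics (hydrophobicity drives irreversible association;
hydrophilic chains stay monomeric; weakened hydrogen bonding plus
hydrophilic weights melt helices; native-contact wells preserve a fold),
not quantitative agreement with any particular protein.

## Analysis definitions

* Minimum intermolecular distance: minimum over all inter-molecule
  particle pairs under minimum image (a flag restricts to heavy
  particles).
* Contact maps: a residue pair counts once per frame when any
  inter-residue particle pair is under 6.5 A; intramolecular maps need
  |i-j| >= 3 and pool both molecules; the homodimer intermolecular map
  is symmetrised. Accumulation is additive over disjoint frame ranges.
* Rg: mass-weighted, per molecule per frame; the distribution uses 1 A
  bins from 0 to 1.5x the maximum observed value and integrates to 1.
* RMSD: Kabsch superposition (via scipy's rotation alignment) over
  backbone particles, matching the backbone-only trajectory export; the
  series is taken against frame 0 per molecule, the 2D matrix over
  strided frames. After independent superposition the triangle
  inequality can be violated; that is expected.
* Association events: hysteresis state machine on the minimum-distance
  trace, binding below 5 A and unbinding above 8 A, which suppresses
  threshold chatter. Bound fraction is the fraction of frames in the
  bound state.
* Collision time: tau = 1/(k C) with the diffusion-limited encounter
  rate k ~ 1e10 /s/M, giving ~200 ns at 0.5 mM — the scale of waiting
  time an explicit-solvent simulation of a 188 A water box cannot reach,
  and the reason the implicit-solvent model exists.

## Problem sizes used by the test suite and acceptance script

The qualitative experiments run at fixture scale, chosen as the smallest
sizes at which the three effects are unambiguous: the association
contrast uses the 20-mer pair at 10 mM (69 A box, ~240 particles, copies
placed in contact — 21 A centre offset, ~4.5 A surface separation — so
the seed-dependent diffusive search is factored out and only binding
behaviour differs) for 5 ns per sequence; the unfolding and
Go-restrained runs use the hydrophilic 16-mer S/E/K helix fixture for
6 ns and 5 ns respectively — all at dt = 10 fs with frames every 10 ps. Statistical checks use
a 24-particle 4-residue helix (equipartition, 1e5 steps at dt = 2 fs so
the kinetic-temperature discretisation bias stays well under the 3%
band) and a 100-particle ideal gas (overdamped displacement variance).

## Known limitations

* Pairwise-additive desolvation overcounts burial in dense aggregates
  (each particle can "lose" its solvation energy to many neighbours);
  the solvation scale is calibrated with this in mind, and aggregate
  interiors are denser than real protein cores.
* No explicit electrostatics: salt bridges and charge repulsion appear
  only through hydropathy averages.
* One bead per side chain cannot form specific, orientation-dependent
  side-chain contacts; binding interfaces are hydrophobicity-driven.
* The integrator choice, thermostat and all parameter values are this
  package's own declared decisions; no claim is made that they
  reproduce any published implementation's internals.
* Analyses treat exactly two molecules (the solution model); the
  single-molecule pathway supports conformational studies only.
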