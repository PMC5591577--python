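# Methods

`restfep` implements, at desk scale, the computational workflow used to
rank congeneric fragment inhibitors by relative binding free energy:
Metropolis Monte Carlo sampling of torsional and rigid-body degrees of
freedom, alchemical free-energy perturbation (FEP) over a lambda
ladder, and Hamiltonian replica exchange with solute tempering (REST)
with a flexible pocket residue included in the tempered region.  The
engine runs on deterministic reduced "pocket" models small enough that
every statistical estimate can be validated against quadrature oracles,
and ships benchmarking analytics for comparing computed rankings with
assay data.

## Potential energy model

The force field is a reduced OPLS-style model:

- **Torsions.** OPLS Fourier form
  `V(phi) = V1/2 (1 + cos phi) + V2/2 (1 - cos 2phi) + V3/2 (1 + cos 3phi)`,
  amplitudes in kcal/mol, angles in degrees on [0, 360).
- **Nonbonded.** Lennard-Jones 12-6 plus Coulomb with the constant
  332.06 kcal Å mol⁻¹ e⁻², geometric combination rules for both sigma
  and epsilon, 1-2/1-3 pairs excluded and 1-4 pairs scaled by 0.5 for
  both terms.  No cutoffs, no periodic boundary, no explicit solvent:
  systems are a few tens of atoms.
- **Rigid fragments.** Bond lengths and angles are frozen; a system is
  a set of rigid bodies joined by rotatable bonds, so the degrees of
  freedom are torsion angles and rigid-body coordinates.  This mirrors
  internal-coordinate Monte Carlo practice and keeps the oracle surface
  (1-D quadrature per torsion) exact.

Every energy is evaluated decomposed into solute–solute (`e_ss`),
solute–environment (`e_sw`) and environment–environment (`e_ww`)
classes, where "solute" means the REST hot region: the ligand plus the
designated flexible residue.  A pair belongs to `ss` if both atoms are
hot, `ww` if neither is, `sw` otherwise; a torsion is classed by the
majority region of its four atoms with the 2–2 tie going to `ss`.  The
`hot_residue_scope` switch (`full` default, `torsion_only`) narrows the
residue's tempering to its torsion term only, reclassifying its
nonbonded contacts as environment.

## Alchemical mutations

Single-topology maps carry endpoint charges, LJ parameters and torsion
amplitudes for the mutated sites only.  Parameters mix linearly in
lambda.  Atoms whose well depth vanishes at an endpoint automatically
use a separation-shifted soft-core LJ form: `r⁶` is replaced by
`r⁶ + alpha sigma⁶ lambda_v` with `alpha = 0.5` and `lambda_v` the
lambda-distance from the fully coupled endpoint, so both endpoints
reproduce the pure Hamiltonians exactly and the vanished particle
cannot produce a singularity.  Charges still mix linearly; because a
vanishing atom's charge goes to zero with its epsilon, the Coulomb term
stays finite in practice for the toy systems (a documented limitation
rather than a full soft-core electrostatics treatment).

## Sampling

One Metropolis chain proposes, per step, one move drawn from a weighted
mix: rigid-body translation (<= 0.15 Å) and rotation (<= 15°) of the
ligand, and single-torsion perturbations (<= 15°).  Torsion moves may
propose, with configurable probability (default 0.1), a large-angle
flip of ±120° or 180° — the proposal that lets rotamer wells
interconvert directly.  All proposals are symmetric.  Acceptance uses
`min(1, exp(-dE/kT))` with `k = 0.0019872 kcal mol⁻¹ K⁻¹` and the
default temperature 298.15 K; energy changes are computed incrementally
from only the interactions of moved atoms (checked against full
recomputation in the tests).

Rotations of a ligand inside a pocket are restricted to transverse
(tilt) axes.  The reduced model has no anchor chemistry holding the
outer ring, so free spinning about the pocket axis would carry the
substituent between binding modes without ever crossing the linker
torsion's barrier — an unphysical bypass of exactly the sampling
problem the package studies.  Free (unbound) ligands keep unrestricted
rotations.

Chains are seeded explicitly (`numpy` PCG64 with a per-chain stream
index); identical configuration and seed reproduce trajectories
bit-for-bit.  The first 20% of each run is discarded as equilibration
and frames are recorded on a fixed stride; both are configuration keys.

## REST

Replica m samples the scaled Hamiltonian
`E_m = r e_ss + sqrt(r) e_sw + e_ww` with `r = beta_m / beta_0 =
T_0 / T_m` (the REST2 scaling), so only hot-region barriers flatten
while the environment stays cold.  The default ladder is 6 replicas,
geometric effective temperatures from 298.15 K to 1200 K
(`r` down to 0.248), with configuration exchanges attempted every 100
steps on alternating even/odd neighbour pairs using
`Delta = beta_0 [E_m(x_n) - E_m(x_m) + E_n(x_m) - E_n(x_n)]`.
The `e_ww` terms cancel algebraically in `Delta` and are never formed.
Replica 0 (`r = 1`) is the physical ensemble; all estimators consume
its frames only.  With one replica the run is bit-identical to a plain
chain at the same seed.

## Free energy estimation

Windows sit on an ascending lambda schedule (default 11 uniform
values).  Each window simulates its interpolated Hamiltonian —
plain MC or REST — and records, per recorded physical-ensemble frame,
double-wide Zwanzig gaps `E(lambda_next) - E(lambda_i)` and
`E(lambda_prev) - E(lambda_i)`, evaluated over only the mutated
interactions.  Window increments use
`dG = -kT ln <exp(-dE/kT)>` with a log-sum-exp guard; the per-interval
estimate averages the forward estimate and the negated reverse
estimate, errors come from block averaging (10 contiguous blocks) and
combine in quadrature, and the forward/backward disagreement is
reported as hysteresis.  Null mutations give identically zero with zero
error.  Relative binding free energies close the thermodynamic cycle
`ddG = dG_mut(complex) - dG_mut(unbound ligand)`; the unbound leg is
the isolated ligand in vacuum with the same force field — the solvated
unbound state of a real calculation is out of scope, which shifts
absolute ddG values but not the engine's self-consistency, and the
benchmark statistics are offset-invariant anyway.

## The toy pocket

`make_pocket_complex` builds a deterministic reduced complex
(30 atoms): 14 Lennard-Jones cage sites on a jittered hemispherical
shell of radius 6.5 Å (the hydrophobic pocket, immobile), a three-site
side-chain rotor anchored to the cage rim with a 3-fold torsion chi
(V3 = 6 kcal/mol; the flexible pocket residue, region `HOT_RESIDUE`),
and a two-ring ligand along the pocket axis whose rings are joined by a
rotatable linker torsion phi (V1 = 0.4, V2 = 4.5 kcal/mol) carrying one
mutable substituent at the meta position of the buried ring.
Substituent identities H, F, Cl, Br and CH3 are synthetic
OPLS-flavoured parameter sets (sigma grows H < F < Cl < Br) defined in
`SUBSTITUENTS`; they are fixture definitions, not published force-field
values.  The rotor tip carries a small positive charge (+0.15 e) so
the halogenated substituents feel a rotamer-dependent electrostatic
contact: a longer-range coupling was needed because pure Lennard-Jones
mode contrasts largely relax away once the ligand pose adjusts during
sampling, whereas the Coulomb differential between rotamer basins
survives relaxation and gives the starting-structure experiments an
unambiguous signal.

The geometry was designed so the (phi, chi) landscape reproduces the
qualitative physics of a flexible fragment against a mobile side chain:

- three viable binding modes near (180°, 180°), (180°, 60°) and
  (330°, 180°), while (330°, 60°) — substituent and rotor tip competing
  for the same slot — is sterically excluded;
- contact energies in the phi = 330° modes grow with substituent bulk,
  so mutations re-weight the modes (the steric coupling that drives
  side-chain reorientation);
- torsional barriers of several kcal/mol (chi ≈ 10 kT, phi ≈ 6 kT), so
  a short plain chain with small-step proposals is kinetically trapped
  in its starting mode, while the hottest REST rung (barriers scaled by
  ~0.25) and flip proposals mix modes freely.

A build-time grid scan (10° in each torsion) verifies at least two
local minima separated by a minimax-path barrier above 2 kT for every
substituent; this check is part of the test suite.

What the toy does *not* emulate: explicit solvent, protein flexibility
beyond one rotor, realistic chemistry of the substituents, and any
absolute energy scale comparable to the real complex.  Tests passing on
the toy validate the *estimators and samplers* (they agree with exact
oracles under these conditions); they do not certify force-field
accuracy on real systems.

## Benchmark analytics

Measured IC50 values (μM) convert to a relative experimental scale
`RT ln(IC50)` at 298.15 K.  Computed ddG values are shifted to the
experimental mean (both scales are relative), and MUE, RMSE and Pearson
r are reported; all three are invariant to constant shifts of either
input.  The packaged series table carries the ten published compounds,
eight of which have measured IC50; the statistics of that eight-
compound subset are frozen in the tests.  Mode populations use
nearest-center assignment on the circle (ties to the lower-indexed
center) and the symmetric-mode entropy is reported as
`T dS = -kT sum p ln p`, i.e. `kT ln 2 = 0.411 kcal/mol` for two equal
modes.

## Numerical choices and problem sizes

- Quadrature oracles use a 0.1° trapezoidal grid (halving the step
  changes dG by < 1e-8 kcal/mol); the V1-only closed form
  `dG = V1/2 - kT ln I0(V1/2kT)` provides an independent check.
- Acceptance-style validation runs use 7–11 windows with 5–15 thousand
  MC steps per window and 6 REST replicas; these sizes give standard
  errors of a few thousandths of a kcal/mol on the toy systems, which
  the package treats as its standard study conditions.
- Degenerate inputs: zero-length samples, non-positive IC50, empty
  alchemical maps, empty hot regions, non-adjacent swap pairs and
  overlapping particles all raise errors rather than returning
  sentinel values.

## Known limitations

- The Zwanzig estimator is the only estimator (no BAR/MBAR); double-
  wide sampling and the forward/reverse average mitigate but do not
  remove its bias at poorly overlapping windows.
- Block-averaged errors assume blocks longer than the autocorrelation
  time; very short windows can under-report uncertainty.
- The unbound leg is in vacuo (see above).
- The pose-anchoring rotation restriction is a modelling device of the
  reduced geometry, not a general-purpose sampler feature.
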