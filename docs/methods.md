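# Methods

This note records the models, conventions and numerical choices behind
`cistraj`, and what its synthetic-data tests do and do not demonstrate
about real simulation data.

## Coordinate model and units

Internal units are nm (length), ps (time), u (mass), e (charge) and
kJ·mol⁻¹ (energy). PDB input (Å) is converted on read; GRO is already nm.
Author residue numbering and chain identifiers are preserved exactly —
analyses address residues the way practitioners do (e.g. "Pro103 in chain
H"), so renumbering would be actively harmful. Periodic boxes are
rectangular only; triclinic cells are rejected. Multi-model PDB is the
trajectory baseline because it is plain text and carries no hidden state;
it stores no time metadata, so frames read from it are numbered
0, 1, 2, ... in frame units (for typical MD output each frame would be a
fixed save interval, e.g. 20 ps, apart — window bounds are interpreted in
whatever unit the frame times carry). GRO files carry no chain field; on
read, a decrease in residue numbering starts a new chain (A, B, C, ...).

Because the force-field parameterisation of a real system is out of scope,
per-atom masses, charges and Lennard-Jones σ/ε come from a user-supplied
TSV table (`chain  res  atom  mass_u  charge_e  sigma_nm  epsilon_kjmol`),
optionally validated against `# net_charge CHAIN VALUE` header comments.
Every atom must be covered; missing rows are reported by name.

## Dihedral angles

All torsions use the IUPAC sign convention: 0° for syn/cis, 180° for
anti/trans, positive by the right-hand rule about the central bond, and all
angles are reported in (−180°, +180°]. This is the convention under which a
cis prolyl bond twisted slightly in the negative direction reads, e.g.,
−12°. ω is Cα(i)–C(i)–N(i+1)–Cα(i+1); φ is C(i−1)–N(i)–Cα(i)–C(i); ψ is
N(i)–Cα(i)–C(i)–N(i+1). Terminal residues yield NaN-marked φ or ψ rather
than errors. Geometry is declared degenerate (error) when a bond-plane
cross product has norm below 1e-9 nm². The implementation is cross-checked
in the test suite against MDAnalysis' dihedral kernel (agreement to the
1e-3° expected of its float32 arithmetic).

## ω classification and distributions

Cis/trans assignment uses |ω| with a "twisted" band around the 90°
transition state: |ω| < 60° → cis, |ω| > 120° → trans, otherwise twisted
(boundaries inclusive into the twisted band). The 90° centre reflects the
transition-state geometry of prolyl isomerisation; the ±30° margin is a
package default, and all three numbers are configurable.

Normalized distributions use fixed 1°-wide bins [k, k+1) for integer
k ∈ [−180, 179], dividing bin counts by the total snapshot count, so
heights always sum to 1 and the distribution of a concatenation of windows
is the snapshot-weighted mixture of the windows' distributions. The single
value ω = +180° is counted in the last bin [179°, 180°). Windowed means
use the circular (directional) mean so that values straddling ±180° average
correctly; near 0° the circular and arithmetic means coincide.

The distance–ω correlation cuts both series into non-overlapping windows
of a configurable number of snapshots (default 100), then takes the Pearson
correlation of per-window mean distance against per-window circular-mean ω;
fewer than three full windows is an error, and zero variance in either
windowed series yields NaN (undefined), not an error.

## Crystal-similarity score

For a pair list {(a, b, r^crystal)} the score of a pose is the RMS of
(r_pair − r_pair^crystal) over the pairs, where r_pair is the minimum
inter-atomic distance between the two residues under the minimum-image
convention. The default distance mode is all-atom, with heavy-atom mode
available (reference data rarely state which convention was used, so both
are first-class). Scores carry nm units. Ranking is by ascending score with
stable tie-breaking; unresolvable candidates are skipped with warnings.

## Nonbonded energetics

E_int between two atom groups is the sum over cross-group pairs of

- Coulomb: f·q_i·q_j / r for r < 1.0 nm, sharply truncated (f =
  138.935458 kJ·mol⁻¹·nm·e⁻²). Only the real-space, short-range part of
  the electrostatics is computed — there is no reciprocal-space (mesh
  Ewald) term. Group–group decompositions of the kind this package reports
  are short-range quantities, but absolute Coulomb totals from this model
  should not be compared against energies that include long-range
  corrections.
- Lennard-Jones: 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combining
  rules (σ_ij arithmetic mean, ε_ij geometric mean), multiplied by the
  quintic smoothstep S(x) = 1 − x³(10 − 15x + 6x²),
  x = (r − 0.8)/(0.9 − 0.8), so the potential is exactly 1× below 0.8 nm,
  exactly 0 above 0.9 nm, and C²-continuous (hence C¹) at both boundaries.

Bonded exclusions are approximated by residue separation: same-chain atom
pairs interact only when their residue indices differ by ≥ 2; inter-chain
pairs always interact. True 1-2/1-3/1-4 exclusions would require bonded
topology, which is out of scope; the intra-molecular residue pairs one
typically inspects (e.g. an aspartate against an arginine three positions
away) satisfy the separation rule. This is a documented limitation, not an
option.

Residue breakdowns average each residue's energy against the entire other
molecule over the frames of a closed time window, then report the mean and
standard error **across independent trajectories** (SE = sample sd/√n,
ddof = 1; SE = 0 for a single trajectory) — frames within a trajectory are
correlated and are never used as independent samples. Because every
cross-group pair belongs to exactly one residue of the chosen side, the
per-residue means sum exactly to the whole-molecule mean (verified to 1e-6
relative in the tests). Interaction-energy pose bins are the half-open
classes ≤−800, (−800,−700], (−700,−600], (−600,−500], (−500,−400] and
>−400 kJ/mol.

## Hydrogen bonds and centres of mass

Hydrogen-bond criteria are geometric and conventional: donor–acceptor
(N/O) heavy-atom distance ≤ 0.35 nm and donor–H–acceptor angle ≥ 120°,
both configurable. Donor hydrogens are resolved geometrically — an H atom
in the donor's residue within 0.125 nm — because bonded topology is not
modelled; donors without a resolvable hydrogen are skipped with a warning.
Centres of mass are mass-weighted means of positions as stored: molecules
must be whole (no unwrapping is attempted), which synthetic systems are by
construction and pre-processed real trajectories are expected to be.

## Synthetic data: what it does and does not emulate

The generators produce inputs with known ground truth, not physics:

- **Peptide builder** — N/Cα/C backbones with ideal internal coordinates
  (N–Cα 0.1458 nm, Cα–C 0.1525 nm, C–N 0.1329 nm; angles N–Cα–C 111°,
  Cα–C–N and C–N–Cα 120°) and exactly prescribed ω/φ/ψ, placed by natural
  extension reference frames. Round-trip agreement between requested and
  measured dihedrals is 1e-6°, which validates the dihedral code
  independently of any trajectory.
- **Toy complexes** — two chains of randomly placed atoms (uniform in a
  periodic box, ≥ 0.1 nm minimum-image separation) with charges uniform in
  [−1, 1] e shifted to integer per-molecule totals, σ ∈ [0.25, 0.35] nm,
  ε ∈ [0.1, 1.0] kJ/mol. The O(N²) scalar-loop `brute_force_energy`
  applies the same physics through an independent summation path and
  serves as the energetics oracle (agreement 1e-10 relative over 100
  seeded complexes).
- **ω ensembles** — wrapped-normal samples around a mean that may drift
  linearly across frames (e.g. −6.3° → +2.7°, emulating a slow positive
  shift of a cis bond's ω distribution). Wrapped-normal was chosen over
  von Mises because for sd ≪ 180° the two are practically identical and
  the wrapped-normal mean/sd are directly the generator parameters, making
  parameter-recovery tests exact. Mean recovery is within 3·sd/√n at
  n = 10⁴.

These fixtures deliberately lack what real MD data has: correlated
dynamics, solvent, realistic force-field parameters and long-range
electrostatics. Passing tests therefore demonstrate the *correctness of
the analysis operations* — not that the packaged defaults reproduce any
particular published simulation's numbers, which would require the
original multi-microsecond trajectories.

All generators are seed-deterministic (one `numpy` Generator per call).
Test and pipeline fixtures use small problem sizes — tens of atoms, tens
of frames, 10⁴-sample angle series — chosen so that the statistical
assertions (3σ bands, oracle equivalences) are already decisive at desk
scale.

## Pipeline determinism

Pipeline stages validate their configuration (including file existence and
stage prerequisites) before any computation, echo the fully defaulted
config into `summary.json`, format all CSV floats with a fixed `%.8g`, and
keep timing in the log rather than the outputs, so a re-run under an
identical config and inputs is byte-identical. Warnings (skipped donors,
skipped candidates) are collected into the summary.

## Known limitations

- No PME reciprocal-space electrostatics; Coulomb truncation is sharp.
- No bonded exclusion topology (residue-separation rule instead).
- Rectangular boxes only; no altloc/insertion-code handling beyond
  pass-through; no mmCIF.
- Centres of mass assume whole molecules.
- Multi-model PDB trajectories carry frame-index times only.
- No secondary-structure assignment or superposition-based similarity
  (the pose score is deliberately distance-based).
- No isomerisation rate or free-energy estimation: those require enhanced
  sampling or rate theory, outside this package's post-processing scope.
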