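# Methods

This note documents the models, parameter choices and numerical conventions
behind `fcrfrag`, and what the test suite does and does not establish.

## Structures and bond perception

Structures are lists of atoms with Å coordinates; PDB files are read through
gemmi (alternate locations resolved to the highest-occupancy conformer),
XYZ files directly, with the formal charge carried on the comment line as
`charge=<int>`. Covalent bonds are perceived geometrically: atoms i, j are
bonded iff `d(i,j) ≤ 1.2 · (r_cov(i) + r_cov(j))` with Pyykkö single-bond
covalent radii. The tolerance 1.2 is the package's own default; any pair
closer than 0.4 Å is rejected as a clash. Perception is invariant under
rigid motions by construction.

Backbone annotation is graph-pattern based so that label-free XYZ input
works: a residue is an N–Cα–C(=O) triple found on the bond graph (carbonyl
carbons are carbons with an oxygen whose only heavy neighbor is that
carbon), peptide bonds are carbonyl-C–N edges between triples, prolines are
backbone nitrogens inside a five-ring, disulfides are S–S edges. PDB
residue labels, when present, are only used for numbering and as a
consistency check.

Hydrogen bonds use the window 1.7 Å < d(H···X) < 2.2 Å with angle
(donor–H···acceptor) > 130°, donors/acceptors restricted to N and O by
default (S can be added via the element set). The distance window is the
implemented variant of the two published criteria; the van-der-Waals-based
variant is not implemented. Closest atom–atom distances include hydrogens;
this is a deliberate reading documented here because the alternative
(heavy-atom only) is also defensible.

## Fragmentation schemes

All schemes first produce an exhaustive partition of the atoms into
connected *disjoint groups* via bond cuts, then scheme-specific
*overlapping combinations*:

* **MFHC** cuts the Cα bonds flanking every interior peptide unit. Terminal
  amino/carboxy groups stay attached to their residue. For proline both ring
  N–C bonds are cut so the peptide unit keeps the nitrogen. Each disulfide
  bridge becomes its own CH2–S–S–CH2 group (the Cα–Cβ bonds of both
  cysteines are cut). Combinations: one per Cα-bearing group, that group
  plus every group sharing a cut bond with it.
* **pp-GMBE** cuts every Cα–C(carbonyl) bond that feeds a peptide bond
  (peptide bonds intact, terminal carboxy stays with its residue). Side
  chains with more than 10 atoms are split off at Cα–Cβ; any group above
  15 atoms is subdivided greedily: cut the acyclic heavy–heavy bond on the
  longest heavy-atom chain whose removal best balances the two halves,
  repeat. Atom counts include hydrogens; caps are not counted. Combinations
  are all group pairs with closest atom–atom distance ≤ 2.2 Å plus all pairs
  linked by a detected hydrogen bond; groups in no pair are emitted as
  singletons so every atom stays covered (a package addition required for a
  well-defined expansion). The 15-atom group cap structurally bounds final
  second-order combinations at 4·15 = 60 atoms.
* **MIM** cuts every C–C bond at the α-carbon. Cutting Cα–Cβ of proline
  does not disconnect the ring (still attached via N–Cδ); such cuts are
  dropped from the recorded cut list since they do not straddle two groups.
  Growth from each seed group adds, one at a time, the eligible group
  nearest to the *seed* (not the growing cluster), where eligible means
  within 1.7 Å of some group already included; the equal-distance tie rule
  (tolerance 1e-9 Å) then adds every eligible group tied with the farthest
  included one, iterated to a fixpoint because new members can make further
  tied candidates covalently eligible. Atom-level closure follows: any atom
  bonded to at least two atoms of the combination is absorbed, iterated to
  a fixpoint — closure can pull atoms across group boundaries, so
  combination atom sets are stored explicitly. Finally subset combinations
  are removed, leaving an antichain.
* **KEM** cuts every peptide bond; disulfide-bridged cysteines stay in one
  group because the S–S bond is not a peptide bond.

## Coupling and coefficients

`NeiY_d` forms unions of k ≤ Y combinations whose proximity graph (edges at
closest atom–atom distance ≤ d; overlapping combinations are distance 0)
restricted to the members is connected. The connected-cluster reading is
used rather than all-pairs-within-cutoff; the two agree at Y = 2, and the
connected reading is the more inclusive generalization. `HierY` is `NeiY`
with an infinite cutoff (and a term-count budget guard, default 200 000).
Results are de-duplicated by atom set and subset-pruned to an antichain.

Coefficients are assigned over the intersection closure of the
combinations' atom sets, processed in decreasing cardinality with
`a_S = 1 − Σ_{T ⊋ S} a_T`. This enforces the counting identity
`Σ_{T ⊇ S} a_T = 1` for every closure member, and hence for every covered
atom set, because the closure sets containing any covered set are closed
under intersection and so have a unique minimal element. Intersections are
taken on atom sets directly, which coincides with group-level intersection
for all schemes except MIM, whose closure-adjusted sets genuinely need the
atom level. Coefficients are exact `Fraction`s; the recursion yields
integers on every antichain and integrality is asserted in tests.

Combinations whose placed caps would fall within 0.9 Å of a non-adjacent
real atom of their own fragment are merged with the offending atom's group
before coefficients are computed (repeated to a fixpoint, then
subset-pruned). The 0.9 Å default is this package's stand-in for the
original merge rule, which is not fully specified in the sources the
schemes descend from; it is configurable. MIM's closure already absorbs
shared neighbors, so its combinations never trigger the merge on the test
fixtures, which is asserted as a property.

## Capping

Each cut bond gets one hydrogen on the ray from the kept atom toward the
lost atom at a fixed distance depending only on the kept element: C 1.112,
N 1.060, O 1.030 Å (UFF-derived), S 1.341 Å. No hybridization dependence,
no cap optimization, no conjugate caps. Caps are collinear with the severed
bond to < 1e-10 Å and capping is equivariant under rigid motions.

## Energies, multilevel and embedding

Energies are kJ/mol throughout; the Coulomb constant is
1389.35457644 kJ mol⁻¹ Å e⁻². Assembly accumulates `p_f · E_f` in
label-sorted order for bit-reproducibility, and a missing or failed term
aborts the assembly rather than being skipped.

The two-level composite follows the substitution (ONIOM-like) reading:
`E^ML = E^LL(low-level expansion or supersystem) + Σ p_f (E_f^HL − E_f^LL)`,
equivalently the high-level terms reappear at the low level with negated
coefficients. The printed constraint form relating the two coefficient sets
is realized implicitly by this construction; no standalone object holds the
intersection coefficients.

Embedded evaluation follows the convention that a backend's embedded energy
contains (i) the fragment in the field, (ii) the fragment–environment
interaction and (iii) the environment charges' mutual Coulomb self-energy.
Under this convention the single `(Σ p_f − 1)·E_Coul` subtraction is exact
in the classical limit. Engines that report energies without item (iii) are
accommodated by the results reader, which can add the environment
self-energy per term (`env_self_energy_included=False`).

Embedding charges come from a small FCR per scheme (`MFHC-[1]`,
`PAIR_2.2_HB-[1]`, `MIM-[η = 3]`, `KEM-[1]`): a gas-phase pass, then two
embedded re-evaluations by default ("two iterations" counted as embedded
re-evaluations after the initial pass; configurable). Cap charges are
redistributed onto the atoms the caps replace — this preserves every
fragment's total charge exactly, at the cost of slightly perturbing the
per-atom weighted average, and the assembled total equals the formal charge
by the counting identity. Caps never carry embedding charges; a term's
environment is every real atom outside its atom set.

## Mock backends

Real population analyses live in the external engine; the mock backends are
deterministic charge/energy models chosen so the engine's algebraic
identities can be tested exactly:

* *additive*: `E = Σ e_Z + Σ_{r ≤ cutoff} w(r)`, caps counted as hydrogens.
  Exact supersystem assembly holds whenever every interacting pair is
  covered by some combination, which makes truncation error controllable in
  tests.
* *classical*: one-body terms plus the Coulomb energy of per-element table
  charges, uniformly shifted per structure so the supersystem total equals
  the formal charge (the mock analogue of a charge-conserving population
  analysis). Caps are passive (zero charge, no one-body term), so the model
  is strictly a function of the real atoms and the embedded assembly
  identity is exact.
* *linear response*: classical charges plus `α · Σ Q_j/r_ij`, re-centered to
  conserve the fragment total — exercises the embedding iteration against
  an independently coded fixed-point map.

Because the mock tables are fractional per element, per-fragment charge
totals are not integers; the integer-total contract applies to engine
results entering through the results reader.

## Synthetic polypeptide generator

The generator emulates what the schemes need from a protein structure:
correct covalent topology (including proline rings and disulfide bridges),
every hydrogen present, realistic bond lengths and angles, and
conformational variety (ideal extended and helical torsions, or seeded coil
jitter). Residues are built by sequential internal-coordinate (NeRF)
placement; side-chain hydrogens complete tetrahedral or staggered
geometries. Prolines get their ring closed by sphere–sphere intersection
with a torsion scan keeping Cδ clear of the preceding carbonyl, and kink an
ideal helix at the preceding residue (as real prolines do). Disulfide
bridges are closed by a deterministic Nelder–Mead adjustment of the bridged
cysteines' χ1 and the intervening backbone torsions, targeting d(S–S) =
2.05 Å under a steric penalty. Termini are neutral (NH2/COOH), so fixtures
have formal charge 0. Every build is validated so that distance-based bond
perception recovers exactly the intended topology; clashing conformations
are retried with seeded, progressively wider torsion jitter.

Not emulated: stereochemistry is consistent but absolute chirality is not
enforced (irrelevant to topology-driven fragmentation); no solvent, ions,
ligands or non-ideal bond lengths; no titration states (lysine amines are
neutral). Consequently, passing tests establish the engine's combinatorial
and algebraic correctness on realistic topologies and geometries — they say
nothing about the quantum-chemical accuracy of any scheme on real proteins,
which depends on the external engine.

## Problem sizes and numerical choices

The test suite uses peptides of 1–20 residues (up to ~240 atoms): large
enough that every cut rule, coupling scheme and embedding path is exercised
with hundreds of terms, small enough that the whole suite runs in well
under a minute of CPU. The acceptance script measures the pp-GMBE size
bound on 200 random 3–10-residue fixtures. The counting identity is checked
exhaustively over all antichain families on up to five groups and on 500
random families over up to eight.

Tolerances: classical-limit embedded exactness 1e-6 kJ/mol, charge
conservation 1e-6 e, cap geometry 1e-9 Å, MIM tie rule 1e-9 Å. Term sums
are accumulated in sorted order; coefficients are exact rationals until the
final float multiply.

## Known limitations

* Only two coupling levels per spec; electrostatic embedding is supported
  for single-level specs (matching the benchmark design the schemes come
  from).
* MOBE-style couplings and distance-based MIM cutoffs are out of scope, as
  are conjugate caps (MFCC/GMFCC), protonation and structure optimization.
* HETATM entities other than water are treated as atoms like any others;
  non-protein components end up as their own groups only insofar as the
  cut rules leave them unconnected.
* The greedy side-chain bisection and the 0.9 Å clash-merge criterion are
  this package's own constructions where the source recipes are
  underspecified; both are configurable.
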