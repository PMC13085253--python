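# fcrfrag

Energy-based molecular fragmentation of proteins and peptides in a common
*fragment combination range* (FCR) formalism.

Quantum-chemical methods scale steeply with system size, so full proteins are
usually out of reach. Fragmentation methods cut the molecule into small,
possibly overlapping pieces, evaluate each piece separately, and recombine
the pieces' energies into an estimate of the total. `fcrfrag` implements four
protein fragmentation schemes on top of one shared engine:

* **MFHC** — molecular fractionation with hydrogen caps: cut the bonds
  joining each interior peptide unit (HN–CO) to its flanking α-carbons, with
  special rules for proline and disulfide bridges;
* **pp-GMBE** — the pair–pair approximation to the generalized many-body
  expansion: cut Cα–C(carbonyl) bonds (peptide bonds stay intact), cap group
  sizes at 15 atoms, pair groups within 2.2 Å or linked by hydrogen bonds;
* **MIM** — the molecules-in-molecules protein recipe: cut all C–C bonds at
  the α-carbon and grow each fragment combination from its seed group by a
  number-based cutoff η with tie, covalent-connectivity, closure and
  subset-removal rules;
* **KEM** — the kernel energy method: cut every peptide bond, one residue
  per group.

## The model

For a set of *fragment combinations* f (unions of the scheme's disjoint
groups) the total energy is assembled as

```
E = Σ_{f ∈ FCR} p_f E_f
```

where the signed integer coefficients `p_f` come from the generalized
inclusion–exclusion principle over the intersection closure of the
combinations. The defining property is the **counting identity**: for every
atom set S contained in at least one combination, Σ over terms T ⊇ S of
`p_T` equals exactly 1, so every interaction fully contained in some
fragment is counted exactly once.

Around this core the package provides:

* **coupling schemes** `NeiY_d` (unions of up to Y combinations whose
  proximity graph at atom–atom cutoff d is connected) and `HierY` (the
  distance-unbounded analogue), plus `Super` (one supersystem term);
* **hydrogen capping**: every severed bond is saturated by an H placed on
  the bond ray at a fixed distance per capped element
  (C 1.112 Å, N 1.060 Å, O 1.030 Å, UFF-derived);
* **multilevel composites** `E^ML = E^LL(base) + Σ p_f (E_f^HL − E_f^LL)`;
* **electrostatic embedding**: point charges derived iteratively from a
  small FCR (cap charges redistributed onto the atoms they replace, then
  coefficient-weighted), each fragment evaluated in the field of all
  remaining atoms, and the double-counted Coulomb energy removed via
  `E ≈ Σ p_f E_f^ee − (Σ p_f − 1)·E_Coul`;
* the full scheme nomenclature, e.g. `MFHC-[Nei2_4.0_ee]`,
  `PAIR_2.2_HB-[Nei2_4.0][Super]`, `MIM-[η = 9]`;
* deterministic mock energy backends (additive one-body+pair, classical
  point-charge, linear-response) and an input-deck writer / results-table
  reader for external quantum-chemistry engines;
* a synthetic polypeptide generator (G, A, K, P, C; extended/helix/coil;
  disulfide bridges) so the whole pipeline is testable offline.

## Worked example

```
$ fcrfrag fixtures --sequence GAKAG --conformation coil --seed 2 --out pep.xyz
pep.xyz: 58 atoms

$ fcrfrag assemble --structure pep.xyz --spec "MFHC-[Nei2_4.0_ee]" --backend classical
E(MFHC-[Nei2_4.0_ee]) = -1340.113489 kJ/mol
E(supersystem) = -1340.113489 kJ/mol
deviation = +0.000000 kJ/mol
```

The fixture is a 5-residue peptide (58 atoms, all hydrogens present). The
MFHC scheme with second-order neighbor coupling at 4.0 Å and electrostatic
embedding assembles, with the classical point-charge backend, to exactly the
supersystem energy: the classical limit of the embedded expansion is exact,
which is the engine's flagship correctness property. With truncated
backends the deviation is nonzero and shrinks as the coupling cutoff grows.

Other verbs: `fragment` (capped fragment XYZ files + manifest),
`coefficients` (the expansion with its inclusion–exclusion coefficients),
`charges` (the iterative embedding-charge derivation), `bench`
(structures × specs with MAD/RMSD of relative energies against the
supersystem reference).

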