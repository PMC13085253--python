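"""Scheme-specific construction of disjoint fragments and overlapping combinations.

Four bond-cutting recipes are implemented, each producing an exhaustive
partition of the atoms into *initial disjoint fragments* (groups) followed by
scheme-specific *initial overlapping fragment combinations*:

* MFHC  - cut the bonds joining each interior peptide unit (HN-CO) to its
  flanking alpha carbons; merge every C-alpha group with the groups it shares
  a cut bond with.  Proline keeps the backbone N with the peptide unit (both
  ring N-C bonds are cut); a disulfide bridge forms a dedicated
  CH2-S-S-CH2 group.
* pp-GMBE - cut C-alpha/C-carbonyl bonds (peptide bonds stay intact), split
  off large side chains so no group exceeds a size cap, then pair groups by
  proximity and hydrogen bonding.
* MIM   - cut all C-C bonds at the alpha carbon (backbone carbonyl and side
  chain); grow a combination from each group by nearest-group distance under
  a covalent-connectivity constraint, with an equal-distance tie rule, an
  atom-level closure that absorbs atoms bonded twice into a combination, and
  subset removal.
* KEM   - cut every peptide bond; each residue is one group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure import (
    BackboneAnnotation,
    BondGraph,
    HydrogenBond,
    Structure,
    StructureError,
    min_atom_distance,
)

__all__ = [
    "DisjointFragmentation",
    "FragmentCombination",
    "SchemeError",
    "mfhc_disjoint",
    "mfhc_overlapping",
    "ppgmbe_disjoint",
    "ppgmbe_pairs",
    "mim_disjoint",
    "mim_overlapping",
    "kem_disjoint",
]


class SchemeError(StructureError):
    """A fragmentation scheme could not be applied to the structure."""


@dataclass(frozen=True)
class FragmentCombination:
    """A set of groups treated as one capped entity.

    ``atom_set`` normally equals the union of the member groups; MIM's
    atom-level closure may pull individual atoms across group boundaries, in
    which case the atom set is a strict superset and is stored explicitly.
    """

    group_indices: frozenset[int]
    atom_set: frozenset[int]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atom_set:
            raise SchemeError("a fragment combination must contain atoms")

    @staticmethod
    def from_groups(
        group_indices: Iterable[int],
        fragmentation: "DisjointFragmentation",
        label: str = "",
    ) -> "FragmentCombination":
        gi = frozenset(group_indices)
        if not gi:
            raise SchemeError("a fragment combination needs at least one group")
        atoms = frozenset().union(*(fragmentation.groups[g] for g in gi))
        return FragmentCombination(group_indices=gi, atom_set=atoms, label=label)


@dataclass
class DisjointFragmentation:
    """An exhaustive partition of all atoms into connected groups."""

    groups: list[frozenset[int]]
    scheme: str
    cut_bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g in self.groups:
            if seen & g:
                raise SchemeError("groups overlap")
            seen |= g

    def group_of(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for gi, g in enumerate(self.groups):
            for a in g:
                out[a] = gi
        return out

    def validate(self, structure: Structure, bonds: BondGraph) -> None:
        """Assert the partition invariants (cover, connectivity, cut bonds)."""
        union = frozenset().union(*self.groups) if self.groups else frozenset()
        if union != frozenset(range(len(structure))):
            raise SchemeError("groups do not cover all atoms exactly")
        for g in self.groups:
            if not bonds.is_connected_subset(set(g)):
                raise SchemeError("a group induces a disconnected subgraph")
        gmap = self.group_of()
        for i, j in self.cut_bonds:
            if not bonds.has_edge(i, j):
                raise SchemeError(f"cut bond ({i},{j}) is not a bond")
            if gmap[i] == gmap[j]:
                raise SchemeError(f"cut bond ({i},{j}) does not straddle two groups")


def _partition_from_cuts(
    structure: Structure,
    bonds: BondGraph,
    cut: set[frozenset[int]],
    scheme: str,
) -> DisjointFragmentation:
    """Components of the bond graph minus ``cut`` edges, canonically ordered.

    Cut bonds whose endpoints remain connected through another path (e.g. a
    severed ring bond) do not straddle two groups and are dropped from the
    recorded cut list.
    """
    comps = bonds.connected_components(removed=cut)
    comps.sort(key=min)
    groups = [frozenset(c) for c in comps]
    gmap = {a: gi for gi, g in enumerate(groups) for a in g}
    cut_bonds = sorted(
        (min(e), max(e)) for e in cut if gmap[min(e)] != gmap[max(e)]
    )
    return DisjointFragmentation(groups=groups, scheme=scheme, cut_bonds=cut_bonds)


# ---------------------------------------------------------------------------
# MFHC


def mfhc_disjoint(
    structure: Structure, bonds: BondGraph, backbone: BackboneAnnotation
) -> DisjointFragmentation:
    """Cut the C-alpha bonds flanking every interior peptide unit.

    Terminal amino/carboxy groups stay attached to their residue; for a
    proline peptide unit both ring N-C bonds are cut so the unit keeps N; each
    disulfide bridge becomes its own CH2-S-S-CH2 group (the C-alpha/C-beta
    bonds of both cysteines are cut as well).
    """
    elements = structure.elements
    res_by_n = {r.n: r for r in backbone.residues}
    res_by_c = {r.c_carbonyl: r for r in backbone.residues}
    cut: set[frozenset[int]] = set()
    for c, n in backbone.peptide_bonds:
        donor = res_by_c[c]
        cut.add(frozenset((donor.c_alpha, c)))
        acceptor = res_by_n[n]
        if acceptor.is_proline:
            # sever both ring N-C bonds (to CA and CD); the peptide C-N
            # bond itself stays with the unit
            for j in bonds.neighbors(n):
                if elements[j] == "C" and j != c:
                    cut.add(frozenset((n, j)))
        else:
            cut.add(frozenset((n, acceptor.c_alpha)))
    for s1, s2 in backbone.disulfide_bridges:
        for s in (s1, s2):
            for cb in bonds.neighbors(s):
                if elements[cb] != "C":
                    continue
                for ca in bonds.neighbors(cb):
                    if ca in backbone.c_alpha_indices:
                        cut.add(frozenset((ca, cb)))
    return _partition_from_cuts(structure, bonds, cut, "mfhc")


def mfhc_overlapping(
    disjoint: DisjointFragmentation,
    bonds: BondGraph,
    backbone: BackboneAnnotation,
) -> list[FragmentCombination]:
    """One combination per C-alpha-bearing group: it plus all cut-bond neighbors."""
    if disjoint.scheme != "mfhc":
        raise SchemeError("mfhc_overlapping requires an MFHC fragmentation")
    gmap = disjoint.group_of()
    adjacency: dict[int, set[int]] = {gi: set() for gi in range(len(disjoint.groups))}
    for i, j in disjoint.cut_bonds:
        adjacency[gmap[i]].add(gmap[j])
        adjacency[gmap[j]].add(gmap[i])
    seeds = sorted({gmap[ca] for ca in backbone.c_alpha_indices})
    out = []
    for k, gi in enumerate(seeds):
        members = {gi} | adjacency[gi]
        out.append(
            FragmentCombination.from_groups(members, disjoint, label=f"mfhc:{k}")
        )
    return out


# ---------------------------------------------------------------------------
# pp-GMBE


def _side_chain_atoms(
    ca: int, cb: int, bonds: BondGraph
) -> set[int]:
    """Atoms reachable from C-beta without passing through the alpha carbon."""
    seen = {cb}
    stack = [cb]
    while stack:
        u = stack.pop()
        for v in bonds.neighbors(u):
            if v == ca or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def _longest_chain_split(
    atoms: set[int], bonds: BondGraph, elements: Sequence[str], max_atoms: int
) -> set[frozenset[int]]:
    """Greedy bisection cuts along the longest heavy-atom chain of a component.

    Returns the acyclic heavy-heavy bonds to sever so every resulting piece
    has at most ``max_atoms`` atoms; pieces that cannot be reduced (no
    cuttable bond) are kept oversize with a warning.
    """
    import networkx as nx

    cuts: set[frozenset[int]] = set()
    queue = [frozenset(atoms)]
    while queue:
        comp = queue.pop()
        if len(comp) <= max_atoms:
            continue
        sub = nx.Graph()
        sub.add_nodes_from(comp)
        sub.add_edges_from(
            (i, j)
            for e in bonds.edges
            if (i := min(e)) in comp and (j := max(e)) in comp
        )
        bridges = {
            frozenset(e)
            for e in nx.bridges(sub)
            if elements[min(e)] != "H" and elements[max(e)] != "H"
        }
        if not bridges:
            warnings.warn(
                f"a {len(comp)}-atom fragment has no cuttable acyclic bond; "
                "keeping it oversize",
                stacklevel=2,
            )
            continue
        # heavy-atom longest path, then cut the bridge on it whose removal
        # best balances the two halves
        heavy = sorted(a for a in comp if elements[a] != "H")
        hsub = sub.subgraph(heavy)
        lengths = nx.single_source_shortest_path_length(hsub, heavy[0])
        far = max(lengths, key=lambda a: (lengths[a], -a))
        paths = nx.single_source_shortest_path(hsub, far)
        end = max(paths, key=lambda a: (len(paths[a]), -a))
        path = paths[end]
        candidates = [
            frozenset((path[i], path[i + 1]))
            for i in range(len(path) - 1)
            if frozenset((path[i], path[i + 1])) in bridges
        ] or sorted(bridges, key=lambda e: (min(e), max(e)))
        best = None
        for e in candidates:
            sub.remove_edge(*tuple(e))
            sides = list(nx.connected_components(sub))
            sub.add_edge(*tuple(e))
            imbalance = abs(len(sides[0]) - len(sides[1]))
            if best is None or imbalance < best[0]:
                best = (imbalance, e)
        cut = best[1]
        cuts.add(cut)
        sub.remove_edge(*tuple(cut))
        queue.extend(frozenset(c) for c in nx.connected_components(sub))
    return cuts


def ppgmbe_disjoint(
    structure: Structure,
    bonds: BondGraph,
    backbone: BackboneAnnotation,
    max_fragment_atoms: int = 15,
    sidechain_split_threshold: int = 10,
) -> DisjointFragmentation:
    """Cut C-alpha/C-carbonyl bonds; split big side chains; cap group size.

    Peptide bonds stay intact.  Side chains larger than
    ``sidechain_split_threshold`` atoms are split off at C-alpha/C-beta and,
    like any remaining oversize group, subdivided greedily along their longest
    chain until every group holds at most ``max_fragment_atoms`` atoms
    (hydrogens included; caps are not counted).
    """
    elements = structure.elements
    res_by_c = {r.c_carbonyl: r for r in backbone.residues}
    cut: set[frozenset[int]] = set()
    for c, _n in backbone.peptide_bonds:
        cut.add(frozenset((res_by_c[c].c_alpha, c)))
    for r in backbone.residues:
        cb_candidates = [
            j
            for j in bonds.neighbors(r.c_alpha)
            if elements[j] == "C" and j != r.c_carbonyl
        ]
        for cb in cb_candidates:
            side = _side_chain_atoms(r.c_alpha, cb, bonds)
            if r.c_alpha in side:  # ring side chain (proline): cutting is moot
                continue
            if len(side) > sidechain_split_threshold:
                cut.add(frozenset((r.c_alpha, cb)))
                cut |= _longest_chain_split(side, bonds, elements, max_fragment_atoms)
    frag = _partition_from_cuts(structure, bonds, cut, "ppgmbe")
    # any group still above the cap is subdivided in place
    extra: set[frozenset[int]] = set(frozenset(e) for e in frag.cut_bonds)
    changed = False
    for g in frag.groups:
        if len(g) > max_fragment_atoms:
            more = _longest_chain_split(set(g), bonds, elements, max_fragment_atoms)
            if more:
                extra |= more
                changed = True
    if changed:
        frag = _partition_from_cuts(structure, bonds, extra, "ppgmbe")
    return frag


def ppgmbe_pairs(
    disjoint: DisjointFragmentation,
    structure: Structure,
    hbonds: Sequence[HydrogenBond] = (),
    pair_cutoff: float = 2.2,
) -> list[FragmentCombination]:
    """All group pairs within ``pair_cutoff`` or linked by a hydrogen bond.

    Any group that ends up in no pair is emitted as a singleton so the
    expansion still covers every atom.
    """
    if disjoint.scheme != "ppgmbe":
        raise SchemeError("ppgmbe_pairs requires a pp-GMBE fragmentation")
    pos = structure.positions
    groups = disjoint.groups
    gmap = disjoint.group_of()
    pairs: set[tuple[int, int]] = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = cdist(pos[sorted(groups[i])], pos[sorted(groups[j])]).min()
            if d <= pair_cutoff:
                pairs.add((i, j))
    for hb in hbonds:
        gi, gj = gmap[hb.hydrogen], gmap[hb.acceptor_heavy]
        if gi != gj:
            pairs.add((min(gi, gj), max(gi, gj)))
    out = []
    covered: set[int] = set()
    for k, (i, j) in enumerate(sorted(pairs)):
        covered |= {i, j}
        out.append(
            FragmentCombination.from_groups((i, j), disjoint, label=f"pair:{i}-{j}")
        )
    for i in range(len(groups)):
        if i not in covered:
            out.append(
                FragmentCombination.from_groups((i,), disjoint, label=f"single:{i}")
            )
    return out


# ---------------------------------------------------------------------------
# MIM


def mim_disjoint(
    structure: Structure, bonds: BondGraph, backbone: BackboneAnnotation
) -> DisjointFragmentation:
    """Cut every C-C bond at the alpha carbon (carbonyl side and side chain)."""
    elements = structure.elements
    res_by_c = {r.c_carbonyl: r for r in backbone.residues}
    cut: set[frozenset[int]] = set()
    for c, _n in backbone.peptide_bonds:
        cut.add(frozenset((res_by_c[c].c_alpha, c)))
    for r in backbone.residues:
        for j in bonds.neighbors(r.c_alpha):
            if elements[j] == "C" and j != r.c_carbonyl:
                cut.add(frozenset((r.c_alpha, j)))
    return _partition_from_cuts(structure, bonds, cut, "mim")


def _group_distance_matrix(
    disjoint: DisjointFragmentation, structure: Structure
) -> np.ndarray:
    pos = structure.positions
    n = len(disjoint.groups)
    idx = [sorted(g) for g in disjoint.groups]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = cdist(pos[idx[i]], pos[idx[j]]).min()
    return d


def _closure(atom_set: frozenset[int], bonds: BondGraph) -> frozenset[int]:
    """Pull in atoms bonded to two or more member atoms, to a fixpoint."""
    atoms = set(atom_set)
    while True:
        added = False
        for a in range(bonds.n_atoms):
            if a in atoms:
                continue
            if len(bonds.neighbors(a) & atoms) >= 2:
                atoms.add(a)
                added = True
        if not added:
            return frozenset(atoms)


def mim_overlapping(
    disjoint: DisjointFragmentation,
    structure: Structure,
    bonds: BondGraph,
    eta: int,
    covalent_threshold: float = 1.7,
    distance_tol: float = 1e-9,
) -> list[FragmentCombination]:
    """Number-based MIM growth with tie rule, closure and subset removal.

    From each seed group, the ``eta - 1`` nearest other groups (distance to the
    *seed*) are added one at a time, each candidate being required to lie
    within ``covalent_threshold`` of some group already in the combination.
    Candidates tied (within ``distance_tol``) with the farthest included group
    are also added.  Atom-level closure then absorbs every atom covalently
    bound to at least two member atoms, and subset combinations are removed.
    """
    from .fcr import remove_subsets

    if disjoint.scheme != "mim":
        raise SchemeError("mim_overlapping requires a MIM fragmentation")
    if eta < 1:
        raise SchemeError("eta must be >= 1")
    n = len(disjoint.groups)
    if eta > n:
        warnings.warn(f"eta={eta} exceeds the {n} groups; capping", stacklevel=2)
        eta = n
    dmat = _group_distance_matrix(disjoint, structure)
    out: list[FragmentCombination] = []
    for seed in range(n):
        members = {seed}
        farthest = 0.0
        while len(members) < eta:
            eligible = [
                g
                for g in range(n)
                if g not in members
                and min(dmat[g, m] for m in members) <= covalent_threshold
            ]
            if not eligible:
                break
            nxt = min(eligible, key=lambda g: (dmat[seed, g], g))
            farthest = max(farthest, dmat[seed, nxt])
            members.add(nxt)
        # equal-distance tie rule, iterated since new members can make more
        # candidates covalently eligible at the same seed distance
        if len(members) > 1:
            while True:
                ties = [
                    g
                    for g in range(n)
                    if g not in members
                    and abs(dmat[seed, g] - farthest) <= distance_tol
                    and min(dmat[g, m] for m in members) <= covalent_threshold
                ]
                if not ties:
                    break
                members.update(ties)
        atoms = frozenset().union(*(disjoint.groups[g] for g in members))
        closed = _closure(atoms, bonds)
        out.append(
            FragmentCombination(
                group_indices=frozenset(members),
                atom_set=closed,
                label=f"mim:{seed}",
            )
        )
    return remove_subsets(out)


# ---------------------------------------------------------------------------
# KEM


def kem_disjoint(
    structure: Structure, bonds: BondGraph, backbone: BackboneAnnotation
) -> DisjointFragmentation:
    """Cut every peptide C-N bond; each residue (with side chain) is one group."""
    cut = {frozenset(pb) for pb in backbone.peptide_bonds}
    return _partition_from_cuts(structure, bonds, cut, "kem")
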