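"""Molecular structures, bond perception and geometric primitives.

Everything downstream (fragmentation schemes, capping, embedding) operates on
the three objects defined here: a :class:`Structure` (atoms with coordinates in
Angstrom), a :class:`BondGraph` (the perceived covalent topology) and a
:class:`BackboneAnnotation` (per-residue N/C-alpha/C-carbonyl roles, peptide
bonds, disulfide bridges and proline flags, all derived from the bond graph by
pattern matching so that label-free XYZ input works).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Structure",
    "BondGraph",
    "ResidueBackbone",
    "BackboneAnnotation",
    "HydrogenBond",
    "StructureError",
    "FormatError",
    "UnsupportedElementError",
    "GeometryError",
    "AnnotationError",
    "COVALENT_RADII",
    "read_structure",
    "write_structure",
    "perceive_bonds",
    "annotate_backbone",
    "detect_hydrogen_bonds",
    "min_atom_distance",
]


class StructureError(Exception):
    """Base class for errors raised by this module."""


class FormatError(StructureError):
    """A structure file could not be parsed."""


class UnsupportedElementError(StructureError):
    """An element symbol is outside the supported periodic-table subset."""


class GeometryError(StructureError):
    """Coordinates are physically inconsistent (clashes, coincident atoms)."""


class AnnotationError(StructureError):
    """Backbone pattern matching failed for a residue."""


# Pyykko & Atsumi single-bond covalent radii (Angstrom) for the elements a
# hydrogen-saturated polypeptide (plus common hetero groups) can contain.
COVALENT_RADII: dict[str, float] = {
    "H": 0.32,
    "B": 0.85,
    "C": 0.75,
    "N": 0.71,
    "O": 0.63,
    "F": 0.64,
    "Na": 1.55,
    "Mg": 1.39,
    "P": 1.11,
    "S": 1.03,
    "Cl": 0.99,
    "K": 1.96,
    "Ca": 1.71,
    "Fe": 1.16,
    "Zn": 1.18,
    "Se": 1.16,
    "Br": 1.14,
    "I": 1.33,
}


@dataclass(frozen=True)
class Atom:
    """One atom: element, position (Angstrom) and optional residue labels."""

    index: int
    element: str
    position: tuple[float, float, float]
    residue_seq: int = 0
    residue_name: str = ""
    chain_id: str = ""
    atom_name: str = ""

    def __post_init__(self) -> None:
        if self.element not in COVALENT_RADII:
            raise UnsupportedElementError(
                f"element {self.element!r} (atom {self.index}) is not supported"
            )
        if not all(math.isfinite(c) for c in self.position):
            raise GeometryError(f"atom {self.index} has non-finite coordinates")


@dataclass
class Structure:
    """An ordered list of atoms forming the supersystem.

    ``formal_charge`` is the integer total charge in units of e.
    """

    atoms: list[Atom]
    formal_charge: int = 0
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("a Structure must contain at least one atom")
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise StructureError(
                    f"atom indices must run 0..N-1 in order (got {atom.index} at {i})"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in Angstrom."""
        return np.asarray([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with positions mapped through ``R x + t`` (rigid motion)."""
        pos = self.positions @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
        atoms = [replace(a, position=tuple(p)) for a, p in zip(self.atoms, pos)]
        return Structure(atoms=atoms, formal_charge=self.formal_charge, title=self.title)


class BondGraph:
    """Symmetric covalent bond topology as a set of unordered index pairs."""

    def __init__(self, edges: Iterable[tuple[int, int]], n_atoms: int):
        self.n_atoms = n_atoms
        self._edges: set[frozenset[int]] = set()
        self._adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
        for i, j in edges:
            self.add_edge(i, j)

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise StructureError(f"self-edge on atom {i}")
        if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
            raise StructureError(f"bond ({i},{j}) references an invalid atom index")
        self._edges.add(frozenset((i, j)))
        self._adj[i].add(j)
        self._adj[j].add(i)

    @property
    def edges(self) -> set[frozenset[int]]:
        return set(self._edges)

    def has_edge(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self._edges

    def neighbors(self, i: int) -> set[int]:
        return set(self._adj[i])

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def __len__(self) -> int:
        return len(self._edges)

    def connected_components(
        self, removed: Iterable[frozenset[int]] = ()
    ) -> list[set[int]]:
        """Connected components after (optionally) deleting ``removed`` edges."""
        removed = set(removed)
        seen: set[int] = set()
        components: list[set[int]] = []
        for start in range(self.n_atoms):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            seen.add(start)
            while stack:
                u = stack.pop()
                for v in self._adj[u]:
                    if v in seen or frozenset((u, v)) in removed:
                        continue
                    seen.add(v)
                    comp.add(v)
                    stack.append(v)
            components.append(comp)
        return components

    def is_connected_subset(self, atoms: set[int]) -> bool:
        """True if ``atoms`` induces a connected subgraph."""
        if not atoms:
            return False
        atoms = set(atoms)
        start = next(iter(atoms))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self._adj[u]:
                if v in atoms and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen == atoms


@dataclass(frozen=True)
class ResidueBackbone:
    """Backbone atom roles of one residue, by atom index."""

    n: int
    c_alpha: int
    c_carbonyl: int
    o_carbonyl: int
    residue_seq: int
    chain_id: str = ""
    is_proline: bool = False


@dataclass
class BackboneAnnotation:
    residues: list[ResidueBackbone]
    peptide_bonds: list[tuple[int, int]]  # (C_carbonyl index, N index), chain order
    disulfide_bridges: list[tuple[int, int]]  # (S, S) index pairs
    termini: dict[str, tuple[int, int]]  # chain id -> (first residue pos, last)

    @property
    def c_alpha_indices(self) -> set[int]:
        return {r.c_alpha for r in self.residues}

    def residue_of(self, annotation_pos: int) -> ResidueBackbone:
        return self.residues[annotation_pos]


@dataclass(frozen=True)
class HydrogenBond:
    """A donor-H...acceptor contact satisfying the configured window."""

    hydrogen: int
    donor_heavy: int
    acceptor_heavy: int
    distance: float  # H...acceptor, Angstrom
    angle: float  # donor-H...acceptor, degrees


# ---------------------------------------------------------------------------
# file I/O


def _parse_xyz(path: Path) -> Structure:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}:1: expected an atom count") from exc
    comment = lines[1] if len(lines) > 1 else ""
    charge = 0
    title_parts = []
    for tok in comment.split():
        if tok.startswith("charge="):
            try:
                charge = int(tok.split("=", 1)[1])
            except ValueError as exc:
                raise FormatError(f"{path}:2: malformed charge token {tok!r}") from exc
        else:
            title_parts.append(tok)
    atoms = []
    for k in range(n):
        lineno = k + 3
        if k + 2 >= len(lines):
            raise FormatError(f"{path}:{lineno}: file ends before {n} atoms were read")
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected 'El x y z'")
        el = parts[0].capitalize()
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad coordinate") from exc
        atoms.append(Atom(index=k, element=el, position=(x, y, z)))
    return Structure(atoms=atoms, formal_charge=charge, title=" ".join(title_parts))


def _parse_pdb(path: Path, include_waters: bool) -> Structure:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    st.setup_entities()
    if not include_waters:
        st.remove_waters()
    # Resolve altlocs to the highest-occupancy conformer.
    st.remove_alternative_conformations()
    atoms: list[Atom] = []
    idx = 0
    if not st or not len(st):
        raise FormatError(f"{path}: no models found")
    model = st[0]
    for chain in model:
        for residue in chain:
            for at in residue:
                el = at.element.name
                if el not in COVALENT_RADII:
                    raise UnsupportedElementError(
                        f"{path}: element {el!r} in residue "
                        f"{residue.name} {residue.seqid.num} is not supported"
                    )
                atoms.append(
                    Atom(
                        index=idx,
                        element=el,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        residue_seq=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        atom_name=at.name,
                    )
                )
                idx += 1
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return Structure(atoms=atoms, title=st.name or path.stem)


def read_structure(path: str | Path, format: str | None = None, *, include_waters: bool = True) -> Structure:
    """Read a PDB or XYZ file into a :class:`Structure`.

    The format is inferred from the suffix when not given.  XYZ comment lines
    may carry the formal charge as a ``charge=<int>`` token.
    """
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if format == "xyz":
        return _parse_xyz(path)
    if format == "pdb":
        return _parse_pdb(path, include_waters)
    raise ValueError(f"unknown format {format!r}")


def write_structure(structure: Structure, path: str | Path, format: str | None = None) -> None:
    """Write a Structure as XYZ (with charge token) or minimal PDB."""
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if format == "xyz":
        lines = [str(len(structure)), f"charge={structure.formal_charge} {structure.title}".rstrip()]
        for a in structure.atoms:
            x, y, z = a.position
            lines.append(f"{a.element:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if format == "pdb":
        lines = []
        for a in structure.atoms:
            x, y, z = a.position
            name = a.atom_name or a.element
            lines.append(
                "ATOM  {serial:>5d} {name:<4s}{alt}{res:<3s} {chain}{seq:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                    serial=a.index + 1,
                    name=name[:4],
                    alt=" ",
                    res=(a.residue_name or "UNK")[:3],
                    chain=a.chain_id or "A",
                    seq=a.residue_seq or 1,
                    x=x,
                    y=y,
                    z=z,
                    occ=1.0,
                    b=0.0,
                    el=a.element,
                )
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# bond perception


def perceive_bonds(
    structure: Structure,
    tolerance: float = 1.2,
    extra_bonds: Iterable[tuple[int, int]] = (),
) -> BondGraph:
    """Perceive covalent bonds from the covalent-radii distance criterion.

    Atoms i, j are bonded iff ``d(i,j) <= tolerance * (r_cov(i) + r_cov(j))``.
    ``extra_bonds`` (e.g. from CONECT records) are added on top of perception.
    Raises :class:`GeometryError` for any pair closer than 0.4 Angstrom.
    """
    pos = structure.positions
    n = len(structure)
    radii = np.array([COVALENT_RADII[a.element] for a in structure.atoms])
    graph = BondGraph([], n)
    if n > 1:
        d = cdist(pos, pos)
        iu, ju = np.triu_indices(n, k=1)
        dv = d[iu, ju]
        clash = dv < 0.4
        if np.any(clash):
            k = int(np.argmax(clash))
            raise GeometryError(
                f"atoms {iu[k]} and {ju[k]} are {dv[k]:.3f} A apart "
                "(clashing or duplicate atoms)"
            )
        thresh = tolerance * (radii[iu] + radii[ju])
        for i, j in zip(iu[dv <= thresh], ju[dv <= thresh]):
            graph.add_edge(int(i), int(j))
    for i, j in extra_bonds:
        graph.add_edge(int(i), int(j))
    return graph


# ---------------------------------------------------------------------------
# backbone annotation


def _carbonyl_carbons(structure: Structure, bonds: BondGraph) -> set[int]:
    """Carbons bonded to an oxygen whose only heavy neighbor is that carbon."""
    out = set()
    elements = structure.elements
    for i, el in enumerate(elements):
        if el != "C":
            continue
        for j in bonds.neighbors(i):
            if elements[j] != "O":
                continue
            heavy = [k for k in bonds.neighbors(j) if elements[k] != "H"]
            if heavy == [i]:
                out.add(i)
                break
    return out


def annotate_backbone(structure: Structure, bonds: BondGraph) -> BackboneAnnotation:
    """Identify backbone N-CA-C(=O) motifs, peptide bonds, disulfides, prolines.

    Pattern matching runs on the bond graph alone; PDB atom names are not
    required (XYZ input works), they only seed residue numbering when present.
    """
    elements = structure.elements
    carbonyls = _carbonyl_carbons(structure, bonds)

    triples: list[tuple[int, int, int, int]] = []  # (n, ca, c, o)
    used_ca: set[int] = set()
    for c in sorted(carbonyls):
        o_idx = min(
            j
            for j in bonds.neighbors(c)
            if elements[j] == "O"
            and [k for k in bonds.neighbors(j) if elements[k] != "H"] == [c]
        )
        for ca in sorted(bonds.neighbors(c)):
            if elements[ca] != "C" or ca in carbonyls:
                continue
            n_candidates = [j for j in bonds.neighbors(ca) if elements[j] == "N"]
            if not n_candidates:
                continue
            if ca in used_ca:
                raise AnnotationError(
                    f"atom {ca} matches the C-alpha pattern of two residues"
                )
            used_ca.add(ca)
            triples.append((min(n_candidates), ca, c, o_idx))

    if not triples:
        raise AnnotationError("no backbone N-CA-C(=O) motif found")

    by_n = {t[0]: t for t in triples}
    by_c = {t[2]: t for t in triples}

    # Peptide bonds: carbonyl C of one residue bonded to the backbone N of another.
    peptide: list[tuple[int, int]] = []
    succ: dict[int, int] = {}  # c-index -> successor n-index
    for c in by_c:
        for j in bonds.neighbors(c):
            if elements[j] == "N" and j in by_n and by_n[j][2] != c:
                peptide.append((c, j))
                succ[c] = j

    # Order residues along chains: start at residues whose N has no peptide bond.
    pred_n = {n for _, n in peptide}
    ordered: list[tuple[int, int, int, int]] = []
    starts = [t for t in triples if t[0] not in pred_n]
    seen_res: set[int] = set()
    chain_ranges: dict[str, tuple[int, int]] = {}
    for start in sorted(starts, key=lambda t: t[1]):
        pos0 = len(ordered)
        t = start
        while True:
            if t[1] in seen_res:
                break
            seen_res.add(t[1])
            ordered.append(t)
            nxt = succ.get(t[2])
            if nxt is None or nxt not in by_n:
                break
            t = by_n[nxt]
        chain_id = structure.atoms[t[1]].chain_id
        chain_ranges.setdefault(chain_id, (pos0, len(ordered) - 1))
    if len(ordered) != len(triples):
        raise AnnotationError("backbone residues do not form simple chains")

    # If the file carried residue labels, every labelled amino-acid residue must
    # have matched exactly one backbone motif.
    labelled = {
        (a.chain_id, a.residue_seq)
        for a in structure.atoms
        if a.residue_name
        and a.residue_name not in {"HOH", "WAT", "UNK"}
        and a.residue_seq
    }
    if labelled:
        matched = {
            (structure.atoms[ca].chain_id, structure.atoms[ca].residue_seq)
            for _, ca, _, _ in ordered
        }
        missing = labelled - matched
        if missing:
            ch, seq = sorted(missing)[0]
            raise AnnotationError(
                f"residue {seq} (chain {ch!r}) is missing a backbone atom"
            )

    residues: list[ResidueBackbone] = []
    for pos, (n, ca, c, o) in enumerate(ordered):
        # Proline: backbone N sits in a five-ring N-CA-CB-CG-CD.
        is_pro = False
        ring_c = [
            d for d in bonds.neighbors(n) if elements[d] == "C" and d not in (ca,) and d not in carbonyls
        ]
        cb_like = [b for b in bonds.neighbors(ca) if elements[b] == "C" and b != c]
        for d in ring_c:
            for g in bonds.neighbors(d):
                if elements[g] != "C" or g in (n, ca):
                    continue
                if any(bonds.has_edge(g, b) for b in cb_like):
                    is_pro = True
        atom = structure.atoms[ca]
        residues.append(
            ResidueBackbone(
                n=n,
                c_alpha=ca,
                c_carbonyl=c,
                o_carbonyl=o,
                residue_seq=atom.residue_seq or pos + 1,
                chain_id=atom.chain_id,
                is_proline=is_pro,
            )
        )

    # Order peptide bonds along the chain.
    c_order = {r.c_carbonyl: k for k, r in enumerate(residues)}
    peptide.sort(key=lambda cn: c_order[cn[0]])

    disulfides = sorted(
        tuple(sorted(e))
        for e in bonds.edges
        if all(elements[k] == "S" for k in e)
    )
    return BackboneAnnotation(
        residues=residues,
        peptide_bonds=peptide,
        disulfide_bridges=[(int(a), int(b)) for a, b in disulfides],
        termini=chain_ranges,
    )


# ---------------------------------------------------------------------------
# hydrogen bonds and distances


def detect_hydrogen_bonds(
    structure: Structure,
    bonds: BondGraph,
    d_min: float = 1.7,
    d_max: float = 2.2,
    angle_min: float = 130.0,
    donor_acceptor_elements: frozenset[str] = frozenset({"N", "O"}),
) -> list[HydrogenBond]:
    """Return H...X contacts with d_min < d(H, X) < d_max and angle > angle_min.

    The hydrogen must be covalently bound to a donor heavy atom of a configured
    element, and must not itself be bound to the acceptor.
    """
    pos = structure.positions
    elements = structure.elements
    hydrogens = [
        i
        for i, el in enumerate(elements)
        if el == "H"
        and any(elements[j] in donor_acceptor_elements for j in bonds.neighbors(i))
    ]
    acceptors = [i for i, el in enumerate(elements) if el in donor_acceptor_elements]
    out: list[HydrogenBond] = []
    for h in hydrogens:
        donor = min(j for j in bonds.neighbors(h) if elements[j] in donor_acceptor_elements)
        for x in acceptors:
            if x == donor or bonds.has_edge(h, x):
                continue
            d = float(np.linalg.norm(pos[x] - pos[h]))
            if not (d_min < d < d_max):
                continue
            v1 = pos[donor] - pos[h]
            v2 = pos[x] - pos[h]
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang > angle_min:
                out.append(
                    HydrogenBond(
                        hydrogen=h,
                        donor_heavy=donor,
                        acceptor_heavy=x,
                        distance=d,
                        angle=ang,
                    )
                )
    out.sort(key=lambda hb: (hb.hydrogen, hb.acceptor_heavy))
    return out


def min_atom_distance(
    atoms_a: Iterable[int],
    atoms_b: Iterable[int],
    structure: Structure | np.ndarray,
) -> float:
    """Closest atom-atom distance between two disjoint index sets (all atoms count)."""
    a = sorted(set(atoms_a))
    b = sorted(set(atoms_b))
    if not a or not b:
        raise ValueError("atom sets must be nonempty")
    if set(a) & set(b):
        raise ValueError("atom sets overlap")
    pos = structure if isinstance(structure, np.ndarray) else structure.positions
    return float(cdist(pos[a], pos[b]).min())
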