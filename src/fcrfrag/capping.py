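"""Hydrogen capping of dangling bonds and merging of clash-prone combinations.

Severed bonds leave dangling valences on a fragment combination; each is
saturated by a hydrogen placed on the ray from the kept atom toward the lost
atom, at a fixed distance that depends only on the kept atom's element
(UFF-derived defaults: C 1.112, N 1.060, O 1.030 Angstrom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .schemes import DisjointFragmentation, FragmentCombination
from .structure import BondGraph, Structure, StructureError

__all__ = [
    "CAP_BOND_LENGTHS",
    "CappingError",
    "CutBond",
    "Cap",
    "CappedFragment",
    "cut_bonds_of",
    "place_caps",
    "merge_clashing",
    "write_capped_xyz",
]

# distance from the kept atom to its hydrogen cap, by kept-atom element
CAP_BOND_LENGTHS: dict[str, float] = {"C": 1.112, "N": 1.060, "O": 1.030, "S": 1.341}


class CappingError(StructureError):
    """Capping could not be performed."""


@dataclass(frozen=True)
class CutBond:
    """A severed bond at the boundary of a combination."""

    kept_atom: int
    lost_atom: int
    kept_element: str


@dataclass(frozen=True)
class Cap:
    position: tuple[float, float, float]
    replaces: int  # the lost atom this hydrogen stands in for
    attached_to: int  # the kept atom it bonds to


@dataclass
class CappedFragment:
    """A combination's real atoms plus the hydrogen caps saturating its cuts."""

    combination: FragmentCombination
    real_atoms: list[int]  # sorted global indices
    caps: list[Cap]
    total_charge: int

    @property
    def n_atoms(self) -> int:
        return len(self.real_atoms) + len(self.caps)

    def all_positions(self, structure: Structure) -> np.ndarray:
        pos = structure.positions[self.real_atoms]
        if self.caps:
            pos = np.vstack([pos, [c.position for c in self.caps]])
        return pos

    def all_elements(self, structure: Structure) -> list[str]:
        return [structure.atoms[i].element for i in self.real_atoms] + [
            "H" for _ in self.caps
        ]


def cut_bonds_of(
    combination: FragmentCombination,
    bonds: BondGraph,
    structure: Structure,
) -> list[CutBond]:
    """All bond-graph edges with exactly one endpoint inside the combination,
    ordered by (kept, lost)."""
    inside = combination.atom_set
    out: list[CutBond] = []
    for kept in sorted(inside):
        for lost in sorted(bonds.neighbors(kept)):
            if lost not in inside:
                out.append(
                    CutBond(
                        kept_atom=kept,
                        lost_atom=lost,
                        kept_element=structure.atoms[kept].element,
                    )
                )
    return out


def place_caps(
    combination: FragmentCombination,
    structure: Structure,
    bonds: BondGraph,
    cap_lengths: Mapping[str, float] | None = None,
    total_charge: int | None = None,
) -> CappedFragment:
    """Place one hydrogen per cut bond on the kept->lost ray.

    The cap sits at ``kept + length * unit(lost - kept)`` with ``length``
    looked up by the kept atom's element.  ``total_charge`` defaults to the
    structure's formal charge when the fragment spans all charged groups, and
    to 0 otherwise (neutral fixtures; engine-facing charges can be overridden).
    """
    lengths = dict(CAP_BOND_LENGTHS)
    if cap_lengths:
        lengths.update(cap_lengths)
    pos = structure.positions
    caps: list[Cap] = []
    for cb in cut_bonds_of(combination, bonds, structure):
        if cb.kept_element not in lengths:
            raise CappingError(
                f"no cap bond length configured for element {cb.kept_element!r}"
            )
        direction = pos[cb.lost_atom] - pos[cb.kept_atom]
        norm = float(np.linalg.norm(direction))
        if norm < 1e-9:
            raise CappingError(
                f"cut bond ({cb.kept_atom},{cb.lost_atom}) has zero length"
            )
        p = pos[cb.kept_atom] + lengths[cb.kept_element] * direction / norm
        caps.append(
            Cap(position=tuple(p), replaces=cb.lost_atom, attached_to=cb.kept_atom)
        )
    if total_charge is None:
        whole = len(combination.atom_set) == len(structure)
        total_charge = structure.formal_charge if whole else 0
    return CappedFragment(
        combination=combination,
        real_atoms=sorted(combination.atom_set),
        caps=caps,
        total_charge=total_charge,
    )


def merge_clashing(
    combinations: Sequence[FragmentCombination],
    structure: Structure,
    bonds: BondGraph,
    fragmentation: DisjointFragmentation,
    clash_cutoff: float = 0.9,
    cap_lengths: Mapping[str, float] | None = None,
) -> list[FragmentCombination]:
    """Merge in the group of a lost atom whose cap would clash with the fragment.

    A placed cap clashes when it comes within ``clash_cutoff`` of a real atom
    of its own fragment other than atoms covalently bound to the cap's kept
    atom.  Merging is repeated to a fixpoint, then subset combinations are
    pruned.
    """
    from .fcr import remove_subsets

    gmap = fragmentation.group_of()
    pos = structure.positions
    current = list(combinations)
    for _ in range(len(fragmentation.groups) + 1):
        changed = False
        merged: list[FragmentCombination] = []
        for combo in current:
            capped = place_caps(combo, structure, bonds, cap_lengths=cap_lengths)
            offender: int | None = None
            for cap in capped.caps:
                allowed = bonds.neighbors(cap.attached_to) | {cap.attached_to}
                others = [a for a in capped.real_atoms if a not in allowed]
                if not others:
                    continue
                d = np.linalg.norm(pos[others] - np.asarray(cap.position), axis=1)
                if float(d.min()) < clash_cutoff:
                    offender = cap.replaces
                    break
            if offender is None:
                merged.append(combo)
            else:
                changed = True
                new_groups = set(combo.group_indices) | {gmap[offender]}
                atoms = frozenset(combo.atom_set) | frozenset(
                    fragmentation.groups[gmap[offender]]
                )
                merged.append(
                    FragmentCombination(
                        group_indices=frozenset(new_groups),
                        atom_set=atoms,
                        label=combo.label + "*",
                    )
                )
                if len(atoms) == len(structure):
                    warnings.warn(
                        "clash merging grew a combination to the whole system",
                        stacklevel=2,
                    )
        current = merged
        if not changed:
            break
    return remove_subsets(current)


def write_capped_xyz(
    fragment: CappedFragment,
    structure: Structure,
    path: str | Path,
    coefficient=None,
) -> None:
    """XYZ writer: real atoms first, caps last; comment records label/p/charge."""
    lines = [str(fragment.n_atoms)]
    comment = (
        f"label={fragment.combination.label or 'fragment'} "
        f"coefficient={coefficient if coefficient is not None else 1} "
        f"charge={fragment.total_charge}"
    )
    lines.append(comment)
    pos = fragment.all_positions(structure)
    for el, p in zip(fragment.all_elements(structure), pos):
        lines.append(f"{el:<2s} {p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")
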