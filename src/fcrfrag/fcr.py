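"""Fragment-combination-range machinery: coupling, coefficients, nomenclature.

The total energy of a fragmented system is the weighted sum

    E = sum_f p_f E_f

over a *fragment combination range* (FCR): a set of fragment combinations f
with signed integer coefficients p_f.  The coefficients are fixed by the
generalized inclusion-exclusion principle through the counting identity: for
every atom set S contained in at least one primary combination, the
coefficients of all FCR terms containing S must sum to exactly one.  That
identity is what makes the expansion exact for any interaction fully
contained in some combination.

Coupling schemes build larger combinations out of the initial overlapping
ones: NeiY_d unites up to Y combinations whose proximity graph (edges at
closest atom-atom distance <= d) is connected; HierY is the same without the
distance restriction; Super is the single whole-system term.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .schemes import DisjointFragmentation, FragmentCombination, SchemeError
from .structure import Structure

__all__ = [
    "CouplingSpec",
    "CouplingLevel",
    "FCRExpansion",
    "FCRTerm",
    "MultilevelExpansion",
    "FCRError",
    "ParseError",
    "neighbor_coupling",
    "hierarchical_coupling",
    "remove_subsets",
    "compute_coefficients",
    "multilevel_split",
    "parse_spec",
    "render_spec",
]


class FCRError(Exception):
    """Inconsistent FCR construction."""


class ParseError(FCRError):
    """Malformed FCR nomenclature string."""


@dataclass(frozen=True)
class FCRTerm:
    combination: FragmentCombination
    coefficient: Fraction


@dataclass
class FCRExpansion:
    """Fragment combinations with signed inclusion-exclusion coefficients."""

    terms: list[FCRTerm]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[frozenset[int]] = set()
        for t in self.terms:
            if t.coefficient == 0:
                raise FCRError("zero coefficient in expansion")
            if t.combination.atom_set in seen:
                raise FCRError("duplicate combination atom set in expansion")
            seen.add(t.combination.atom_set)

    @property
    def coefficient_sum(self) -> Fraction:
        return sum((t.coefficient for t in self.terms), Fraction(0))

    def coefficients_integral(self) -> bool:
        return all(t.coefficient.denominator == 1 for t in self.terms)


@dataclass
class MultilevelExpansion:
    """Eq-2 decomposition: HL terms, their negated LL corrections, LL base."""

    hl_terms: FCRExpansion
    correction_terms: FCRExpansion
    ll_terms: FCRExpansion

    def __post_init__(self) -> None:
        hl = {t.combination.atom_set: t.coefficient for t in self.hl_terms.terms}
        corr = {
            t.combination.atom_set: t.coefficient for t in self.correction_terms.terms
        }
        if hl.keys() != corr.keys() or any(hl[k] != -corr[k] for k in hl):
            raise FCRError(
                "correction terms must mirror the HL terms with opposite sign"
            )


# ---------------------------------------------------------------------------
# coupling schemes


def _proximity_graph(
    combinations: Sequence[FragmentCombination],
    structure: Structure,
    cutoff: float | None,
) -> list[set[int]]:
    """Adjacency lists; with cutoff None the graph is complete."""
    n = len(combinations)
    adj: list[set[int]] = [set() for _ in range(n)]
    if cutoff is None:
        for i in range(n):
            adj[i] = set(range(n)) - {i}
        return adj
    pos = structure.positions
    idx = [sorted(c.atom_set) for c in combinations]
    for i in range(n):
        for j in range(i + 1, n):
            if combinations[i].atom_set & combinations[j].atom_set:
                d = 0.0
            else:
                d = cdist(pos[idx[i]], pos[idx[j]]).min()
            if d <= cutoff:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _connected_subsets(adj: list[set[int]], max_size: int) -> list[frozenset[int]]:
    """All connected vertex subsets of size 1..max_size (standard extension)."""
    n = len(adj)
    out: list[frozenset[int]] = []

    def extend(subset: set[int], frontier: set[int], forbidden: set[int]) -> None:
        out.append(frozenset(subset))
        if len(subset) == max_size:
            return
        frontier = set(frontier)
        banned = set(forbidden)
        while frontier:
            v = min(frontier)
            frontier.discard(v)
            banned.add(v)
            new_frontier = frontier | (adj[v] - subset - banned - {v})
            extend(subset | {v}, new_frontier, banned)

    for v in range(n):
        extend({v}, adj[v] - set(range(v + 1)), set(range(v + 1)))
    return out


def _union_combination(
    members: Iterable[int], combinations: Sequence[FragmentCombination]
) -> FragmentCombination:
    members = sorted(members)
    groups = frozenset(itertools.chain.from_iterable(
        combinations[m].group_indices for m in members
    ))
    atoms = frozenset(itertools.chain.from_iterable(
        combinations[m].atom_set for m in members
    ))
    label = "+".join(combinations[m].label or str(m) for m in members)
    return FragmentCombination(group_indices=groups, atom_set=atoms, label=label)


def neighbor_coupling(
    combinations: Sequence[FragmentCombination],
    order: int,
    cutoff: float,
    structure: Structure,
) -> list[FragmentCombination]:
    """NeiY_d: unions of up to ``order`` combinations whose proximity graph
    restricted to the members is connected; de-duplicated and subset-pruned."""
    if order < 1:
        raise FCRError("coupling order must be >= 1")
    if cutoff <= 0:
        raise FCRError("distance cutoff must be positive")
    adj = _proximity_graph(combinations, structure, cutoff)
    unions = [
        _union_combination(s, combinations)
        for s in _connected_subsets(adj, order)
    ]
    return remove_subsets(unions)


def hierarchical_coupling(
    combinations: Sequence[FragmentCombination],
    order: int,
    term_budget: int = 200_000,
) -> list[FragmentCombination]:
    """HierY: all unions of up to ``order`` combinations, no distance bound."""
    if order < 1:
        raise FCRError("coupling order must be >= 1")
    n = len(combinations)
    total = sum(
        int(np.prod([n - t for t in range(k)]) // np.prod(range(1, k + 1)))
        for k in range(1, min(order, n) + 1)
    )
    if total > term_budget:
        raise FCRError(
            f"hierarchical coupling of order {order} over {n} combinations "
            f"would generate {total} candidate terms (budget {term_budget})"
        )
    unions = [
        _union_combination(s, combinations)
        for k in range(1, min(order, n) + 1)
        for s in itertools.combinations(range(n), k)
    ]
    return remove_subsets(unions)


def remove_subsets(
    combinations: Sequence[FragmentCombination],
) -> list[FragmentCombination]:
    """Maximal antichain under atom-set inclusion, first occurrence kept."""
    kept: list[FragmentCombination] = []
    for c in combinations:
        dominated = False
        for other in combinations:
            if other.atom_set > c.atom_set:
                dominated = True
                break
        if dominated:
            continue
        if any(k.atom_set == c.atom_set for k in kept):
            continue
        kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# inclusion-exclusion coefficients


def compute_coefficients(
    final_combinations: Sequence[FragmentCombination],
    require_cover: Iterable[int] | None = None,
    provenance: str = "",
) -> FCRExpansion:
    """Assign inclusion-exclusion coefficients over the intersection closure.

    The closure of the combinations' atom sets under pairwise intersection is
    processed in order of decreasing cardinality with

        a_S = 1 - sum of a_T over closure members T strictly containing S,

    which enforces the counting identity (sum over T >= S of a_T equals one)
    for every closure member, and hence -- because the closure sets containing
    any covered atom set have a unique minimal element -- for every atom set
    contained in some primary combination.  Zero-coefficient terms are
    dropped; coefficients are exact rationals (integral for every antichain).
    """
    primaries = list(final_combinations)
    atom_sets = [c.atom_set for c in primaries]
    for i, a in enumerate(atom_sets):
        for j, b in enumerate(atom_sets):
            if i != j and a < b:
                raise FCRError("final combinations must form an antichain")
    if len(set(atom_sets)) != len(atom_sets):
        raise FCRError("duplicate combinations")
    if require_cover is not None:
        missing = set(require_cover) - set().union(*atom_sets)
        if missing:
            raise FCRError(
                f"atoms {sorted(missing)[:8]} are covered by no combination"
            )

    closure: set[frozenset[int]] = set(atom_sets)
    frontier = set(atom_sets)
    while frontier:
        new: set[frozenset[int]] = set()
        for s in frontier:
            for t in closure:
                inter = s & t
                if inter and inter not in closure and inter not in new:
                    new.add(inter)
        closure |= new
        frontier = new

    by_size = sorted(closure, key=lambda s: (-len(s), sorted(s)))
    coeff: dict[frozenset[int], Fraction] = {}
    for s in by_size:
        acc = Fraction(1)
        for t in closure:
            if t > s:
                acc -= coeff[t]
        coeff[s] = acc

    primary_by_set = {c.atom_set: c for c in primaries}
    terms: list[FCRTerm] = []
    for s in by_size:
        if coeff[s] == 0:
            continue
        combo = primary_by_set.get(s)
        if combo is None:
            member_groups = frozenset(
                itertools.chain.from_iterable(
                    c.group_indices for c in primaries if c.atom_set >= s
                )
            )
            combo = FragmentCombination(
                group_indices=member_groups,
                atom_set=s,
                label="∩".join(
                    sorted(c.label for c in primaries if c.atom_set >= s)
                )
                or f"int:{min(s)}",
            )
        terms.append(FCRTerm(combination=combo, coefficient=coeff[s]))
    return FCRExpansion(terms=terms, provenance=provenance)


# ---------------------------------------------------------------------------
# multilevel


def multilevel_split(
    spec: "CouplingSpec",
    hl_expansion: FCRExpansion,
    ll_expansion_or_super: FCRExpansion,
) -> MultilevelExpansion:
    """Substitution reading of the two-level composite energy.

    total = (LL evaluation of the LL expansion, or of the supersystem term)
            + sum over HL terms of p_f (E_f at HL - E_f at LL).
    """
    hl_atoms = frozenset().union(
        *(t.combination.atom_set for t in hl_expansion.terms)
    )
    ll_atoms = frozenset().union(
        *(t.combination.atom_set for t in ll_expansion_or_super.terms)
    )
    if hl_atoms != ll_atoms:
        raise FCRError(
            "high- and low-level expansions do not cover the same atoms"
        )
    correction = FCRExpansion(
        terms=[
            FCRTerm(combination=t.combination, coefficient=-t.coefficient)
            for t in hl_expansion.terms
        ],
        provenance=hl_expansion.provenance + " (LL correction)",
    )
    return MultilevelExpansion(
        hl_terms=hl_expansion,
        correction_terms=correction,
        ll_terms=ll_expansion_or_super,
    )


# ---------------------------------------------------------------------------
# nomenclature


@dataclass(frozen=True)
class CouplingLevel:
    kind: str  # neighbor | hierarchical | super | base
    order: int | None = None
    cutoff: float | None = None
    ee: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"neighbor", "hierarchical", "super", "base"}:
            raise FCRError(f"unknown coupling level kind {self.kind!r}")
        if self.kind == "neighbor" and (self.order is None or self.cutoff is None):
            raise FCRError("neighbor level needs order and cutoff")
        if self.kind == "hierarchical" and self.order is None:
            raise FCRError("hierarchical level needs an order")


@dataclass(frozen=True)
class CouplingSpec:
    """Parsed FCR nomenclature: scheme, scheme parameters, coupling levels."""

    scheme: str  # mfhc | ppgmbe | mim | kem
    levels: tuple[CouplingLevel, ...]
    pair_cutoff: float | None = None  # pp-GMBE
    hydrogen_bonds: bool = False  # pp-GMBE "HB" superscript
    eta: int | None = None  # MIM

    def __post_init__(self) -> None:
        if self.scheme not in {"mfhc", "ppgmbe", "mim", "kem"}:
            raise FCRError(f"unknown scheme {self.scheme!r}")
        if not self.levels:
            raise FCRError("at least one coupling level is required")
        if sum(1 for lv in self.levels if lv.ee) > 1:
            raise FCRError("at most one level may be electrostatically embedded")
        for lv in self.levels[:-1]:
            if lv.kind == "super":
                raise FCRError("[Super] may only be the last (lowest) level")
        if self.scheme == "mim" and self.eta is None:
            raise FCRError("MIM requires an eta parameter")

    @property
    def embedded(self) -> bool:
        return any(lv.ee for lv in self.levels)

    @property
    def multilevel(self) -> bool:
        return len(self.levels) > 1


_SCHEME_RE = re.compile(
    r"^(?P<name>MFHC|PAIR|MIM|KEM)"
    r"(?:_(?P<cut>\d+(?:\.\d+)?)_?)?"
    r"(?:\^?(?P<hb>HB)\^?)?"
    r"-"
)
_BRACKET_RE = re.compile(r"\[([^\[\]]*)\]")
_NEI_RE = re.compile(r"^Nei(\d+)_(\d+(?:\.\d+)?)_?(ee)?$")
_HIER_RE = re.compile(r"^Hier(\d+)(ee)?$")
_ETA_RE = re.compile(r"^(?:η|eta)\s*=\s*(\d+)\s*(ee)?$")
_BASE_RE = re.compile(r"^1(ee)?$")


def parse_spec(text: str) -> CouplingSpec:
    """Parse an FCR nomenclature string, e.g. ``MFHC-[Nei2_4.0_ee][Super]``.

    Accepted scheme tokens: MFHC, PAIR (with optional ``_d`` pair cutoff and
    ``HB`` superscript, caret markup tolerated), MIM (eta inside the first
    bracket, Greek or spelled out), KEM.  Level brackets: ``NeiY_d``,
    ``HierY``, ``Super``, ``1``, each with an optional ``ee`` suffix.
    """
    text = text.strip()
    m = _SCHEME_RE.match(text)
    if not m:
        raise ParseError(f"cannot read a scheme token at position 0 in {text!r}")
    name = m.group("name")
    scheme = {"MFHC": "mfhc", "PAIR": "ppgmbe", "MIM": "mim", "KEM": "kem"}[name]
    pair_cutoff = float(m.group("cut")) if m.group("cut") else None
    hb = m.group("hb") is not None
    if name != "PAIR" and (pair_cutoff is not None or hb):
        raise ParseError(f"only PAIR takes a cutoff/HB decoration ({text!r})")
    if name == "PAIR" and pair_cutoff is None:
        pair_cutoff = 2.2
    rest = text[m.end():]
    brackets = _BRACKET_RE.findall(rest)
    if not brackets or _BRACKET_RE.sub("", rest).strip():
        raise ParseError(
            f"expected only bracketed coupling levels after position {m.end()} "
            f"in {text!r}"
        )
    levels: list[CouplingLevel] = []
    eta: int | None = None
    for k, b in enumerate(brackets):
        b = b.strip()
        if (mm := _NEI_RE.match(b)) is not None:
            levels.append(
                CouplingLevel(
                    kind="neighbor",
                    order=int(mm.group(1)),
                    cutoff=float(mm.group(2)),
                    ee=mm.group(3) is not None,
                )
            )
        elif (mm := _HIER_RE.match(b)) is not None:
            levels.append(
                CouplingLevel(
                    kind="hierarchical",
                    order=int(mm.group(1)),
                    ee=mm.group(2) is not None,
                )
            )
        elif b in ("Super", "super"):
            levels.append(CouplingLevel(kind="super"))
        elif (mm := _ETA_RE.match(b)) is not None:
            if scheme != "mim":
                raise ParseError(f"eta bracket only applies to MIM ({text!r})")
            if k != 0:
                raise ParseError(f"the eta bracket must come first ({text!r})")
            eta = int(mm.group(1))
            levels.append(CouplingLevel(kind="base", ee=mm.group(2) is not None))
        elif (mm := _BASE_RE.match(b)) is not None:
            levels.append(CouplingLevel(kind="base", ee=mm.group(1) is not None))
        else:
            raise ParseError(f"cannot parse coupling level {b!r} in {text!r}")
    if scheme == "mim" and eta is None:
        raise ParseError(f"MIM spec must carry an eta bracket ({text!r})")
    return CouplingSpec(
        scheme=scheme,
        levels=tuple(levels),
        pair_cutoff=pair_cutoff,
        hydrogen_bonds=hb,
        eta=eta,
    )


def _format_num(x: float) -> str:
    s = f"{x:.1f}" if abs(x - round(x, 1)) < 1e-9 else f"{x:g}"
    return s


def render_spec(spec: CouplingSpec) -> str:
    """Canonical nomenclature string; ``parse_spec(render_spec(c)) == c``."""
    if spec.scheme == "mfhc":
        head = "MFHC"
    elif spec.scheme == "ppgmbe":
        head = f"PAIR_{_format_num(spec.pair_cutoff or 2.2)}"
        if spec.hydrogen_bonds:
            head += "_HB"
    elif spec.scheme == "mim":
        head = "MIM"
    else:
        head = "KEM"
    parts = []
    for k, lv in enumerate(spec.levels):
        ee = "ee" if lv.ee else ""
        if spec.scheme == "mim" and k == 0 and lv.kind == "base":
            parts.append(f"[η = {spec.eta}{ee}]")
        elif lv.kind == "neighbor":
            parts.append(f"[Nei{lv.order}_{_format_num(lv.cutoff)}{'_ee' if lv.ee else ''}]")
        elif lv.kind == "hierarchical":
            parts.append(f"[Hier{lv.order}{ee}]")
        elif lv.kind == "super":
            parts.append("[Super]")
        else:
            parts.append(f"[1{ee}]")
    return head + "-" + "".join(parts)
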