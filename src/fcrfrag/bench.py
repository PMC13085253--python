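"""Synthetic polypeptide fixtures and benchmark statistics.

The fixture builder produces ideal-geometry polypeptide chains (glycine,
alanine, a lysine-type long side chain, proline and cysteine, optionally
paired into disulfide bridges) with every hydrogen placed, so the whole
fragmentation pipeline can be exercised without any external structure file.
Geometry is built residue by residue from internal coordinates (NeRF
placement); disulfide bridges are closed by a deterministic derivative-free
adjustment of the bridged cysteines' side-chain torsions and the intervening
backbone torsions.

The statistics half of the module implements relative conformer energies,
MAD/RMSD against a reference method, fragment-size histograms, and the
benchmark driver that runs structures x fragmentation specs end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .structure import (
    COVALENT_RADII,
    Atom,
    BondGraph,
    Structure,
    StructureError,
)

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "build_polypeptide",
    "random_fixture_spec",
    "relative_energies",
    "mad_rmsd",
    "fragment_size_histogram",
    "BenchmarkReport",
    "run_benchmark",
]

SUPPORTED_RESIDUES = {"G": "GLY", "A": "ALA", "K": "LYS", "P": "PRO", "C": "CYS"}

_CONFORMATIONS = {
    "extended": (-139.0, 135.0),
    "helix": (-57.0, -47.0),
}


class FixtureError(StructureError):
    """Invalid fixture specification or failed fixture construction."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic polypeptide.

    ``sequence`` uses one-letter codes from ``GAKPC``; ``disulfide_pairs``
    holds 0-based residue index pairs that must both be cysteine.
    """

    sequence: str
    conformation: str = "extended"
    disulfide_pairs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FixtureError("sequence must be nonempty")
        bad = set(self.sequence) - set(SUPPORTED_RESIDUES)
        if bad:
            raise FixtureError(f"unsupported residue letters: {sorted(bad)}")
        if self.conformation not in (*_CONFORMATIONS, "coil"):
            raise FixtureError(f"unknown conformation {self.conformation!r}")
        seen: set[int] = set()
        for i, j in self.disulfide_pairs:
            for k in (i, j):
                if not 0 <= k < len(self.sequence):
                    raise FixtureError(f"disulfide residue index {k} out of range")
                if self.sequence[k] != "C":
                    raise FixtureError(f"disulfide residue {k} is not cysteine")
                if k in seen:
                    raise FixtureError(f"residue {k} appears in two disulfide pairs")
                seen.add(k)
            if i == j:
                raise FixtureError("disulfide pair references one residue twice")


# ---------------------------------------------------------------------------
# internal-coordinate geometry


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise FixtureError("degenerate geometry (zero-length reference vector)")
    return v / n


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom at ``bond`` from c, angle b-c-new, torsion a-b-c-new."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = _unit(np.asarray(c) - np.asarray(b))
    n = _unit(np.cross(np.asarray(b) - np.asarray(a), bc))
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return np.asarray(c) + d[0] * bc + d[1] * m + d[2] * n


_TET_HALF = math.radians(109.47) / 2.0


def _branch_directions(center, n1, n2) -> tuple[np.ndarray, np.ndarray]:
    """The two tetrahedral directions at ``center`` completing neighbors n1, n2."""
    u1 = _unit(np.asarray(n1) - center)
    u2 = _unit(np.asarray(n2) - center)
    bis = -_unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    d1 = bis * math.cos(_TET_HALF) + perp * math.sin(_TET_HALF)
    d2 = bis * math.cos(_TET_HALF) - perp * math.sin(_TET_HALF)
    return d1, d2


class _Builder:
    """Accumulates atoms, intended bonds and per-residue named positions."""

    def __init__(self, seq: str):
        self.seq = seq
        self.elements: list[str] = []
        self.names: list[str] = []
        self.res_index: list[int] = []
        self.coords: list[np.ndarray] = []
        self.bonds: set[frozenset[int]] = set()
        self.named: list[dict[str, int]] = [dict() for _ in seq]

    def add(self, element, name, res, pos, bonded_to: Sequence[int] = ()) -> int:
        idx = len(self.elements)
        self.elements.append(element)
        self.names.append(name)
        self.res_index.append(res)
        self.coords.append(np.asarray(pos, dtype=float))
        for j in bonded_to:
            self.bonds.add(frozenset((idx, j)))
        self.named[res][name] = idx
        return idx

    def pos(self, res: int, name: str) -> np.ndarray:
        return self.coords[self.named[res][name]]

    def idx(self, res: int, name: str) -> int:
        return self.named[res][name]


def _add_ch2_hydrogens(b: _Builder, res, center_name, n1_name, n2_name, names, length=1.092):
    c = b.pos(res, center_name)
    ci = b.idx(res, center_name)
    d1, d2 = _branch_directions(c, b.pos(res, n1_name), b.pos(res, n2_name))
    for name, d in zip(names, (d1, d2)):
        b.add("H", name, res, c + length * d, [ci])


def _build_chain(
    seq: str,
    phi: Sequence[float],
    psi: Sequence[float],
    chi1: dict[int, float],
    bridged: set[int],
) -> _Builder:
    """Place all atoms of the chain. ``bridged`` cysteines get no HG."""
    b = _Builder(seq)
    n_res = len(seq)
    for k, aa in enumerate(seq):
        is_pro = aa == "P"
        if k == 0:
            n_pos = np.array([0.0, 0.0, 0.0])
            ca_pos = np.array([1.458, 0.0, 0.0])
            ang = math.radians(111.2)
            c_pos = ca_pos + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
            ni = b.add("N", "N", 0, n_pos)
            cai = b.add("C", "CA", 0, ca_pos, [ni])
        else:
            prev = k - 1
            n_pos = _place(
                b.pos(prev, "N"), b.pos(prev, "CA"), b.pos(prev, "C"), 1.329, 116.2, psi[prev]
            )
            ca_pos = _place(b.pos(prev, "CA"), b.pos(prev, "C"), n_pos, 1.458, 121.7, 180.0)
            c_pos = _place(b.pos(prev, "C"), n_pos, ca_pos, 1.525, 111.2, phi[k])
            ni = b.add("N", "N", k, n_pos, [b.idx(prev, "C")])
            cai = b.add("C", "CA", k, ca_pos, [ni])
            if not is_pro:
                h_pos = _place(b.pos(prev, "CA"), b.pos(prev, "C"), n_pos, 1.010, 119.0, 0.0)
                b.add("H", "H", k, h_pos, [ni])
        ci = b.add("C", "C", k, c_pos, [cai])
        o_pos = _place(n_pos, ca_pos, c_pos, 1.231, 120.5, psi[k] + 180.0)
        b.add("O", "O", k, o_pos, [ci])

        # --- side chain heavy atoms ---
        if aa == "G":
            _add_ch2_hydrogens(b, k, "CA", "N", "C", ("HA2", "HA3"))
        else:
            d_cb, d_ha = _branch_directions(ca_pos, n_pos, c_pos)
            cb_pos = ca_pos + 1.530 * d_cb
            cbi = b.add("C", "CB", k, cb_pos, [cai])
            b.add("H", "HA", k, ca_pos + 1.092 * d_ha, [cai])
            if aa == "A":
                for t, name in ((60.0, "HB1"), (180.0, "HB2"), (300.0, "HB3")):
                    b.add("H", name, k, _place(n_pos, ca_pos, cb_pos, 1.092, 109.5, t), [cbi])
            elif aa == "C":
                sg_pos = _place(n_pos, ca_pos, cb_pos, 1.810, 114.0, chi1.get(k, 180.0))
                sgi = b.add("S", "SG", k, sg_pos, [cbi])
                _add_ch2_hydrogens(b, k, "CB", "CA", "SG", ("HB2", "HB3"))
                if k not in bridged:
                    b.add("H", "HG", k, _place(ca_pos, cb_pos, sg_pos, 1.341, 96.0, 180.0), [sgi])
            elif aa == "K":
                cg = _place(n_pos, ca_pos, cb_pos, 1.530, 111.5, chi1.get(k, 180.0))
                cgi = b.add("C", "CG", k, cg, [cbi])
                cd = _place(ca_pos, cb_pos, cg, 1.530, 111.5, 180.0)
                cdi = b.add("C", "CD", k, cd, [cgi])
                ce = _place(cb_pos, cg, cd, 1.530, 111.5, 180.0)
                cei = b.add("C", "CE", k, ce, [cdi])
                nz = _place(cg, cd, ce, 1.470, 111.0, 180.0)
                nzi = b.add("N", "NZ", k, nz, [cei])
                _add_ch2_hydrogens(b, k, "CB", "CA", "CG", ("HB2", "HB3"))
                _add_ch2_hydrogens(b, k, "CG", "CB", "CD", ("HG2", "HG3"))
                _add_ch2_hydrogens(b, k, "CD", "CG", "CE", ("HD2", "HD3"))
                _add_ch2_hydrogens(b, k, "CE", "CD", "NZ", ("HE2", "HE3"))
                for t, name in ((60.0, "HZ1"), (300.0, "HZ2")):
                    b.add("H", name, k, _place(cd, ce, nz, 1.020, 109.5, t), [nzi])
            elif aa == "P":
                # CD closes the pyrrolidine ring on CB's side of the CA-N axis.
                # For interior prolines, scan the ring-pucker torsion for the
                # position farthest from the preceding carbonyl carbon that
                # still lets CG bridge CB and CD.
                if k > 0:
                    cprev = b.pos(k - 1, "C")
                    best = None
                    for t in np.arange(-60.0, 60.1, 2.0):
                        cand = _place(cb_pos, ca_pos, n_pos, 1.473, 108.0, t)
                        if not 2.2 <= np.linalg.norm(cand - cb_pos) <= 2.55:
                            continue
                        d_prev = np.linalg.norm(cand - cprev)
                        if best is None or d_prev > best[0]:
                            best = (d_prev, cand)
                    cd_pos = best[1]
                else:
                    cd_pos = _place(cb_pos, ca_pos, n_pos, 1.473, 108.0, 0.0)
                cdi = b.add("C", "CD", k, cd_pos, [ni])
                # CG closes the ring: intersection of spheres around CB and CD,
                # taking the solution pointing away from the CA-N edge.
                cg_pos = _ring_close(cb_pos, cd_pos, ca_pos, n_pos, 1.526, 1.506)
                cgi = b.add("C", "CG", k, cg_pos, [cbi, cdi])
                _add_ch2_hydrogens(b, k, "CB", "CA", "CG", ("HB2", "HB3"))
                _add_ch2_hydrogens(b, k, "CG", "CB", "CD", ("HG2", "HG3"))
                _add_ch2_hydrogens(b, k, "CD", "CG", "N", ("HD2", "HD3"))

        # --- terminal groups ---
        if k == 0:
            if is_pro:
                u1 = _unit(b.pos(0, "CA") - n_pos)
                u2 = _unit(b.pos(0, "CD") - n_pos)
                b.add("H", "H", 0, n_pos + 1.010 * (-_unit(u1 + u2)), [ni])
            else:
                for t, name in ((60.0, "H1"), (300.0, "H2")):
                    b.add("H", name, 0, _place(c_pos, ca_pos, n_pos, 1.010, 109.5, t), [ni])
        if k == n_res - 1:
            oxt_pos = _place(n_pos, ca_pos, c_pos, 1.340, 113.0, psi[k])
            oxti = b.add("O", "OXT", k, oxt_pos, [ci])
            hxt = _place(ca_pos, c_pos, oxt_pos, 0.980, 110.5, 180.0)
            b.add("H", "HXT", k, hxt, [oxti])
    return b


def _ring_close(p1, p2, away1, away2, r1: float, r2: float) -> np.ndarray:
    """Point at distance r1 from p1 and r2 from p2, pushed away from away1/away2."""
    d = np.linalg.norm(p2 - p1)
    if d >= r1 + r2 or d <= abs(r1 - r2):
        raise FixtureError(f"proline ring cannot close (CB-CD distance {d:.2f} A)")
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h = math.sqrt(max(r1**2 - a**2, 0.0))
    base = p1 + a * _unit(p2 - p1)
    ref = 0.5 * (np.asarray(away1) + np.asarray(away2))
    perp = np.cross(p2 - p1, ref - base)
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(p2 - p1, np.array([0.0, 0.0, 1.0]))
    w = _unit(np.cross(perp, p2 - p1))
    c1 = base + h * w
    c2 = base - h * w
    return c1 if np.linalg.norm(c1 - ref) >= np.linalg.norm(c2 - ref) else c2


def _spurious_contact_penalty(b: _Builder) -> float:
    """Quadratic penalty for nonbonded pairs approaching perception range.

    1-3 pairs (sharing a bonded neighbor) occur at short range by construction
    (ring geometry, geminal atoms); they are only held above the hard bond
    perception threshold, while more distant pairs get a comfort margin.
    """
    pos = np.asarray(b.coords)
    n = len(pos)
    radii = np.array([COVALENT_RADII[e] for e in b.elements])
    adj: list[set[int]] = [set() for _ in range(n)]
    for e in b.bonds:
        i, j = tuple(e)
        adj[i].add(j)
        adj[j].add(i)
    d = cdist(pos, pos)
    iu, ju = np.triu_indices(n, k=1)
    bonded = np.fromiter(
        (int(j) in adj[int(i)] for i, j in zip(iu, ju)), dtype=bool, count=len(iu)
    )
    geminal = np.fromiter(
        (bool(adj[int(i)] & adj[int(j)]) for i, j in zip(iu, ju)),
        dtype=bool,
        count=len(iu),
    )
    margin = np.where(geminal, 0.03, 0.25)
    gap = 1.2 * (radii[iu] + radii[ju]) + margin - d[iu, ju]
    viol = np.where(~bonded & (gap > 0), gap, 0.0)
    return float(np.sum(viol**2))


def _close_disulfides(
    seq, phi, psi, pairs, rng_angles
) -> tuple[list[float], list[float], dict[int, float]]:
    """Adjust torsions so each disulfide pair's SG atoms end up ~2.05 A apart.

    Uses Nelder-Mead over the bridged cysteines' chi1 and the phi/psi of the
    residues spanned by each pair; deterministic (fixed initial simplex).
    """
    phi = list(phi)
    psi = list(psi)
    chi1: dict[int, float] = {}
    bridged = {k for pair in pairs for k in pair}
    all_pairs = sorted(tuple(sorted(p)) for p in pairs)
    for i, j in all_pairs:
        span = list(range(i, j + 1))
        var_names: list[tuple[str, int]] = [("chi1", i), ("chi1", j)]
        for k in span:
            var_names.extend((("phi", k), ("psi", k)))

        def rebuild(x):
            ph, ps, c1 = list(phi), list(psi), dict(chi1)
            for (kind, k), v in zip(var_names, x):
                if kind == "chi1":
                    c1[k] = v
                elif kind == "phi":
                    ph[k] = v
                else:
                    ps[k] = v
            built = _build_chain(seq, ph, ps, c1, bridged)
            # intended S-S bonds must not register as steric clashes
            for a, c in all_pairs:
                built.bonds.add(frozenset((built.idx(a, "SG"), built.idx(c, "SG"))))
            return built, ph, ps, c1

        def objective(x):
            try:
                built, *_ = rebuild(x)
            except FixtureError:
                return 1e6
            dss = np.linalg.norm(built.pos(i, "SG") - built.pos(j, "SG"))
            return (dss - 2.05) ** 2 + 5.0 * _spurious_contact_penalty(built)

        best = None
        for attempt, (c_i, c_j) in enumerate(
            [(-60.0, -60.0), (180.0, 180.0), (-60.0, 60.0), (60.0, -60.0), (60.0, 60.0)]
        ):
            x0 = [c_i, c_j] + [v for k in span for v in (phi[k], psi[k])]
            x0 = np.asarray(x0, dtype=float)
            if attempt:
                x0[2:] += rng_angles.uniform(-25.0, 25.0, size=len(x0) - 2)
            res = minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxiter": 400 * len(x0), "xatol": 1e-3, "fatol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < 1e-4:
                break
        if best is None or best.fun > 0.04:  # |d - 2.05| > 0.2 A or residual clash
            raise FixtureError(
                f"could not close disulfide bridge between residues {i} and {j}"
            )
        _, phi, psi, chi1 = rebuild(best.x)
    return phi, psi, chi1


def build_polypeptide(spec: FixtureSpec) -> Structure:
    """Build an all-hydrogen ideal-geometry polypeptide from a fixture recipe.

    Termini are neutral (NH2 / COOH) so the formal charge is 0.  The result is
    deterministic for a fixed spec; by construction, distance-based bond
    perception on the result recovers exactly the intended topology
    (``len(sequence) - 1`` peptide bonds and one S-S bond per disulfide pair).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.sequence)
    for attempt in range(24):
        if spec.conformation == "coil":
            phi = list(-120.0 + rng.uniform(-40.0, 40.0, size=n))
            psi = list(130.0 + rng.uniform(-40.0, 40.0, size=n))
        else:
            p0, s0 = _CONFORMATIONS[spec.conformation]
            phi = [p0] * n
            psi = [s0] * n
            if spec.conformation == "helix":
                # prolines break helices: the ring CD collides with the i-4
                # carbonyl oxygen, so kink the turn before each proline.
                for k, aa in enumerate(spec.sequence):
                    if aa == "P" and k > 0:
                        psi[k - 1] = 135.0
            if attempt:
                # residual collisions are relaxed by seeded jitter that
                # widens with each attempt.
                amp = min(6.0 + 4.0 * attempt, 40.0)
                phi = list(np.asarray(phi) + rng.uniform(-amp, amp, size=n))
                psi = list(np.asarray(psi) + rng.uniform(-amp, amp, size=n))
        chi1: dict[int, float] = {}
        bridged = {k for pair in spec.disulfide_pairs for k in pair}
        try:
            if spec.disulfide_pairs:
                phi, psi, chi1 = _close_disulfides(
                    spec.sequence, phi, psi, spec.disulfide_pairs, rng
                )
            built = _build_chain(spec.sequence, phi, psi, chi1, bridged)
        except FixtureError:
            continue
        for i, j in spec.disulfide_pairs:
            built.bonds.add(frozenset((built.idx(i, "SG"), built.idx(j, "SG"))))
        if _spurious_contact_penalty(built) == 0.0:
            break
    else:
        raise FixtureError(
            f"no clash-free conformation found for {spec.sequence!r} "
            f"({spec.conformation}, seed {spec.seed})"
        )
    atoms = [
        Atom(
            index=idx,
            element=el,
            position=tuple(pos),
            residue_seq=res + 1,
            residue_name=SUPPORTED_RESIDUES[spec.sequence[res]],
            chain_id="A",
            atom_name=name,
        )
        for idx, (el, name, res, pos) in enumerate(
            zip(built.elements, built.names, built.res_index, built.coords)
        )
    ]
    title = f"fixture {spec.sequence} {spec.conformation} seed={spec.seed}"
    return Structure(atoms=atoms, formal_charge=0, title=title)


def random_fixture_spec(
    rng: np.random.Generator,
    min_len: int = 3,
    max_len: int = 10,
    alphabet: str = "GAKPC",
    conformations: Sequence[str] = ("extended", "helix", "coil"),
) -> FixtureSpec:
    """Draw a random fixture recipe (no disulfides; those are opt-in)."""
    length = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(alphabet), size=length))
    conf = str(rng.choice(list(conformations)))
    return FixtureSpec(sequence=seq, conformation=conf, seed=int(rng.integers(2**31 - 1)))


# ---------------------------------------------------------------------------
# benchmark statistics


def relative_energies(series: Sequence[float]) -> list[float]:
    """Energies relative to the lowest-energy entry (the conformer at 0)."""
    if len(series) == 0:
        raise ValueError("series must be nonempty")
    lo = min(series)
    return [e - lo for e in series]


def mad_rmsd(test: Sequence[float], reference: Sequence[float]) -> tuple[float, float]:
    """Mean absolute and root-mean-square deviation between two relative-energy series."""
    if len(test) != len(reference):
        raise ValueError("series lengths differ")
    if len(test) == 0:
        raise ValueError("series must be nonempty")
    delta = np.asarray(test, dtype=float) - np.asarray(reference, dtype=float)
    return float(np.mean(np.abs(delta))), float(np.sqrt(np.mean(delta**2)))


def fragment_size_histogram(expansion, bin_width: int = 5):
    """Histogram of uncapped atom counts over an expansion's terms.

    Returns ``(bin_edges, counts, n_terms, max_size)``; bins are
    ``[k*w, (k+1)*w)``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    sizes = [len(term.combination.atom_set) for term in expansion.terms]
    max_size = max(sizes) if sizes else 0
    n_bins = max_size // bin_width + 1
    edges = [k * bin_width for k in range(n_bins + 1)]
    counts = [0] * n_bins
    for s in sizes:
        counts[s // bin_width] += 1
    return edges, counts, len(sizes), max_size


@dataclass
class BenchmarkReport:
    """Tabular outcome of a benchmark run plus per-spec summary statistics."""

    rows: list[dict] = field(default_factory=list)
    summaries: dict[str, dict] = field(default_factory=dict)
    histograms: dict[str, dict] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.rows).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rows": self.rows,
            "summaries": self.summaries,
            "histograms": self.histograms,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_benchmark(
    structures: Sequence[Structure],
    spec_strings: Sequence[str],
    backend,
    reference: str = "supersystem",
    backend_low=None,
    structure_ids: Sequence[str] | None = None,
) -> BenchmarkReport:
    """Run the full pipeline for every structure x fragmentation spec.

    ``reference='supersystem'`` evaluates the whole system with the same
    backend; relative energies (per spec, across structures) are compared to
    the reference's relative energies via MAD/RMSD.
    """
    from .pipeline import evaluate_supersystem, run_spec

    if structure_ids is None:
        structure_ids = [s.title or f"structure-{k}" for k, s in enumerate(structures)]
    report = BenchmarkReport()
    ref_energies = [evaluate_supersystem(s, backend) for s in structures]
    per_spec: dict[str, list[float]] = {}
    for spec_text in spec_strings:
        energies = []
        for sid, st in zip(structure_ids, structures):
            try:
                outcome = run_spec(st, spec_text, backend, backend_low=backend_low)
                energies.append(outcome.energy)
                edges, counts, n_terms, max_size = fragment_size_histogram(
                    outcome.expansion_hl
                )
                report.rows.append(
                    {
                        "structure_id": sid,
                        "spec": spec_text,
                        "n_terms": n_terms,
                        "max_fragment_atoms": max_size,
                        "energy_kj_mol": outcome.energy,
                        "reference_kj_mol": ref_energies[structure_ids.index(sid)],
                        "deviation": outcome.energy
                        - ref_energies[structure_ids.index(sid)],
                        "error": "",
                    }
                )
                report.histograms.setdefault(spec_text, {})[sid] = {
                    "edges": edges,
                    "counts": counts,
                }
            except Exception as exc:  # failed cells are recorded, not fatal
                energies.append(math.nan)
                report.rows.append(
                    {
                        "structure_id": sid,
                        "spec": spec_text,
                        "n_terms": 0,
                        "max_fragment_atoms": 0,
                        "energy_kj_mol": math.nan,
                        "reference_kj_mol": ref_energies[structure_ids.index(sid)],
                        "deviation": math.nan,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
        per_spec[spec_text] = energies
        ok = [k for k, e in enumerate(energies) if not math.isnan(e)]
        if len(ok) >= 1:
            rel_test = relative_energies([energies[k] for k in ok])
            rel_ref = relative_energies([ref_energies[k] for k in ok])
            mad, rmsd = mad_rmsd(rel_test, rel_ref)
            report.summaries[spec_text] = {
                "mad_kj_mol": mad,
                "rmsd_kj_mol": rmsd,
                "n_structures": len(ok),
            }
    return report
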