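"""Energy backends, expansion assembly and QC input-deck writing.

Backends satisfy one contract: ``evaluate(fragment, structure, embedding)``
returns the fragment's energy (kJ/mol) and per-atom charges (e) over real
atoms and caps.  When an embedding is supplied the returned energy comprises
(i) the fragment's internal energy in the field of the environment point
charges, (ii) the fragment-environment charge interaction and (iii) the
environment charges' mutual Coulomb self-energy.  Under that convention the
electrostatically embedded total

    E = sum_f p_f E_f^ee - (sum_f p_f - 1) E_Coul

is exact in the classical limit, because each embedded term carries one full
copy of the total Coulomb energy and the counting identity makes the
single subtraction cancel the surplus.

Two deterministic mock backends stand in for an electronic-structure engine:
an additive one-body + short-range pair model, and a classical point-charge
model whose charges come from a fixed per-element table.  Real engines are
reached through the input-deck writer / results-table reader pair.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .capping import CappedFragment
from .fcr import FCRExpansion, MultilevelExpansion
from .structure import GeometryError, Structure

__all__ = [
    "COULOMB_KJ_MOL",
    "EnergyError",
    "BackendResult",
    "EnvironmentCharges",
    "EnergyLedger",
    "AdditiveBackend",
    "ClassicalBackend",
    "LinearResponseBackend",
    "coulomb_energy",
    "assemble_energy",
    "assemble_multilevel",
    "assemble_ee",
    "write_qc_inputs",
    "read_results_table",
]

# e^2 / (4 pi eps0) * N_A, in kJ/mol * Angstrom / e^2
COULOMB_KJ_MOL = 1389.35457644


class EnergyError(Exception):
    """Assembly or backend bookkeeping failure."""


@dataclass(frozen=True)
class BackendResult:
    """Energy in kJ/mol and charges (e) over real atoms followed by caps."""

    energy: float
    charges: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise EnergyError("backend produced a non-finite energy")


@dataclass(frozen=True)
class EnvironmentCharges:
    """Point charges of the atoms not contained in a fragment."""

    indices: tuple[int, ...]
    charges: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.indices) == len(self.charges) == len(self.positions)):
            raise EnergyError("environment charge arrays disagree in length")


@dataclass
class _Record:
    energy: float
    embedded: bool
    charges: np.ndarray | None = None


@dataclass
class EnergyLedger:
    """Per-term energies keyed by (term label, level tag)."""

    records: dict[tuple[str, str], _Record] = field(default_factory=dict)

    def add(
        self,
        label: str,
        level: str,
        energy: float,
        charges: np.ndarray | None = None,
        embedded: bool = False,
    ) -> None:
        if not np.isfinite(energy):
            raise EnergyError(f"non-finite energy for term {label!r}")
        self.records[(label, level)] = _Record(
            energy=float(energy), embedded=embedded, charges=charges
        )

    def get(self, label: str, level: str) -> _Record:
        try:
            return self.records[(label, level)]
        except KeyError:
            raise EnergyError(
                f"ledger holds no energy for term {label!r} at level {level!r}"
            ) from None


# ---------------------------------------------------------------------------
# Coulomb


def coulomb_energy(charges: Sequence[float], positions: np.ndarray) -> float:
    """k * sum_{i<j} q_i q_j / r_ij over all charge pairs, in kJ/mol."""
    q = np.asarray(charges, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = len(q)
    if n < 2:
        return 0.0
    d = cdist(pos, pos)
    iu, ju = np.triu_indices(n, k=1)
    r = d[iu, ju]
    if np.any(r < 1e-9):
        raise GeometryError("coincident charges in Coulomb sum")
    return float(COULOMB_KJ_MOL * np.sum(q[iu] * q[ju] / r))


def _cross_coulomb(q1, pos1, q2, pos2) -> float:
    if len(q1) == 0 or len(q2) == 0:
        return 0.0
    d = cdist(np.asarray(pos1, float), np.asarray(pos2, float))
    if np.any(d < 1e-9):
        raise GeometryError("coincident charges in Coulomb cross term")
    return float(COULOMB_KJ_MOL * np.sum(np.outer(q1, q2) / d))


# ---------------------------------------------------------------------------
# mock backends


class AdditiveBackend:
    """One-body element energies plus a short-range pair term.

    ``E = sum_atoms e_Z + sum_{i<j, r_ij <= cutoff} w(r_ij)``; caps count as
    hydrogen atoms.  Charges come from a fixed per-element table (default all
    zero).  Exact supersystem assembly holds whenever every pair within the
    cutoff is covered by some combination.
    """

    def __init__(
        self,
        element_energies: Mapping[str, float] | None = None,
        pair_fn: Callable[[np.ndarray], np.ndarray] | None = None,
        cutoff: float = 4.0,
        charge_table: Mapping[str, float] | None = None,
    ):
        self.element_energies = dict(
            element_energies
            or {"H": -1.0, "C": -10.0, "N": -14.0, "O": -18.0, "S": -25.0}
        )
        self.pair_fn = pair_fn if pair_fn is not None else (lambda r: -np.exp(-r))
        self.cutoff = cutoff
        self.charge_table = dict(charge_table or {})

    def _charges(self, elements: Sequence[str]) -> np.ndarray:
        return np.array([self.charge_table.get(el, 0.0) for el in elements])

    def evaluate(
        self,
        fragment: CappedFragment,
        structure: Structure,
        embedding: EnvironmentCharges | None = None,
    ) -> BackendResult:
        elements = fragment.all_elements(structure)
        pos = fragment.all_positions(structure)
        energy = float(sum(self.element_energies[el] for el in elements))
        if len(pos) > 1:
            d = cdist(pos, pos)
            iu, ju = np.triu_indices(len(pos), k=1)
            r = d[iu, ju]
            within = r <= self.cutoff
            if np.any(within):
                energy += float(np.sum(self.pair_fn(r[within])))
        q = self._charges(elements)
        if embedding is not None:
            energy += _cross_coulomb(q, pos, embedding.charges, embedding.positions)
            energy += coulomb_energy(embedding.charges, embedding.positions)
        return BackendResult(energy=energy, charges=q)


class ClassicalBackend:
    """Point-charge model: one-body terms plus the Coulomb energy of a fixed
    per-element charge table.  Caps are passive (zero charge, no one-body
    term), so the model is strictly a function of the real atoms; embedding
    with its own charges reproduces the supersystem energy exactly through
    the embedded assembly identity.
    """

    def __init__(
        self,
        charge_table: Mapping[str, float] | None = None,
        element_energies: Mapping[str, float] | None = None,
    ):
        self.charge_table = dict(
            charge_table
            or {"H": 0.11, "C": -0.06, "N": -0.32, "O": -0.38, "S": -0.16}
        )
        self.element_energies = dict(
            element_energies or {"H": -2.0, "C": -20.0, "N": -28.0, "O": -36.0, "S": -50.0}
        )

    def charges_for(self, structure: Structure, indices: Sequence[int]) -> np.ndarray:
        """Table charges with a uniform shift making the supersystem's total
        match its formal charge exactly (the mock analogue of a population
        analysis conserving the molecular charge)."""
        table_total = sum(
            self.charge_table[a.element] for a in structure.atoms
        )
        shift = (table_total - structure.formal_charge) / len(structure)
        return np.array(
            [self.charge_table[structure.atoms[i].element] - shift for i in indices]
        )

    def evaluate(
        self,
        fragment: CappedFragment,
        structure: Structure,
        embedding: EnvironmentCharges | None = None,
    ) -> BackendResult:
        real = fragment.real_atoms
        pos = structure.positions[real]
        q = self.charges_for(structure, real)
        energy = float(
            sum(self.element_energies[structure.atoms[i].element] for i in real)
        )
        energy += coulomb_energy(q, pos)
        if embedding is not None:
            energy += _cross_coulomb(q, pos, embedding.charges, embedding.positions)
            energy += coulomb_energy(embedding.charges, embedding.positions)
        charges = np.concatenate([q, np.zeros(len(fragment.caps))])
        return BackendResult(energy=energy, charges=charges)


class LinearResponseBackend(ClassicalBackend):
    """Classical backend whose charges respond linearly to the embedding field.

    ``q_i = q0_i + alpha * sum_env Q_j / r_ij`` (polarizable-mock, used to
    exercise the iterative embedding-charge loop); the charge response is
    damped by charge conservation: the response terms are shifted to keep the
    fragment total unchanged.
    """

    def __init__(self, alpha: float = 0.01, **kwargs):
        super().__init__(**kwargs)
        self.alpha = alpha

    def evaluate(
        self,
        fragment: CappedFragment,
        structure: Structure,
        embedding: EnvironmentCharges | None = None,
    ) -> BackendResult:
        base = super().evaluate(fragment, structure, embedding)
        if embedding is None or len(embedding.indices) == 0:
            return base
        real = fragment.real_atoms
        pos = structure.positions[real]
        d = cdist(pos, np.asarray(embedding.positions, float))
        v = np.sum(np.asarray(embedding.charges, float)[None, :] / d, axis=1)
        dq = self.alpha * v
        dq -= dq.mean()  # conserve the fragment total charge
        charges = base.charges.copy()
        charges[: len(real)] += dq
        return BackendResult(energy=base.energy, charges=charges)


# ---------------------------------------------------------------------------
# assembly


def _sorted_terms(expansion: FCRExpansion):
    return sorted(expansion.terms, key=lambda t: t.combination.label)


def assemble_energy(
    expansion: FCRExpansion, ledger: EnergyLedger, level: str = "SL"
) -> float:
    """``sum_f p_f E_f`` in canonical (label-sorted) order."""
    total = 0.0
    for t in _sorted_terms(expansion):
        rec = ledger.get(t.combination.label, level)
        total += float(t.coefficient) * rec.energy
    return total


def assemble_multilevel(ml: MultilevelExpansion, ledger: EnergyLedger) -> float:
    """``E = assemble(LL expansion at LL) + sum_f p_f (E_f^HL - E_f^LL)``."""
    total = assemble_energy(ml.ll_terms, ledger, level="LL")
    for t in _sorted_terms(ml.hl_terms):
        hl = ledger.get(t.combination.label, "HL").energy
        ll = ledger.get(t.combination.label, "LL").energy
        total += float(t.coefficient) * (hl - ll)
    return total


def assemble_ee(
    expansion: FCRExpansion, ledger: EnergyLedger, e_coul: float, level: str = "SL"
) -> float:
    """``sum_f p_f E_f^ee - (sum_f p_f - 1) E_Coul`` (embedded records only)."""
    total = 0.0
    for t in _sorted_terms(expansion):
        rec = ledger.get(t.combination.label, level)
        if not rec.embedded:
            raise EnergyError(
                f"term {t.combination.label!r} was not evaluated with embedding"
            )
        total += float(t.coefficient) * rec.energy
    total -= float(expansion.coefficient_sum - 1) * e_coul
    return total


# ---------------------------------------------------------------------------
# external-engine exchange


def write_qc_inputs(
    expansion: FCRExpansion,
    fragments: Mapping[str, CappedFragment],
    structure: Structure,
    out_dir: str | Path,
    method: str = "! PBEh-3c",
    embedding=None,
    dialect: str = "generic",
) -> Path:
    """One input deck per term plus a manifest; optional point-charge files.

    ``embedding`` is a ChargeSet-like object with a ``charges`` array over all
    real atoms; each term then gets a companion ``.pc`` file listing the
    environment charges (ORCA layout: count, then ``q x y z`` per line).
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"method": method, "dialect": dialect, "terms": []}
    for t in _sorted_terms(expansion):
        label = t.combination.label
        frag = fragments[label]
        stem = label.replace("/", "_").replace(":", "_")
        deck = out / f"{stem}.inp"
        lines = [method]
        pc_name = None
        if embedding is not None:
            pc_name = f"{stem}.pc"
            lines.append(f'%pointcharges "{pc_name}"')
        lines.append(f"* xyz {frag.total_charge} 1")
        for el, p in zip(frag.all_elements(structure), frag.all_positions(structure)):
            lines.append(f"  {el:<2s} {p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f}")
        lines.append("*")
        deck.write_text("\n".join(lines) + "\n")
        if embedding is not None:
            env = [i for i in range(len(structure)) if i not in t.combination.atom_set]
            pc_lines = [str(len(env))]
            for i in env:
                x, y, z = structure.atoms[i].position
                pc_lines.append(
                    f"{float(embedding.charges[i]):12.8f} {x:15.8f} {y:15.8f} {z:15.8f}"
                )
            (out / pc_name).write_text("\n".join(pc_lines) + "\n")
        manifest["terms"].append(
            {
                "label": label,
                "deck": deck.name,
                "pointcharges": pc_name,
                "coefficient": str(t.coefficient),
                "n_real_atoms": len(frag.real_atoms),
                "n_caps": len(frag.caps),
                "charge": frag.total_charge,
            }
        )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_results_table(
    path: str | Path,
    embedding=None,
    structure: Structure | None = None,
    expansion: FCRExpansion | None = None,
    env_self_energy_included: bool = True,
) -> EnergyLedger:
    """Read ``label, level, energy_kj_mol[, q0, q1, ...]`` rows into a ledger.

    Engines usually report the fragment-in-field energy without the
    environment charges' mutual Coulomb self-energy; pass
    ``env_self_energy_included=False`` together with ``embedding`` (ChargeSet
    over all real atoms), ``structure`` and ``expansion`` to add it, restoring
    the backend convention this package assembles with.
    """
    ledger = EnergyLedger()
    atom_sets = (
        {t.combination.label: t.combination.atom_set for t in expansion.terms}
        if expansion is not None
        else {}
    )
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"]
            level = row.get("level", "SL") or "SL"
            energy = float(row["energy_kj_mol"])
            qcols = sorted(
                (k for k in row if k.startswith("q") and k[1:].isdigit()),
                key=lambda k: int(k[1:]),
            )
            charges = (
                np.array([float(row[k]) for k in qcols if row[k] != ""])
                if qcols
                else None
            )
            embedded = embedding is not None
            if embedded and not env_self_energy_included:
                if structure is None or label not in atom_sets:
                    raise EnergyError(
                        "adding the environment self-energy requires the "
                        "structure and the expansion"
                    )
                env = sorted(set(range(len(structure))) - atom_sets[label])
                energy += coulomb_energy(
                    np.asarray(embedding.charges)[env], structure.positions[env]
                )
            ledger.add(label, level, energy, charges=charges, embedded=embedded)
    return ledger
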