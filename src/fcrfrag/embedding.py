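"""Iterative derivation of embedding point charges from a small FCR.

Per-fragment charges from the backend are first *redistributed*: each
hydrogen cap's charge is added onto the atom the cap replaces, which keeps
every fragment's total charge exact while only mildly perturbing individual
atomic charges.  The redistributed per-term charges are then combined with
the FCR coefficients (the counting identity makes this a weighted average
with unit weight per atom, up to cap spill-over), giving one point charge per
real atom.  Re-evaluating the small FCR inside the field of those charges and
re-assembling yields the next iterate; two embedded iterations after the
initial gas-phase pass are the default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .capping import CappedFragment
from .energy import EnergyError, EnvironmentCharges
from .fcr import FCRExpansion
from .structure import Structure

__all__ = [
    "ChargeSet",
    "EmbeddingConfig",
    "ChargeError",
    "redistribute_cap_charges",
    "assemble_atomic_charges",
    "environment_for",
    "iterate_embedding_charges",
    "write_charge_csv",
    "read_charge_csv",
]

DEFAULT_CHARGE_FCR_SPECS = {
    "mfhc": "MFHC-[1]",
    "ppgmbe": "PAIR_2.2_HB-[1]",
    "mim": "MIM-[η = 3]",
    "kem": "KEM-[1]",
}


class ChargeError(EnergyError):
    """Charge bookkeeping failure (coverage, conservation, missing data)."""


@dataclass
class ChargeSet:
    """Per-atom point charges (e) over all real atoms of the structure."""

    charges: np.ndarray
    iteration: int = 0
    source_spec: str = ""

    def validate_total(self, formal_charge: int, tol: float = 1e-6) -> None:
        total = float(np.sum(self.charges))
        if abs(total - formal_charge) > tol:
            raise ChargeError(
                f"charges sum to {total:.8f} e, expected {formal_charge}"
            )


@dataclass(frozen=True)
class EmbeddingConfig:
    """How embedding charges are derived: iterations and per-scheme small FCR."""

    n_iterations: int = 2
    charge_fcr_specs: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHARGE_FCR_SPECS)
    )

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ChargeError("n_iterations must be >= 0")


def redistribute_cap_charges(
    fragment: CappedFragment, charges: np.ndarray
) -> dict[int, float]:
    """Fold each cap's charge onto the atom the cap replaces.

    ``charges`` covers real atoms then caps.  The result maps global atom
    indices (fragment atoms plus replaced atoms) to charges; the total is
    preserved exactly.
    """
    charges = np.asarray(charges, dtype=float)
    n_real = len(fragment.real_atoms)
    if len(charges) != n_real + len(fragment.caps):
        raise ChargeError(
            f"expected {n_real + len(fragment.caps)} charges, got {len(charges)}"
        )
    out: dict[int, float] = {
        a: float(q) for a, q in zip(fragment.real_atoms, charges[:n_real])
    }
    for cap, q in zip(fragment.caps, charges[n_real:]):
        if cap.replaces is None:
            raise ChargeError("cap has no recorded replaced atom")
        out[cap.replaces] = out.get(cap.replaces, 0.0) + float(q)
    return out


def assemble_atomic_charges(
    expansion: FCRExpansion,
    per_term_charges: Mapping[str, Mapping[int, float]],
    n_atoms: int,
    iteration: int = 0,
) -> ChargeSet:
    """Coefficient-weighted combination of redistributed per-term charges."""
    covered: set[int] = set()
    for t in expansion.terms:
        covered |= t.combination.atom_set
    missing = set(range(n_atoms)) - covered
    if missing:
        raise ChargeError(f"atoms {sorted(missing)[:8]} appear in no term")
    q = np.zeros(n_atoms)
    for t in expansion.terms:
        contrib = per_term_charges[t.combination.label]
        p = float(t.coefficient)
        for a, qa in contrib.items():
            q[a] += p * qa
    return ChargeSet(charges=q, iteration=iteration, source_spec=expansion.provenance)


def environment_for(
    fragment: CappedFragment, charge_set: ChargeSet, structure: Structure
) -> EnvironmentCharges:
    """Charges of every real atom outside the fragment (caps never carry any)."""
    inside = set(fragment.real_atoms)
    env = [i for i in range(len(structure)) if i not in inside]
    return EnvironmentCharges(
        indices=tuple(env),
        charges=np.asarray(charge_set.charges)[env],
        positions=structure.positions[env],
    )


def iterate_embedding_charges(
    structure: Structure,
    expansion: FCRExpansion,
    fragments: Mapping[str, CappedFragment],
    backend,
    config: EmbeddingConfig = EmbeddingConfig(),
) -> ChargeSet:
    """Gas-phase pass, then ``n_iterations`` embedded re-evaluations.

    Every iterate is checked to sum to the structure's formal charge.
    """
    def one_pass(charge_set: ChargeSet | None, iteration: int) -> ChargeSet:
        per_term: dict[int, dict[int, float]] = {}
        for t in expansion.terms:
            frag = fragments[t.combination.label]
            emb = (
                environment_for(frag, charge_set, structure)
                if charge_set is not None
                else None
            )
            try:
                result = backend.evaluate(frag, structure, embedding=emb)
            except Exception as exc:
                raise ChargeError(
                    f"backend failed on term {t.combination.label!r} "
                    f"at iteration {iteration}: {exc}"
                ) from exc
            per_term[t.combination.label] = redistribute_cap_charges(
                frag, result.charges
            )
        cs = assemble_atomic_charges(
            expansion, per_term, len(structure), iteration=iteration
        )
        cs.validate_total(structure.formal_charge)
        return cs

    current = one_pass(None, 0)
    for k in range(1, config.n_iterations + 1):
        current = one_pass(current, k)
    return current


def write_charge_csv(charge_set: ChargeSet, structure: Structure, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["atom_index", "element", "q"])
        for i, atom in enumerate(structure.atoms):
            w.writerow([i, atom.element, f"{charge_set.charges[i]:.10f}"])


def read_charge_csv(path: str | Path, n_atoms: int | None = None) -> ChargeSet:
    rows: dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows[int(row["atom_index"])] = float(row["q"])
    n = n_atoms if n_atoms is not None else (max(rows) + 1 if rows else 0)
    if set(rows) != set(range(n)):
        raise ChargeError("charge CSV does not cover atoms 0..N-1 exactly")
    return ChargeSet(charges=np.array([rows[i] for i in range(n)]))
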