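"""End-to-end driver: nomenclature string + structure -> assembled energy.

This module glues the building blocks together in the canonical order:
perceive bonds, annotate the backbone, build the scheme's disjoint fragments
and initial overlapping combinations, apply the coupling levels, merge
clash-prone combinations, compute inclusion-exclusion coefficients, cap,
evaluate with a backend (optionally inside iteratively derived embedding
charges) and assemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .capping import CappedFragment, place_caps, merge_clashing, write_capped_xyz
from .embedding import (
    ChargeSet,
    EmbeddingConfig,
    environment_for,
    iterate_embedding_charges,
)
from .energy import (
    EnergyLedger,
    assemble_ee,
    assemble_energy,
    assemble_multilevel,
    coulomb_energy,
)
from .fcr import (
    CouplingLevel,
    CouplingSpec,
    FCRError,
    FCRExpansion,
    FCRTerm,
    compute_coefficients,
    hierarchical_coupling,
    multilevel_split,
    neighbor_coupling,
    parse_spec,
    render_spec,
)
from .schemes import (
    DisjointFragmentation,
    FragmentCombination,
    kem_disjoint,
    mfhc_disjoint,
    mfhc_overlapping,
    mim_disjoint,
    mim_overlapping,
    ppgmbe_disjoint,
    ppgmbe_pairs,
)
from .structure import (
    BackboneAnnotation,
    BondGraph,
    Structure,
    annotate_backbone,
    detect_hydrogen_bonds,
    perceive_bonds,
)

__all__ = [
    "FragmentationContext",
    "BuiltExpansion",
    "PipelineOutcome",
    "prepare",
    "build_expansion",
    "run_spec",
    "evaluate_supersystem",
    "export_fragments",
    "write_expansion_manifest",
]


@dataclass
class FragmentationContext:
    structure: Structure
    bonds: BondGraph
    backbone: BackboneAnnotation
    hbonds: list = field(default_factory=list)


def prepare(structure: Structure, bond_tolerance: float = 1.2) -> FragmentationContext:
    bonds = perceive_bonds(structure, tolerance=bond_tolerance)
    backbone = annotate_backbone(structure, bonds)
    hbonds = detect_hydrogen_bonds(structure, bonds)
    return FragmentationContext(
        structure=structure, bonds=bonds, backbone=backbone, hbonds=hbonds
    )


def _disjoint_for(ctx: FragmentationContext, spec: CouplingSpec) -> DisjointFragmentation:
    if spec.scheme == "mfhc":
        return mfhc_disjoint(ctx.structure, ctx.bonds, ctx.backbone)
    if spec.scheme == "ppgmbe":
        return ppgmbe_disjoint(ctx.structure, ctx.bonds, ctx.backbone)
    if spec.scheme == "mim":
        return mim_disjoint(ctx.structure, ctx.bonds, ctx.backbone)
    return kem_disjoint(ctx.structure, ctx.bonds, ctx.backbone)


def _initial_overlapping(
    ctx: FragmentationContext,
    spec: CouplingSpec,
    disjoint: DisjointFragmentation,
) -> list[FragmentCombination]:
    if spec.scheme == "mfhc":
        return mfhc_overlapping(disjoint, ctx.bonds, ctx.backbone)
    if spec.scheme == "ppgmbe":
        hb = ctx.hbonds if spec.hydrogen_bonds else []
        return ppgmbe_pairs(
            disjoint, ctx.structure, hbonds=hb, pair_cutoff=spec.pair_cutoff or 2.2
        )
    if spec.scheme == "mim":
        return mim_overlapping(disjoint, ctx.structure, ctx.bonds, eta=spec.eta)
    # KEM: each residue group is its own initial overlapping combination
    return [
        FragmentCombination.from_groups((gi,), disjoint, label=f"kem:{gi}")
        for gi in range(len(disjoint.groups))
    ]


@dataclass
class BuiltExpansion:
    expansion: FCRExpansion
    fragments: dict[str, CappedFragment]
    disjoint: DisjointFragmentation
    level: CouplingLevel


def _relabel(expansion: FCRExpansion, prefix: str) -> FCRExpansion:
    """Give terms unique, deterministic labels (ledger and deck keys)."""
    terms = []
    for k, t in enumerate(
        sorted(expansion.terms, key=lambda t: (min(t.combination.atom_set),
                                               -len(t.combination.atom_set),
                                               sorted(t.combination.atom_set)))
    ):
        combo = FragmentCombination(
            group_indices=t.combination.group_indices,
            atom_set=t.combination.atom_set,
            label=f"{prefix}{k:04d}",
        )
        terms.append(FCRTerm(combination=combo, coefficient=t.coefficient))
    return FCRExpansion(terms=terms, provenance=expansion.provenance)


def _build_level(
    ctx: FragmentationContext,
    spec: CouplingSpec,
    level: CouplingLevel,
    disjoint: DisjointFragmentation,
    initial: list[FragmentCombination],
    prefix: str,
) -> BuiltExpansion:
    from .fcr import remove_subsets

    n_atoms = len(ctx.structure)
    if level.kind == "super":
        combo = FragmentCombination(
            group_indices=frozenset(range(len(disjoint.groups))),
            atom_set=frozenset(range(n_atoms)),
            label=f"{prefix}super",
        )
        expansion = FCRExpansion(
            terms=[FCRTerm(combination=combo, coefficient=Fraction(1))],
            provenance=render_spec(spec),
        )
        fragments = {
            combo.label: place_caps(combo, ctx.structure, ctx.bonds)
        }
        return BuiltExpansion(
            expansion=expansion, fragments=fragments, disjoint=disjoint, level=level
        )
    if level.kind == "base":
        combos = remove_subsets(initial)
    elif level.kind == "neighbor":
        combos = neighbor_coupling(initial, level.order, level.cutoff, ctx.structure)
    elif level.kind == "hierarchical":
        combos = hierarchical_coupling(initial, level.order)
    else:  # pragma: no cover - spec validation forbids this
        raise FCRError(f"unsupported level kind {level.kind!r}")
    combos = merge_clashing(combos, ctx.structure, ctx.bonds, disjoint)
    expansion = compute_coefficients(
        combos, require_cover=range(n_atoms), provenance=render_spec(spec)
    )
    expansion = _relabel(expansion, prefix)
    fragments = {
        t.combination.label: place_caps(t.combination, ctx.structure, ctx.bonds)
        for t in expansion.terms
    }
    return BuiltExpansion(
        expansion=expansion, fragments=fragments, disjoint=disjoint, level=level
    )


def build_expansion(
    structure_or_ctx: Structure | FragmentationContext,
    spec_text: str | CouplingSpec,
    level_index: int = 0,
) -> BuiltExpansion:
    """Build the FCR expansion of one coupling level of a nomenclature spec."""
    ctx = (
        structure_or_ctx
        if isinstance(structure_or_ctx, FragmentationContext)
        else prepare(structure_or_ctx)
    )
    spec = spec_text if isinstance(spec_text, CouplingSpec) else parse_spec(spec_text)
    level = spec.levels[level_index]
    disjoint = _disjoint_for(ctx, spec)
    initial = (
        _initial_overlapping(ctx, spec, disjoint) if level.kind != "super" else []
    )
    prefix = "hl" if level_index == 0 else "ll"
    return _build_level(ctx, spec, level, disjoint, initial, prefix=f"{prefix}-")


@dataclass
class PipelineOutcome:
    energy: float
    spec: CouplingSpec
    expansion_hl: FCRExpansion
    expansion_ll: FCRExpansion | None = None
    ledger: EnergyLedger | None = None
    charge_set: ChargeSet | None = None


def evaluate_supersystem(structure: Structure, backend) -> float:
    """Whole-system single-fragment evaluation with the given backend."""
    ctx = prepare(structure)
    combo = FragmentCombination(
        group_indices=frozenset({0}),
        atom_set=frozenset(range(len(structure))),
        label="super",
    )
    frag = place_caps(combo, ctx.structure, ctx.bonds)
    return backend.evaluate(frag, structure).energy


def _evaluate_terms(
    built: BuiltExpansion,
    structure: Structure,
    backend,
    ledger: EnergyLedger,
    level_tag: str,
    charge_set: ChargeSet | None = None,
) -> None:
    for t in built.expansion.terms:
        frag = built.fragments[t.combination.label]
        emb = (
            environment_for(frag, charge_set, structure)
            if charge_set is not None
            else None
        )
        result = backend.evaluate(frag, structure, embedding=emb)
        ledger.add(
            t.combination.label,
            level_tag,
            result.energy,
            charges=result.charges,
            embedded=emb is not None,
        )


def run_spec(
    structure: Structure,
    spec_text: str | CouplingSpec,
    backend,
    backend_low=None,
    embedding_config: EmbeddingConfig = EmbeddingConfig(),
) -> PipelineOutcome:
    """Full pipeline for one nomenclature spec on one structure."""
    ctx = prepare(structure)
    spec = spec_text if isinstance(spec_text, CouplingSpec) else parse_spec(spec_text)
    built_hl = build_expansion(ctx, spec, level_index=0)
    ledger = EnergyLedger()

    if spec.embedded:
        if spec.multilevel:
            raise FCRError(
                "electrostatic embedding is supported for single-level specs"
            )
        small_text = embedding_config.charge_fcr_specs[spec.scheme]
        small_spec = parse_spec(small_text)
        if spec.scheme == "ppgmbe":
            small_spec = CouplingSpec(
                scheme="ppgmbe",
                levels=small_spec.levels,
                pair_cutoff=spec.pair_cutoff,
                hydrogen_bonds=spec.hydrogen_bonds,
            )
        built_small = build_expansion(ctx, small_spec, level_index=0)
        charge_set = iterate_embedding_charges(
            structure,
            built_small.expansion,
            built_small.fragments,
            backend,
            config=embedding_config,
        )
        _evaluate_terms(built_hl, structure, backend, ledger, "SL", charge_set)
        e_coul = coulomb_energy(charge_set.charges, structure.positions)
        energy = assemble_ee(built_hl.expansion, ledger, e_coul, level="SL")
        return PipelineOutcome(
            energy=energy,
            spec=spec,
            expansion_hl=built_hl.expansion,
            ledger=ledger,
            charge_set=charge_set,
        )

    if spec.multilevel:
        if len(spec.levels) != 2:
            raise FCRError("only two-level multilevel specs are supported")
        backend_low = backend_low if backend_low is not None else backend
        built_ll = build_expansion(ctx, spec, level_index=1)
        ml = multilevel_split(spec, built_hl.expansion, built_ll.expansion)
        _evaluate_terms(built_hl, structure, backend, ledger, "HL")
        _evaluate_terms(built_hl, structure, backend_low, ledger, "LL")
        # LL base terms may coincide with HL terms by label only within their
        # own expansion; evaluate them under the LL tag as well
        _evaluate_terms(built_ll, structure, backend_low, ledger, "LL")
        energy = assemble_multilevel(ml, ledger)
        return PipelineOutcome(
            energy=energy,
            spec=spec,
            expansion_hl=built_hl.expansion,
            expansion_ll=built_ll.expansion,
            ledger=ledger,
        )

    _evaluate_terms(built_hl, structure, backend, ledger, "SL")
    energy = assemble_energy(built_hl.expansion, ledger, level="SL")
    return PipelineOutcome(
        energy=energy, spec=spec, expansion_hl=built_hl.expansion, ledger=ledger
    )


# ---------------------------------------------------------------------------
# exports


def export_fragments(
    built: BuiltExpansion, structure: Structure, out_dir: str | Path
) -> Path:
    """Write one capped-fragment XYZ per term plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    coeff = {t.combination.label: t.coefficient for t in built.expansion.terms}
    for label in sorted(built.fragments):
        frag = built.fragments[label]
        path = out / f"{label}.xyz"
        write_capped_xyz(frag, structure, path, coefficient=coeff.get(label))
        manifest.append(
            {
                "label": label,
                "file": path.name,
                "coefficient": str(coeff.get(label)),
                "group_indices": sorted(frag.combination.group_indices),
                "atom_indices": frag.real_atoms,
                "n_caps": len(frag.caps),
            }
        )
    manifest_path = out / "fragments.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def write_expansion_manifest(
    expansion: FCRExpansion, path: str | Path, fmt: str = "json"
) -> None:
    """JSON/CSV listing of spec string, labels, groups, sizes, coefficients."""
    rows = [
        {
            "spec": expansion.provenance,
            "label": t.combination.label,
            "group_indices": sorted(t.combination.group_indices),
            "n_atoms": len(t.combination.atom_set),
            "coefficient": str(t.coefficient),
        }
        for t in expansion.terms
    ]
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=1))
    elif fmt == "csv":
        import csv as _csv

        with open(path, "w", newline="") as fh:
            w = _csv.DictWriter(
                fh, fieldnames=["spec", "label", "group_indices", "n_atoms", "coefficient"]
            )
            w.writeheader()
            for r in rows:
                r = dict(r)
                r["group_indices"] = " ".join(map(str, r["group_indices"]))
                w.writerow(r)
    else:
        raise ValueError(f"unknown manifest format {fmt!r}")
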