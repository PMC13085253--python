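"""Scheme-specific disjoint fragmentations and overlapping combinations."""

from __future__ import annotations

import numpy as np
import pytest

from fcrfrag.bench import FixtureSpec, build_polypeptide, random_fixture_spec
from fcrfrag.schemes import (
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
from fcrfrag.structure import Atom, HydrogenBond, Structure, perceive_bonds, annotate_backbone


def _all_schemes(structure, ctx):
    bonds, bb = ctx.bonds, ctx.backbone
    return {
        "mfhc": mfhc_disjoint(structure, bonds, bb),
        "ppgmbe": ppgmbe_disjoint(structure, bonds, bb),
        "mim": mim_disjoint(structure, bonds, bb),
        "kem": kem_disjoint(structure, bonds, bb),
    }


class TestMFHC:
    def test_single_residue_is_one_group(self, single_gly, ctx_of):
        ctx = ctx_of(single_gly)
        dj = mfhc_disjoint(single_gly, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 1
        assert dj.groups[0] == frozenset(range(len(single_gly)))

    def test_dipeptide_three_groups(self, dipeptide_ala, ctx_of):
        ctx = ctx_of(dipeptide_ala)
        dj = mfhc_disjoint(dipeptide_ala, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 3
        # the central peptide unit is HN-CO: 4 atoms
        sizes = sorted(len(g) for g in dj.groups)
        assert 4 in sizes
        peptide_group = [g for g in dj.groups if len(g) == 4][0]
        elements = sorted(dipeptide_ala.atoms[i].element for i in peptide_group)
        assert elements == ["C", "H", "N", "O"]

    def test_disulfide_forms_dedicated_group(self, cys_bridge, ctx_of):
        ctx = ctx_of(cys_bridge)
        dj = mfhc_disjoint(cys_bridge, ctx.bonds, ctx.backbone)
        ss_groups = [
            g
            for g in dj.groups
            if any(cys_bridge.atoms[i].element == "S" for i in g)
        ]
        assert len(ss_groups) == 1
        elements = sorted(cys_bridge.atoms[i].element for i in ss_groups[0])
        # CH2-S-S-CH2: two carbons, four hydrogens, two sulfurs
        assert elements == ["C", "C", "H", "H", "H", "H", "S", "S"]

    def test_proline_peptide_unit_keeps_nitrogen(self, proline_peptide, ctx_of):
        ctx = ctx_of(proline_peptide)
        dj = mfhc_disjoint(proline_peptide, ctx.bonds, ctx.backbone)
        pro_n = ctx.backbone.residues[1].n
        unit = [g for g in dj.groups if pro_n in g][0]
        # the unit holds the preceding carbonyl C and O plus this N, no H on N
        elements = sorted(proline_peptide.atoms[i].element for i in unit)
        assert elements == ["C", "N", "O"]

    def test_overlapping_dipeptide(self, dipeptide_ala, ctx_of):
        ctx = ctx_of(dipeptide_ala)
        dj = mfhc_disjoint(dipeptide_ala, ctx.bonds, ctx.backbone)
        combos = mfhc_overlapping(dj, ctx.bonds, ctx.backbone)
        assert len(combos) == 2
        inter = combos[0].atom_set & combos[1].atom_set
        peptide_group = [g for g in dj.groups if len(g) == 4][0]
        assert inter == peptide_group

    def test_overlapping_tripeptide_middle_holds_three_groups(
        self, tripeptide_ala, ctx_of
    ):
        ctx = ctx_of(tripeptide_ala)
        dj = mfhc_disjoint(tripeptide_ala, ctx.bonds, ctx.backbone)
        combos = mfhc_overlapping(dj, ctx.bonds, ctx.backbone)
        assert len(combos) == 3
        sizes = sorted(len(c.group_indices) for c in combos)
        assert sizes == [2, 2, 3]

    def test_single_residue_single_combination(self, single_gly, ctx_of):
        ctx = ctx_of(single_gly)
        dj = mfhc_disjoint(single_gly, ctx.bonds, ctx.backbone)
        combos = mfhc_overlapping(dj, ctx.bonds, ctx.backbone)
        assert len(combos) == 1
        assert combos[0].atom_set == frozenset(range(len(single_gly)))

    def test_every_group_appears_in_a_combination(self, pentapeptide, ctx_of):
        ctx = ctx_of(pentapeptide)
        dj = mfhc_disjoint(pentapeptide, ctx.bonds, ctx.backbone)
        combos = mfhc_overlapping(dj, ctx.bonds, ctx.backbone)
        covered = set().union(*(c.group_indices for c in combos))
        assert covered == set(range(len(dj.groups)))


class TestPpGMBE:
    def test_glycine_dipeptide_peptide_bond_intact(self, dipeptide_gly, ctx_of):
        ctx = ctx_of(dipeptide_gly)
        dj = ppgmbe_disjoint(dipeptide_gly, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 2
        (c, n), = ctx.backbone.peptide_bonds
        gmap = dj.group_of()
        assert gmap[c] == gmap[n]

    def test_long_side_chain_split_off(self, ctx_of):
        st = build_polypeptide(FixtureSpec("GKG", "extended", seed=1))
        ctx = ctx_of(st)
        dj = ppgmbe_disjoint(st, ctx.bonds, ctx.backbone)
        lys_ca = ctx.backbone.residues[1].c_alpha
        gmap = dj.group_of()
        backbone_group = dj.groups[gmap[lys_ca]]
        # the 13-atom side chain is its own group; backbone keeps C-alpha
        nz = [i for i, a in enumerate(st.atoms) if a.atom_name == "NZ"][0]
        assert gmap[nz] != gmap[lys_ca]
        assert all(len(g) <= 15 for g in dj.groups)
        assert len(backbone_group) <= 15

    @pytest.mark.parametrize("n", [4, 9, 14])
    def test_polyglycine_groups_within_cap(self, n, ctx_of):
        st = build_polypeptide(FixtureSpec("G" * n, "extended", seed=1))
        ctx = ctx_of(st)
        dj = ppgmbe_disjoint(st, ctx.bonds, ctx.backbone)
        assert all(len(g) <= 15 for g in dj.groups)

    def test_size_cap_on_random_sequences(self, rng):
        for _ in range(25):
            spec = random_fixture_spec(rng, min_len=3, max_len=8)
            st = build_polypeptide(spec)
            bonds = perceive_bonds(st)
            bb = annotate_backbone(st, bonds)
            dj = ppgmbe_disjoint(st, bonds, bb)
            assert all(len(g) <= 15 for g in dj.groups), spec

    def test_covalently_linked_groups_paired(self, dipeptide_gly, ctx_of):
        ctx = ctx_of(dipeptide_gly)
        dj = ppgmbe_disjoint(dipeptide_gly, ctx.bonds, ctx.backbone)
        combos = ppgmbe_pairs(dj, dipeptide_gly)
        assert any(c.group_indices == frozenset({0, 1}) for c in combos)

    def test_hydrogen_bond_rule_joins_distant_groups(self):
        # two far-apart groups joined only through an explicitly supplied H-bond
        atoms = [
            Atom(index=0, element="N", position=(0, 0, 0)),
            Atom(index=1, element="H", position=(1.01, 0, 0)),
            Atom(index=2, element="O", position=(4.5, 0, 0)),
            Atom(index=3, element="H", position=(5.1, 0.7, 0)),
        ]
        st = Structure(atoms=atoms)
        dj = DisjointFragmentation(
            groups=[frozenset({0, 1}), frozenset({2, 3})], scheme="ppgmbe"
        )
        assert ppgmbe_pairs(dj, st) == [
            c for c in ppgmbe_pairs(dj, st) if len(c.group_indices) == 1
        ]  # 3.49 A apart: no distance pair
        hb = HydrogenBond(hydrogen=1, donor_heavy=0, acceptor_heavy=2,
                          distance=3.49, angle=180.0)
        combos = ppgmbe_pairs(dj, st, hbonds=[hb])
        assert any(c.group_indices == frozenset({0, 1}) for c in combos)

    def test_isolated_groups_fall_back_to_singletons(self):
        atoms = [
            Atom(index=0, element="C", position=(0, 0, 0)),
            Atom(index=1, element="C", position=(10, 0, 0)),
        ]
        st = Structure(atoms=atoms)
        dj = DisjointFragmentation(
            groups=[frozenset({0}), frozenset({1})], scheme="ppgmbe"
        )
        combos = ppgmbe_pairs(dj, st)
        assert sorted(c.group_indices for c in combos) == [
            frozenset({0}),
            frozenset({1}),
        ]


class TestMIM:
    def test_glycine_dipeptide_two_groups(self, dipeptide_gly, ctx_of):
        ctx = ctx_of(dipeptide_gly)
        dj = mim_disjoint(dipeptide_gly, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 2

    def test_alanine_dipeptide_four_groups(self, dipeptide_ala, ctx_of):
        ctx = ctx_of(dipeptide_ala)
        dj = mim_disjoint(dipeptide_ala, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 4
        methyl_sizes = sorted(len(g) for g in dj.groups)
        assert methyl_sizes.count(4) == 2  # two CH3 side chains

    def test_single_glycine_one_group(self, single_gly, ctx_of):
        ctx = ctx_of(single_gly)
        dj = mim_disjoint(single_gly, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 1

    def test_eta_one_yields_per_group_antichain(self, dipeptide_ala, ctx_of):
        ctx = ctx_of(dipeptide_ala)
        dj = mim_disjoint(dipeptide_ala, ctx.bonds, ctx.backbone)
        combos = mim_overlapping(dj, dipeptide_ala, ctx.bonds, eta=1)
        for a in combos:
            for b in combos:
                if a is not b:
                    assert not a.atom_set <= b.atom_set

    def test_growth_is_nearest_to_seed_with_covalent_constraint(self):
        # three collinear single-atom groups A-B-C; from seed A with eta=2 the
        # nearest covalently reachable group is B
        atoms = [
            Atom(index=0, element="C", position=(0, 0, 0)),
            Atom(index=1, element="C", position=(1.5, 0, 0)),
            Atom(index=2, element="C", position=(3.0, 0, 0)),
        ]
        st = Structure(atoms=atoms)
        bonds = perceive_bonds(st)
        dj = DisjointFragmentation(
            groups=[frozenset({0}), frozenset({1}), frozenset({2})], scheme="mim"
        )
        combos = mim_overlapping(dj, st, bonds, eta=2)
        atom_sets = {c.atom_set for c in combos}
        assert frozenset({0, 1}) in atom_sets or frozenset({0, 1, 2}) in atom_sets
        # seed A cannot jump straight to C (3.0 A > 1.7 A covalent threshold)
        assert frozenset({0, 2}) not in atom_sets

    def test_equal_distance_tie_rule_includes_both(self):
        # two candidates at exactly the same distance from the seed
        atoms = [
            Atom(index=0, element="C", position=(0, 0, 0)),
            Atom(index=1, element="C", position=(1.5, 0, 0)),
            Atom(index=2, element="C", position=(-1.5, 0, 0)),
        ]
        st = Structure(atoms=atoms)
        bonds = perceive_bonds(st)
        dj = DisjointFragmentation(
            groups=[frozenset({0}), frozenset({1}), frozenset({2})], scheme="mim"
        )
        combos = mim_overlapping(dj, st, bonds, eta=2)
        seed0 = [c for c in combos if 0 in c.atom_set]
        # eta=2 would take one neighbor; the tie rule pulls in the second
        assert any(len(c.atom_set) == 3 for c in seed0)

    def test_closure_can_cross_group_boundaries(self, proline_peptide, ctx_of):
        ctx = ctx_of(proline_peptide)
        dj = mim_disjoint(proline_peptide, ctx.bonds, ctx.backbone)
        combos = mim_overlapping(dj, proline_peptide, ctx.bonds, eta=2)
        union_ok = []
        for c in combos:
            union = frozenset().union(*(dj.groups[g] for g in c.group_indices))
            union_ok.append(c.atom_set >= union)
        assert all(union_ok)

    def test_eta_larger_than_group_count_is_capped(self, dipeptide_gly, ctx_of):
        ctx = ctx_of(dipeptide_gly)
        dj = mim_disjoint(dipeptide_gly, ctx.bonds, ctx.backbone)
        with pytest.warns(UserWarning, match="capping"):
            combos = mim_overlapping(dj, dipeptide_gly, ctx.bonds, eta=10)
        assert combos[0].atom_set == frozenset(range(len(dipeptide_gly)))

    def test_output_is_antichain(self, pentapeptide, ctx_of):
        ctx = ctx_of(pentapeptide)
        dj = mim_disjoint(pentapeptide, ctx.bonds, ctx.backbone)
        combos = mim_overlapping(dj, pentapeptide, ctx.bonds, eta=3)
        for a in combos:
            for b in combos:
                if a is not b:
                    assert not (a.atom_set <= b.atom_set)


class TestKEM:
    def test_pentapeptide(self, pentapeptide, ctx_of):
        ctx = ctx_of(pentapeptide)
        dj = kem_disjoint(pentapeptide, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 5
        assert len(dj.cut_bonds) == 4

    def test_single_residue(self, single_gly, ctx_of):
        ctx = ctx_of(single_gly)
        assert len(kem_disjoint(single_gly, ctx.bonds, ctx.backbone).groups) == 1

    def test_disulfide_bridged_residues_stay_together(self, cys_bridge, ctx_of):
        ctx = ctx_of(cys_bridge)
        dj = kem_disjoint(cys_bridge, ctx.bonds, ctx.backbone)
        assert len(dj.groups) == 1


class TestSchemeInvariants:
    def test_partition_cover_and_connectivity(self, rng, ctx_of):
        for _ in range(12):
            spec = random_fixture_spec(rng, min_len=2, max_len=7)
            st = build_polypeptide(spec)
            bonds = perceive_bonds(st)
            bb = annotate_backbone(st, bonds)
            for name, dj in {
                "mfhc": mfhc_disjoint(st, bonds, bb),
                "ppgmbe": ppgmbe_disjoint(st, bonds, bb),
                "mim": mim_disjoint(st, bonds, bb),
                "kem": kem_disjoint(st, bonds, bb),
            }.items():
                dj.validate(st, bonds)

    def test_determinism(self, pentapeptide, ctx_of):
        ctx = ctx_of(pentapeptide)
        a = mfhc_disjoint(pentapeptide, ctx.bonds, ctx.backbone)
        b = mfhc_disjoint(pentapeptide, ctx.bonds, ctx.backbone)
        assert a.groups == b.groups and a.cut_bonds == b.cut_bonds
        ca = mim_overlapping(a if a.scheme == "mim" else
                             mim_disjoint(pentapeptide, ctx.bonds, ctx.backbone),
                             pentapeptide, ctx.bonds, eta=3)
        cb = mim_overlapping(mim_disjoint(pentapeptide, ctx.bonds, ctx.backbone),
                             pentapeptide, ctx.bonds, eta=3)
        assert [c.atom_set for c in ca] == [c.atom_set for c in cb]
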