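"""Backends, Coulomb sums, expansion assembly and the QC exchange format."""

from __future__ import annotations

import csv
import math
from fractions import Fraction

import numpy as np
import pytest

from fcrfrag.capping import place_caps
from fcrfrag.energy import (
    COULOMB_KJ_MOL,
    AdditiveBackend,
    ClassicalBackend,
    EnergyError,
    EnergyLedger,
    EnvironmentCharges,
    assemble_ee,
    assemble_energy,
    assemble_multilevel,
    coulomb_energy,
    read_results_table,
    write_qc_inputs,
)
from fcrfrag.fcr import (
    FCRExpansion,
    FCRTerm,
    compute_coefficients,
    multilevel_split,
    parse_spec,
)
from fcrfrag.pipeline import build_expansion, evaluate_supersystem, run_spec
from fcrfrag.schemes import FragmentCombination
from fcrfrag.structure import Atom, GeometryError, Structure, perceive_bonds


def _combo(atoms, label=""):
    return FragmentCombination(
        group_indices=frozenset(atoms), atom_set=frozenset(atoms), label=label
    )


def _structure(coords_elements):
    return Structure(
        atoms=[
            Atom(index=i, element=el, position=tuple(p))
            for i, (el, p) in enumerate(coords_elements)
        ]
    )


def _fragment(structure, atoms=None, label="f"):
    bonds = perceive_bonds(structure)
    atoms = frozenset(atoms) if atoms is not None else frozenset(range(len(structure)))
    combo = FragmentCombination(
        group_indices=frozenset({0}), atom_set=atoms, label=label
    )
    return place_caps(combo, structure, bonds)


class TestCoulomb:
    def test_single_charge_is_zero(self):
        assert coulomb_energy([1.0], np.zeros((1, 3))) == 0.0

    def test_unit_charges_at_one_angstrom(self):
        e = coulomb_energy([1.0, -1.0], np.array([[0, 0, 0], [1, 0, 0]]))
        assert e == pytest.approx(-COULOMB_KJ_MOL, abs=1e-9)

    def test_three_charges_match_pair_sum(self, rng):
        q = rng.normal(size=3)
        pos = rng.normal(size=(3, 3)) * 3
        brute = COULOMB_KJ_MOL * sum(
            q[i] * q[j] / np.linalg.norm(pos[i] - pos[j])
            for i in range(3)
            for j in range(i + 1, 3)
        )
        assert coulomb_energy(q, pos) == pytest.approx(brute, abs=1e-9)

    def test_rigid_motion_and_sign_flip_invariance(self, rng):
        q = rng.normal(size=5)
        pos = rng.normal(size=(5, 3)) * 4
        e = coulomb_energy(q, pos)
        rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert coulomb_energy(q, pos @ rot.T + 7.0) == pytest.approx(e, abs=1e-8)
        assert coulomb_energy(-q, pos) == pytest.approx(e, abs=1e-9)

    def test_coincident_charges_rejected(self):
        with pytest.raises(GeometryError):
            coulomb_energy([1.0, 1.0], np.zeros((2, 3)))


class TestAdditiveBackend:
    def test_single_hydrogen_one_body(self):
        s = _structure([("H", (0, 0, 0))])
        be = AdditiveBackend(element_energies={"H": -1.0})
        assert be.evaluate(_fragment(s), s).energy == pytest.approx(-1.0)

    def test_pair_beyond_cutoff_excluded(self):
        s = _structure([("C", (0, 0, 0)), ("C", (9.0, 0, 0))])
        be = AdditiveBackend(element_energies={"C": -5.0}, cutoff=4.0)
        assert be.evaluate(_fragment(s), s).energy == pytest.approx(-10.0)

    def test_matches_bruteforce_double_loop(self, rng):
        pts = rng.normal(size=(5, 3)) * 2.5
        s = _structure([("C", tuple(p)) for p in pts])
        be = AdditiveBackend(
            element_energies={"C": -3.0}, pair_fn=lambda r: 1.0 / r, cutoff=5.0
        )
        brute = -15.0
        for i in range(5):
            for j in range(i + 1, 5):
                r = np.linalg.norm(pts[i] - pts[j])
                if r <= 5.0:
                    brute += 1.0 / r
        got = be.evaluate(_fragment(s), s).energy
        assert got == pytest.approx(brute, abs=1e-9)

    def test_caps_count_as_hydrogen(self, dipeptide_ala, ctx_of):
        ctx = ctx_of(dipeptide_ala)
        combo = FragmentCombination(
            group_indices=frozenset({0}),
            atom_set=frozenset(
                g for g in range(len(dipeptide_ala)) if g not in
                {a.index for a in dipeptide_ala.atoms if a.residue_seq == 2}
            ),
            label="res1",
        )
        frag = place_caps(combo, dipeptide_ala, ctx.bonds)
        assert len(frag.caps) > 0
        be = AdditiveBackend(
            element_energies={"H": -1.0, "C": 0.0, "N": 0.0, "O": 0.0},
            pair_fn=lambda r: np.zeros_like(r),
        )
        n_h = sum(
            1 for i in frag.real_atoms if dipeptide_ala.atoms[i].element == "H"
        )
        e = be.evaluate(frag, dipeptide_ala).energy
        assert e == pytest.approx(-(n_h + len(frag.caps)))


class TestClassicalBackend:
    def test_whole_system_embedded_equals_plain(self, dipeptide_gly):
        be = ClassicalBackend()
        frag = _fragment(dipeptide_gly)
        plain = be.evaluate(frag, dipeptide_gly).energy
        empty_env = EnvironmentCharges(
            indices=(), charges=np.zeros(0), positions=np.zeros((0, 3))
        )
        embedded = be.evaluate(frag, dipeptide_gly, embedding=empty_env).energy
        assert embedded == pytest.approx(plain, abs=1e-12)

    def test_three_atom_toy_matches_hand_sum(self):
        s = _structure([("H", (0, 0, 0)), ("H", (2, 0, 0)), ("H", (0, 2, 0))])
        be = ClassicalBackend(
            charge_table={"H": 0.2}, element_energies={"H": -1.0}
        )
        # neutralizing shift: table total 0.6 over 3 atoms -> all charges 0
        e = be.evaluate(_fragment(s), s).energy
        assert e == pytest.approx(-3.0, abs=1e-10)

    def test_supersystem_charge_neutralization(self, pentapeptide):
        be = ClassicalBackend()
        q = be.charges_for(pentapeptide, range(len(pentapeptide)))
        assert float(q.sum()) == pytest.approx(
            pentapeptide.formal_charge, abs=1e-10
        )


class TestAssembly:
    def _ledger_for(self, expansion, energies):
        ledger = EnergyLedger()
        for t, e in zip(sorted(expansion.terms, key=lambda t: t.combination.label), energies):
            ledger.add(t.combination.label, "SL", e)
        return ledger

    def test_single_term(self):
        exp = FCRExpansion(terms=[FCRTerm(_combo({0}, "a"), Fraction(1))])
        ledger = self._ledger_for(exp, [-7.25])
        assert assemble_energy(exp, ledger) == pytest.approx(-7.25)

    def test_missing_term_is_named(self):
        exp = FCRExpansion(terms=[FCRTerm(_combo({0}, "lonely"), Fraction(1))])
        with pytest.raises(EnergyError, match="lonely"):
            assemble_energy(exp, EnergyLedger())

    def test_linearity_in_ledger(self, rng):
        combos = [_combo({0, 1}, "a"), _combo({1, 2}, "b")]
        exp = compute_coefficients(combos)
        energies = list(rng.normal(size=len(exp.terms)) * 10)
        base = assemble_energy(exp, self._ledger_for(exp, energies))
        scaled = assemble_energy(
            exp, self._ledger_for(exp, [3.0 * e for e in energies])
        )
        assert scaled == pytest.approx(3.0 * base, abs=1e-9)
        kappa = 11.5
        shifted = assemble_energy(
            exp, self._ledger_for(exp, [e + kappa for e in energies])
        )
        assert shifted == pytest.approx(
            base + kappa * float(exp.coefficient_sum), abs=1e-9
        )

    def test_bonded_pair_truncated_additive_backend_is_exact(
        self, pentapeptide
    ):
        # pair terms limited to covalent range: every scheme covers all bonded
        # pairs, so the assembled energy equals the supersystem energy
        be = AdditiveBackend(
            element_energies={"H": 0.0, "C": 0.0, "N": 0.0, "O": 0.0, "S": 0.0},
            pair_fn=lambda r: -1.0 / r,
            cutoff=1.9,
        )
        sup = evaluate_supersystem(pentapeptide, be)
        for spec in ["MFHC-[Nei2_4.0]", "PAIR_2.2_HB-[Nei2_4.0]",
                     "MIM-[η = 3]", "KEM-[Nei2_4.0]"]:
            out = run_spec(pentapeptide, spec, be)
            assert out.energy == pytest.approx(sup, abs=1e-8), spec


class TestMultilevelAssembly:
    def test_identical_levels_collapse_to_plain(self, pentapeptide):
        be = AdditiveBackend(cutoff=3.0)
        ml = run_spec(pentapeptide, "KEM-[Nei2_4.0][Hier2]", be, backend_low=be)
        ll = run_spec(pentapeptide, "KEM-[Hier2]", be)
        assert ml.energy == pytest.approx(ll.energy, abs=1e-9)

    def test_super_low_level_with_additive_backends_is_exact(self, pentapeptide):
        hl = AdditiveBackend(cutoff=3.0)
        ll = AdditiveBackend(
            element_energies={"H": -0.5, "C": -8.0, "N": -11.0, "O": -15.0, "S": -20.0},
            cutoff=3.0,
        )
        out = run_spec(pentapeptide, "MFHC-[Nei2_4.0][Super]", hl, backend_low=ll)
        # substitution identity computed independently: E_super^LL + sum p dE
        sup_ll = evaluate_supersystem(pentapeptide, ll)
        corr = 0.0
        built = build_expansion(pentapeptide, "MFHC-[Nei2_4.0]")
        for t in built.expansion.terms:
            frag = built.fragments[t.combination.label]
            e_hl = hl.evaluate(frag, pentapeptide).energy
            e_ll = ll.evaluate(frag, pentapeptide).energy
            corr += float(t.coefficient) * (e_hl - e_ll)
        assert out.energy == pytest.approx(sup_ll + corr, abs=1e-8)

    def test_tripeptide_two_level_matches_exhaustive_term_table(
        self, tripeptide_ala
    ):
        hl = AdditiveBackend(cutoff=3.5)
        ll = AdditiveBackend(
            element_energies={"H": -0.9, "C": -9.0, "N": -13.0, "O": -17.0, "S": -24.0},
            pair_fn=lambda r: -0.5 * np.exp(-r),
            cutoff=3.5,
        )
        out = run_spec(tripeptide_ala, "KEM-[Nei2_4.0][Hier2]", hl, backend_low=ll)
        built_hl = build_expansion(tripeptide_ala, "KEM-[Nei2_4.0]", 0)
        built_ll = build_expansion(tripeptide_ala, "KEM-[Nei2_4.0][Hier2]", 1)
        total = 0.0
        for t in built_ll.expansion.terms:
            frag = built_ll.fragments[t.combination.label]
            total += float(t.coefficient) * ll.evaluate(frag, tripeptide_ala).energy
        for t in built_hl.expansion.terms:
            frag = built_hl.fragments[t.combination.label]
            total += float(t.coefficient) * (
                hl.evaluate(frag, tripeptide_ala).energy
                - ll.evaluate(frag, tripeptide_ala).energy
            )
        assert out.energy == pytest.approx(total, abs=1e-9)


class TestEmbeddedAssembly:
    def test_supersystem_term_has_zero_correction(self):
        exp = FCRExpansion(terms=[FCRTerm(_combo({0, 1}, "s"), Fraction(1))])
        ledger = EnergyLedger()
        ledger.add("s", "SL", -42.0, embedded=True)
        assert assemble_ee(exp, ledger, e_coul=123.4) == pytest.approx(-42.0)

    def test_hand_computed_three_term_toy(self):
        # coefficients +1, +1, +1 (disjoint): sum p = 3
        exp = FCRExpansion(
            terms=[
                FCRTerm(_combo({0}, "a"), Fraction(1)),
                FCRTerm(_combo({1}, "b"), Fraction(1)),
                FCRTerm(_combo({2}, "c"), Fraction(1)),
            ]
        )
        ledger = EnergyLedger()
        for label, e in [("a", -1.0), ("b", -2.0), ("c", -4.0)]:
            ledger.add(label, "SL", e, embedded=True)
        # E = (-7) - (3 - 1) * 0.5 = -8
        assert assemble_ee(exp, ledger, e_coul=0.5) == pytest.approx(-8.0)

    def test_unembedded_record_rejected(self):
        exp = FCRExpansion(terms=[FCRTerm(_combo({0}, "a"), Fraction(1))])
        ledger = EnergyLedger()
        ledger.add("a", "SL", -1.0, embedded=False)
        with pytest.raises(EnergyError, match="embedding"):
            assemble_ee(exp, ledger, e_coul=0.0)

    def test_classical_limit_identity_on_fixture(self, pentapeptide):
        be = ClassicalBackend()
        sup = evaluate_supersystem(pentapeptide, be)
        out = run_spec(pentapeptide, "KEM-[Nei2_4.0_ee]", be)
        assert out.energy == pytest.approx(sup, abs=1e-6)


class TestQCExchange:
    def test_deck_count_and_manifest(self, tmp_path, dipeptide_gly):
        built = build_expansion(dipeptide_gly, "KEM-[Nei2_4.0]")
        manifest = write_qc_inputs(
            built.expansion, built.fragments, dipeptide_gly, tmp_path
        )
        assert manifest.exists()
        decks = sorted(tmp_path.glob("*.inp"))
        assert len(decks) == len(built.expansion.terms)

    def test_pointcharge_files_cover_environment(self, tmp_path, pentapeptide):
        from fcrfrag.embedding import ChargeSet

        built = build_expansion(pentapeptide, "KEM-[Nei2_4.0]")
        cs = ChargeSet(charges=np.zeros(len(pentapeptide)))
        write_qc_inputs(
            built.expansion, built.fragments, pentapeptide, tmp_path, embedding=cs
        )
        for t in built.expansion.terms:
            stem = t.combination.label.replace(":", "_")
            pc = (tmp_path / f"{stem}.pc").read_text().splitlines()
            assert int(pc[0]) == len(pentapeptide) - len(t.combination.atom_set)
            assert len(pc) == int(pc[0]) + 1

    def test_results_round_trip_matches_direct_assembly(self, tmp_path, pentapeptide):
        be = AdditiveBackend(cutoff=3.0)
        built = build_expansion(pentapeptide, "KEM-[Nei2_4.0]")
        write_qc_inputs(built.expansion, built.fragments, pentapeptide, tmp_path)
        table = tmp_path / "results.csv"
        with open(table, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "level", "energy_kj_mol"])
            for t in built.expansion.terms:
                frag = built.fragments[t.combination.label]
                e = be.evaluate(frag, pentapeptide).energy
                w.writerow([t.combination.label, "SL", repr(e)])
        ledger = read_results_table(table)
        via_table = assemble_energy(built.expansion, ledger, level="SL")
        direct = run_spec(pentapeptide, "KEM-[Nei2_4.0]", be).energy
        assert via_table == pytest.approx(direct, abs=1e-9)
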