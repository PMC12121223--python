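"""Geometry, in-silico mutation, clash screening and the design pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgfhs import (design_candidates, detect_clashes, make_toy_alignment,
                   make_toy_complex, min_distance_to_ligand, mutate_residue,
                   read_structure, to_pdb)
from fgfhs.structure import (BACKBONE_ATOMS, SIDE_CHAIN_TEMPLATES, Atom,
                             Structure)
from fgfhs.synthetic import toy_ligand_residues

from conftest import brute_force_clash, brute_force_min_ligand_distance


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = np.cos(angle / 2)
    b, c, d = -axis * np.sin(angle / 2)
    return np.array([
        [a*a+b*b-c*c-d*d, 2*(b*c+a*d), 2*(b*d-a*c)],
        [2*(b*c-a*d), a*a+c*c-b*b-d*d, 2*(c*d+a*b)],
        [2*(b*d+a*c), 2*(c*d-a*b), a*a+d*d-b*b-c*c]])


class TestReadWrite:
    def test_round_trip_atom_set(self, toy_complex):
        back = read_structure(to_pdb(toy_complex))
        key = lambda a: (a.chain, a.res_seq, a.name)
        assert sorted(map(key, back.atoms)) == sorted(map(key, toy_complex.atoms))
        for a, b in zip(sorted(toy_complex.atoms, key=key),
                        sorted(back.atoms, key=key)):
            assert np.allclose(a.pos, b.pos, atol=1e-3)
            assert a.is_ligand == b.is_ligand

    def test_waters_dropped_and_no_protein_errors(self):
        water_only = ("HETATM    1  O   HOH A   1      0.000   0.000   "
                      "0.000  1.00  0.00           O\nEND\n")
        with pytest.raises(ValueError, match="no protein"):
            read_structure(water_only)

    def test_malformed_coordinates_report_line_number(self, toy_complex):
        text = to_pdb(toy_complex)
        lines = text.splitlines()
        i = next(i for i, ln in enumerate(lines) if ln.startswith("ATOM"))
        lines[i] = lines[i][:30] + "xxxxxxxx" + lines[i][38:]
        with pytest.raises(ValueError, match=f"line {i + 1}"):
            read_structure("\n".join(lines))

    def test_ligand_name_override(self, toy_complex):
        text = to_pdb(toy_complex)
        none_flagged = read_structure(text, ligand_names=())
        assert not none_flagged.ligand_atoms
        flagged = read_structure(text, ligand_names=("LIG",))
        assert len(flagged.ligand_atoms) == 5


class TestMinDistance:
    def test_three_four_five_triangle(self):
        atoms = (
            Atom("A", 1, "", "ALA", "CA", "C", 3.0, 4.0, 0.0),
            Atom("L", 2, "", "LIG", "C1", "C", 0.0, 0.0, 0.0, is_ligand=True),
        )
        assert min_distance_to_ligand(Structure(atoms), 1) == pytest.approx(5.0)

    def test_min_unchanged_by_farther_ligand_atom(self):
        near = Atom("L", 2, "", "LIG", "C1", "C", 0.0, 0.0, 0.0, is_ligand=True)
        far = Atom("L", 2, "", "LIG", "C2", "C", 50.0, 0.0, 0.0, is_ligand=True)
        res = Atom("A", 1, "", "ALA", "CA", "C", 3.0, 4.0, 0.0)
        d1 = min_distance_to_ligand(Structure((res, near)), 1)
        d2 = min_distance_to_ligand(Structure((res, near, far)), 1)
        assert d1 == d2

    def test_flagged_residues_at_constructed_offset(self):
        st_ = make_toy_complex(11, ligand_offset=6.5, seed=0)
        for pos in toy_ligand_residues(11):
            assert min_distance_to_ligand(st_, pos) == pytest.approx(6.5)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        st_ = make_toy_complex(n, float(rng.uniform(1, 12)), seed=seed)
        for pos in range(1, n + 1):
            assert min_distance_to_ligand(st_, pos) == pytest.approx(
                brute_force_min_ligand_distance(st_, pos), abs=1e-9)


class TestMutateResidue:
    def test_to_glycine_truncates(self, toy_complex):
        mutated = mutate_residue(toy_complex, (5, "G"))
        names = {a.name for a in mutated.residue_atoms(5)}
        assert names == {"N", "CA", "C", "O"}
        assert len(mutated.atoms) == len(toy_complex.atoms) - 1

    def test_to_lysine_adds_template_atoms(self, toy_complex):
        mutated = mutate_residue(toy_complex, (5, "K"))
        names = {a.name for a in mutated.residue_atoms(5)}
        assert names == {"N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"}
        assert mutated.residue_name(5) == "LYS"

    def test_backbone_untouched(self, toy_complex):
        mutated = mutate_residue(toy_complex, (5, "R"))
        for name in ("N", "CA", "C", "O"):
            before = next(a for a in toy_complex.residue_atoms(5) if a.name == name)
            after = next(a for a in mutated.residue_atoms(5) if a.name == name)
            assert before.pos.tolist() == after.pos.tolist()

    @pytest.mark.parametrize("new_res", ["K", "R", "W", "S"])
    def test_terminal_atom_collinear_at_template_length(self, toy_complex, new_res):
        mutated = mutate_residue(toy_complex, (5, new_res))
        by_name = {a.name: a for a in mutated.residue_atoms(5)}
        ca, cb = by_name["CA"].pos, by_name["CB"].pos
        u = (cb - ca) / np.linalg.norm(cb - ca)
        template = SIDE_CHAIN_TEMPLATES[new_res]
        tip = by_name[template[-1]].pos if template else cb
        expected = cb + len(template) * 1.53 * u
        assert np.allclose(tip, expected, atol=1e-9)

    def test_from_glycine_synthesizes_cb(self, toy_complex):
        gly = mutate_residue(toy_complex, (5, "G"))
        back = mutate_residue(gly, (5, "K"))
        names = {a.name for a in back.residue_atoms(5)}
        assert "CB" in names and "NZ" in names


class TestDetectClashes:
    def test_planted_clash_detected_after_mutation(self):
        st_ = make_toy_complex(10, 5.0, clash_positions=(4,), seed=1)
        assert not detect_clashes(st_, 4)  # wild-type alanine is fine
        mutated = mutate_residue(st_, (4, "K"))
        report = detect_clashes(mutated, 4)
        assert report.clash and report.pairs
        a, b, d = report.pairs[0]
        assert d < 2.4

    def test_far_field_is_clean(self, toy_complex):
        mutated = mutate_residue(toy_complex, (1, "R"))
        assert not detect_clashes(mutated, 1, clash_cutoff=2.4)

    def test_offending_pairs_report_distances(self):
        st_ = make_toy_complex(8, 5.0, clash_positions=(4,), seed=0)
        report = detect_clashes(mutate_residue(st_, (4, "R")), 4)
        assert all(d == pytest.approx(np.linalg.norm(x.pos - y.pos))
                   for x, y, d in report.pairs)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        clash_at = tuple(int(p) for p in
                         rng.choice(np.arange(1, n + 1),
                                    size=rng.integers(0, 3), replace=False))
        st_ = make_toy_complex(n, float(rng.uniform(2, 10)), clash_at, seed)
        cutoff = float(rng.uniform(1.5, 4.0))
        for pos in range(1, n + 1):
            mutated = mutate_residue(st_, (pos, "R"))
            assert bool(detect_clashes(mutated, pos, cutoff)) == \
                brute_force_clash(mutated, pos, cutoff)


class TestDesignCandidates:
    def make_system(self, clash_positions=(8,), n=12, offset=5.0):
        # ligand spans residues 4..8; plant supports at columns for
        # positions 4 (pass), 6 (pass), 8 (clash), 10 (far), 2 (low support)
        aln = make_toy_alignment("A" * n, {3: 3, 5: 4, 7: 3, 9: 3, 1: 2},
                                 n_rows=6, seed=5)
        st_ = make_toy_complex(n, offset, clash_positions=clash_positions,
                               seed=1)
        return aln, st_

    def test_planted_sites_pass_and_failures_drop(self):
        aln, st_ = self.make_system()
        sites = design_candidates(aln, "target", st_)
        assert [s.position for s in sites] == [6, 4]  # dist ties -> support
        assert all(not s.clash for s in sites)
        assert [s.rank for s in sites] == [1, 2]

    def test_three_planted_passes(self):
        aln, st_ = self.make_system(clash_positions=())
        sites = design_candidates(aln, "target", st_)
        assert sorted(s.position for s in sites) == [4, 6, 8]

    def test_zero_vicinity_returns_nothing(self):
        aln, st_ = self.make_system()
        assert design_candidates(aln, "target", st_, vicinity_cutoff=0.0) == []

    def test_arginine_preferred_when_both_pass(self):
        aln, st_ = self.make_system(clash_positions=())
        assert all(s.proposed_residue == "R"
                   for s in design_candidates(aln, "target", st_))

    def test_monotone_in_vicinity_cutoff(self):
        aln, st_ = self.make_system(clash_positions=())
        counts = [len(design_candidates(aln, "target", st_, vicinity_cutoff=v))
                  for v in (0.0, 4.0, 5.0, 8.0, 12.0)]
        assert counts == sorted(counts)

    def test_monotone_in_min_support(self):
        aln, st_ = self.make_system(clash_positions=())
        counts = [len(design_candidates(aln, "target", st_, min_support=k))
                  for k in (1, 2, 3, 4, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_monotone_in_clash_strictness(self):
        aln, st_ = self.make_system(clash_positions=(4, 8))
        counts = [len(design_candidates(aln, "target", st_, clash_cutoff=c))
                  for c in (0.5, 2.4, 3.5, 5.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invariant_under_rigid_motion(self):
        aln, st_ = self.make_system()
        rot = rotation_matrix([1.0, 2.0, 0.5], 1.1)
        moved = st_.transformed(rot, np.array([10.0, -3.0, 7.0]))
        a = [(s.position, s.proposed_residue, s.basic_support, round(s.min_ligand_distance, 9))
             for s in design_candidates(aln, "target", st_)]
        b = [(s.position, s.proposed_residue, s.basic_support, round(s.min_ligand_distance, 9))
             for s in design_candidates(aln, "target", moved)]
        assert a == b

    def test_invariant_under_atom_reordering(self):
        aln, st_ = self.make_system()
        shuffled = Structure(tuple(reversed(st_.atoms)))
        assert [s.position for s in design_candidates(aln, "target", st_)] == \
            [s.position for s in design_candidates(aln, "target", shuffled)]
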