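"""Rotamer building, DEE, simulated annealing and water bookkeeping."""

import numpy as np
import pytest

import biotite.structure.info as info

from aquabridge.chemistry import GeometryParams
from aquabridge.packing import (PackingProblem, Rotamer, _dihedral,
                                build_solvated_rotamers, dee_goldstein,
                                emit_model, enumerate_rotamers,
                                exhaustive_gmec, load_rotamer_library,
                                mc_simulated_annealing, pairwise_energy)
from aquabridge.structure import AtomRecord, Structure


def residue_atoms(res, chain, res_id, shift, flip=False):
    arr = info.residue(res)
    rot = np.diag([-1.0, -1.0, 1.0]) if flip else np.eye(3)
    out = []
    for i in range(arr.array_length()):
        if str(arr.element[i]) == "H" or str(arr.atom_name[i]) == "OXT":
            continue
        out.append(AtomRecord(
            element=str(arr.element[i]), name=str(arr.atom_name[i]),
            res_name=res, chain=chain, res_id=res_id,
            position=rot @ arr.coord[i].astype(float)
            + np.asarray(shift, float)))
    return out


def toy_rotamer(pos_id, pos, res="ALA"):
    """Single-pseudo-atom rotamer for combinatorial toys."""
    return Rotamer(position=pos_id, res_type=res, chi=(),
                   atoms=[AtomRecord(element="C", name="CA",
                                     res_name=res, chain=pos_id[0],
                                     res_id=pos_id[1],
                                     position=np.asarray(pos, float))])


def toy_problem(rng, n_pos=3, n_rot=4, spread=5.0):
    """Random pseudo-atom packing toy with non-trivial steric energies."""
    positions = [("A", i + 1) for i in range(n_pos)]
    sets = {}
    for k, p in enumerate(positions):
        base = np.array([k * 4.0, 0.0, 0.0])
        sets[p] = [toy_rotamer(p, base + rng.uniform(-spread / 2,
                                                     spread / 2, size=3))
                   for _ in range(n_rot)]
    return PackingProblem(context=Structure(atoms=[]),
                          positions=positions, rotamer_sets=sets)


class TestEnumeration:
    def test_alanine_single_rotamer(self):
        s = Structure(atoms=residue_atoms("ALA", "A", 1, [0, 0, 0]))
        rots = enumerate_rotamers(s, ("A", 1), "ALA")
        assert len(rots) == 1 and rots[0].chi == ()

    def test_glycine_backbone_only(self):
        s = Structure(atoms=residue_atoms("GLY", "A", 1, [0, 0, 0]))
        rots = enumerate_rotamers(s, ("A", 1), "GLY")
        assert len(rots) == 1
        assert "CB" not in {a.name for a in rots[0].atoms}

    def test_expand_chi1_triples(self):
        lib = load_rotamer_library()
        s = Structure(atoms=residue_atoms("LEU", "A", 1, [0, 0, 0]))
        plain = enumerate_rotamers(s, ("A", 1), "LEU")
        expanded = enumerate_rotamers(s, ("A", 1), "LEU",
                                      expand_chi1=True)
        assert len(plain) == len(lib["LEU"])
        assert len(expanded) == 3 * len(plain)
        chi1s = sorted(r.chi[0] for r in expanded
                       if abs(r.chi[1] - plain[0].chi[1]) < 1e-9
                       and abs(abs(r.chi[0] - plain[0].chi[0])) < 11)
        assert chi1s == pytest.approx([plain[0].chi[0] - 10,
                                       plain[0].chi[0],
                                       plain[0].chi[0] + 10])

    def test_chi_angles_are_set_exactly(self):
        s = Structure(atoms=residue_atoms("LYS", "A", 1, [0, 0, 0]))
        for rot in enumerate_rotamers(s, ("A", 1), "LYS"):
            c = {a.name: a.position for a in rot.atoms}
            chi1 = _dihedral(c["N"], c["CA"], c["CB"], c["CG"])
            chi4 = _dihedral(c["CG"], c["CD"], c["CE"], c["NZ"])
            assert chi1 == pytest.approx(rot.chi[0], abs=1e-6)
            assert chi4 == pytest.approx(rot.chi[3], abs=1e-6)

    def test_backbone_is_preserved(self):
        shift = np.array([3.0, -2.0, 1.0])
        atoms = residue_atoms("SER", "A", 1, shift)
        s = Structure(atoms=atoms)
        rot = enumerate_rotamers(s, ("A", 1), "SER")[0]
        orig = {a.name: a.position for a in atoms}
        built = {a.name: a.position for a in rot.atoms}
        for n in ("N", "CA", "C", "O"):
            np.testing.assert_allclose(built[n], orig[n], atol=1e-9)

    def test_unknown_residue(self):
        s = Structure(atoms=residue_atoms("ALA", "A", 1, [0, 0, 0]))
        with pytest.raises(ValueError):
            enumerate_rotamers(s, ("A", 1), "XXX")


class TestCombinatorics:
    @pytest.mark.parametrize("seed", range(8))
    def test_dee_mc_matches_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        prob = toy_problem(rng, n_pos=3, n_rot=4)  # 64 assignments
        _, e_ref = exhaustive_gmec(prob)
        pruned, _ = dee_goldstein(prob)
        _, e_mc = mc_simulated_annealing(pruned, seed=seed)
        assert e_mc == pytest.approx(e_ref, abs=1e-9)

    def test_dee_never_eliminates_gmec(self):
        rng = np.random.default_rng(99)
        prob = toy_problem(rng, n_pos=4, n_rot=3)  # 81 assignments
        best, e_ref = exhaustive_gmec(prob)
        pruned, alive = dee_goldstein(prob)
        for p in prob.positions:
            assert best[p] in alive[p]

    def test_single_position_self_energy(self):
        p = ("A", 1)
        r1 = toy_rotamer(p, [0, 0, 0])
        r2 = toy_rotamer(p, [0, 0, 0])
        prob = PackingProblem(context=Structure(atoms=[]), positions=[p],
                              rotamer_sets={p: [r1, r2]})
        from aquabridge.packing import _energy_tables
        selfE, pairE = _energy_tables(prob)
        selfE[p][1] += 5.0  # hand the second rotamer a penalty
        pruned, alive = dee_goldstein(prob, tables=(selfE, pairE))
        assert alive[p] == [0]

    def test_singletons_unchanged(self):
        rng = np.random.default_rng(1)
        prob = toy_problem(rng, n_pos=3, n_rot=1)
        pruned, alive = dee_goldstein(prob)
        assert all(len(v) == 1 for v in alive.values())
        a, e = mc_simulated_annealing(pruned, seed=0)
        assert a == {p: 0 for p in prob.positions}

    def test_mc_reproducible(self):
        rng = np.random.default_rng(2)
        prob = toy_problem(rng, n_pos=3, n_rot=5)
        a1, e1 = mc_simulated_annealing(prob, seed=7)
        a2, e2 = mc_simulated_annealing(prob, seed=7)
        assert a1 == a2 and e1 == e2


class TestPairwise:
    def test_distant_rotamers_zero(self):
        a = toy_rotamer(("A", 1), [0, 0, 0])
        b = toy_rotamer(("A", 2), [20.0, 0, 0])
        assert pairwise_energy(a, b) == 0.0

    def test_steric_overlap_positive(self):
        a = toy_rotamer(("A", 1), [0, 0, 0])
        b = toy_rotamer(("A", 2), [1.0, 0, 0])
        assert pairwise_energy(a, b) > 10.0


def facing_serines():
    ser1 = residue_atoms("SER", "A", 1, np.zeros(3))
    ser2 = residue_atoms("SER", "A", 5, np.array([7.0, 0.0, 0.0]),
                         flip=True)
    return Structure(atoms=ser1 + ser2)


class TestSolvatedRotamers:
    def setup_method(self):
        self.s = facing_serines()
        self.positions = [("A", 1), ("A", 5)]
        self.sets = {p: enumerate_rotamers(self.s, p, "SER")
                     for p in self.positions}

    def make_problem(self):
        return PackingProblem(
            context=self.s, positions=list(self.positions),
            rotamer_sets={p: list(v) for p, v in self.sets.items()})

    def test_duplication_onto_both_rotamers(self):
        prob = build_solvated_rotamers(self.make_problem())
        solvated = {p: [r for r in prob.rotamer_sets[p] if r.is_solvated]
                    for p in self.positions}
        assert all(solvated[p] for p in self.positions)
        # each cross-pair bridge id appears at both positions
        ids1 = {b for r in solvated[("A", 1)] for b in r.bridge_ids}
        ids5 = {b for r in solvated[("A", 5)] for b in r.bridge_ids}
        cross = ids1 & ids5
        assert cross
        # originals retained
        for p in self.positions:
            assert any(not r.is_solvated for r in prob.rotamer_sets[p])

    def test_solvation_never_raises_gmec(self):
        plain = self.make_problem()
        _, e_plain = exhaustive_gmec(plain)
        solv = build_solvated_rotamers(self.make_problem())
        _, e_solv = exhaustive_gmec(solv)
        assert e_solv <= e_plain + 1e-9

    def test_bridge_lowers_energy_vs_unsolvated(self):
        prob = build_solvated_rotamers(self.make_problem())
        _, e_solv = exhaustive_gmec(prob)
        _, e_plain = exhaustive_gmec(self.make_problem())
        assert e_solv < e_plain  # a favourable bridge exists here

    def test_emit_model_dedupes_shared_bridge(self):
        prob = build_solvated_rotamers(self.make_problem())
        pruned, _ = dee_goldstein(prob)
        assignment, _ = mc_simulated_annealing(pruned, seed=1)
        model = emit_model(pruned, assignment)
        waters = [a for a in model.atoms
                  if a.is_water and a.element == "O"]
        # no two waters within the merge radius
        for i in range(len(waters)):
            for j in range(i + 1, len(waters)):
                assert np.linalg.norm(waters[i].position
                                      - waters[j].position) >= 1.0

    def test_context_bridge_attaches_to_rotamer_only(self):
        """A bridge to a fixed context site (the ligand rule) only adds
        a water to the amino-acid rotamer."""
        ser = residue_atoms("SER", "A", 1, np.zeros(3))
        # fixed carbonyl fragment playing the ligand/backbone part
        from aquabridge.fixtures import _carbonyl_fragment
        rng = np.random.default_rng(0)
        # aim the fragment's lone pair at a plausible bridge point
        og = next(a.position for a in ser if a.name == "OG")
        target = og + np.array([2.0, 1.0, 0.5])
        frag = _carbonyl_fragment(
            target + 2.73 * np.array([1.0, 0, 0]), target, rng, 50)
        ctx = Structure(atoms=ser + frag)
        prob = PackingProblem(
            context=ctx, positions=[("A", 1)],
            rotamer_sets={("A", 1): enumerate_rotamers(ctx, ("A", 1),
                                                       "SER")})
        prob = build_solvated_rotamers(prob)
        solvated = [r for r in prob.rotamer_sets[("A", 1)]
                    if r.is_solvated]
        # any bridge found is carried by the rotamer; the context has no
        # rotamer set to carry anything
        for r in solvated:
            assert all(w.bridge_id is not None
                       for w in r.attached_waters)
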