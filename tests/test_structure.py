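"""Structure I/O, superposition, divergence profiles, mutations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lipidshift.alignment import Alignment
from lipidshift.structure import (
    MutationSpec,
    apply_point_mutation,
    kabsch_superpose,
    pair_by_alignment,
    per_residue_divergence,
    read_structure,
    refined_superpose,
    write_conservation_bfactor,
    write_structure,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.800   5.206  -4.212  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40 11.00           C
ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C
END
"""


def random_coords(rng, n=20):
    return rng.normal(size=(n, 3)) * 5.0


def random_rigid(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10, 10, size=3)
    return R, t


class TestReadStructure:
    def test_minimal_pdb_exact_coords(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert model.n_atoms == 3
        np.testing.assert_allclose(
            model.atoms.coord[0], [11.104, 6.134, -6.504], atol=1e-6
        )

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_structure(p)
        assert model.n_atoms == 2
        np.testing.assert_allclose(model.atoms.coord[0],
                                   [1.0, 0.0, 0.0], atol=1e-6)

    def test_no_atoms_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER  NOTHING\nEND\n")
        with pytest.raises(Exception):
            read_structure(p)

    def test_roundtrip_three_decimals(self, tmp_path, rng):
        from lipidshift.simulate import (
            SyntheticScenario,
            make_model_ensemble,
        )

        models, _ = make_model_ensemble(SyntheticScenario(seed=4))
        p = tmp_path / "rt.pdb"
        write_structure(models[0], p)
        back = read_structure(p)
        np.testing.assert_allclose(
            back.atoms.coord, models[0].atoms.coord, atol=5e-4
        )


class TestKabsch:
    def test_self_superposition(self, rng):
        A = random_coords(rng)
        res = kabsch_superpose(A, A)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self, rng):
        A = random_coords(rng)
        R, t = random_rigid(rng)
        B = (A - t) @ R  # arbitrary rigid scramble
        res = kabsch_superpose(A, B)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_ninety_degree_rotation_about_z(self):
        A = np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]])
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        B = A @ Rz.T + np.array([3.0, -2.0, 5.0])
        res = kabsch_superpose(A, B)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        A, B = random_coords(rng), random_coords(rng)
        assert kabsch_superpose(A, B).rmsd == pytest.approx(
            kabsch_superpose(B, A).rmsd, abs=1e-9
        )

    def test_invariant_to_rigid_pretransform(self, rng):
        A, B = random_coords(rng), random_coords(rng)
        base = kabsch_superpose(A, B).rmsd
        R, t = random_rigid(rng)
        assert kabsch_superpose(A @ R.T + t, B).rmsd == pytest.approx(
            base, abs=1e-8
        )
        assert kabsch_superpose(A, B @ R.T + t).rmsd == pytest.approx(
            base, abs=1e-8
        )

    def test_agrees_with_scipy_align_vectors(self, rng):
        A, B = random_coords(rng, 12), random_coords(rng, 12)
        res = kabsch_superpose(A, B)
        rot, scipy_rssd = Rotation.align_vectors(
            A - A.mean(axis=0), B - B.mean(axis=0)
        )
        scipy_rmsd = scipy_rssd / np.sqrt(len(A))
        assert res.rmsd == pytest.approx(scipy_rmsd, abs=1e-8)
        np.testing.assert_allclose(res.rotation, rot.as_matrix(),
                                   atol=1e-6)

    def test_four_point_displaced_case(self):
        # 3 fixed points + 1 displaced: optimum from the independent
        # scipy implementation
        A = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]])
        B = A.copy()
        B[3] = [0.5, 0.5, 3.0]
        res = kabsch_superpose(A, B)
        rot, rssd = Rotation.align_vectors(
            A - A.mean(axis=0), B - B.mean(axis=0)
        )
        assert res.rmsd == pytest.approx(rssd / 2.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestRefined:
    def test_identical_sets_match_plain(self, rng):
        A = random_coords(rng, 30)
        plain = kabsch_superpose(A, A)
        ref = refined_superpose(A, A)
        assert ref.rmsd == pytest.approx(plain.rmsd, abs=1e-12)
        assert ref.n_atoms_used == 30

    def test_gross_outlier_rejected(self, rng):
        A = random_coords(rng, 50)
        B = A + rng.normal(scale=0.1, size=A.shape)
        B[17] += np.array([25.0, 0.0, 0.0])
        plain = kabsch_superpose(A, B)
        ref = refined_superpose(A, B)
        # outlier rejected (iterative trimming may drop a few extra
        # pairs, so the final RMSD is at or below the inlier RMSD)
        assert 40 <= ref.n_atoms_used < 50
        inlier = np.ones(50, dtype=bool)
        inlier[17] = False
        inlier_rmsd = kabsch_superpose(A[inlier], B[inlier]).rmsd
        assert ref.rmsd <= inlier_rmsd + 1e-12
        assert ref.rmsd < plain.rmsd

    def test_refined_never_worse_than_plain(self, rng):
        for _ in range(5):
            A = random_coords(rng, 40)
            B = A + rng.normal(scale=rng.uniform(0.05, 1.0),
                               size=A.shape)
            assert (
                refined_superpose(A, B).rmsd
                <= kabsch_superpose(A, B).rmsd + 1e-12
            )


class TestPairing:
    def _models(self, seqs, rng):
        import biotite.structure as struc
        from lipidshift.structure import ONE_TO_THREE, StructureModel

        models = []
        for label, seq in seqs:
            n = len(seq)
            atoms = struc.AtomArray(n)
            atoms.coord = rng.normal(size=(n, 3)).astype(np.float32) * 10
            atoms.chain_id = np.full(n, "A")
            atoms.res_id = np.arange(1, n + 1)
            atoms.res_name = np.array([ONE_TO_THREE[c] for c in seq])
            atoms.atom_name = np.full(n, "CA")
            atoms.element = np.full(n, "C")
            models.append(StructureModel(atoms, label))
        return models

    def test_gap_column_unpaired(self, rng):
        aln = Alignment(["s1", "s2"], ["MKVAW", "MK-AW"])
        models = self._models([("s1", "MKVAW"), ("s2", "MKAW")], rng)
        pairing = pair_by_alignment(aln, models)
        assert pairing.columns == [1, 2, 4, 5]

    def test_all_columns_paired_when_ungapped(self, rng):
        aln = Alignment(["s1", "s2"], ["MKVA", "MKVA"])
        models = self._models([("s1", "MKVA"), ("s2", "MKVA")], rng)
        pairing = pair_by_alignment(aln, models)
        assert pairing.columns == [1, 2, 3, 4]
        assert pairing.ca_sets.shape == (2, 4, 3)

    def test_map_roundtrips(self, rng):
        aln = Alignment(["s1", "s2"], ["MKV-AW", "M-VKAW"])
        models = self._models([("s1", "MKVAW"), ("s2", "MVKAW")], rng)
        pairing = pair_by_alignment(aln, models)
        for c2r, r2c in zip(pairing.col_to_residue,
                            pairing.residue_to_col):
            for col, res in c2r.items():
                assert r2c[res] == col

    def test_mismatch_reported_with_column(self, rng):
        aln = Alignment(["s1"], ["MKVA"])
        models = self._models([("s1", "MKIA")], rng)
        with pytest.raises(ValueError, match="column 3"):
            pair_by_alignment(aln, models)


class TestDivergence:
    def test_identical_models(self, rng):
        A = random_coords(rng, 15)
        prof = per_residue_divergence(np.stack([A, A, A]))
        np.testing.assert_allclose(prof.deviation, 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.conservation, 1.0)

    def test_uniform_translation_without_superposition(self, rng):
        A = random_coords(rng, 15)
        B = A + np.array([2.0, 0.0, 0.0])
        prof = per_residue_divergence(
            np.stack([A, B]), superpose_onto_first=False
        )
        np.testing.assert_allclose(prof.deviation, 2.0, atol=1e-9)

    def test_mobile_loop_ranks_highest(self):
        from lipidshift.simulate import (
            SyntheticScenario,
            make_model_ensemble,
        )

        sc = SyntheticScenario(seed=9, loop_amplitude=3.0)
        models, loop_mask = make_model_ensemble(sc)
        ca = np.stack([m.ca_coords() for m in models])
        prof = per_residue_divergence(ca)
        top = np.argsort(prof.deviation)[-5:]
        assert loop_mask[top].all()

    def test_model_order_invariance(self, rng):
        sets = np.stack([random_coords(rng, 10) for _ in range(4)])
        a = per_residue_divergence(sets, superpose_onto_first=False)
        b = per_residue_divergence(sets[::-1],
                                   superpose_onto_first=False)
        np.testing.assert_allclose(a.deviation, b.deviation, atol=1e-9)

    def test_requires_two_models(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            per_residue_divergence(random_coords(rng, 5)[None])


class TestConservationPainting:
    def test_scores_written_and_reread(self, tmp_path):
        from lipidshift.simulate import (
            SyntheticScenario,
            make_model_ensemble,
        )

        sc = SyntheticScenario(seed=10, loop_amplitude=2.0, n_models=3)
        models, _ = make_model_ensemble(sc)
        ca = np.stack([m.ca_coords() for m in models])
        prof = per_residue_divergence(ca)
        p = tmp_path / "painted.pdb"
        write_conservation_bfactor(models[0], prof, p)
        back = read_structure(p)
        np.testing.assert_allclose(
            back.atoms.b_factor,
            np.round(prof.conservation, 2),
            atol=5e-3,
        )

    def test_unpaired_residue_sentinel(self, tmp_path):
        from lipidshift.simulate import (
            SyntheticScenario,
            make_model_ensemble,
        )
        from lipidshift.structure import ResidueDivergenceProfile

        models, _ = make_model_ensemble(SyntheticScenario(seed=10))
        prof = ResidueDivergenceProfile(
            residue_ids=np.arange(1, 11),  # only first 10 residues
            deviation=np.zeros(10),
            conservation=np.ones(10),
        )
        p = tmp_path / "partial.pdb"
        painted = write_conservation_bfactor(models[0], prof, p)
        b = painted.atoms.b_factor
        assert (b[:10] == 1.0).all()
        assert (b[10:] == 99.99).all()


class TestPointMutation:
    def _model(self, seq="MKVAW"):
        import biotite.structure as struc
        from lipidshift.structure import ONE_TO_THREE, StructureModel

        atoms_per_res = ["N", "CA", "C", "O", "CB", "CG"]
        n = len(seq) * len(atoms_per_res)
        atoms = struc.AtomArray(n)
        coords, names, resids, resnames = [], [], [], []
        for i, aa in enumerate(seq):
            for j, an in enumerate(atoms_per_res):
                coords.append([i * 3.0, j * 1.0, 0.0])
                names.append(an)
                resids.append(i + 1)
                resnames.append(ONE_TO_THREE[aa])
        atoms.coord = np.array(coords, dtype=np.float32)
        atoms.atom_name = np.array(names)
        atoms.res_id = np.array(resids)
        atoms.res_name = np.array(resnames)
        atoms.chain_id = np.full(n, "A")
        atoms.element = np.array(
            [an[0] for an in names]
        )
        return StructureModel(atoms, "toy")

    def test_stub_mutation_renames_and_truncates(self):
        model = self._model()
        mutated = apply_point_mutation(
            model, MutationSpec(position=3, from_res="V", to_res="W")
        )
        sel = mutated.atoms.res_id == 3
        assert set(mutated.atoms.res_name[sel]) == {"TRP"}
        assert set(mutated.atoms.atom_name[sel]) == {
            "N", "CA", "C", "O", "CB"
        }
        assert any("STUB MUTATION V3W" in r for r in mutated.remarks)

    def test_to_glycine_drops_cbeta(self):
        model = self._model()
        mutated = apply_point_mutation(
            model, MutationSpec(position=2, from_res="K", to_res="G")
        )
        sel = mutated.atoms.res_id == 2
        assert "CB" not in set(mutated.atoms.atom_name[sel])
        assert set(mutated.atoms.res_name[sel]) == {"GLY"}

    def test_from_res_mismatch_quotes_observed(self):
        model = self._model()
        with pytest.raises(ValueError, match="structure has V"):
            apply_point_mutation(
                model, MutationSpec(position=3, from_res="A", to_res="W")
            )

    def test_other_residues_untouched(self):
        model = self._model()
        mutated = apply_point_mutation(
            model, MutationSpec(position=3, from_res="V", to_res="W")
        )
        other = mutated.atoms.res_id != 3
        assert other.sum() == 4 * 6
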