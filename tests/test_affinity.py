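"""Free energy to Kd conversion, Vina parsing, swap and scan logic."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidshift.affinity import (
    DockingRecord,
    R_KCAL,
    kd_from_dg,
    mutational_scan,
    parse_vina_output,
    parse_vina_dir,
    read_dg_table,
    swap_feasibility,
    write_dg_table,
)

VINA_LOG = """\
#################################################################
# If you used AutoDock Vina in your work, please cite:          #
#################################################################

Detected 4 CPUs
Reading input ... done.
Performing search ... done.

mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1         -8.0      0.000      0.000
   2         -7.4      1.877      3.262
   3         -6.9      2.641      5.498
Writing output ... done.
"""


class TestKdFromDg:
    def test_zero_energy_is_one_molar(self):
        assert kd_from_dg(0.0) == 1.0

    def test_decade_closed_form(self):
        # dG = RT ln(0.1) at 298.15 K gives exactly 0.1 M
        dg = R_KCAL * 298.15 * math.log(0.1)
        assert dg == pytest.approx(-1.3642, abs=1e-3)
        assert kd_from_dg(-1.3642) == pytest.approx(0.1, rel=1e-3)

    def test_closed_form_evaluation(self):
        expected = math.exp(-8.0 / (R_KCAL * 298.15))
        assert kd_from_dg(-8.0) == expected
        assert expected == pytest.approx(1.37e-6, rel=0.01)

    @given(
        st.floats(-15, 5),
        st.floats(-3, 3),
    )
    def test_log_additivity(self, a, b):
        rt = R_KCAL * 298.15
        lhs = kd_from_dg(a + b)
        rhs = kd_from_dg(a) * math.exp(b / rt)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    @given(st.floats(-15, 5), st.floats(-15, 5))
    def test_strictly_monotone(self, a, b):
        if a < b:
            assert kd_from_dg(a) < kd_from_dg(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kd_from_dg(-8.0, temperature=0.0)
        with pytest.raises(ValueError):
            kd_from_dg(float("nan"))


class TestVinaParsing:
    def test_three_modes_rank_one_lowest(self, tmp_path):
        p = tmp_path / "hCD1a__DDM.log"
        p.write_text(VINA_LOG)
        records = parse_vina_output(p)
        assert len(records) == 3
        assert records[0].pose_rank == 1
        assert records[0].delta_g == -8.0
        assert min(r.delta_g for r in records) == records[0].delta_g
        assert records[0].receptor == "hCD1a"
        assert records[0].ligand == "DDM"

    def test_no_table_error(self, tmp_path):
        p = tmp_path / "bad.log"
        p.write_text("nothing useful here\n")
        with pytest.raises(ValueError, match="no affinity table"):
            parse_vina_output(p)

    def test_batch_directory_labels_from_filenames(self, tmp_path):
        for name in ("recA__lig1.log", "recB__lig1.log"):
            (tmp_path / name).write_text(VINA_LOG)
        records = parse_vina_dir(tmp_path, class_map={"lig1": "endogenous"})
        receptors = {r.receptor for r in records}
        assert receptors == {"recA", "recB"}
        assert all(r.ligand_class == "endogenous" for r in records)

    def test_roundtrip_through_csv(self, tmp_path):
        p = tmp_path / "r__l.log"
        p.write_text(VINA_LOG)
        records = parse_vina_output(p, ligand_class="exogenous")
        csv = tmp_path / "dg.csv"
        write_dg_table(records, csv)
        back = read_dg_table(csv)
        assert [(r.receptor, r.ligand, r.delta_g, r.pose_rank,
                 r.ligand_class) for r in back] == [
            (r.receptor, r.ligand, r.delta_g, r.pose_rank,
             r.ligand_class) for r in records
        ]


def _records(receptor, endo_kds_dg, exo_dg):
    recs = [
        DockingRecord(receptor, f"endo{i}", dg, 1, "endogenous")
        for i, dg in enumerate(endo_kds_dg, 1)
    ]
    recs.append(DockingRecord(receptor, "DDM", exo_dg, 1, "exogenous"))
    return recs


class TestSwap:
    def test_tighter_exogenous_swaps(self):
        rt = R_KCAL * 298.15
        recs = _records("r", [rt * math.log(1e-6), rt * math.log(1e-7)],
                        rt * math.log(1e-8))
        call = swap_feasibility(recs, "DDM")
        assert call.fold == pytest.approx(10.0, rel=1e-9)
        assert call.verdict == "swap"
        assert call.best_endogenous == "endo2"

    def test_tie_counts_as_swap(self):
        recs = _records("r", [-8.0], -8.0)
        call = swap_feasibility(recs, "DDM")
        assert call.fold == pytest.approx(1.0)
        assert call.verdict == "swap"

    def test_weaker_exogenous_no_swap(self):
        rt = R_KCAL * 298.15
        recs = _records("r", [rt * math.log(1e-7)], rt * math.log(1e-6))
        call = swap_feasibility(recs, "DDM")
        assert call.fold == pytest.approx(0.1, rel=1e-9)
        assert call.verdict == "no_swap"

    def test_missing_classes_errors(self):
        only_endo = [DockingRecord("r", "e", -7.0, 1, "endogenous")]
        with pytest.raises(ValueError, match="absent"):
            swap_feasibility(only_endo, "DDM")
        only_exo = [DockingRecord("r", "DDM", -7.0, 1, "exogenous")]
        with pytest.raises(ValueError, match="no endogenous"):
            swap_feasibility(only_exo, "DDM")

    def test_global_energy_shift_preserves_verdict(self):
        # shifting every dG by a constant rescales all Kds by one factor
        recs = _records("r", [-7.0, -6.2], -7.5)
        base = swap_feasibility(recs, "DDM")
        shifted = [
            DockingRecord(r.receptor, r.ligand, r.delta_g + 1.3,
                          r.pose_rank, r.ligand_class)
            for r in recs
        ]
        after = swap_feasibility(shifted, "DDM")
        assert after.verdict == base.verdict
        assert after.fold == pytest.approx(base.fold, rel=1e-9)

    def test_higher_energy_poses_never_change_verdict(self):
        recs = _records("r", [-7.0, -6.2], -7.5)
        base = swap_feasibility(recs, "DDM")
        extra = recs + [
            DockingRecord("r", "endo1", -6.0, 2, "endogenous"),
            DockingRecord("r", "DDM", -5.0, 2, "exogenous"),
        ]
        after = swap_feasibility(extra, "DDM")
        assert (after.verdict, after.fold) == (base.verdict, base.fold)


class TestMutationalScan:
    def test_identical_tables_all_folds_one(self):
        wt = _records("wt", [-7.0, -6.5], -7.5)
        mut = [
            DockingRecord("mut", r.ligand, r.delta_g, r.pose_rank,
                          r.ligand_class)
            for r in wt
        ]
        cmp = mutational_scan(wt, mut, exo_ligand="DDM")
        assert all(c.fold == pytest.approx(1.0) for c in cmp.changes)
        assert cmp.verdict_changed is False

    def test_endogenous_tightening_flips_swap_to_no_swap(self):
        rt = R_KCAL * 298.15
        wt = _records("wt", [-7.0], -7.5)   # exo tighter: swap
        mut = [
            DockingRecord(
                "mut", r.ligand,
                r.delta_g - (rt * math.log(10.0)
                             if r.ligand_class == "endogenous" else 0.0),
                r.pose_rank, r.ligand_class,
            )
            for r in wt
        ]
        cmp = mutational_scan(wt, mut, exo_ligand="DDM")
        assert cmp.wt_call.verdict == "swap"
        assert cmp.mut_call.verdict == "no_swap"
        assert cmp.verdict_changed is True
        assert "increased affinity for all endogenous" in cmp.summary()

    def test_exogenous_affinity_gain_increases_fold_spread(self):
        # mutation improves only the exogenous ligand: swap fold grows
        wt = _records("wt", [-7.0, -6.8], -6.9)
        mut = [
            DockingRecord(
                "mut", r.ligand,
                r.delta_g - (1.5 if r.ligand_class == "exogenous"
                             else 0.0),
                r.pose_rank, r.ligand_class,
            )
            for r in wt
        ]
        cmp = mutational_scan(wt, mut, exo_ligand="DDM")
        assert cmp.mut_call.fold > cmp.wt_call.fold

    def test_panel_mismatch_lists_difference(self):
        wt = _records("wt", [-7.0], -7.5)
        mut = [DockingRecord("mut", "other", -7.0, 1, "endogenous")]
        with pytest.raises(ValueError, match="only in background"):
            mutational_scan(wt, mut)
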