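"""Dataset I/O, eligibility filtering and body-composition arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fupk import (AdverseEventRecord, AnalysisDataset, SchemaError,
                  apply_time_window_filter, compute_auc, compute_smi,
                  dichotomize_grades, muscle_area_from_hu_grid, read_dataset,
                  write_dataset)
from fupk.dataset import read_ae_table, write_ae_table

from conftest import make_subject
from fupk import ConcentrationObservation, DoseEvent


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_round_trip_is_lossless(self, toy_dataset, tmp_path):
        p = write_dataset(toy_dataset, tmp_path / "d.csv")
        back = read_dataset(p)
        assert back.n_subjects == 2 and back.n_observations == 4
        for a, b in zip(toy_dataset.observations, back.observations):
            assert a.dv == b.dv and a.time == b.time and a.cycle == b.cycle
        for a, b in zip(toy_dataset.subjects, back.subjects):
            assert a.bsa == b.bsa and a.smi_back == b.smi_back
        for a, b in zip(toy_dataset.doses, back.doses):
            assert a.dose_amount == b.dose_amount
            assert a.infusion_duration == b.infusion_duration

    def test_counts_preserved_on_toy_csv(self, tmp_path):
        csv = (
            "ID,TIME,EVID,MDV,AMT,RATE,DV,CYCLE,BSA,SMIBM,CTDAYS\n"
            "1,0,1,1,4800,200,.,1,1.97,3.78,0\n"
            "1,18,0,0,900,.,900,1,1.97,3.78,0\n"
            "1,22,0,0,.,.,950,1,1.97,3.78,0\n"
            "2,0,1,1,4800,200,.,1,2.10,4.00,0\n"
            "2,18,0,0,.,.,850,1,2.10,4.00,0\n"
            "2,22,0,0,.,.,870,1,2.10,4.00,0\n"
        )
        # DV column on observation rows is what matters; AMT/RATE ignored there
        path = tmp_path / "toy.csv"
        path.write_text(csv)
        ds = read_dataset(path)
        assert ds.n_subjects == 2
        assert ds.n_observations == 4
        assert len(ds.doses) == 2

    def test_mdv_row_with_na_dv_accepted(self, tmp_path):
        csv = ("ID,TIME,EVID,MDV,AMT,RATE,DV,CYCLE\n"
               "1,0,1,1,4800,200,NA,1\n"
               "1,18,0,0,.,.,900,1\n")
        path = tmp_path / "na.csv"
        path.write_text(csv)
        assert read_dataset(path).n_observations == 1

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME,EVID,AMT,RATE,DV\n1,0,1,10,1,.\n")
        with pytest.raises(SchemaError, match="MDV"):
            read_dataset(path)

    def test_non_numeric_dv_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME,EVID,MDV,AMT,RATE,DV,CYCLE\n"
                        "1,0,1,1,4800,200,.,1\n"
                        "1,18,0,0,.,.,oops,1\n")
        with pytest.raises(SchemaError, match="row 3"):
            read_dataset(path)

    def test_unknown_evid_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME,EVID,MDV,AMT,RATE,DV,CYCLE\n"
                        "1,0,7,1,4800,200,.,1\n")
        with pytest.raises(ValueError, match="EVID"):
            read_dataset(path)

    def test_below_lloq_dropped_with_warning(self, tmp_path):
        path = tmp_path / "blq.csv"
        path.write_text("ID,TIME,EVID,MDV,AMT,RATE,DV,CYCLE\n"
                        "1,0,1,1,4800,200,.,1\n"
                        "1,18,0,0,.,.,50,1\n"
                        "1,22,0,0,.,.,900,1\n")
        with pytest.warns(UserWarning, match="LLOQ"):
            ds = read_dataset(path)
        assert ds.n_observations == 1

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = AnalysisDataset(subjects=[], doses=[], observations=[])
        p = write_dataset(ds, tmp_path / "empty.csv")
        df = pd.read_csv(p)
        assert len(df) == 0 and "ID" in df.columns and "DV" in df.columns

    def test_ae_table_round_trip(self, tmp_path, toy_dataset):
        recs = [AdverseEventRecord("A", "fatigue", 3),
                AdverseEventRecord("B", "nausea", 0)]
        p = write_ae_table(recs, tmp_path / "ae.csv")
        assert read_ae_table(p) == recs


# ---------------------------------------------------------------------------
# Eligibility window
# ---------------------------------------------------------------------------

class TestTimeWindowFilter:
    def _ds(self, offsets):
        subjects = [make_subject(f"S{i}", ct_offset_days=o)
                    for i, o in enumerate(offsets)]
        doses = [DoseEvent(s.subject_id, 1, 4000.0, 24.0) for s in subjects]
        return AnalysisDataset(subjects=subjects, doses=doses,
                               observations=[])

    def test_boundary_is_inclusive(self):
        kept, report = apply_time_window_filter(self._ds([10, 205, 206]))
        assert [s.subject_id for s in kept.subjects] == ["S0", "S1"]
        assert list(report["subject_id"]) == ["S2"]
        assert list(report["ct_offset_days"]) == [206]

    def test_zero_offsets_identity(self):
        ds = self._ds([0, 0, 0])
        kept, report = apply_time_window_filter(ds)
        assert kept.n_subjects == 3 and report.empty

    def test_zero_window_boundary(self):
        kept, _ = apply_time_window_filter(self._ds([0, -1]), max_days=0)
        assert [s.subject_id for s in kept.subjects] == ["S0"]

    def test_missing_offset_names_subject(self):
        ds = self._ds([0])
        object.__setattr__(ds.subjects[0], "ct_offset_days", float("nan"))
        with pytest.raises(ValueError, match="S0"):
            apply_time_window_filter(ds)

    @given(st.lists(st.integers(-400, 400), min_size=1, max_size=12),
           st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_monotone(self, offsets, w1, w2):
        ds = self._ds(offsets)
        once, _ = apply_time_window_filter(ds, max_days=w1)
        twice, _ = apply_time_window_filter(once, max_days=w1)
        assert [s.subject_id for s in once.subjects] == \
            [s.subject_id for s in twice.subjects]
        lo, hi = sorted((w1, w2))
        small, _ = apply_time_window_filter(ds, max_days=lo)
        big, _ = apply_time_window_filter(ds, max_days=hi)
        assert {s.subject_id for s in small.subjects} <= \
            {s.subject_id for s in big.subjects}


# ---------------------------------------------------------------------------
# Body-composition arithmetic
# ---------------------------------------------------------------------------

class TestMuscleArea:
    def test_hand_counted_area(self):
        grid = np.full((3, 3), -100.0)
        grid[0, 0] = grid[0, 1] = grid[1, 1] = grid[2, 2] = 40.0
        assert muscle_area_from_hu_grid(grid, (5.0, 5.0)) == pytest.approx(1.0)

    def test_window_bounds_inclusive(self):
        grid = np.full((2, 2), -100.0)
        grid[0, 0], grid[1, 1] = 35.0, 50.0
        assert muscle_area_from_hu_grid(grid, (1.0, 1.0)) == \
            pytest.approx(0.02)

    def test_all_zero_hu_outside_window(self):
        assert muscle_area_from_hu_grid(np.zeros((4, 4)), (1.0, 1.0)) == 0.0

    def test_shape_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            muscle_area_from_hu_grid(np.zeros((2, 2)), (1, 1),
                                     roi_mask=np.ones((3, 3), bool))
        with pytest.raises(ValueError):
            muscle_area_from_hu_grid(np.zeros((0, 0)), (1, 1))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_additive_over_disjoint_masks_and_window_invariance(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.uniform(-150, 150, (6, 6))
        mask = rng.random((6, 6)) < 0.5
        a_all = muscle_area_from_hu_grid(grid, (2.0, 2.0))
        a1 = muscle_area_from_hu_grid(grid, (2.0, 2.0), roi_mask=mask)
        a2 = muscle_area_from_hu_grid(grid, (2.0, 2.0), roi_mask=~mask)
        assert a1 + a2 == pytest.approx(a_all)
        # values outside the window are irrelevant
        grid2 = np.where((grid >= 35) & (grid <= 50), grid, -1000.0)
        assert muscle_area_from_hu_grid(grid2, (2.0, 2.0)) == \
            pytest.approx(a_all)


class TestSmiAndAuc:
    def test_hand_values(self):
        assert compute_smi(15.12, 2.0) == pytest.approx(3.78)
        assert compute_smi(0.0, 1.8) == 0.0
        assert compute_smi(7.5, 1.0) == 7.5
        assert compute_auc(1000.0, 24.0) == pytest.approx(24.0)
        assert compute_auc(0.0, 24.0) == 0.0
        assert compute_auc(821.0, 24.0) == pytest.approx(19.704)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_smi(10.0, 0.0)
        with pytest.raises(ValueError):
            compute_auc(-1.0, 24.0)

    @given(st.floats(0.1, 100), st.floats(0.5, 2.5), st.floats(0.5, 10))
    @settings(max_examples=50, deadline=None)
    def test_degree_one_homogeneity(self, area, height, k):
        assert compute_smi(k * area, height) == \
            pytest.approx(k * compute_smi(area, height))
        assert compute_auc(k * area, 24.0) == \
            pytest.approx(k * compute_auc(area, 24.0))


class TestDichotomizeGrades:
    def test_grade_coding_rule(self):
        recs = [AdverseEventRecord("A", "fatigue", g) for g in (0, 1)] + \
               [AdverseEventRecord(s, "fatigue", g)
                for s, g in (("B", 2), ("C", 3), ("D", 4))]
        out = dichotomize_grades(recs, "fatigue")
        coded = dict(zip(out["subject_id"], out["outcome"]))
        assert coded == {"A": 0, "B": 1, "C": 1, "D": 1}

    def test_max_grade_collapse_across_visits(self):
        recs = [AdverseEventRecord("A", "nausea", 1),
                AdverseEventRecord("A", "nausea", 3)]
        out = dichotomize_grades(recs, "nausea")
        assert out.loc[0, "outcome"] == 1

    def test_unobserved_subject_coded_zero_and_flagged(self):
        out = dichotomize_grades([AdverseEventRecord("A", "emesis", 2)],
                                 "emesis", subject_ids=["A", "B"])
        assert list(out["outcome"]) == [1, 0]
        assert list(out["observed"]) == [True, False]

    def test_empty_and_unknown_type(self):
        assert dichotomize_grades([], "fatigue").empty
        with pytest.raises(ValueError, match="ae_type"):
            dichotomize_grades([], "gout")
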