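import numpy as np
import pandas as pd
import pytest

from gastropd.cohort import (
    CohortTable,
    CohortValidationError,
    ColumnMapError,
    VisitObservation,
    derive_pcr,
    derive_response,
    derive_response_combined,
    read_cohort,
    write_cohort,
)
from gastropd.simulate import SimulationConfig, simulate_cohort
from tests.conftest import make_patient


class TestDeriveResponse:
    @pytest.mark.parametrize(
        "stages, expected",
        [
            ([3, 2, 0], [2, 0, 0]),      # downstaging -> partial response
            ([3, 3], [2, 1]),            # no change -> stable disease
            ([2, 4], [2, 2]),            # upstaging -> progression
            ([3], [2]),                  # diagnosis alone
            ([3, None, 2], [2, None, 0]),  # missing propagates, not imputed
        ],
    )
    def test_stage_change_rule(self, stages, expected):
        assert derive_response(stages) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            derive_response([])

    def test_output_invariants_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 5)
            stages = rng.integers(0, 6, size=n).tolist()
            out = derive_response(stages)
            assert len(out) == len(stages)
            assert out[0] == 2
            assert set(out) <= {0, 1, 2}

    def test_combined_t_n_rule(self):
        # upstaging in either dimension dominates
        assert derive_response_combined([3, 2], [1, 2]) == [2, 2]
        # downstaging without upstaging
        assert derive_response_combined([3, 2], [1, 1]) == [2, 0]
        # unchanged both
        assert derive_response_combined([3, 3], [1, 1]) == [2, 1]


class TestDerivePcr:
    @pytest.mark.parametrize("ypt, ypn, expected", [(0, 0, True), (0, 1, False),
                                                    (2, 0, False)])
    def test_rule(self, ypt, ypn, expected):
        assert derive_pcr(make_patient(ypt=ypt, ypn=ypn)) is expected

    def test_missing_pathology_is_none(self):
        assert derive_pcr(make_patient(ypt=None, ypn=None)) is None

    def test_pcr_count_matches_generator_injection(self):
        cohort = simulate_cohort(SimulationConfig(n_patients=400, seed=9))
        n_pcr = sum(
            bool(derive_pcr(row)) for _, row in cohort.patients.iterrows()
        )
        n_ypt0 = int((cohort.patients["ypt"] == 0).sum())
        assert n_pcr == n_ypt0  # ypT0 => ypN0 coupling injects exactly these


class TestValidation:
    def test_valid_cohort_passes(self, three_patient_cohort):
        assert three_patient_cohort.validation_report() == []

    def test_metastasis_after_death_reported(self, three_patient_cohort):
        c = three_patient_cohort
        bad_events = pd.concat(
            [c.events, pd.DataFrame([
                {"patient_id": "P3", "event_type": "death", "time_days": 100.0,
                 "observed": True},
                {"patient_id": "P3", "event_type": "metastasis", "time_days": 150.0,
                 "observed": True},
            ])],
            ignore_index=True,
        )
        bad = CohortTable(c.patients, c.visits, bad_events)
        report = bad.validation_report()
        assert any("metastasis after death" in v for v in report)
        with pytest.raises(CohortValidationError):
            bad.validate()

    def test_all_violations_enumerated(self, three_patient_cohort):
        c = three_patient_cohort
        pats = c.patients.copy()
        pats.loc[0, "age_years"] = 10.0     # under-age
        pats.loc[1, "sex"] = "unknown"      # bad level
        bad = CohortTable(pats, c.visits, c.events)
        report = bad.validation_report()
        assert len(report) >= 2

    def test_diagnosis_visit_must_be_progression(self, three_patient_cohort):
        c = three_patient_cohort
        vis = c.visits.copy()
        vis.loc[vis.index[0], "response_dv"] = 0
        report = CohortTable(c.patients, vis, c.events).validation_report()
        assert any("expected 2" in v for v in report)


class TestRoundTrip:
    def test_fixture_round_trip(self, three_patient_cohort, tmp_path):
        write_cohort(three_patient_cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert back.equals(three_patient_cohort)
        assert back.n_patients == 3
        assert len(back.visits) == 9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_synthetic_cohort_round_trip(self, seed, tmp_path):
        cohort = simulate_cohort(SimulationConfig(n_patients=115, seed=seed))
        write_cohort(cohort, tmp_path / str(seed))
        back = read_cohort(tmp_path / str(seed))
        assert back.equals(cohort)

    def test_missing_pathology_serialized_as_empty_cell(self, tmp_path):
        cohort = CohortTable.from_records(
            [make_patient(ypt=None, ypn=None)],
            [VisitObservation("P1", 1, 0.0, 2)],
        )
        write_cohort(cohort, tmp_path)
        text = (tmp_path / "patients.csv").read_text()
        row = text.splitlines()[1]
        assert row.endswith(",,")  # ypt, ypn empty, no sentinel
        assert pd.isna(read_cohort(tmp_path).patients.loc[0, "ypt"])

    def test_empty_cohort_writes_header_only(self, tmp_path):
        empty = CohortTable(pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
        write_cohort(empty, tmp_path)
        assert len((tmp_path / "patients.csv").read_text().splitlines()) == 1


class TestColumnMappedReader:
    def test_column_map_renames_source_columns(self, three_patient_cohort, tmp_path):
        write_cohort(three_patient_cohort, tmp_path)
        # mimic a spreadsheet export with foreign headers
        pats = pd.read_csv(tmp_path / "patients.csv")
        pats = pats.rename(columns={"patient_id": "ID", "age_years": "AGE"})
        pats.to_csv(tmp_path / "patients.csv", index=False)
        with pytest.raises(ColumnMapError):
            read_cohort(tmp_path)
        back = read_cohort(
            tmp_path, column_maps={"patients": {"patient_id": "ID", "age_years": "AGE"}}
        )
        assert back.n_patients == 3

    def test_mapping_error_names_missing_field(self, three_patient_cohort, tmp_path):
        write_cohort(three_patient_cohort, tmp_path)
        pats = pd.read_csv(tmp_path / "patients.csv").drop(columns=["sex"])
        pats.to_csv(tmp_path / "patients.csv", index=False)
        with pytest.raises(ColumnMapError, match="sex"):
            read_cohort(tmp_path)

    def test_xlsx_ingestion(self, three_patient_cohort, tmp_path):
        write_cohort(three_patient_cohort, tmp_path)
        for name in ("patients", "visits", "events"):
            df = pd.read_csv(tmp_path / f"{name}.csv")
            df.to_excel(tmp_path / f"{name}.xlsx", index=False)
            (tmp_path / f"{name}.csv").unlink()
        back = read_cohort(tmp_path)
        assert back.equals(three_patient_cohort)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        (tmp_path / "patients.csv").write_bytes(b"\x00\x01binary\x02")
        (tmp_path / "visits.csv").write_text("patient_id\n")
        with pytest.raises((ValueError, ColumnMapError)):
            read_cohort(tmp_path)
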