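"""Round-trip and validation tests of the file dialects."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paee.accelerometry import EpochStream
from paee.data_io import (
    CohortValidationError,
    EpochFormatError,
    read_cohort,
    read_epoch_stream,
    read_isotope_records,
    read_results,
    write_cohort,
    write_epoch_stream,
    write_isotope_records,
    write_results,
)
from paee.dlw_energy import EnergyResult, IsotopeRecord, IsotopeSample
from paee.equations import FittedEquation
from paee.synthetic import (
    SimulationConfig,
    generate_participants,
    iter_isotope_records,
)

MONDAY = dt.datetime(2017, 6, 5)


class TestCohort:
    def test_small_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            {
                "participant_id": ["B001", "G001"],
                "sex_code": [1, 0],
                "age": [12.5, 11.25],
                "weight": [34.2, 36.8],
                "height": [1.42, 1.51],
            }
        )
        path = tmp_path / "cohort.csv"
        write_cohort(frame, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back, frame)

    def test_generated_cohort_round_trips_field_for_field(self, tmp_path):
        config = SimulationConfig(seed=1, n_boys=41, n_girls=38)
        cohort, _ = generate_participants(config)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert len(back) == 79
        pd.testing.assert_frame_equal(back, cohort, check_exact=False, rtol=1e-12)

    @pytest.mark.parametrize(
        "column,value,message",
        [
            ("sex_code", 2, "sex_code"),
            ("weight", -1.0, "weight"),
            ("height", 0.0, "height"),
        ],
    )
    def test_invalid_rows_are_named(self, tmp_path, column, value, message):
        frame = pd.DataFrame(
            {
                "participant_id": ["B001"],
                "sex_code": [1],
                "age": [12.0],
                "weight": [34.2],
                "height": [1.42],
            }
        )
        frame.loc[0, column] = value
        path = tmp_path / "cohort.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match=message):
            read_cohort(path)

    def test_duplicate_id_rejected(self, tmp_path):
        frame = pd.DataFrame(
            {
                "participant_id": ["B001", "B001"],
                "sex_code": [1, 1],
                "age": [12.0, 12.1],
                "weight": [34.2, 30.0],
                "height": [1.42, 1.40],
            }
        )
        path = tmp_path / "cohort.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="duplicate"):
            read_cohort(path)


class TestEpochFiles:
    def _stream(self, n=4, epoch_s=15):
        counts = np.arange(n * 3, dtype=np.int64).reshape(n, 3)
        return EpochStream(start=MONDAY, epoch_s=epoch_s, counts=counts)

    def test_round_trip(self, tmp_path):
        stream = self._stream(8)
        path = tmp_path / "epochs.csv"
        write_epoch_stream(stream, path, participant_id="B001")
        back = read_epoch_stream(path)
        assert back.epoch_s == 15
        assert back.start == stream.start
        assert np.array_equal(back.counts, stream.counts)

    def test_four_epochs_give_length_four(self, tmp_path):
        path = tmp_path / "epochs.csv"
        write_epoch_stream(self._stream(4), path)
        assert len(read_epoch_stream(path, epoch_s=15)) == 4

    def test_gap_reported_with_line_number(self, tmp_path):
        path = tmp_path / "epochs.csv"
        write_epoch_stream(self._stream(6), path)
        lines = path.read_text().splitlines()
        del lines[13]  # drop the third epoch row (file line 14)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(EpochFormatError, match="line 14"):
            read_epoch_stream(path)

    def test_ten_day_generated_file_has_57600_epochs_per_day(self, tmp_path):
        from paee.synthetic import generate_epoch_stream, _rng

        config = SimulationConfig(seed=2, n_boys=1, n_girls=0)
        _, truth = generate_participants(config)
        stream, _ = generate_epoch_stream(
            truth.iloc[0].to_dict(), config, _rng(config.seed, 0, 2)
        )
        assert len(stream) == config.study_days * 86400 // 15
        path = tmp_path / "epochs.csv"
        write_epoch_stream(stream, path, participant_id="B001")
        back = read_epoch_stream(path)
        assert len(back) == len(stream)
        assert np.array_equal(back.counts, stream.counts)


class TestIsotopeFiles:
    def test_generated_records_round_trip(self, tmp_path, small_config, small_cohort):
        _, truth = small_cohort
        records = iter_isotope_records(small_config, truth)
        path = tmp_path / "isotopes.csv"
        write_isotope_records(records, path)
        back = read_isotope_records(path)
        assert set(back) == set(records)
        for pid, rec in records.items():
            got = back[pid]
            assert got.dose_2h_g == pytest.approx(rec.dose_2h_g, rel=1e-9)
            for label in ("baseline", "post4h", "day10"):
                a, b = getattr(rec, label), getattr(got, label)
                assert b.e_2h_ppm == pytest.approx(a.e_2h_ppm, rel=1e-9)
                assert b.e_18o_ppm == pytest.approx(a.e_18o_ppm, rel=1e-9)

    def test_missing_sample_row_read_as_incomplete(self, tmp_path):
        record = IsotopeRecord(
            participant_id="B001", dose_2h_g=2.46, dose_18o_g=36.9,
            baseline=IsotopeSample(0.0, 155.8, 2005.2),
            post4h=IsotopeSample(4.0, 260.0, 2180.0),
            day10=None,
        )
        path = tmp_path / "iso.csv"
        write_isotope_records({"B001": record}, path)
        back = read_isotope_records(path)
        assert back["B001"].day10 is None


class TestResults:
    def test_energy_result_round_trip_at_six_digits(self, tmp_path):
        result = EnergyResult(
            participant_id="B001", kd_per_day=0.101234567, ko_per_day=0.13456789,
            nd_mol=1103.2345, no_mol=1066.789, tbw_kg=19.123456, ffm_kg=25.03456,
            fm_kg=9.16543, rco2_mol_day=14.91234, tee_kcal_day=1987.6543,
            tee_kcal_min=1.3803, bmr_kcal_day=1263.0567, paee_kcal_min=0.365432,
            flags=["negative_fat_mass"],
        )
        path = tmp_path / "energy.json"
        write_results(result, path)
        back = read_results(path)
        for f in dataclasses.fields(EnergyResult):
            value = getattr(result, f.name)
            if isinstance(value, float):
                assert back[f.name] == pytest.approx(value, rel=1e-6)
        assert back["flags"] == ["negative_fat_mass"]

    def test_fitted_equation_lists_all_coefficients(self, tmp_path):
        eq = FittedEquation(
            predictors=["cpm", "weight"],
            coefficients={"intercept": -0.1, "cpm": 0.001, "weight": 0.002},
            r=0.8, r2_pct=64.0, rmse=0.13, n=54,
        )
        path = tmp_path / "eq.json"
        write_results(eq, path)
        back = read_results(path)
        assert set(back["coefficients"]) == {"intercept", "cpm", "weight"}

    def test_validation_report_carries_both_agreement_limits(self, tmp_path):
        from paee.validation import ValidationReport

        report = ValidationReport(
            n=25, mean_criterion=0.39, sd_criterion=0.27, mean_predicted=0.36,
            sd_predicted=0.18, t_statistic=1.2, p_value=0.24, correlation_r=0.84,
            pure_error=0.14, rmse_validation=0.13, bias=0.06, sd_diff=0.16,
            loa_lower=-0.2536, loa_upper=0.3736,
        )
        path = tmp_path / "report.json"
        write_results(report, path)
        back = read_results(path)
        assert back["loa_lower"] == pytest.approx(-0.2536)
        assert back["loa_upper"] == pytest.approx(0.3736)

    @settings(max_examples=25, deadline=None)
    @given(
        values=st.lists(
            st.floats(
                min_value=-1e6, max_value=1e6,
                allow_nan=False, allow_infinity=False,
            ),
            min_size=1, max_size=8,
        )
    )
    def test_write_read_identity_on_random_payloads(self, tmp_path_factory, values):
        payload = {f"k{i}": v for i, v in enumerate(values)}
        path = tmp_path_factory.mktemp("results") / "payload.json"
        write_results(payload, path)
        back = read_results(path)
        for key, value in payload.items():
            assert back[key] == value  # repr round-trip is exact


def test_reader_never_silently_drops_rows(tmp_path):
    """Parsed + rejected rows always account for every input row."""
    frame = pd.DataFrame(
        {
            "participant_id": [f"B{i:03d}" for i in range(5)],
            "sex_code": [1, 1, 0, 0, 1],
            "age": [12.0] * 5,
            "weight": [30.0, 31.0, 32.0, 33.0, 34.0],
            "height": [1.4] * 5,
        }
    )
    path = tmp_path / "cohort.csv"
    frame.to_csv(path, index=False)
    assert len(read_cohort(path)) == 5  # all parse: none dropped
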