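"""Dose-log data model, I/O, descriptive statistics, annualization."""

import math

import numpy as np
import pytest

from cathlar import (
    ProcedureType,
    Role,
    SchemaError,
    ValidationError,
    annualize,
    read_dose_log,
    read_dose_log_xlsx,
    summarize,
    write_dose_log,
)
from conftest import make_record


class TestIO:
    def test_round_trip_is_lossless(self, small_log, tmp_path):
        path = tmp_path / "log.csv"
        write_dose_log(small_log, path)
        back = read_dose_log(path)
        assert back == small_log

    def test_three_row_csv_parses_three_procedures(self, tmp_path):
        records = [make_record(pid=f"P{i}") for i in range(3)]
        path = tmp_path / "log.csv"
        write_dose_log(records, path)
        assert len(read_dose_log(path)) == 3

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("procedure_id,dap_gycm2\nP1,5\n")
        with pytest.raises(SchemaError, match="missing mandatory column"):
            read_dose_log(path)

    def test_negative_dap_names_offending_row(self, small_log, tmp_path):
        path = tmp_path / "log.csv"
        write_dose_log(small_log[:2], path)
        text = path.read_text().splitlines()
        text[1] = text[1].replace(text[1].split(",")[8], "-1.0", 1)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_dose_log(path)

    def test_skip_bad_rows_drops_instead_of_failing(self, small_log, tmp_path):
        path = tmp_path / "log.csv"
        write_dose_log(small_log[:3], path)
        lines = path.read_text().splitlines()
        lines.insert(2, lines[1].replace("CA", "NOT_A_TYPE", 1))
        path.write_text("\n".join(lines) + "\n")
        kept = read_dose_log(path, skip_bad_rows=True)
        assert 2 <= len(kept) <= 3

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(SchemaError):
            read_dose_log(tmp_path / "x.csv", dialect="doselog-v99")

    def test_xlsx_import_matches_csv(self, small_log, tmp_path):
        import openpyxl

        from cathlar.dose_records import DOSELOG_V1_COLUMNS, records_to_frame

        frame = records_to_frame(small_log[:5])
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append(DOSELOG_V1_COLUMNS)
        for _, row in frame.iterrows():
            ws.append([row[c] for c in DOSELOG_V1_COLUMNS])
        path = tmp_path / "log.xlsx"
        wb.save(path)
        records = read_dose_log_xlsx(path)
        assert len(records) == 5
        assert records[0].operator_doses[0].epd_dose_usv == pytest.approx(
            small_log[0].operator_doses[0].epd_dose_usv
        )


class TestValidation:
    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            make_record(doses=((Role.PRIMARY, -1.0),))

    def test_zero_dap_only_for_others_without_cine(self):
        with pytest.raises(ValidationError):
            make_record(dap=0.0)
        rec = make_record(dap=0.0, ptype=ProcedureType.OTHERS, acq_time_s=0.0)
        assert rec.dap_gycm2 == 0.0

    def test_age_range_enforced(self):
        from cathlar import OperatorDose, Sex

        with pytest.raises(ValidationError):
            OperatorDose("X", Role.PRIMARY, 17.0, Sex.M, 1.0)


class TestSummarize:
    def test_sample_sd_uses_n_minus_1(self):
        records = [
            make_record(pid=f"P{i}", doses=((Role.PRIMARY, d),))
            for i, d in enumerate([1.0, 2.0, 3.0])
        ]
        stats = summarize(records).dose_stats
        row = stats[stats.role == "PRIMARY"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)  # ddof=1; population SD would be 0.816

    def test_single_record_reports_mean_without_sd(self):
        stats = summarize([make_record(doses=((Role.ASSISTANT, 4.0),))]).dose_stats
        row = stats.iloc[0]
        assert row["n"] == 1 and row["mean"] == 4.0 and math.isnan(row["sd"])

    def test_equal_doses_give_zero_sd(self):
        records = [make_record(pid=f"P{i}", doses=((Role.PRIMARY, 5.0),)) for i in range(2)]
        assert summarize(records).dose_stats.iloc[0]["sd"] == 0.0

    def test_permutation_invariance(self, small_log):
        forward = summarize(small_log).dose_stats
        backward = summarize(list(reversed(small_log))).dose_stats
        assert np.allclose(
            forward[["n", "mean", "sd"]].to_numpy(float),
            backward[["n", "mean", "sd"]].to_numpy(float),
            equal_nan=True,
        )

    def test_group_counts_sum_to_totals(self, small_log):
        summary = summarize(small_log)
        n_ops = sum(len(r.operator_doses) for r in small_log)
        assert summary.dose_stats["n"].sum() == n_ops
        assert summary.n_procedures == len(small_log)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestAnnualize:
    def test_12_month_window_sums_and_converts(self):
        # 3,490 μSv over a year -> 3.49 mSv/yr
        records = [
            make_record(pid=f"P{i}", doses=((Role.PRIMARY, 349.0),)) for i in range(10)
        ]
        assert annualize(records, Role.PRIMARY) == pytest.approx(3.49)

    def test_study_caseload_weighted_means(self):
        # 43 x 59.33 + 16 x 39.81 + 12 x 21.92 μSv = 3451.19 μSv -> 3.45 mSv/yr
        records = (
            [make_record(pid=f"A{i}", doses=((Role.PRIMARY, 59.33),)) for i in range(43)]
            + [make_record(pid=f"B{i}", doses=((Role.PRIMARY, 39.81),)) for i in range(16)]
            + [make_record(pid=f"C{i}", doses=((Role.PRIMARY, 21.92),)) for i in range(12)]
        )
        assert round(annualize(records, Role.PRIMARY), 2) == 3.45

    def test_window_rescaling_and_linearity(self):
        records = [make_record(doses=((Role.PRIMARY, 600.0),))]
        assert annualize(records, Role.PRIMARY, window_months=6) == pytest.approx(1.2)
        doubled = [make_record(doses=((Role.PRIMARY, 1200.0),))]
        assert annualize(doubled, Role.PRIMARY, window_months=6) == pytest.approx(2.4)

    def test_missing_role_rejected(self):
        records = [make_record(doses=((Role.PRIMARY, 10.0),))]
        with pytest.raises(ValueError, match="ASSISTANT"):
            annualize(records, Role.ASSISTANT)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            annualize([make_record()], Role.PRIMARY, window_months=0)
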