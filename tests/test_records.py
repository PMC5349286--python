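"""Record validation and CSV round-tripping."""

import math

import pandas as pd
import pytest

from rumenh2 import (
    RecordValidationError,
    SchemaError,
    VesselDayRecord,
    read_records,
    read_results,
    write_records,
    write_results,
)
from rumenh2.records import column_aliases, records_to_frame

HEADER = ("vessel,treatment,day,vfa_total,acetate,propionate,butyrate,"
          "isobutyrate,valerate,isovalerate,caproate,heptanoate,formate,"
          "nitrate,ch4_pct,gas_total")
ROW = "V1,CON,8,65.5,52.1,12.6,15.3,0.56,5.56,7.61,4.72,1.57,5.76,0.00,17.1,0.74"


def _write(tmp_path, lines, name="records.csv"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReader:
    def test_three_rows_give_three_records(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW,
                                 ROW.replace("V1,CON,8", "V1,CON,9"),
                                 ROW.replace("V1", "V2")])
        records = read_records(path)
        assert len(records) == 3
        assert records[0].vfa_total == 65.5
        assert records[0].vfa_profile["acetate"] == 52.1

    def test_header_only_gives_empty_collection(self, tmp_path):
        assert read_records(_write(tmp_path, [HEADER])) == []

    def test_out_of_range_gas_fraction_rejected(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW.replace(",17.1,", ",105,")])
        with pytest.raises(RecordValidationError, match=r"\[0, 100\]"):
            read_records(path)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = _write(tmp_path, ["vessel,day,vfa_total", "V1,8,65.5"])
        with pytest.raises(SchemaError, match="treatment"):
            read_records(path)

    def test_negative_concentration_names_the_row(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW, ROW.replace("65.5", "-1.0")])
        with pytest.raises(RecordValidationError, match="row 3"):
            read_records(path)

    def test_unknown_columns_reported_not_dropped(self, tmp_path):
        path = _write(tmp_path, [HEADER + ",mystery", ROW + ",42"])
        with pytest.warns(UserWarning, match="mystery"):
            read_records(path)
        with pytest.raises(SchemaError):
            read_records(path, on_unknown="error")

    def test_aliases_are_case_insensitive(self, tmp_path):
        path = _write(tmp_path, ["Fermenter,TRT,Study_Day,Total VFA (mM)"
                                 .replace(" (mM)", "_mM"),
                                 "V1,CON,8,65.5"])
        (record,) = read_records(path)
        assert record.vessel_id == "V1" and record.vfa_total == 65.5

    def test_alias_table_covers_all_canonical_fields(self):
        aliases = column_aliases()
        assert {"vessel", "treatment", "day", "vfa_total", "acetate",
                "ch4"}.issubset(aliases)


class TestValidation:
    def test_measured_zero_is_not_missing(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW])
        (record,) = read_records(path)
        assert record.nitrate == 0.0      # a measurement
        assert record.ammonium is None    # absent column -> missing

    def test_profile_sum_checked_without_formate(self):
        # the eight normalized acids must sum to ~100; formate sits outside
        shares = {"acetate": 52.1, "propionate": 12.6, "butyrate": 15.3,
                  "isobutyrate": 0.56, "valerate": 5.56, "isovalerate": 7.61,
                  "caproate": 4.72, "heptanoate": 1.57, "formate": 5.76}
        VesselDayRecord("V1", "CON", 8, vfa_total=65.5, vfa_profile=shares)
        bad = {**shares, "acetate": 60.0}
        with pytest.raises(RecordValidationError, match="sum to 100"):
            VesselDayRecord("V1", "CON", 8, vfa_total=65.5, vfa_profile=bad)

    def test_unknown_product_rejected(self):
        with pytest.raises(RecordValidationError, match="unknown VFA"):
            VesselDayRecord("V1", "CON", 8, vfa_profile={"octanoate": 1.0})


class TestRoundTrip:
    def test_records_roundtrip_preserves_values_and_missingness(self, tmp_path):
        records = [
            VesselDayRecord("V1", "CON", 8, vfa_total=65.5,
                            vfa_profile={"acetate": 52.1},
                            gas_fractions={"ch4": 17.1}, nitrate=0.0),
            VesselDayRecord("V2", "NIT", 9, ammonium=11.3, dissolved_h2=28.7),
        ]
        path = tmp_path / "out.csv"
        write_records(records, path)
        back = read_records(path)
        assert [r.vessel_id for r in back] == ["V1", "V2"]
        assert back[0].nitrate == 0.0
        assert back[0].ammonium is None and back[1].vfa_total is None
        assert back[0].vfa_profile == {"acetate": 52.1}
        assert back[1].dissolved_h2 == 28.7

    def test_result_tables_roundtrip_within_1e9(self, tmp_path):
        table = pd.DataFrame({"item": ["acetate", "butyrate"],
                              "CON": [42.72548, 12.54654]})
        write_results({"ledger": table}, tmp_path)
        back = read_results(tmp_path)["ledger"]
        assert list(back.columns) == ["item", "CON"]
        assert max(abs(back["CON"] - table["CON"])) < 1e-9
        assert (tmp_path / "ledger.csv").exists()

    def test_empty_table_writes_header_only(self, tmp_path):
        write_results({"empty": pd.DataFrame(columns=["item", "CON"])}, tmp_path)
        assert (tmp_path / "empty.csv").read_text().strip() == "item,CON"
        assert read_results(tmp_path)["empty"].empty

    def test_frame_roundtrip_keeps_nan_for_missing(self):
        record = VesselDayRecord("V1", "CON", 8, vfa_total=65.5)
        frame = records_to_frame([record])
        assert pd.isna(frame.loc[0, "ammonium"])
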