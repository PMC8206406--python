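from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cohortperm as cp
from cohortperm.claims import ClaimsSchemaError, CodeMapError, merge_spans

from conftest import make_dataset


@pytest.fixture()
def tiny_dataset():
    return make_dataset(
        [("A", "male", 1960), ("B", "female", 1975)],
        [("A", "2010-01-01", "2015-12-31"), ("B", "2011-02-01", "2013-01-31")],
        [
            ("A", "2010-03-01", "diagnosis", "ICD9", "401.9"),
            ("A", "2010-04-01", "diagnosis", "ICD10", "E11.9"),
            ("B", "2011-03-01", "lab_result", "LOINC", "4548-4", 5.6),
        ],
    )


class TestReadWrite:
    def test_round_trip_is_byte_identical(self, tiny_dataset, tmp_path):
        d1, d2 = tmp_path / "one", tmp_path / "two"
        cp.write_claims(tiny_dataset, d1)
        ds = cp.read_claims(d1)
        assert ds.n_members == 2 and ds.n_events == 3
        cp.write_claims(ds, d2)
        for name in ("members.csv", "enrollment.csv", "events.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_empty_tables_give_empty_dataset(self, tmp_path):
        (tmp_path / "members.csv").write_text("member_id,sex,birth_year\n")
        (tmp_path / "enrollment.csv").write_text("member_id,start,end\n")
        (tmp_path / "events.csv").write_text("member_id,date,kind,system,code,value\n")
        ds = cp.read_claims(tmp_path)
        assert ds.n_members == 0 and ds.n_events == 0
        assert cp.qualifying_windows(ds.enrollment).empty

    def test_misnamed_column_is_a_schema_error(self, tiny_dataset, tmp_path):
        cp.write_claims(tiny_dataset, tmp_path)
        text = (tmp_path / "members.csv").read_text().replace("member_id", "memberid")
        (tmp_path / "members.csv").write_text(text)
        with pytest.raises(ClaimsSchemaError, match="member_id"):
            cp.read_claims(tmp_path)

    def test_bad_date_reports_line_number(self, tiny_dataset, tmp_path):
        cp.write_claims(tiny_dataset, tmp_path)
        lines = (tmp_path / "events.csv").read_text().splitlines()
        lines[2] = lines[2].replace("2010-04-01", "04/01/2010")
        (tmp_path / "events.csv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ClaimsSchemaError, match="line 3"):
            cp.read_claims(tmp_path)

    def test_unknown_column_ignored_with_warning(self, tiny_dataset, tmp_path, caplog):
        cp.write_claims(tiny_dataset, tmp_path)
        mem = pd.read_csv(tmp_path / "members.csv")
        mem["plan_type"] = "PPO"
        mem.to_csv(tmp_path / "members.csv", index=False)
        with caplog.at_level("WARNING"):
            ds = cp.read_claims(tmp_path)
        assert "plan_type" in caplog.text
        assert "plan_type" not in ds.members.columns


class TestCodeMap:
    def test_single_event_translation(self, tiny_dataset):
        cm = cp.CodeMap("ICD10", "ICD9", {"E11.9": "250.00"})
        out = cp.apply_code_map(tiny_dataset, cm)
        assert (out.events["system"] != "ICD10").all()
        assert (out.events["code"] == "250.00").sum() == 1
        # ICD-9 rows untouched
        assert (out.events["code"] == "401.9").sum() == 1

    def test_icd9_only_dataset_is_identity(self, toy_dataset):
        cm = cp.CodeMap("ICD10", "ICD9", {"E11.9": "250.00"})
        out = cp.apply_code_map(toy_dataset, cm)
        pd.testing.assert_frame_equal(out.events, toy_dataset.events)

    def test_idempotent(self, tiny_dataset):
        cm = cp.CodeMap("ICD10", "ICD9", {"E11.9": "250.00"})
        once = cp.apply_code_map(tiny_dataset, cm)
        twice = cp.apply_code_map(once, cm)
        pd.testing.assert_frame_equal(once.events, twice.events)

    def test_strict_policy_names_unmapped_code(self, tiny_dataset):
        cm = cp.CodeMap("ICD10", "ICD9", {"E10.9": "250.01"})
        with pytest.raises(CodeMapError, match="E11.9"):
            cp.apply_code_map(tiny_dataset, cm)

    def test_drop_policy_removes_unmapped_events(self, tiny_dataset):
        cm = cp.CodeMap("ICD10", "ICD9", {"E10.9": "250.01"})
        out = cp.apply_code_map(tiny_dataset, cm, policy="drop")
        assert out.n_events == 2
        assert (out.events["system"] != "ICD10").all()

    def test_csv_round_trip(self, tmp_path):
        cm = cp.CodeMap("ICD10", "ICD9", {"E11.9": "250.00", "E11.65": "250.02"})
        cm.to_csv(tmp_path / "map.csv")
        back = cp.CodeMap.from_csv(tmp_path / "map.csv")
        assert back.entries == cm.entries


class TestWindowing:
    def test_six_year_span_gives_four_year_window(self):
        m = cp.MemberRecord("A", "male", 1960,
                            [(date(2010, 1, 1), date(2015, 12, 31))])
        w = cp.qualifying_window(m)
        assert w.start_date == date(2010, 1, 1)
        assert w.end_date == date(2013, 12, 31)
        assert w.n_days == 1461

    def test_two_short_spans_with_gap_do_not_qualify(self):
        m = cp.MemberRecord("A", "male", 1960, [
            (date(2010, 1, 1), date(2012, 12, 31)),
            (date(2013, 6, 1), date(2016, 5, 31)),
        ])
        assert cp.qualifying_window(m) is None

    def test_exact_four_year_span_is_its_own_window(self):
        m = cp.MemberRecord("A", "male", 1960,
                            [(date(2010, 1, 1), date(2013, 12, 31))])
        w = cp.qualifying_window(m)
        assert (w.start_date, w.end_date) == (date(2010, 1, 1), date(2013, 12, 31))

    def test_administrative_gap_is_bridged(self):
        # 31-day gap: continuous under the default grace period
        m = cp.MemberRecord("A", "male", 1960, [
            (date(2010, 1, 1), date(2011, 12, 31)),
            (date(2012, 2, 1), date(2014, 12, 31)),
        ])
        assert cp.qualifying_window(m) is not None
        # 32-day gap: not continuous
        m2 = cp.MemberRecord("A", "male", 1960, [
            (date(2010, 1, 1), date(2011, 12, 31)),
            (date(2012, 2, 2), date(2014, 12, 31)),
        ])
        assert cp.qualifying_window(m2) is None

    @given(st.lists(
        st.tuples(st.integers(0, 3000), st.integers(1, 2500)),
        min_size=1, max_size=4))
    @settings(derandomize=True, max_examples=60)
    def test_window_lies_inside_a_merged_span(self, raw):
        base = date(2008, 1, 1)
        spans, cursor = [], 0
        for offset, length in raw:
            start = cursor + offset
            spans.append((base + pd.Timedelta(days=start).to_pytimedelta(),
                          base + pd.Timedelta(days=start + length).to_pytimedelta()))
            cursor = start + length + 40   # keep raw spans disjoint
        m = cp.MemberRecord("A", "male", 1960, spans)
        w = cp.qualifying_window(m)
        merged = merge_spans(spans)
        if w is None:
            assert all((e - s).days + 1 < 1461 for s, e in merged)
        else:
            assert any(s <= w.start_date and w.end_date <= e for s, e in merged)
            assert w.n_days == 1461

    def test_vectorized_windows_agree_with_scalar(self):
        enrollment = pd.DataFrame({
            "member_id": ["A", "A", "B", "C"],
            "start": pd.to_datetime(
                ["2010-01-01", "2012-02-01", "2011-01-01", "2012-01-01"]),
            "end": pd.to_datetime(
                ["2011-12-31", "2014-12-31", "2011-12-31", "2016-06-30"]),
        })
        vec = cp.qualifying_windows(enrollment).set_index("member_id")
        for mid in ["A", "B", "C"]:
            spans = [(s.date(), e.date()) for _, s, e in
                     enrollment[enrollment["member_id"] == mid].itertuples(index=False)]
            w = cp.qualifying_window(cp.MemberRecord(mid, "male", 1960, spans))
            if w is None:
                assert mid not in vec.index
            else:
                assert vec.loc[mid, "start"].date() == w.start_date
                assert vec.loc[mid, "end"].date() == w.end_date


class TestMemberRecord:
    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cp.MemberRecord("A", "male", 1960, [
                (date(2010, 1, 1), date(2012, 1, 1)),
                (date(2011, 1, 1), date(2013, 1, 1)),
            ])

    def test_reversed_span_rejected(self):
        with pytest.raises(ValueError, match="ends before"):
            cp.MemberRecord("A", "male", 1960,
                            [(date(2012, 1, 1), date(2010, 1, 1))])

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            cp.MemberRecord("A", "other", 1960, [])


class TestFactsPerYear:
    def test_eight_diagnoses_over_four_years(self, toy_dataset):
        w = cp.ObservationWindow("X", date(2010, 1, 1), date(2013, 12, 31))
        ds = make_dataset(
            [("X", "male", 1960)], [("X", "2010-01-01", "2014-12-31")],
            [("X", f"2010-0{m}-15", "diagnosis", "ICD9", "401.9")
             for m in range(1, 9)],
        )
        assert cp.facts_per_year(ds, w) == 2.0

    def test_no_diagnoses_is_zero(self):
        ds = make_dataset([("X", "male", 1960)],
                          [("X", "2010-01-01", "2014-12-31")],
                          [("X", "2010-05-01", "procedure", "CPT", "82947")])
        w = cp.ObservationWindow("X", date(2010, 1, 1), date(2013, 12, 31))
        assert cp.facts_per_year(ds, w) == 0.0

    def test_out_of_window_diagnoses_not_counted(self):
        ds = make_dataset([("X", "male", 1960)],
                          [("X", "2010-01-01", "2015-12-31")],
                          [("X", "2010-05-01", "diagnosis", "ICD9", "401.9"),
                           ("X", "2014-05-01", "diagnosis", "ICD9", "401.9")])
        w = cp.ObservationWindow("X", date(2010, 1, 1), date(2013, 12, 31))
        assert cp.facts_per_year(ds, w) == 0.25

    def test_vectorized_rates_match_scalar(self, toy_dataset):
        windows = cp.qualifying_windows(toy_dataset.enrollment)
        rates = cp.claims.facts_per_year_table(toy_dataset.events, windows)
        for mid, rate in rates.items():
            start = windows.set_index("member_id").loc[mid, "start"].date()
            w = cp.ObservationWindow(mid, start,
                                     (pd.Timestamp(start) + pd.Timedelta(days=1460)).date())
            assert rate == cp.facts_per_year(toy_dataset, w)
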