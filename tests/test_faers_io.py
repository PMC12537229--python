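"""Table reading, date parsing, case deduplication and dataset assembly."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.faers_io import (
    AnalysisConfig,
    SchemaError,
    assemble_dataset,
    deduplicate,
    filter_primary_suspect,
    normalize_age_years,
    parse_faers_date,
    read_table,
    reporter_category,
)


# ---------------------------------------------------------------- read_table

def test_read_table_parses_and_trims(tmp_path):
    p = tmp_path / "DEMO.txt"
    p.write_text("primaryid$caseid$fda_dt$sex\n1001$100$20220315$F\n")
    df = read_table(p, "DEMO")
    assert len(df) == 1
    assert df.iloc[0]["sex"] == "F"
    assert df.iloc[0]["fda_dt"] == "20220315"


def test_read_table_header_only_is_empty(tmp_path):
    p = tmp_path / "DEMO.txt"
    p.write_text("primaryid$caseid$fda_dt$sex\n")
    assert read_table(p, "DEMO").empty


def test_read_table_empty_fields_become_missing(tmp_path):
    p = tmp_path / "DEMO.txt"
    p.write_text("primaryid$caseid$fda_dt$sex\n1001$100$20220315$\n")
    assert pd.isna(read_table(p, "DEMO").iloc[0]["sex"])


def test_read_table_missing_required_column(tmp_path):
    p = tmp_path / "DRUG.txt"
    p.write_text("primaryid$drugname\n1$X\n")
    with pytest.raises(SchemaError, match="role_cod"):
        read_table(p, "DRUG")


# ---------------------------------------------------------- parse_faers_date

@pytest.mark.parametrize(
    "raw, date, precision",
    [
        ("20220315", dt.date(2022, 3, 15), "day"),
        ("202203", dt.date(2022, 3, 1), "month"),
        ("2022", dt.date(2022, 1, 1), "year"),
        ("", None, "missing"),
        (None, None, "missing"),
        ("20220230", None, "missing"),  # invalid calendar date
    ],
)
def test_parse_faers_date(raw, date, precision):
    parsed = parse_faers_date(raw)
    assert parsed.date == date
    assert parsed.precision == precision


def test_parse_faers_date_rejects_nondigit():
    with pytest.raises(ValueError):
        parse_faers_date("2022-03-15")


# --------------------------------------------------------------- deduplicate

def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])


def test_dedup_keeps_latest_fda_then_highest_primaryid():
    demo = _demo([("1001", "100", "20220101"),
                  ("1002", "100", "20220301"),
                  ("1003", "100", "20220301")])
    kept = deduplicate(demo)
    assert list(kept["primaryid"]) == ["1003"]


def test_dedup_single_record_is_identity():
    demo = _demo([("1001", "100", "20220101")])
    assert deduplicate(demo).equals(demo)


def test_dedup_numeric_primaryid_tiebreak():
    # lexicographically "999" > "1000" but numerically 1000 wins
    demo = _demo([("999", "1", "20220101"), ("1000", "1", "20220101")])
    assert list(deduplicate(demo)["primaryid"]) == ["1000"]


@st.composite
def demo_tables(draw):
    n = draw(st.integers(1, 25))
    rows = []
    for i in range(n):
        caseid = str(draw(st.integers(1, 8)))
        fda = draw(st.sampled_from(["20220101", "20220301", "20230515", "2022"]))
        rows.append((str(1000 + i), caseid, fda))
    return _demo(rows)


@settings(deadline=None, max_examples=50)
@given(demo_tables())
def test_dedup_idempotent_and_counts_distinct_cases(demo):
    once = deduplicate(demo)
    assert once["caseid"].nunique() == demo["caseid"].nunique() == len(once)
    assert deduplicate(once).equals(once)


# ------------------------------------------------- filter_primary_suspect

def _drugs(rows):
    return pd.DataFrame(rows, columns=["primaryid", "drugname", "role_cod"])


def test_ps_filter_role_and_normalization():
    drugs = _drugs([("1001", "TYRVAYA", "PS"), ("1002", "TYRVAYA", "C"),
                    ("1003", "tyrvaya ", "PS")])
    assert filter_primary_suspect(drugs, {"TYRVAYA"}) == {"1001", "1003"}


def test_ps_filter_exact_mode_does_not_substring_match():
    drugs = _drugs([("1", "VARENICLINE NASAL SPRAY", "PS"), ("2", "VARENICLINE", "PS")])
    got = filter_primary_suspect(drugs, {"TYRVAYA", "VARENICLINE NASAL SPRAY"})
    assert got == {"1"}


def test_ps_filter_substring_mode():
    drugs = _drugs([("1", "TYRVAYA 0.03MG", "PS")])
    assert filter_primary_suspect(drugs, {"TYRVAYA"}) == set()
    assert filter_primary_suspect(drugs, {"TYRVAYA"}, substring=True) == {"1"}


def test_ps_filter_empty_synonyms_is_error():
    with pytest.raises(ValueError):
        filter_primary_suspect(_drugs([("1", "X", "PS")]), set())


# ------------------------------------------------------- field normalization

@pytest.mark.parametrize(
    "age, cod, years",
    [("45", "YR", 45.0), ("6", "DEC", 60.0), ("18", "MON", 1.5),
     ("730.5", "DY", 2.0), ("45", None, 45.0), ("300", "YR", None),
     ("-1", "YR", None), (None, "YR", None)],
)
def test_age_normalization(age, cod, years):
    got = normalize_age_years(age, cod)
    if years is None:
        assert got is None
    else:
        assert got == pytest.approx(years)


@pytest.mark.parametrize("cod, cat", [("CN", "consumer"), ("MD", "physician"),
                                      ("PH", "pharmacist"), ("HP", "health_professional"),
                                      ("OT", "health_professional"), (None, "missing"),
                                      ("XX", "missing")])
def test_reporter_mapping(cod, cat):
    assert reporter_category(cod) == cat


# ----------------------------------------------------------- assemble_dataset

def test_assemble_toy_fixture_counts(toy_tables, toy_config):
    ds = assemble_dataset(toy_tables["DEMO"], toy_tables["DRUG"],
                          toy_tables["REAC"], toy_tables["THER"], toy_config)
    assert ds.counts["raw_demo_rows"] == 4
    assert ds.counts["dedup_cases"] == 3
    assert ds.counts["ps_cases"] == 2
    assert len(ds.cases) == 2
    # target pairs: 1002 -> {SNEEZING, COUGH}; 2001 -> {HEADACHE} (dup collapses)
    assert ds.counts["target_pairs"] == 3
    assert ds.counts["total_pairs"] == 4
    assert ds.target_ids == {"1002", "2001"}
    case = ds.cases.set_index("primaryid").loc["2001"]
    assert case["reporter_category"] == "physician"
    assert case["report_year"] == 2022
    assert case["age_years"] == 70.0


def test_assemble_window_excluding_everything(toy_tables):
    cfg = AnalysisConfig(window_start="19900101", window_end="19901231")
    ds = assemble_dataset(toy_tables["DEMO"], toy_tables["DRUG"],
                          toy_tables["REAC"], toy_tables["THER"], cfg)
    assert ds.cases.empty and ds.counts["windowed_cases"] == 0


def test_assemble_monotone_under_tighter_window(toy_tables, toy_config):
    wide = assemble_dataset(toy_tables["DEMO"], toy_tables["DRUG"],
                            toy_tables["REAC"], toy_tables["THER"], toy_config)
    tight = assemble_dataset(
        toy_tables["DEMO"], toy_tables["DRUG"], toy_tables["REAC"],
        toy_tables["THER"],
        AnalysisConfig(window_start="20220101", window_end="20221231"),
    )
    assert len(tight.cases) <= len(wide.cases)
    # case 300 (fda 2023) drops out of the windowed background
    assert tight.counts["windowed_cases"] == 2


def test_assemble_roundtrip_through_ascii(toy_tables, toy_dir, toy_config):
    tables = {k: read_table(toy_dir / f"{k}.txt", k) for k in toy_tables}
    direct = assemble_dataset(toy_tables["DEMO"], toy_tables["DRUG"],
                              toy_tables["REAC"], toy_tables["THER"], toy_config)
    reread = assemble_dataset(tables["DEMO"], tables["DRUG"], tables["REAC"],
                              tables["THER"], toy_config)
    assert direct.counts == reread.counts
    pd.testing.assert_frame_equal(direct.cases, reread.cases)
    pd.testing.assert_frame_equal(
        direct.reactions.reset_index(drop=True), reread.reactions.reset_index(drop=True)
    )


def test_assemble_month_precision_dates_window_by_period_start(toy_tables):
    demo = toy_tables["DEMO"].copy()
    demo.loc[demo["primaryid"] == "2001", "fda_dt"] = "202204"  # month precision
    cfg = AnalysisConfig(window_start="20220401", window_end="20220430")
    ds = assemble_dataset(demo, toy_tables["DRUG"], toy_tables["REAC"],
                          toy_tables["THER"], cfg)
    assert ds.counts["windowed_cases"] == 1
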